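"""Two-sample Kolmogorov-Smirnov comparison used for spot-count statistics."""

from __future__ import annotations

import numpy as np
from scipy import stats as _scipy_stats

__all__ = ["ks_two_sample"]


def ks_two_sample(sample_a, sample_b, method: str = "auto") -> tuple[float, float]:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b| and its p-value.

    ``method`` is ``"exact"`` (enumeration of the D distribution, feasible for
    small samples), ``"asymp"`` (Kolmogorov asymptotics with the standard
    two-sample effective size) or ``"auto"`` (exact when ``n_a * n_b <=
    10_000``).  Both samples need at least two values.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    if method not in ("auto", "exact", "asymp"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        method = "exact" if len(a) * len(b) <= 10_000 else "asymp"
    res = _scipy_stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
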