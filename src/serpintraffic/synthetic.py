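"""Synthetic inputs with known ground truth for every pipeline stage.

:func:`generate_pla_pair` emulates a proximity-ligation-assay acquisition: a
nuclei channel of smooth elliptical blobs and a spot channel of
diffraction-limited Gaussian puncta placed in the cytoplasmic region around
each nucleus, degraded by Poisson shot noise plus Gaussian read noise.  The
planted truth (spot centroids and effective areas, nucleus geometry, the
spots-per-cell ratio) is returned and can be serialized next to the images.

:func:`generate_ks_samples` draws seeded replicate sample pairs for
calibrating the Kolmogorov-Smirnov test under null and alternative
hypotheses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["GroundTruth", "generate_pla_pair", "generate_ks_samples", "write_pla_pair", "read_pla_pair"]

_BACKGROUND = 200.0  # camera counts
_NUCLEUS_AMPLITUDE = 3000.0
_READ_NOISE_SD = 3.0


@dataclass
class GroundTruth:
    """Planted content of one synthetic PLA image pair."""

    spot_centroids: np.ndarray  # (n, 2) as (y, x)
    spot_sigma_px: float
    spot_area_px: float  # area above half-maximum of one planted spot
    spot_amplitude: float
    nucleus_centers: np.ndarray  # (m, 2) as (y, x)
    nucleus_axes: np.ndarray  # (m, 2) semi-axes (a, b)
    spots_per_cell: float
    snr: float
    seed: int
    image_size: tuple[int, int]

    @property
    def n_spots(self) -> int:
        return len(self.spot_centroids)

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_centers)


def _peak_amplitude(snr: float, background: float, read_sd: float) -> float:
    """Amplitude A with peak SNR = A / sqrt(A + background + read_sd^2).

    Noise at the peak combines Poisson shot noise of (signal + background)
    with the Gaussian read noise.
    """
    c = background + read_sd**2
    return 0.5 * (snr**2 + snr * math.sqrt(snr**2 + 4.0 * c))


def _poisson_disk(rng, n, region_mask, min_sep, margin, shape, max_tries=20_000):
    """Rejection-sample n points inside region_mask, pairwise >= min_sep apart."""
    ys, xs = np.nonzero(region_mask)
    if len(ys) == 0:
        raise ValueError("no admissible region for spot placement")
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} spots with separation {min_sep:.1f}px "
                f"in the available region"
            )
        k = rng.integers(len(ys))
        y = ys[k] + rng.uniform(-0.5, 0.5)
        x = xs[k] + rng.uniform(-0.5, 0.5)
        if not (margin <= y < shape[0] - margin and margin <= x < shape[1] - margin):
            continue
        if all((y - py) ** 2 + (x - px) ** 2 >= min_sep**2 for py, px in pts):
            pts.append((y, x))
    return np.array(pts).reshape(-1, 2)


def generate_pla_pair(
    n_nuclei: int,
    spots_per_cell: float,
    psf_sigma_px: float = 2.0,
    snr: float = 8.0,
    image_size: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Synthetic (spots image, nuclei image, truth) triple, 16-bit, seeded.

    Spots are Gaussian puncta of width ``psf_sigma_px`` placed within the
    cells' cytoplasmic disks with pairwise separation >= 4 sigma and a border
    margin of 3 sigma; ``snr`` is the planted peak signal over the total
    noise standard deviation at the peak.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w]

    nuclei_clean = np.zeros((h, w))
    centers = []
    axes = []
    placed = 0
    tries = 0
    while placed < n_nuclei:
        tries += 1
        if tries > 10_000:
            raise ValueError(f"could not place {n_nuclei} nuclei in a {h}x{w} image")
        a = rng.uniform(8, 12)
        b = a * rng.uniform(0.85, 1.0)
        cy, cx = rng.uniform(3 * a, h - 3 * a), rng.uniform(3 * a, w - 3 * a)
        if any((cy - py) ** 2 + (cx - px) ** 2 < (5.5 * max(a, b)) ** 2 for py, px in centers):
            continue
        centers.append((cy, cx))
        axes.append((a, b))
        phi = rng.uniform(0, math.pi)
        c, s = math.cos(phi), math.sin(phi)
        u = (yy - cy) * c + (xx - cx) * s
        v = -(yy - cy) * s + (xx - cx) * c
        d2 = (u / a) ** 2 + (v / b) ** 2
        nuclei_clean += _NUCLEUS_AMPLITUDE / (1.0 + np.exp(np.clip(8.0 * (d2 - 1.0), -60.0, 60.0)))
        placed += 1
    centers_arr = np.array(centers).reshape(-1, 2)
    axes_arr = np.array(axes).reshape(-1, 2)

    # cytoplasm: disks around nuclei where PLA spots may occur
    cell_mask = np.zeros((h, w), dtype=bool)
    for (cy, cx), (a, b) in zip(centers, axes):
        cell_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 < (3.0 * max(a, b)) ** 2

    amplitude = _peak_amplitude(snr, _BACKGROUND, _READ_NOISE_SD)
    n_spots = int(round(n_nuclei * spots_per_cell))
    margin = 3.0 * psf_sigma_px
    if n_spots > 0:
        pts = _poisson_disk(rng, n_spots, cell_mask, 4.0 * psf_sigma_px, margin, (h, w))
    else:
        pts = np.zeros((0, 2))
    spots_clean = np.zeros((h, w))
    for y, x in pts:
        spots_clean += amplitude * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * psf_sigma_px**2)
        )

    def corrupt(clean):
        img = rng.poisson(clean + _BACKGROUND).astype(np.float64)
        img += rng.normal(0.0, _READ_NOISE_SD, clean.shape)
        return np.clip(np.round(img), 0, 65535).astype(np.uint16)

    truth = GroundTruth(
        spot_centroids=pts,
        spot_sigma_px=psf_sigma_px,
        spot_area_px=math.pi * (psf_sigma_px * math.sqrt(2.0 * math.log(2.0))) ** 2,
        spot_amplitude=amplitude,
        nucleus_centers=centers_arr,
        nucleus_axes=axes_arr,
        spots_per_cell=spots_per_cell,
        snr=snr,
        seed=seed,
        image_size=(h, w),
    )
    return corrupt(spots_clean), corrupt(nuclei_clean), truth


def write_pla_pair(
    outdir, spots_img: np.ndarray, nuclei_img: np.ndarray, truth: GroundTruth, stem: str = "pla"
) -> dict[str, Path]:
    """Serialize the pair as 16-bit TIFFs plus CSV/JSON ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "spots": outdir / f"{stem}_spots.tif",
        "nuclei": outdir / f"{stem}_nuclei.tif",
        "truth_spots": outdir / f"{stem}_truth_spots.csv",
        "truth_nuclei": outdir / f"{stem}_truth_nuclei.csv",
        "meta": outdir / f"{stem}_meta.json",
    }
    tifffile.imwrite(paths["spots"], spots_img)
    tifffile.imwrite(paths["nuclei"], nuclei_img)
    pd.DataFrame(truth.spot_centroids, columns=["y", "x"]).to_csv(paths["truth_spots"], index=False)
    nuc = pd.DataFrame(
        np.hstack([truth.nucleus_centers, truth.nucleus_axes]),
        columns=["y", "x", "semi_axis_a", "semi_axis_b"],
    )
    nuc.to_csv(paths["truth_nuclei"], index=False)
    meta = {
        k: v
        for k, v in asdict(truth).items()
        if k not in ("spot_centroids", "nucleus_centers", "nucleus_axes")
    }
    paths["meta"].write_text(json.dumps(meta, indent=2, default=float) + "\n")
    return paths


def read_pla_pair(outdir, stem: str = "pla"):
    """Round-trip loader for :func:`write_pla_pair` outputs."""
    outdir = Path(outdir)
    spots_img = tifffile.imread(outdir / f"{stem}_spots.tif")
    nuclei_img = tifffile.imread(outdir / f"{stem}_nuclei.tif")
    spot_truth = pd.read_csv(outdir / f"{stem}_truth_spots.csv")
    nuc_truth = pd.read_csv(outdir / f"{stem}_truth_nuclei.csv")
    meta = json.loads((outdir / f"{stem}_meta.json").read_text())
    truth = GroundTruth(
        spot_centroids=spot_truth[["y", "x"]].to_numpy().reshape(-1, 2),
        spot_sigma_px=meta["spot_sigma_px"],
        spot_area_px=meta["spot_area_px"],
        spot_amplitude=meta["spot_amplitude"],
        nucleus_centers=nuc_truth[["y", "x"]].to_numpy().reshape(-1, 2),
        nucleus_axes=nuc_truth[["semi_axis_a", "semi_axis_b"]].to_numpy().reshape(-1, 2),
        spots_per_cell=meta["spots_per_cell"],
        snr=meta["snr"],
        seed=int(meta["seed"]),
        image_size=tuple(meta["image_size"]),
    )
    return spots_img, nuclei_img, truth


_DISTRIBUTIONS = {
    "normal": lambda rng, p, n: rng.normal(p[0], p[1], n),
    "lognormal": lambda rng, p, n: rng.lognormal(p[0], p[1], n),
    "empirical": lambda rng, p, n: rng.choice(np.asarray(p, dtype=float), size=n, replace=True),
}


def generate_ks_samples(spec_a, spec_b, n_a: int, n_b: int, replicates: int, seed: int = 0):
    """Seeded replicate sample pairs for KS calibration.

    A spec is ``("normal", mu, sigma)``, ``("lognormal", mu, sigma)`` or
    ``("empirical", values)``.  Returns a list of ``(a, b)`` array pairs.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("sample sizes must be >= 2")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    pairs = []
    for r in range(replicates):
        rng = np.random.default_rng(np.random.SeedSequence((seed, r)))
        out = []
        for spec, n in ((spec_a, n_a), (spec_b, n_b)):
            name, *params = spec
            if name not in _DISTRIBUTIONS:
                raise ValueError(f"unknown distribution {name!r}")
            arg = params[0] if name == "empirical" else params
            out.append(_DISTRIBUTIONS[name](rng, arg, n))
        pairs.append(tuple(out))
    return pairs
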