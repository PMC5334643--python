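"""Budding-outcome classification and the stiffness/adhesion phase diagram.

A finished run is classified from its final configuration:

* **detached** — the coat-membrane adhesion energy is weaker than the
  elastic scale (``|E_adh| < detach_energy``): the interface is mechanically
  broken.  (At zero temperature a released coat still *rests* against the
  membrane, so detachment is scored by binding energy rather than by a purely
  geometric contact count.)
* **vesicle** — the membrane bud wraps at least ``wrap_min`` radians around
  the circle fitted to the coat contact patch *and* the membrane flanks
  bounding the bud pinch to within ``neck_max`` (a closed neck);
* **stable_no_vesicle** — bound interface, but the bud never closes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import VesicleTrajectory, integrate
from .model import CouplingParams, Protocol, init_system

PHASE_VESICLE = "vesicle"
PHASE_STABLE = "stable_no_vesicle"
PHASE_DETACHED = "detached"


@dataclass(frozen=True)
class OutcomePhase:
    """Classification of one budding run with its diagnostics."""

    label: str
    wrap_angle: float  # radians of the fitted bud circle covered by the membrane
    neck_gap: float  # closest approach of the membrane flanks bounding the bud
    attached_fraction: float
    adhesion_energy: float = math.nan  # coat-membrane binding energy (model units)
    failed: bool = False

    def __post_init__(self) -> None:
        if self.label not in (PHASE_VESICLE, PHASE_STABLE, PHASE_DETACHED, "failed"):
            raise ValueError(f"unknown phase label {self.label!r}")


def _fit_circle(points: np.ndarray) -> tuple[float, float]:
    """Algebraic (Kasa) least-squares circle fit; returns the center."""
    A = np.column_stack([2.0 * points[:, 0], 2.0 * points[:, 1], np.ones(len(points))])
    rhs = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return float(sol[0]), float(sol[1])


def _adhesion_energy(mem: np.ndarray, sca_adhesive: np.ndarray, params: CouplingParams) -> float:
    """Truncated-and-shifted LJ binding energy of the adhesive coat nodes."""
    if len(sca_adhesive) == 0:
        return 0.0
    d2 = ((sca_adhesive[:, None, :] - mem[None, :, :]) ** 2).sum(axis=2)
    mask = d2 < params.r_cut**2
    if not mask.any():
        return 0.0
    s6 = (params.sigma**2 / d2[mask]) ** 3
    sc6 = (params.sigma / params.r_cut) ** 6
    shift = 4.0 * params.eps_LJ * (sc6 * sc6 - sc6)
    return float((4.0 * params.eps_LJ * (s6 * s6 - s6) - shift).sum())


def _bud_wrap(mem: np.ndarray, contact: np.ndarray) -> float:
    """Angular coverage of the bud: membrane nodes near the circle fitted to the contact patch."""
    pts = mem[contact]
    if len(pts) < 3:
        return 0.0
    cx, cy = _fit_circle(pts)
    r_fit = float(np.sqrt(((pts - (cx, cy)) ** 2).sum(axis=1)).mean())
    rad = np.sqrt((mem[:, 0] - cx) ** 2 + (mem[:, 1] - cy) ** 2)
    sel = mem[rad <= 1.4 * r_fit]
    if len(sel) < 3:
        return 0.0
    ang = np.sort(np.arctan2(sel[:, 1] - cy, sel[:, 0] - cx))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2.0 * math.pi]]))
    return float(2.0 * math.pi - gaps.max())


def _neck_gap(mem: np.ndarray, min_ring_sep: int = 12) -> float:
    """Closest approach of membrane nodes that are distant along the chain.

    A closed bud shows up as two far-apart (along the ring) nodes nearly in
    contact: the neck.  Pairs closer than ``min_ring_sep`` along the ring are
    ignored so ordinary curvature does not register as a pinch.
    """
    n = len(mem)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    ring_sep = np.minimum(sep, n - sep)
    d = np.sqrt(((mem[:, None, :] - mem[None, :, :]) ** 2).sum(axis=2))
    eligible = ring_sep >= min_ring_sep
    if not eligible.any():
        return math.inf
    return float(d[eligible].min())


def classify_outcome(
    trajectory: VesicleTrajectory,
    params: CouplingParams,
    wrap_min: float = 5.0 * math.pi / 3.0,
    neck_max: float | None = None,
    detach_energy: float = 1.0,
) -> OutcomePhase:
    """Label a completed run as vesicle / stable_no_vesicle / detached."""
    if not trajectory.ok:
        return OutcomePhase("failed", math.nan, math.nan, math.nan, failed=True)
    mem = trajectory.final_membrane
    sca = trajectory.final_scaffold
    cap = min(params.cap_nodes, len(sca) // 2)
    sca = sca[cap : len(sca) - cap]  # adhesion acts through the inner coat nodes
    neck_max = 1.5 * params.sigma if neck_max is None else neck_max
    d = sca[:, None, :] - mem[None, :, :]
    dist = np.sqrt((d**2).sum(axis=2))
    attached = float((dist.min(axis=1) < params.r_cut).mean())
    contact = dist.min(axis=0) < params.r_cut  # per membrane node
    e_adh = _adhesion_energy(mem, sca, params)
    wrap = _bud_wrap(mem, contact)
    neck = _neck_gap(mem)
    if e_adh > -detach_energy:
        return OutcomePhase(PHASE_DETACHED, wrap, neck, attached, e_adh)
    if wrap >= wrap_min and neck <= neck_max:
        return OutcomePhase(PHASE_VESICLE, wrap, neck, attached, e_adh)
    return OutcomePhase(PHASE_STABLE, wrap, neck, attached, e_adh)


def run_point(
    km_over_ks: float,
    eps_over_ks: float,
    N_m: int = 100,
    K_s: float = 1.0,
    protocol: Protocol | None = None,
    seed: int = 0,
    scaffold_bond: float | None = None,
    **classify_kwargs,
) -> tuple[OutcomePhase, VesicleTrajectory]:
    """Initialize, integrate and classify a single phase-diagram point."""
    params = CouplingParams(eps_LJ=eps_over_ks * K_s)
    membrane, scaffold = init_system(
        N_m=N_m,
        K_m=km_over_ks * K_s,
        K_s=K_s,
        params=params,
        seed=seed,
        scaffold_bond=scaffold_bond,
        relax_tol=1e-4,
    )
    if protocol is None:
        # tighten the coat ring slightly past full closure
        protocol = Protocol(theta_s_target=1.05 * 2.0 * math.pi / (scaffold.n_nodes - 2))
    traj = integrate(membrane, scaffold, params, protocol, seed=seed)
    return classify_outcome(traj, params, **classify_kwargs), traj


def phase_diagram(
    km_over_ks_values,
    eps_over_ks_values,
    N_m: int = 100,
    protocol: Protocol | None = None,
    seed: int = 0,
    **classify_kwargs,
) -> pd.DataFrame:
    """Classify one run per grid point; failed runs are flagged, not fatal."""
    km_vals, eps_vals = list(km_over_ks_values), list(eps_over_ks_values)
    if len(km_vals) < 3 or len(eps_vals) < 3:
        raise ValueError("phase diagram grid must be at least 3x3")
    rows = []
    for i, km in enumerate(km_vals):
        for j, eps in enumerate(eps_vals):
            pt_seed = int(np.random.SeedSequence((seed, i, j)).generate_state(1)[0])
            outcome, traj = run_point(
                km, eps, N_m=N_m, protocol=protocol, seed=pt_seed, **classify_kwargs
            )
            rows.append(
                {
                    "Km_over_Ks": float(km),
                    "eps_over_Ks": float(eps),
                    "phase": outcome.label,
                    "wrap_angle": outcome.wrap_angle,
                    "neck_gap": outcome.neck_gap,
                    "attached_fraction": outcome.attached_fraction,
                    "adhesion_energy": outcome.adhesion_energy,
                    "max_strain": traj.max_strain,
                    "failed": outcome.failed,
                }
            )
    return pd.DataFrame(rows)


def membrane_self_intersects(mem: np.ndarray) -> bool:
    """Segment-intersection test on the closed membrane polygon."""
    n = len(mem)
    segs = [(mem[i], mem[(i + 1) % n]) for i in range(n)]

    def ccw(a, b, c):
        return (c[1] - a[1]) * (b[0] - a[0]) > (b[1] - a[1]) * (c[0] - a[0])

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            a, b = segs[i]
            c, d = segs[j]
            if ccw(a, c, d) != ccw(b, c, d) and ccw(a, b, c) != ccw(a, b, d):
                return True
    return False
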