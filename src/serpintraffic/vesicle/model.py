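"""Domain types and energies of the membrane/scaffold budding model.

Both chains are polygons of near-inextensible bonds (stiff harmonic springs,
penalty method) resisting bending through an angular spring
``E = sum_v K/2 (theta_v - theta0)^2`` in the turn (exterior) angle.  A
closed chain sums over all vertices, an open chain over its interior ones.
The coat adheres to the membrane through a truncated-and-shifted 12-6
Lennard-Jones potential acting node-to-node, and the membrane carries a short
purely repulsive (WCA) self-exclusion that prevents unphysical
self-crossing at the bud neck.  All energies here are plain numpy reference
implementations; :mod:`serpintraffic.vesicle.dynamics` provides the matching
analytic forces for the integrator and is tested against finite differences
of these functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np


@dataclass
class ElasticChain:
    """A 2D polygon chain: closed (membrane) or open (scaffold)."""

    positions: np.ndarray  # (N, 2) float64
    bond_length: float
    K: float  # bending stiffness, energy units
    theta0: float  # equilibrium turn angle, radians
    closed: bool
    bond_stiffness: float = 2000.0  # penalty-spring stiffness (energy / length^2)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array")
        if self.n_nodes < 3:
            raise ValueError("chain needs at least 3 nodes")
        if self.bond_length <= 0 or self.K < 0 or self.bond_stiffness <= 0:
            raise ValueError("bond_length and bond_stiffness must be positive, K >= 0")

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    def bonds(self) -> np.ndarray:
        """Bond vectors; N for a closed chain, N-1 for an open one."""
        p = self.positions
        if self.closed:
            return np.roll(p, -1, axis=0) - p
        return p[1:] - p[:-1]

    def turn_angles(self) -> np.ndarray:
        """Signed exterior angles; N for closed chains, N-2 for open ones."""
        b = self.bonds()
        if np.any(np.linalg.norm(b, axis=1) == 0):
            raise ValueError("degenerate zero-length bond")
        u = b if self.closed else b[:-1]
        v = np.roll(b, -1, axis=0) if self.closed else b[1:]
        cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
        dot = (u * v).sum(axis=1)
        return np.arctan2(cross, dot)

    def copy(self) -> "ElasticChain":
        return replace(self, positions=self.positions.copy())


@dataclass(frozen=True)
class CouplingParams:
    """Coat-membrane adhesion (LJ) and excluded-volume terms.

    ``cap_nodes`` terminal scaffold nodes at each end are the coat's rim and
    are purely repulsive (WCA at the same ``sigma``): the membrane binds the
    coat's inner face, not its edge, which keeps it from curling around the
    coat ends to reach the non-physical outer face.
    """

    eps_LJ: float = 1.0
    sigma: float = 1.0
    r_cut: float = 2.5
    eps_excluded: float = 1.0
    sigma_excluded: float = 0.9
    cap_nodes: int = 1
    sigma_cap: float = 1.2  # rim-node WCA radius

    def __post_init__(self) -> None:
        if self.eps_LJ < 0:
            raise ValueError("eps_LJ must be >= 0")
        if self.r_cut <= self.sigma:
            raise ValueError("r_cut must exceed sigma")
        if self.eps_excluded < 0 or self.sigma_excluded <= 0:
            raise ValueError("invalid excluded-volume parameters")
        if self.cap_nodes < 0:
            raise ValueError("cap_nodes must be >= 0")


@dataclass(frozen=True)
class Protocol:
    """Ramp-and-hold schedule for the scaffold's preferred turn angle."""

    theta_s_target: float
    ramp_steps: int = 100_000
    hold_steps: int = 600_000
    dt: float | None = None  # None -> stability-bound default
    gamma: float = 0.3
    record_every: int = 5_000

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.ramp_steps < 0 or self.hold_steps < 0:
            raise ValueError("step counts must be >= 0")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")

    def resolved_dt(self, chain: ElasticChain) -> float:
        if self.dt is not None:
            return self.dt
        # unit node mass; the stiff bond springs set the fastest mode
        dt_bond = 0.25 / math.sqrt(2.0 * chain.bond_stiffness)
        dt_bend = 0.05 * chain.bond_length / math.sqrt(max(chain.K, 1e-12))
        return min(dt_bond, dt_bend)


# ---------------------------------------------------------------------------
# energies (numpy reference implementations)
# ---------------------------------------------------------------------------


def bending_energy(chain: ElasticChain) -> float:
    """Angular-spring energy sum(K/2 (theta_v - theta0)^2) over the chain's vertices."""
    th = chain.turn_angles()
    return float(0.5 * chain.K * ((th - chain.theta0) ** 2).sum())


def bond_energy(chain: ElasticChain) -> float:
    """Penalty-spring energy of bond-length deviations."""
    ln = np.linalg.norm(chain.bonds(), axis=1)
    return float(0.5 * chain.bond_stiffness * ((ln - chain.bond_length) ** 2).sum())


def _lj_shifted(r2: np.ndarray, eps: float, sigma: float, r_cut: float) -> np.ndarray:
    s2 = sigma * sigma / r2
    s6 = s2 * s2 * s2
    sc2 = (sigma / r_cut) ** 2
    sc6 = sc2**3
    u_shift = 4.0 * eps * (sc6 * sc6 - sc6)
    return 4.0 * eps * (s6 * s6 - s6) - u_shift


def coupling_energy(membrane: ElasticChain, scaffold: ElasticChain, params: CouplingParams) -> float:
    """Coat-membrane interaction energy over all node pairs.

    Adhesive scaffold nodes contribute the truncated-and-shifted 12-6 LJ;
    the ``cap_nodes`` rim nodes at each end contribute a WCA repulsion at the
    same ``sigma``.
    """
    d = scaffold.positions[:, None, :] - membrane.positions[None, :, :]
    r2 = (d**2).sum(axis=2)
    if np.any(r2 == 0.0):
        raise ValueError("overlapping scaffold and membrane nodes (r = 0)")
    ns = scaffold.n_nodes
    cap = min(params.cap_nodes, ns // 2)
    adhesive = np.zeros(ns, dtype=bool)
    adhesive[cap : ns - cap] = True
    e = 0.0
    mask = adhesive[:, None] & (r2 < params.r_cut**2)
    if mask.any():
        e += float(_lj_shifted(r2[mask], params.eps_LJ, params.sigma, params.r_cut).sum())
    rc_cap = 2.0 ** (1.0 / 6.0) * params.sigma_cap
    mask_cap = (~adhesive)[:, None] & (r2 < rc_cap**2)
    if mask_cap.any():
        e += float(_lj_shifted(r2[mask_cap], params.eps_excluded, params.sigma_cap, rc_cap).sum())
    return e


def excluded_volume_energy(membrane: ElasticChain, params: CouplingParams) -> float:
    """WCA repulsion between non-bonded membrane node pairs (self-crossing guard)."""
    n = membrane.n_nodes
    p = membrane.positions
    rc = 2.0 ** (1.0 / 6.0) * params.sigma_excluded
    e = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            if membrane.closed and i == 0 and j == n - 1:
                continue  # ring-adjacent pair
            r2 = ((p[i] - p[j]) ** 2).sum()
            if r2 < rc * rc:
                e += _lj_shifted(np.array([r2]), params.eps_excluded, params.sigma_excluded, rc)[0]
    return float(e)


def total_energy(membrane: ElasticChain, scaffold: ElasticChain, params: CouplingParams) -> float:
    """Full conservative energy: bending + bonds + adhesion + self-exclusion."""
    return (
        bending_energy(membrane)
        + bending_energy(scaffold)
        + bond_energy(membrane)
        + bond_energy(scaffold)
        + coupling_energy(membrane, scaffold, params)
        + excluded_volume_energy(membrane, params)
    )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def init_system(
    N_m: int = 100,
    ratio: int = 10,
    b: float = 1.0,
    scaffold_bond: float | None = None,
    K_m: float = 1.0,
    K_s: float = 1.0,
    params: CouplingParams | None = None,
    seed: int = 0,
    jitter: float = 1e-8,
    relax: bool = True,
    relax_tol: float = 1e-6,
) -> tuple[ElasticChain, ElasticChain]:
    """Pseudo-circular equilibrium: regular membrane polygon plus unstressed coat arc.

    The membrane is a regular ``N_m``-gon of side ``b``; the scaffold's
    ``N_s = N_m / ratio`` nodes sit on a concentric circle one LJ minimum
    distance outside it, with its preferred turn angle set to its actual
    geometry so that, after a short damped micro-relaxation, the net force on
    every node is below ``relax_tol``.  The coat subunits are an order of
    magnitude larger than the membrane's quasi-lipid nodes (``scaffold_bond``
    defaults to ``10 b``, the size ratio behind ``N_m / N_s = 10``), so the
    coat arc spans most of the membrane perimeter and each coat node acts as
    an adhesion pin whose grip does not depend on the local curvature.
    """
    if N_m < 40:
        raise ValueError("N_m must be >= 40")
    N_s = N_m // ratio
    if N_s < 4:
        raise ValueError("scaffold too short: N_m / ratio must be >= 4")
    b_s = 10.0 * b if scaffold_bond is None else scaffold_bond
    params = params or CouplingParams(sigma=b, r_cut=2.5 * b)
    rng = np.random.default_rng(seed)

    R = b / (2.0 * math.sin(math.pi / N_m))
    ang = 2.0 * math.pi * np.arange(N_m) / N_m
    mem_pos = R * np.stack([np.cos(ang), np.sin(ang)], axis=1)

    Rs = R + 2.0 ** (1.0 / 6.0) * params.sigma
    dphi = 2.0 * math.asin(b_s / (2.0 * Rs))
    phis = (np.arange(N_s) - (N_s - 1) / 2.0) * dphi
    sca_pos = Rs * np.stack([np.cos(phis), np.sin(phis)], axis=1)

    mem_pos += rng.uniform(-jitter, jitter, mem_pos.shape)
    sca_pos += rng.uniform(-jitter, jitter, sca_pos.shape)

    membrane = ElasticChain(mem_pos, bond_length=b, K=K_m, theta0=0.0, closed=True)
    scaffold = ElasticChain(sca_pos, bond_length=b_s, K=K_s, theta0=dphi, closed=False)

    if relax:
        from .dynamics import relax_to_equilibrium

        relax_to_equilibrium(membrane, scaffold, params, tol=relax_tol)
    return membrane, scaffold
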