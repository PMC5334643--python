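"""Reference (pure-Python) semantics of the lattice aggregation model.

This module defines the domain types and the exact event semantics of the
kinetic Monte Carlo model: every possible event, its propensity, and how it
transforms the state.  It is the readable, object-level definition that the
fast array kernel in :mod:`serpintraffic.aggregation.engine` must agree with
(an agreement that is asserted by the test-suite).  Use it directly for
small systems and for inspecting event catalogues; use
:func:`~serpintraffic.aggregation.engine.run_until` for production runs.

Model summary
-------------
Monomer-sized protein units live on a cubic lattice, periodic in x and y and
closed in z.  Units enter at empty sites of the two z-boundary layers with
rate ``k_in`` per site and leave from the boundaries with rate
``k_out / i**3`` where ``i`` is the size of the entity (``i = 1`` for a free
monomer; a polymer is ejectable when any of its sites touches a boundary
layer).  Free monomers diffuse (``k_D`` per free neighbouring site), are
activated (``k_A``) and may then turn latent (``k_L``); latent monomers never
bond.  Bonds form at rate ``k_H`` between lattice-adjacent units when both
are bondable (free monomer or polymer endpoint) and at least one is an
active monomer or already polymerized.  Polymers relax by reptation
(``k_R / i**2`` per feasible slide), end rotation (``k_E``) and kink flips
(``k_K``), and fragment at any internal bond with rate ``k_f``.  Time is
measured in units of ``1 / k_in``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

INACTIVE = "inactive"
ACTIVE = "active"
LATENT = "latent"

#: axis-direction order used everywhere: +x, -x, +y, -y, +z, -z
DIRECTIONS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
POSITIVE_DIRS = (0, 2, 4)

RATE_NAMES = ("k_in", "k_out", "k_D", "k_H", "k_R", "k_E", "k_K", "k_f", "k_A", "k_L")


class AbsorbingStateError(RuntimeError):
    """Raised when no event is possible (total propensity is zero)."""


@dataclass(frozen=True)
class RateSet:
    """The ten kinetic rate constants, in units of ``k_in``."""

    k_in: float = 1.0
    k_out: float = 1.0
    k_D: float = 10.0
    k_H: float = 10.0
    k_R: float = 1.0
    k_E: float = 1.0
    k_K: float = 1.0
    k_f: float = 0.01
    k_A: float = 1.0
    k_L: float = 0.0

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"rate {name} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RATE_NAMES], dtype=np.float64)

    def with_kout(self, k_out: float) -> "RateSet":
        return replace(self, k_out=k_out)


@dataclass(frozen=True)
class LatticeConfig:
    """Cubic-lattice geometry: periodic in x/y, closed in z."""

    Lx: int = 100
    Ly: int = 100
    Lz: int = 25

    def __post_init__(self) -> None:
        for name in ("Lx", "Ly", "Lz"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 2:
                raise ValueError(f"lattice dimension {name} must be an integer >= 2, got {v!r}")

    @property
    def n_sites(self) -> int:
        return self.Lx * self.Ly * self.Lz

    @property
    def n_boundary_sites(self) -> int:
        # the z = 0 and z = Lz-1 layers (Lz >= 2, so always two distinct layers)
        return 2 * self.Lx * self.Ly

    def is_boundary(self, pos: tuple[int, int, int]) -> bool:
        return pos[2] == 0 or pos[2] == self.Lz - 1

    def in_bounds(self, pos: tuple[int, int, int]) -> bool:
        x, y, z = pos
        return 0 <= x < self.Lx and 0 <= y < self.Ly and 0 <= z < self.Lz

    def neighbor(self, pos: tuple[int, int, int], d: int) -> Optional[tuple[int, int, int]]:
        """Neighbour of ``pos`` along direction index ``d``; None past a z-wall."""
        dx, dy, dz = DIRECTIONS[d]
        z = pos[2] + dz
        if z < 0 or z >= self.Lz:
            return None
        return ((pos[0] + dx) % self.Lx, (pos[1] + dy) % self.Ly, z)

    def neighbors(self, pos: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        out = []
        for d in range(6):
            n = self.neighbor(pos, d)
            if n is not None:
                out.append(n)
        return out

    def wrap(self, pos: tuple[int, int, int]) -> tuple[int, int, int]:
        return (pos[0] % self.Lx, pos[1] % self.Ly, pos[2])

    def displacement(self, a: tuple[int, int, int], b: tuple[int, int, int]) -> tuple[int, int, int]:
        """Minimal-image displacement from a to b (assumes |disp| <= 1 per axis)."""

        def axis(da: int, L: int) -> int:
            if da > L // 2:
                da -= L
            elif da < -(L // 2):
                da += L
            # for L == 2 the two images coincide; use +1 by convention
            if L == 2 and da == -1:
                da = 1
            return da

        return (
            axis(b[0] - a[0], self.Lx),
            axis(b[1] - a[1], self.Ly),
            b[2] - a[2],
        )


@dataclass
class Monomer:
    position: tuple[int, int, int]
    state: str = INACTIVE

    def __post_init__(self) -> None:
        if self.state not in (INACTIVE, ACTIVE, LATENT):
            raise ValueError(f"unknown monomer state {self.state!r}")


@dataclass
class Polymer:
    """An ordered self-avoiding chain of nearest-neighbour lattice sites."""

    sites: list[tuple[int, int, int]]

    @property
    def size(self) -> int:
        return len(self.sites)

    def validate(self, config: LatticeConfig) -> None:
        if self.size < 2:
            raise ValueError("polymer must contain at least 2 sites")
        if len(set(self.sites)) != self.size:
            raise ValueError("polymer repeats a site (self-avoidance violated)")
        for s in self.sites:
            if not config.in_bounds(s):
                raise ValueError(f"polymer site {s} out of bounds")
        for a, b in zip(self.sites, self.sites[1:]):
            d = config.displacement(a, b)
            if sorted(map(abs, d)) != [0, 0, 1]:
                raise ValueError(f"polymer sites {a} and {b} are not lattice-adjacent")

    def ends(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        return self.sites[0], self.sites[-1]


@dataclass
class SimState:
    """Full simulation state: entities, clock and the mass ledger."""

    config: LatticeConfig
    monomers: dict[int, Monomer] = field(default_factory=dict)
    polymers: dict[int, Polymer] = field(default_factory=dict)
    t: float = 0.0
    injected: int = 0
    ejected: int = 0
    _next_id: int = 0

    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id

    def occupancy(self) -> dict[tuple[int, int, int], tuple]:
        occ: dict[tuple[int, int, int], tuple] = {}
        for i, m in self.monomers.items():
            if m.position in occ:
                raise ValueError(f"double occupancy at {m.position}")
            occ[m.position] = ("m", i)
        for j, p in self.polymers.items():
            for k, s in enumerate(p.sites):
                if s in occ:
                    raise ValueError(f"double occupancy at {s}")
                occ[s] = ("p", j, k)
        return occ

    @property
    def n_units(self) -> int:
        return len(self.monomers) + sum(p.size for p in self.polymers.values())

    def check_invariants(self) -> None:
        """Assert single occupancy, self-avoidance, bounds and the mass ledger."""
        occ = self.occupancy()  # raises on double occupancy
        for m in self.monomers.values():
            if not self.config.in_bounds(m.position):
                raise ValueError(f"monomer out of bounds at {m.position}")
        for p in self.polymers.values():
            p.validate(self.config)
        if self.injected - self.ejected != self.n_units:
            raise ValueError(
                f"mass ledger broken: injected - ejected = {self.injected - self.ejected} "
                f"but state holds {self.n_units} units"
            )
        del occ

    def add_monomer(self, pos: tuple[int, int, int], state: str = INACTIVE) -> int:
        i = self.new_id()
        self.monomers[i] = Monomer(pos, state)
        return i

    def add_polymer(self, sites: Iterable[tuple[int, int, int]]) -> int:
        j = self.new_id()
        self.polymers[j] = Polymer(list(sites))
        return j


@dataclass
class Trajectory:
    """Sampled aggregate counts along a run."""

    times: np.ndarray
    aggregate_counts: np.ndarray
    min_size: int
    n_units: np.ndarray
    n_monomers: np.ndarray
    injected: np.ndarray
    ejected: np.ndarray
    absorbed: bool = False
    final_state: Optional[SimState] = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.aggregate_counts < 0):
            raise ValueError("aggregate counts must be >= 0")


@dataclass(frozen=True)
class Event:
    kind: str
    info: tuple
    propensity: float


@dataclass
class EventList:
    events: list[Event]

    @property
    def total(self) -> float:
        return float(sum(e.propensity for e in self.events))

    def by_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]


def init_state(config: LatticeConfig) -> SimState:
    """Empty lattice at t = 0 with zeroed ledgers."""
    return SimState(config=config)


# ---------------------------------------------------------------------------
# event catalogue
# ---------------------------------------------------------------------------


def _bondable(entry: tuple, state: SimState) -> bool:
    """A unit can form a new bond if it is a non-latent free monomer or a chain endpoint."""
    if entry[0] == "m":
        return state.monomers[entry[1]].state != LATENT
    _, j, k = entry
    return k == 0 or k == state.polymers[j].size - 1


def _pair_eligible(a: tuple, b: tuple, state: SimState) -> bool:
    """Bond eligibility: both bondable, not same chain, at least one active/polymerized."""
    if not (_bondable(a, state) and _bondable(b, state)):
        return False
    if a[0] == "p" and b[0] == "p" and a[1] == b[1]:
        return False  # ring closure of a single chain is not allowed
    activated = False
    for e in (a, b):
        if e[0] == "p" or state.monomers[e[1]].state == ACTIVE:
            activated = True
    return activated


def event_catalogue(state: SimState, rates: RateSet) -> EventList:
    """Enumerate every currently possible event with its propensity.

    Infeasible moves (into occupied sites, past closed walls) never enter the
    catalogue, so no rejection sampling is needed downstream.
    """
    cfg = state.config
    occ = state.occupancy()
    events: list[Event] = []

    # injection at empty boundary sites
    if rates.k_in > 0:
        for z in (0, cfg.Lz - 1):
            for x in range(cfg.Lx):
                for y in range(cfg.Ly):
                    pos = (x, y, z)
                    if pos not in occ:
                        events.append(Event("inject", (pos,), rates.k_in))

    # monomer events
    for i, m in state.monomers.items():
        pos = m.position
        if rates.k_D > 0:
            for d in range(6):
                n = cfg.neighbor(pos, d)
                if n is not None and n not in occ:
                    events.append(Event("diffuse", (i, n, d), rates.k_D))
        if m.state == INACTIVE and rates.k_A > 0:
            events.append(Event("activate", (i,), rates.k_A))
        if m.state == ACTIVE and rates.k_L > 0:
            events.append(Event("latent", (i,), rates.k_L))
        if cfg.is_boundary(pos) and rates.k_out > 0:
            events.append(Event("eject", (("m", i),), rates.k_out))

    # bond formation: one event per unordered adjacent eligible pair.
    # Enumerate each lattice edge once via positive directions.
    if rates.k_H > 0:
        for pos, entry in occ.items():
            for d in POSITIVE_DIRS:
                n = cfg.neighbor(pos, d)
                if n is None or n not in occ:
                    continue
                other = occ[n]
                if _pair_eligible(entry, other, state):
                    events.append(Event("bond", (entry, other, pos, n), rates.k_H))

    # polymer events
    for j, p in state.polymers.items():
        i = p.size
        # reptation: chain slides one site toward a free site adjacent to either end
        if rates.k_R > 0:
            for end, end_pos in ((0, p.sites[0]), (1, p.sites[-1])):
                for d in range(6):
                    n = cfg.neighbor(end_pos, d)
                    if n is not None and n not in occ:
                        events.append(Event("reptate", (j, end, n), rates.k_R / i**2))
        # end rotation: endpoint relocates to a free site adjacent to its neighbour
        if rates.k_E > 0:
            for end, end_pos, nb_pos in ((0, p.sites[0], p.sites[1]), (1, p.sites[-1], p.sites[-2])):
                for d in range(6):
                    n = cfg.neighbor(nb_pos, d)
                    if n is not None and n not in occ:
                        events.append(Event("end_rotate", (j, end, n), rates.k_E))
        # kink: a 90-degree corner flips across the diagonal to the free complementary site
        if rates.k_K > 0:
            for k in range(1, i - 1):
                a, s, b = p.sites[k - 1], p.sites[k], p.sites[k + 1]
                da = cfg.displacement(s, a)
                db = cfg.displacement(s, b)
                if sum(x * y for x, y in zip(da, db)) != 0:
                    continue  # collinear, not a corner
                comp_z = s[2] + da[2] + db[2]
                if comp_z < 0 or comp_z >= cfg.Lz:
                    continue
                comp = cfg.wrap((s[0] + da[0] + db[0], s[1] + da[1] + db[1], comp_z))
                if comp not in occ:
                    events.append(Event("kink", (j, k, comp), rates.k_K))
        # fragmentation at any internal bond
        if rates.k_f > 0:
            for b in range(i - 1):
                events.append(Event("fragment", (j, b), rates.k_f))
        # ejection of a boundary-touching polymer (whole entity, one event)
        if rates.k_out > 0 and any(cfg.is_boundary(s) for s in p.sites):
            events.append(Event("eject", (("p", j),), rates.k_out / i**3))

    return EventList(events)


# ---------------------------------------------------------------------------
# event application
# ---------------------------------------------------------------------------


def apply_event(state: SimState, event: Event) -> None:
    """Apply ``event`` to ``state`` in place (does not advance the clock)."""
    kind = event.kind
    if kind == "inject":
        state.add_monomer(event.info[0], INACTIVE)
        state.injected += 1
    elif kind == "diffuse":
        i, target = event.info[0], event.info[1]
        state.monomers[i].position = target
    elif kind == "activate":
        state.monomers[event.info[0]].state = ACTIVE
    elif kind == "latent":
        state.monomers[event.info[0]].state = LATENT
    elif kind == "bond":
        _apply_bond(state, event.info)
    elif kind == "reptate":
        j, end, target = event.info
        p = state.polymers[j]
        if end == 0:
            p.sites = [target] + p.sites[:-1]
        else:
            p.sites = p.sites[1:] + [target]
    elif kind == "end_rotate":
        j, end, target = event.info
        p = state.polymers[j]
        if end == 0:
            p.sites[0] = target
        else:
            p.sites[-1] = target
    elif kind == "kink":
        j, k, comp = event.info
        state.polymers[j].sites[k] = comp
    elif kind == "fragment":
        _apply_fragment(state, *event.info)
    elif kind == "eject":
        (ekind, idx) = event.info[0]
        if ekind == "m":
            del state.monomers[idx]
            state.ejected += 1
        else:
            state.ejected += state.polymers[idx].size
            del state.polymers[idx]
    else:  # pragma: no cover
        raise ValueError(f"unknown event kind {kind!r}")


def _apply_bond(state: SimState, info: tuple) -> None:
    a, b, pos_a, pos_b = info
    if a[0] == "m" and b[0] == "m":
        del state.monomers[a[1]], state.monomers[b[1]]
        state.add_polymer([pos_a, pos_b])
        return
    if a[0] == "m" or b[0] == "m":
        (mono, mpos), (poly, _ppos) = ((a, pos_a), (b, pos_b)) if a[0] == "m" else ((b, pos_b), (a, pos_a))
        del state.monomers[mono[1]]
        p = state.polymers[poly[1]]
        if poly[2] == 0:
            p.sites.insert(0, mpos)
        else:
            p.sites.append(mpos)
        return
    # endpoint-to-endpoint join of two distinct chains
    pa, pb = state.polymers[a[1]], state.polymers[b[1]]
    sa = pa.sites if a[2] != 0 else pa.sites[::-1]  # orient so the joining end is last
    sb = pb.sites if b[2] == 0 else pb.sites[::-1]  # ...and first
    del state.polymers[a[1]], state.polymers[b[1]]
    state.add_polymer(sa + sb)


def _apply_fragment(state: SimState, j: int, b: int) -> None:
    p = state.polymers.pop(j)
    left, right = p.sites[: b + 1], p.sites[b + 1 :]
    for part in (left, right):
        if len(part) == 1:
            state.add_monomer(part[0], ACTIVE)  # size-1 fragments stay activated
        else:
            state.add_polymer(part)


# ---------------------------------------------------------------------------
# stepping and counting
# ---------------------------------------------------------------------------


def gillespie_step(
    state: SimState, rates: RateSet, rng: np.random.Generator
) -> tuple[SimState, float]:
    """Draw one exact-stochastic event and apply it atomically.

    The waiting time ``dt`` is exponential with rate equal to the total
    propensity and the event is chosen with probability proportional to its
    propensity.  Raises :class:`AbsorbingStateError` when nothing can happen.
    """
    catalogue = event_catalogue(state, rates)
    total = catalogue.total
    if total <= 0:
        raise AbsorbingStateError("no event is possible (total propensity is zero)")
    dt = rng.exponential(1.0 / total)
    r = rng.random() * total
    acc = 0.0
    chosen = catalogue.events[-1]
    for ev in catalogue.events:
        acc += ev.propensity
        if r < acc:
            chosen = ev
            break
    apply_event(state, chosen)
    state.t += dt
    return state, dt


def count_aggregates(state: SimState, min_size: int) -> int:
    """Number of polymers with size >= ``min_size`` (free monomers never count)."""
    if not isinstance(min_size, (int, np.integer)) or min_size < 2:
        raise ValueError(f"min_size must be an integer >= 2, got {min_size!r}")
    return sum(1 for p in state.polymers.values() if p.size >= min_size)
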