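"""Reference-semantics tests of the lattice aggregation model.

The event catalogue is checked event-by-event against an independent
brute-force enumerator written directly from the model rules; stepping is
checked against the exact-stochastic laws (exponential waiting times,
propensity-proportional selection).
"""

import collections
import math

import numpy as np
import pytest

from serpintraffic.aggregation import (
    ACTIVE,
    INACTIVE,
    LATENT,
    AbsorbingStateError,
    LatticeConfig,
    RateSet,
    count_aggregates,
    event_catalogue,
    gillespie_step,
    init_state,
)
from conftest import random_state

# ---------------------------------------------------------------------------
# independent brute-force enumerator (the oracle)
# ---------------------------------------------------------------------------


def oracle_events(state, rates):
    """Naive, direct enumeration of every possible event as canonical tuples."""
    cfg = state.config
    occ = state.occupancy()
    out = []

    def is_bondable(e):
        if e[0] == "m":
            return state.monomers[e[1]].state != LATENT
        return e[2] in (0, state.polymers[e[1]].size - 1)

    def is_activated(e):
        return e[0] == "p" or state.monomers[e[1]].state == ACTIVE

    all_sites = [
        (x, y, z) for x in range(cfg.Lx) for y in range(cfg.Ly) for z in range(cfg.Lz)
    ]
    # injection at empty boundary sites
    if rates.k_in > 0:
        for pos in all_sites:
            if pos[2] in (0, cfg.Lz - 1) and pos not in occ:
                out.append(("inject", pos, rates.k_in))
    # free monomers
    for i, m in state.monomers.items():
        if rates.k_D > 0:
            for d in range(6):
                n = cfg.neighbor(m.position, d)
                if n is not None and n not in occ:
                    out.append(("diffuse", m.position, n, rates.k_D))
        if m.state == INACTIVE and rates.k_A > 0:
            out.append(("activate", m.position, rates.k_A))
        if m.state == ACTIVE and rates.k_L > 0:
            out.append(("latent", m.position, rates.k_L))
        if m.position[2] in (0, cfg.Lz - 1) and rates.k_out > 0:
            out.append(("eject_m", m.position, rates.k_out))
    # bonds: each lattice edge once, via positive directions
    if rates.k_H > 0:
        for pos in all_sites:
            if pos not in occ:
                continue
            a = occ[pos]
            for d in (0, 2, 4):
                n = cfg.neighbor(pos, d)
                if n is None or n not in occ:
                    continue
                b = occ[n]
                if not (is_bondable(a) and is_bondable(b)):
                    continue
                if a[0] == "p" and b[0] == "p" and a[1] == b[1]:
                    continue
                if is_activated(a) or is_activated(b):
                    out.append(("bond", pos, n, rates.k_H))
    # polymers
    for j, p in state.polymers.items():
        i = p.size
        for end_pos, nb_pos in ((p.sites[0], p.sites[1]), (p.sites[-1], p.sites[-2])):
            if rates.k_R > 0:
                for d in range(6):
                    n = cfg.neighbor(end_pos, d)
                    if n is not None and n not in occ:
                        out.append(("reptate", end_pos, n, rates.k_R / i**2))
            if rates.k_E > 0:
                for d in range(6):
                    n = cfg.neighbor(nb_pos, d)
                    if n is not None and n not in occ:
                        out.append(("end_rotate", end_pos, n, rates.k_E))
        if rates.k_K > 0:
            for k in range(1, i - 1):
                a, s, b = p.sites[k - 1], p.sites[k], p.sites[k + 1]
                # a genuine 90-degree corner: a and b must not be the two
                # opposite-direction neighbours of s along one axis
                collinear = any(
                    {a, b} == {cfg.neighbor(s, d), cfg.neighbor(s, d + 1)}
                    for d in (0, 2, 4)
                    if cfg.neighbor(s, d) is not None and cfg.neighbor(s, d + 1) is not None
                )
                if collinear:
                    continue
                # the flip target is the common neighbour of both chain
                # neighbours other than the corner site itself
                common = set(cfg.neighbors(a)) & set(cfg.neighbors(b)) - {s}
                for comp in common:
                    if comp not in occ:
                        out.append(("kink", s, comp, rates.k_K))
        if rates.k_f > 0:
            for b in range(i - 1):
                pair = tuple(sorted((p.sites[b], p.sites[b + 1])))
                out.append(("fragment", pair, rates.k_f))
        if rates.k_out > 0 and any(s[2] in (0, cfg.Lz - 1) for s in p.sites):
            out.append(("eject_p", tuple(sorted(p.sites)), rates.k_out / i**3))
    return out


def canon(state, ev):
    """Canonical tuple form of an implementation event, for oracle comparison."""
    if ev.kind == "inject":
        return ("inject", ev.info[0], ev.propensity)
    if ev.kind == "diffuse":
        return ("diffuse", state.monomers[ev.info[0]].position, ev.info[1], ev.propensity)
    if ev.kind in ("activate", "latent"):
        return (ev.kind, state.monomers[ev.info[0]].position, ev.propensity)
    if ev.kind == "bond":
        return ("bond", ev.info[2], ev.info[3], ev.propensity)
    if ev.kind in ("reptate", "end_rotate"):
        j, end, target = ev.info
        pos = state.polymers[j].sites[0 if end == 0 else -1]
        return (ev.kind, pos, target, ev.propensity)
    if ev.kind == "kink":
        j, k, comp = ev.info
        return ("kink", state.polymers[j].sites[k], comp, ev.propensity)
    if ev.kind == "fragment":
        j, b = ev.info
        sites = state.polymers[j].sites
        return ("fragment", tuple(sorted((sites[b], sites[b + 1]))), ev.propensity)
    if ev.kind == "eject":
        ekind, idx = ev.info[0]
        if ekind == "m":
            return ("eject_m", state.monomers[idx].position, ev.propensity)
        return ("eject_p", tuple(sorted(state.polymers[idx].sites)), ev.propensity)
    raise ValueError(ev.kind)


def assert_catalogue_matches_oracle(state, rates):
    cat = event_catalogue(state, rates)
    got = collections.Counter(canon(state, e) for e in cat.events)
    want = collections.Counter(oracle_events(state, rates))
    assert got == want


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def test_init_state_geometry():
    st = init_state(LatticeConfig(100, 100, 25))
    assert st.config.n_sites == 100 * 100 * 25
    assert st.config.n_boundary_sites == 2 * 100 * 100
    assert st.t == 0.0 and st.injected == 0 and st.ejected == 0 and st.n_units == 0
    # degenerate height: both layers are boundaries, every site is a boundary site
    tiny = LatticeConfig(2, 2, 2)
    assert tiny.n_sites == 8 and tiny.n_boundary_sites == 8
    assert all(tiny.is_boundary((x, y, z)) for x in range(2) for y in range(2) for z in range(2))


def test_init_state_rejects_thin_lattice():
    with pytest.raises(ValueError):
        LatticeConfig(1, 5, 5)


# ---------------------------------------------------------------------------
# event catalogue vs brute force
# ---------------------------------------------------------------------------


def test_catalogue_handcrafted_state_matches_bruteforce():
    """Handcrafted 3x3x3 state with two monomers and one dimer."""
    cfg = LatticeConfig(3, 3, 3)
    state = init_state(cfg)
    state.add_polymer([(0, 0, 1), (0, 1, 1)])
    state.add_monomer((2, 2, 0), ACTIVE)
    state.add_monomer((1, 1, 2), INACTIVE)
    state.injected = state.n_units
    state.check_invariants()
    assert_catalogue_matches_oracle(state, RateSet())


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize(
    "rates",
    [
        RateSet(),
        RateSet(k_L=0.5, k_out=3.0),
        RateSet(k_D=0.0, k_H=2.0, k_f=1.0),
    ],
    ids=["default", "with-latency", "no-diffusion"],
)
def test_catalogue_random_states_match_bruteforce(seed, rates):
    cfg = LatticeConfig(4, 4, 3)
    state = random_state(cfg, seed, n_monomers=5, chain_lengths=(2, 3, 4))
    assert_catalogue_matches_oracle(state, rates)


def test_dimer_reptation_rate_scales_inverse_square():
    """Reptation propensity of a dimer is k_R / 2**2 per feasible slot."""
    cfg = LatticeConfig(5, 5, 4)
    state = init_state(cfg)
    state.add_polymer([(2, 2, 1), (2, 3, 1)])
    state.injected = 2
    rates = RateSet(k_R=3.0)
    reptations = event_catalogue(state, rates).by_kind("reptate")
    assert reptations, "dimer with free neighbours must have reptation slots"
    for ev in reptations:
        assert ev.propensity == pytest.approx(3.0 / 4)


def test_trimer_boundary_ejection_rate_scales_inverse_cube():
    """A trimer touching a z-boundary is ejected with propensity k_out / 27."""
    cfg = LatticeConfig(5, 5, 4)
    state = init_state(cfg)
    state.add_polymer([(1, 1, 0), (1, 2, 0), (1, 3, 0)])
    state.injected = 3
    rates = RateSet(k_out=2.0)
    ejections = event_catalogue(state, rates).by_kind("eject")
    assert len(ejections) == 1
    assert ejections[0].propensity == pytest.approx(2.0 / 27)


def test_empty_lattice_only_injection():
    cfg = LatticeConfig(6, 5, 3)
    state = init_state(cfg)
    cat = event_catalogue(state, RateSet(k_in=0.7))
    assert all(e.kind == "inject" for e in cat.events)
    assert cat.total == pytest.approx(0.7 * cfg.n_boundary_sites)


def test_latent_monomers_never_bond():
    cfg = LatticeConfig(4, 4, 3)
    state = init_state(cfg)
    state.add_monomer((1, 1, 1), LATENT)
    state.add_monomer((1, 2, 1), ACTIVE)
    state.injected = 2
    cat = event_catalogue(state, RateSet())
    assert not cat.by_kind("bond")


def test_two_inactive_monomers_cannot_bond():
    cfg = LatticeConfig(4, 4, 3)
    state = init_state(cfg)
    state.add_monomer((1, 1, 1), INACTIVE)
    state.add_monomer((1, 2, 1), INACTIVE)
    state.injected = 2
    assert not event_catalogue(state, RateSet()).by_kind("bond")


# ---------------------------------------------------------------------------
# stepping laws
# ---------------------------------------------------------------------------


def _single_event_state():
    cfg = LatticeConfig(3, 3, 3)
    state = init_state(cfg)
    state.add_monomer((1, 1, 1), INACTIVE)
    state.injected = 1
    return state


def test_single_event_waiting_time_is_exponential():
    """One event with propensity R: mean dt -> 1/R within 3 standard errors."""
    R = 2.0
    rates = RateSet(k_in=0.0, k_D=0.0, k_H=0.0, k_R=0.0, k_E=0.0, k_K=0.0, k_f=0.0, k_A=R, k_L=0.0, k_out=0.0)
    rng = np.random.default_rng(42)
    n = 10_000
    dts = np.empty(n)
    for k in range(n):
        state = _single_event_state()
        _, dts[k] = gillespie_step(state, rates, rng)
        assert state.monomers[1].state == ACTIVE  # the only event fired
    se = dts.std(ddof=1) / math.sqrt(n)
    assert abs(dts.mean() - 1.0 / R) < 3 * se


def test_event_selection_proportional_to_propensity():
    """Two events with propensities 1 and 3: the second fires with frequency 3/4."""
    rates = RateSet(k_in=0.0, k_D=0.0, k_H=0.0, k_R=0.0, k_E=0.0, k_K=0.0, k_f=0.0, k_A=1.0, k_L=3.0, k_out=0.0)
    rng = np.random.default_rng(7)
    n = 10_000
    hits = 0
    for _ in range(n):
        cfg = LatticeConfig(3, 3, 3)
        state = init_state(cfg)
        state.add_monomer((0, 0, 1), INACTIVE)  # activation, propensity 1
        state.add_monomer((2, 2, 1), ACTIVE)  # latency, propensity 3
        state.injected = 2
        gillespie_step(state, rates, rng)
        if state.monomers[2].state == LATENT:
            hits += 1
    phat = hits / n
    ci = 4 * math.sqrt(0.75 * 0.25 / n)
    assert abs(phat - 0.75) < ci


def test_absorbing_state_raises():
    cfg = LatticeConfig(3, 3, 3)
    state = init_state(cfg)
    rates = RateSet(k_in=0.0, k_out=0.0)
    with pytest.raises(AbsorbingStateError):
        gillespie_step(state, rates, np.random.default_rng(0))


def test_invariants_hold_along_a_simulated_path():
    """Self-avoidance, single occupancy and the ledger survive every event."""
    cfg = LatticeConfig(3, 3, 3)
    state = init_state(cfg)
    rates = RateSet(k_out=0.5, k_f=0.5, k_L=0.2)
    rng = np.random.default_rng(11)
    for _ in range(600):
        gillespie_step(state, rates, rng)
        state.check_invariants()


# ---------------------------------------------------------------------------
# aggregate counting
# ---------------------------------------------------------------------------


def test_count_aggregates():
    cfg = LatticeConfig(12, 12, 4)
    state = init_state(cfg)
    assert count_aggregates(state, 2) == 0
    state.add_polymer([(0, 0, 1), (0, 1, 1)])
    state.add_polymer([(3 + k, 3, 1) for k in range(5)])
    state.add_polymer([(6, 1 + k, 2) for k in range(9)])
    state.add_monomer((10, 10, 1), ACTIVE)
    state.injected = state.n_units
    state.check_invariants()
    assert count_aggregates(state, 2) == 3
    assert count_aggregates(state, 6) == 1
    with pytest.raises(ValueError):
        count_aggregates(state, 1)


def test_bond_join_produces_valid_chain():
    """Endpoint-to-endpoint joins keep the chain ordered and self-avoiding."""
    from serpintraffic.aggregation import Event, apply_event

    cfg = LatticeConfig(6, 6, 3)
    state = init_state(cfg)
    a = state.add_polymer([(1, 1, 1), (1, 2, 1)])
    b = state.add_polymer([(2, 1, 1), (3, 1, 1), (3, 2, 1)])
    state.injected = state.n_units
    # join end (1,1,1) of chain a with end (2,1,1) of chain b
    apply_event(
        state,
        Event("bond", (("p", a, 0), ("p", b, 0), (1, 1, 1), (2, 1, 1)), 1.0),
    )
    assert len(state.polymers) == 1
    (poly,) = state.polymers.values()
    assert poly.size == 5
    poly.validate(cfg)
    state.check_invariants()


def test_fragmentation_yields_active_monomer():
    from serpintraffic.aggregation import Event, apply_event

    cfg = LatticeConfig(6, 6, 3)
    state = init_state(cfg)
    j = state.add_polymer([(1, 1, 1), (1, 2, 1), (1, 3, 1)])
    state.injected = 3
    apply_event(state, Event("fragment", (j, 1), 1.0))  # break the second bond
    assert len(state.polymers) == 1 and len(state.monomers) == 1
    (mono,) = state.monomers.values()
    assert mono.state == ACTIVE and mono.position == (1, 3, 1)
    state.check_invariants()
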