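"""Fast-kernel tests: agreement with the reference catalogue and exact laws.

The numba kernel maintains per-site anchored propensities incrementally; here
it is checked against the pure-Python catalogue on randomized states, against
a direct master-equation integration on a tiny lattice, and against exact
bookkeeping identities.
"""

import numpy as np
import pytest
from scipy.linalg import expm

from serpintraffic.aggregation import (
    LatticeConfig,
    RateSet,
    count_aggregates,
    event_catalogue,
    init_state,
    run_until,
    sweep_kout,
)
from serpintraffic.aggregation.engine import (
    catalogue_site_sums,
    site_propensities,
    state_to_arrays,
    arrays_to_state,
)
from conftest import random_state


@pytest.mark.parametrize("seed", range(10))
def test_kernel_propensities_match_reference_catalogue(seed):
    """Per-site anchored propensity sums agree between kernel and catalogue."""
    cfg = LatticeConfig(4, 4, 3)
    state = random_state(cfg, seed, n_monomers=6, chain_lengths=(2, 3, 4, 5))
    rates = RateSet(k_L=0.3, k_out=2.5, k_f=0.7)
    kernel = site_propensities(state, rates)
    reference = catalogue_site_sums(event_catalogue(state, rates), state)
    np.testing.assert_allclose(kernel, reference, rtol=1e-12, atol=1e-12)


def test_array_round_trip_preserves_state():
    cfg = LatticeConfig(5, 4, 3)
    state = random_state(cfg, 3, n_monomers=5, chain_lengths=(2, 4))
    st, nb1, nb2, clen, oend, bcnt = state_to_arrays(state)
    back = arrays_to_state(cfg, st, nb1, nb2, oend, injected=state.injected)
    assert {m.position: m.state for m in back.monomers.values()} == {
        m.position: m.state for m in state.monomers.values()
    }
    orig = {frozenset(p.sites) for p in state.polymers.values()}
    assert {frozenset(p.sites) for p in back.polymers.values()} == orig
    back.check_invariants()


def test_incremental_propensities_survive_audit():
    """Full propensity recomputation matches the incremental updates everywhere."""
    cfg = LatticeConfig(6, 6, 4)
    state = init_state(cfg)
    # audit raises if any stored propensity drifts from a fresh recomputation
    run_until(state, RateSet(k_out=1.0, k_L=0.1, k_f=0.1), t_max=4.0, record_every=1.0, seed=5, min_size=2, audit_interval=200)
    state.check_invariants()


def test_identical_seeds_give_identical_trajectories():
    cfg = LatticeConfig(8, 8, 5)
    rates = RateSet(k_out=1.0)
    runs = []
    for _ in range(2):
        state = init_state(cfg)
        traj = run_until(state, rates, t_max=3.0, record_every=0.5, seed=123, min_size=2)
        runs.append((traj, state))
    a, b = runs
    np.testing.assert_array_equal(a[0].aggregate_counts, b[0].aggregate_counts)
    np.testing.assert_array_equal(a[0].injected, b[0].injected)
    assert {m.position for m in a[1].monomers.values()} == {m.position for m in b[1].monomers.values()}
    assert {frozenset(p.sites) for p in a[1].polymers.values()} == {
        frozenset(p.sites) for p in b[1].polymers.values()
    }
    # a different seed must explore a different path
    state = init_state(cfg)
    other = run_until(state, rates, t_max=3.0, record_every=0.5, seed=124, min_size=2)
    assert not np.array_equal(other.injected, a[0].injected)


def test_mass_ledger_exact_at_every_sample():
    """injected - ejected equals the units in the system, exactly, always."""
    cfg = LatticeConfig(8, 8, 5)
    state = init_state(cfg)
    traj = run_until(state, RateSet(k_out=2.0, k_f=0.2), t_max=5.0, record_every=0.25, seed=9, min_size=2)
    np.testing.assert_array_equal(traj.injected - traj.ejected, traj.n_units)
    state.check_invariants()  # recount on the final state


def test_pure_injection_matches_exact_occupation_law():
    """With only injection active, each boundary site fills independently.

    The exact law is Binomial(B, 1 - exp(-k_in t)); the total count's mean is
    checked within three standard errors (this is the Poisson regime for
    k_in * t << 1).
    """
    cfg = LatticeConfig(6, 6, 4)
    rates = RateSet(k_in=1.0, k_out=0.0, k_D=0.0, k_H=0.0, k_R=0.0, k_E=0.0, k_K=0.0, k_f=0.0, k_A=0.0, k_L=0.0)
    t_obs, reps = 0.2, 400
    counts = np.empty(reps)
    for r in range(reps):
        state = init_state(cfg)
        run_until(state, rates, t_max=t_obs, record_every=t_obs, seed=1000 + r, min_size=2)
        counts[r] = state.n_units
        assert not state.polymers
    B = cfg.n_boundary_sites
    p = 1.0 - np.exp(-rates.k_in * t_obs)
    se = np.sqrt(B * p * (1 - p) / reps)
    assert abs(counts.mean() - B * p) < 3 * se


def test_small_lattice_matches_master_equation():
    """Injection/ejection-only dynamics on 2x2x2 vs. direct master-equation integration.

    All 8 sites are boundary sites; the occupation number n performs a birth-
    death process with birth rate (8-n) k_in and death rate n k_out.  The
    empirical distribution of n at a fixed time over many replicates must be
    within total-variation distance 0.02 of expm(Q t) applied to the empty
    state.
    """
    k_in, k_out, t_obs = 1.0, 2.0, 2.0
    B = 8
    Q = np.zeros((B + 1, B + 1))
    for n in range(B + 1):
        if n < B:
            Q[n + 1, n] += (B - n) * k_in
            Q[n, n] -= (B - n) * k_in
        if n > 0:
            Q[n - 1, n] += n * k_out
            Q[n, n] -= n * k_out
    p0 = np.zeros(B + 1)
    p0[0] = 1.0
    exact = expm(Q * t_obs) @ p0

    cfg = LatticeConfig(2, 2, 2)
    rates = RateSet(k_in=k_in, k_out=k_out, k_D=0.0, k_H=0.0, k_R=0.0, k_E=0.0, k_K=0.0, k_f=0.0, k_A=0.0, k_L=0.0)
    reps = 8000
    hist = np.zeros(B + 1)
    for r in range(reps):
        state = init_state(cfg)
        run_until(state, rates, t_max=t_obs, record_every=t_obs, seed=r, min_size=2)
        hist[state.n_units] += 1
    hist /= reps
    tv = 0.5 * np.abs(hist - exact).sum()
    assert tv < 0.02


def test_absorbing_run_is_padded_and_flagged():
    cfg = LatticeConfig(3, 3, 3)
    state = init_state(cfg)
    state.add_monomer((1, 1, 1))
    state.injected = 1
    dead = RateSet(k_in=0.0, k_out=0.0, k_D=0.0, k_H=0.0, k_R=0.0, k_E=0.0, k_K=0.0, k_f=0.0, k_A=0.0, k_L=0.0)
    traj = run_until(state, dead, t_max=2.0, record_every=0.5, seed=0, min_size=2)
    assert traj.absorbed
    assert len(traj.times) == 5
    np.testing.assert_array_equal(traj.n_units, np.ones(5))


def test_sweep_clearance_dominated_limit_and_accumulation():
    """Very fast clearance leaves (almost) no aggregates; zero clearance accumulates."""
    cfg = LatticeConfig(10, 10, 6)
    res = sweep_kout(
        [0.0, 10.0, 1e4],
        replicates=4,
        t_obs=4.0,
        rates=RateSet(),
        config=cfg,
        min_size=10,
        seed=2,
    )
    s = res.summary.set_index("k_out_over_k_in")["mean_aggregates"]
    assert s.loc[1e4] < 0.5  # clearance-dominated limit
    assert s.loc[0.0] > s.loc[1e4]
    # with k_out = 0 the aggregate count grows with observation time
    means = []
    for t_obs in (1.0, 3.0, 6.0):
        res_t = sweep_kout([0.0, 1.0, 2.0], replicates=3, t_obs=t_obs, rates=RateSet(), config=cfg, min_size=10, seed=3)
        means.append(res_t.summary.set_index("k_out_over_k_in")["mean_aggregates"].loc[0.0])
    assert means[0] < means[1] < means[2]


def test_sweep_table_sorted_and_validated():
    cfg = LatticeConfig(6, 6, 4)
    res = sweep_kout([5.0, 0.5, 50.0], replicates=3, t_obs=1.0, rates=RateSet(), config=cfg, min_size=2, seed=4)
    ratios = res.summary["k_out_over_k_in"].to_numpy()
    assert np.all(np.diff(ratios) > 0)
    with pytest.raises(ValueError):
        sweep_kout([1.0, 2.0], replicates=3, t_obs=1.0, rates=RateSet(), config=cfg, seed=0)
    with pytest.raises(ValueError):
        sweep_kout([1.0, 2.0, 3.0], replicates=2, t_obs=1.0, rates=RateSet(), config=cfg, seed=0)
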