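"""Elasticity closed forms, analytic forces vs finite differences, integrator checks."""

import math

import numpy as np
import pytest

from serpintraffic.vesicle import (
    CouplingParams,
    ElasticChain,
    Protocol,
    bending_energy,
    compute_forces,
    coupling_energy,
    init_system,
    integrate,
    total_energy,
)


def regular_polygon(n, side=1.0):
    R = side / (2.0 * math.sin(math.pi / n))
    ang = 2.0 * math.pi * np.arange(n) / n
    return R * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def test_straight_open_chain_has_zero_bending_energy():
    pos = np.column_stack([np.arange(10.0), np.zeros(10)])
    chain = ElasticChain(pos, bond_length=1.0, K=2.0, theta0=0.0, closed=False)
    assert bending_energy(chain) == pytest.approx(0.0, abs=1e-14)


def test_regular_hexagon_closed_form():
    chain = ElasticChain(regular_polygon(6), bond_length=1.0, K=1.0, theta0=0.0, closed=True)
    assert bending_energy(chain) == pytest.approx(math.pi**2 / 3.0, abs=1e-12)


@pytest.mark.parametrize("n", [5, 8, 12, 40])
def test_regular_polygon_matches_closed_form_and_spontaneous_curvature(n):
    """E = N (K/2)(2 pi/N - theta0)^2 for any regular N-gon; zero when matched."""
    K = 1.7
    pos = regular_polygon(n)
    chain = ElasticChain(pos, bond_length=1.0, K=K, theta0=0.0, closed=True)
    assert bending_energy(chain) == pytest.approx(n * K / 2.0 * (2 * math.pi / n) ** 2, rel=1e-12)
    matched = ElasticChain(pos, bond_length=1.0, K=K, theta0=2 * math.pi / n, closed=True)
    assert bending_energy(matched) == pytest.approx(0.0, abs=1e-12)


def test_degenerate_bond_rejected():
    pos = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
    chain = ElasticChain(pos, bond_length=1.0, K=1.0, theta0=0.0, closed=False)
    with pytest.raises(ValueError):
        bending_energy(chain)


def test_lj_minimum_and_cutoff():
    """A single pair at the LJ minimum has energy -eps (up to the cutoff shift)."""
    eps, sigma, r_cut = 2.0, 1.0, 2.5
    mem = ElasticChain(np.array([[0.0, 0.0], [50.0, 0.0], [100.0, 0.0]]), 1.0, 1.0, 0.0, closed=False)
    r_min = 2.0 ** (1.0 / 6.0) * sigma
    sca = ElasticChain(
        np.array([[0.0, r_min], [200.0, 0.0], [300.0, 0.0]]), 1.0, 1.0, 0.0, closed=False
    )
    params = CouplingParams(eps_LJ=eps, sigma=sigma, r_cut=r_cut, cap_nodes=0)
    sc6 = (sigma / r_cut) ** 6
    shift = 4.0 * eps * (sc6**2 - sc6)
    assert coupling_energy(mem, sca, params) == pytest.approx(-eps - shift, rel=1e-12)
    # beyond the cutoff the interaction vanishes identically
    far = ElasticChain(np.array([[0.0, 3.0], [200.0, 0.0], [300.0, 0.0]]), 1.0, 1.0, 0.0, closed=False)
    assert coupling_energy(mem, far, params) == 0.0


def test_lj_two_pair_formula_oracle():
    """Two pairs at r1 = sigma and r2 = 1.5 sigma against direct evaluation."""
    eps, sigma, r_cut = 1.3, 1.0, 2.5

    def u(r):
        s6 = (sigma / r) ** 6
        sc6 = (sigma / r_cut) ** 6
        return 4 * eps * (s6**2 - s6) - 4 * eps * (sc6**2 - sc6)

    mem = ElasticChain(np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0]]), 1.0, 1.0, 0.0, closed=False)
    sca = ElasticChain(np.array([[0.0, 1.0], [100.0, 1.5], [300.0, 0.0]]), 1.0, 1.0, 0.0, closed=False)
    params = CouplingParams(eps_LJ=eps, sigma=sigma, r_cut=r_cut, cap_nodes=0)
    assert coupling_energy(mem, sca, params) == pytest.approx(u(1.0) + u(1.5), rel=1e-12)


def test_overlapping_nodes_rejected():
    mem = ElasticChain(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]), 1.0, 1.0, 0.0, closed=False)
    sca = ElasticChain(np.array([[0.0, 0.0], [5.0, 5.0], [6.0, 5.0]]), 1.0, 1.0, 0.0, closed=False)
    with pytest.raises(ValueError):
        coupling_energy(mem, sca, CouplingParams())


def test_init_system_geometry_and_equilibrium():
    """N_s = N_m/10; equal bonds; forces below 1e-6 after micro-relaxation."""
    params = CouplingParams()
    pristine, _ = init_system(N_m=60, ratio=10, params=params, seed=4, jitter=0.0, relax=False)
    lengths = np.linalg.norm(pristine.bonds(), axis=1)
    np.testing.assert_allclose(lengths, lengths[0], rtol=1e-12)
    membrane, scaffold = init_system(N_m=60, ratio=10, params=params, seed=4)
    assert scaffold.n_nodes == 6
    fm, fs, _, _ = compute_forces(membrane, scaffold, params)
    fmax = max(np.linalg.norm(fm, axis=1).max(), np.linalg.norm(fs, axis=1).max())
    assert fmax < 1e-6
    with pytest.raises(ValueError):
        init_system(N_m=39)
    with pytest.raises(ValueError):
        init_system(N_m=60, ratio=20)


def test_forces_match_finite_differences():
    """Analytic forces are the exact negative gradient of the total energy."""
    rng = np.random.default_rng(0)
    params = CouplingParams(eps_LJ=0.8)
    membrane, scaffold = init_system(N_m=40, params=params, seed=1, relax=False)
    membrane.positions += rng.normal(0, 0.02, membrane.positions.shape)
    scaffold.positions += rng.normal(0, 0.02, scaffold.positions.shape)
    scaffold.theta0 = 0.4  # stressed configuration
    fm, fs, _, _ = compute_forces(membrane, scaffold, params)
    h = 1e-6
    worst = 0.0
    for chain, f in ((membrane, fm), (scaffold, fs)):
        for i in range(chain.n_nodes):
            for d in range(2):
                orig = chain.positions[i, d]
                chain.positions[i, d] = orig + h
                ep = total_energy(membrane, scaffold, params)
                chain.positions[i, d] = orig - h
                em = total_energy(membrane, scaffold, params)
                chain.positions[i, d] = orig
                fd = -(ep - em) / (2 * h)
                scale = max(1.0, abs(f[i, d]))
                worst = max(worst, abs(fd - f[i, d]) / scale)
    assert worst < 1e-6


def test_energy_conserved_without_damping():
    """gamma = 0 velocity Verlet: relative energy drift < 1e-4 over 1e5 steps."""
    params = CouplingParams(eps_LJ=0.8)
    membrane, scaffold = init_system(N_m=60, params=params, seed=2, relax_tol=1e-4)
    membrane.positions[0, 0] += 0.05  # perturb to create motion
    proto = Protocol(
        theta_s_target=scaffold.theta0, ramp_steps=0, hold_steps=100_000,
        gamma=0.0, dt=0.0015, record_every=10_000,
    )
    traj = integrate(membrane, scaffold, params, proto)
    assert traj.ok
    E = traj.e_pot + traj.e_kin
    assert abs(E[-1] - E[0]) / abs(E[0]) < 1e-4


def test_stationary_at_equilibrium_with_damping():
    """Started at equilibrium with theta_s held, nothing moves."""
    params = CouplingParams(eps_LJ=0.5)
    membrane, scaffold = init_system(N_m=60, params=params, seed=3)
    start = membrane.positions.copy()
    proto = Protocol(theta_s_target=scaffold.theta0, ramp_steps=0, hold_steps=20_000, gamma=0.5)
    traj = integrate(membrane, scaffold, params, proto)
    disp = np.linalg.norm(traj.final_membrane - start, axis=1).max()
    assert disp < 1e-3 * membrane.bond_length
    assert traj.max_strain < 0.01
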