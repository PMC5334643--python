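import numpy as np
import pytest

from serpintraffic.aggregation import (
    ACTIVE,
    INACTIVE,
    LATENT,
    LatticeConfig,
    SimState,
    init_state,
)


def random_chain(cfg: LatticeConfig, rng: np.random.Generator, occupied: set, length: int):
    """A random self-avoiding nearest-neighbour chain on free sites, or None."""
    free = [
        (x, y, z)
        for x in range(cfg.Lx)
        for y in range(cfg.Ly)
        for z in range(cfg.Lz)
        if (x, y, z) not in occupied
    ]
    for _ in range(300):
        if not free:
            return None
        sites = [free[rng.integers(len(free))]]
        ok = True
        for _ in range(length - 1):
            cand = [
                n
                for n in cfg.neighbors(sites[-1])
                if n not in occupied and n not in sites
            ]
            if not cand:
                ok = False
                break
            sites.append(cand[rng.integers(len(cand))])
        if ok:
            occupied.update(sites)
            return sites
    return None


def random_state(
    cfg: LatticeConfig,
    seed: int,
    n_monomers: int = 4,
    chain_lengths=(2, 3),
) -> SimState:
    """A random valid state with mixed monomer states and self-avoiding chains."""
    rng = np.random.default_rng(seed)
    state = init_state(cfg)
    occupied: set = set()
    for length in chain_lengths:
        sites = random_chain(cfg, rng, occupied, length)
        if sites is not None:
            state.add_polymer(sites)
    states = [INACTIVE, ACTIVE, LATENT]
    free = [
        (x, y, z)
        for x in range(cfg.Lx)
        for y in range(cfg.Ly)
        for z in range(cfg.Lz)
        if (x, y, z) not in occupied
    ]
    rng.shuffle(free)
    for pos in free[:n_monomers]:
        state.add_monomer(pos, states[rng.integers(3)])
    state.injected = state.n_units  # satisfy the mass ledger for handmade states
    state.check_invariants()
    return state


@pytest.fixture
def small_config():
    return LatticeConfig(4, 4, 3)
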