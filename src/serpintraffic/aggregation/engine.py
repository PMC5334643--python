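"""Event-driven numba kernel for the lattice aggregation model.

The kernel keeps, for every lattice site, the summed propensity of all events
*anchored* at that site, maintains the sums incrementally after each event,
and samples events through a Fenwick (binary-indexed) tree in O(log N).
Anchoring rules (they only affect bookkeeping, not the physics):

* injection at the empty boundary site itself;
* monomer events (diffusion, activation, latency, ejection) at the monomer;
* bond formation at the first site of each lattice edge enumerated along the
  positive +x/+y/+z directions;
* fragmentation at the bond's lower-index site;
* kink flips at the corner site;
* end rotations and reptation slots at the respective chain endpoint;
* polymer ejection at the chain endpoint with the smaller site index.

Chain connectivity is stored as site-level links (``nb1``/``nb2``; an
endpoint has only ``nb1``).  Chain length, boundary-contact count and the
opposite-end pointer are cached at both endpoints so every propensity is a
local function of the site's neighbourhood.

The pure-Python catalogue in :mod:`serpintraffic.aggregation.model` is the
reference semantics; the test-suite asserts per-site agreement between the
two on randomized states, and the kernel's audit mode (full recomputation of
all propensities every ``audit_interval`` events) guards the incremental
updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .model import (
    ACTIVE,
    INACTIVE,
    LATENT,
    LatticeConfig,
    Polymer,
    RateSet,
    SimState,
    Trajectory,
    init_state,
)

# site-state codes
EMPTY, S_INACTIVE, S_ACTIVE, S_LATENT, S_POLY = 0, 1, 2, 3, 4
_STATE_CODE = {INACTIVE: S_INACTIVE, ACTIVE: S_ACTIVE, LATENT: S_LATENT}
_CODE_STATE = {v: k for k, v in _STATE_CODE.items()}

# rates array layout (matches model.RATE_NAMES)
R_IN, R_OUT, R_D, R_H, R_R, R_E, R_K, R_F, R_A, R_L = range(10)

_REBUILD_EVERY = 1 << 20


# ---------------------------------------------------------------------------
# lattice tables and state conversion
# ---------------------------------------------------------------------------


def build_tables(config: LatticeConfig) -> tuple[np.ndarray, np.ndarray]:
    """Neighbour table (N, 6) in +x,-x,+y,-y,+z,-z order and boundary flags."""
    Lx, Ly, Lz = config.Lx, config.Ly, config.Lz
    s = np.arange(config.n_sites)
    # site index s = x + Lx*(y + Ly*z)
    x = s % Lx
    y = (s // Lx) % Ly
    z = s // (Lx * Ly)

    def idx(xx, yy, zz):
        return xx + Lx * (yy + Ly * zz)

    N = config.n_sites
    nbr = np.full((N, 6), -1, dtype=np.int64)
    nbr[:, 0] = idx((x + 1) % Lx, y, z)
    nbr[:, 1] = idx((x - 1) % Lx, y, z)
    nbr[:, 2] = idx(x, (y + 1) % Ly, z)
    nbr[:, 3] = idx(x, (y - 1) % Ly, z)
    up, dn = z + 1 < Lz, z - 1 >= 0
    nbr[up, 4] = idx(x[up], y[up], z[up] + 1)
    nbr[dn, 5] = idx(x[dn], y[dn], z[dn] - 1)
    isb = ((z == 0) | (z == Lz - 1)).astype(np.uint8)
    return nbr, isb


def site_index(config: LatticeConfig, pos: tuple[int, int, int]) -> int:
    return pos[0] + config.Lx * (pos[1] + config.Ly * pos[2])


def site_pos(config: LatticeConfig, s: int) -> tuple[int, int, int]:
    x = s % config.Lx
    y = (s // config.Lx) % config.Ly
    z = s // (config.Lx * config.Ly)
    return (int(x), int(y), int(z))


def state_to_arrays(state: SimState):
    cfg = state.config
    N = cfg.n_sites
    st = np.zeros(N, dtype=np.uint8)
    nb1 = np.full(N, -1, dtype=np.int64)
    nb2 = np.full(N, -1, dtype=np.int64)
    clen = np.zeros(N, dtype=np.int64)
    oend = np.full(N, -1, dtype=np.int64)
    bcnt = np.zeros(N, dtype=np.int64)
    for m in state.monomers.values():
        s = site_index(cfg, m.position)
        if st[s] != EMPTY:
            raise ValueError(f"double occupancy at {m.position}")
        st[s] = _STATE_CODE[m.state]
    for p in state.polymers.values():
        idxs = [site_index(cfg, s) for s in p.sites]
        bc = sum(1 for s in p.sites if cfg.is_boundary(s))
        for k, s in enumerate(idxs):
            if st[s] != EMPTY:
                raise ValueError(f"double occupancy at {p.sites[k]}")
            st[s] = S_POLY
            if k > 0:
                nb1[s] = idxs[k - 1]
            if k < len(idxs) - 1:
                if k > 0:
                    nb2[s] = idxs[k + 1]
                else:
                    nb1[s] = idxs[k + 1]
        for e, o in ((idxs[0], idxs[-1]), (idxs[-1], idxs[0])):
            clen[e] = len(idxs)
            oend[e] = o
            bcnt[e] = bc
    return st, nb1, nb2, clen, oend, bcnt


def arrays_to_state(
    config: LatticeConfig,
    st: np.ndarray,
    nb1: np.ndarray,
    nb2: np.ndarray,
    oend: np.ndarray,
    t: float = 0.0,
    injected: int = 0,
    ejected: int = 0,
) -> SimState:
    state = SimState(config=config, t=t, injected=injected, ejected=ejected)
    for s in np.nonzero((st >= S_INACTIVE) & (st <= S_LATENT))[0]:
        state.add_monomer(site_pos(config, int(s)), _CODE_STATE[int(st[s])])
    ends = np.nonzero((st == S_POLY) & (nb2 < 0))[0]
    for s in ends:
        s = int(s)
        if s > int(oend[s]):
            continue  # visit each chain once from its canonical endpoint
        sites = [s]
        prev, cur = s, int(nb1[s])
        while cur >= 0:
            sites.append(cur)
            nxt = int(nb1[cur]) if int(nb1[cur]) != prev else int(nb2[cur])
            prev, cur = cur, nxt
        state.polymers[state.new_id()] = Polymer([site_pos(config, q) for q in sites])
    return state


# ---------------------------------------------------------------------------
# numba primitives
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _pcg32(rng):
    old = rng[0]
    rng[0] = old * np.uint64(6364136223846793005) + rng[1]
    xs = np.uint32(((old >> np.uint64(18)) ^ old) >> np.uint64(27))
    rot = np.uint32(old >> np.uint64(59))
    return np.uint32((xs >> rot) | (xs << ((np.uint32(32) - rot) & np.uint32(31))))


@njit(cache=True, inline="always")
def _rand(rng):
    # uniform in (0, 1]
    return (np.float64(_pcg32(rng)) + 1.0) * (1.0 / 4294967296.0)


@njit(cache=True)
def _seed_rng(rng, seed):
    rng[0] = np.uint64(0)
    rng[1] = (np.uint64(seed) << np.uint64(1)) | np.uint64(1)
    _pcg32(rng)
    rng[0] = rng[0] + np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
    _pcg32(rng)


@njit(cache=True)
def _fw_build(p, f):
    n = p.shape[0]
    for i in range(n + 1):
        f[i] = 0.0
    for i in range(1, n + 1):
        f[i] += p[i - 1]
        j = i + (i & (-i))
        if j <= n:
            f[j] += f[i]


@njit(cache=True, inline="always")
def _fw_add(f, i, delta):
    n = f.shape[0] - 1
    i += 1
    while i <= n:
        f[i] += delta
        i += i & (-i)


@njit(cache=True)
def _fw_find(f, r):
    """Site index s with prefix(s) <= r < prefix(s+1); returns (s, residual)."""
    n = f.shape[0] - 1
    bit = 1
    while (bit << 1) <= n:
        bit <<= 1
    pos = 0
    rem = r
    while bit > 0:
        nxt = pos + bit
        if nxt <= n and f[nxt] < rem:
            pos = nxt
            rem -= f[nxt]
        bit >>= 1
    return pos, rem


@njit(cache=True, inline="always")
def _bondable(q, st, nb2):
    sq = st[q]
    if sq == S_INACTIVE or sq == S_ACTIVE:
        return True
    if sq == S_POLY:
        return nb2[q] < 0  # endpoint
    return False


@njit(cache=True, inline="always")
def _pair_ok(s, t, st, nb2, oend):
    if not (_bondable(s, st, nb2) and _bondable(t, st, nb2)):
        return False
    if st[s] == S_POLY and st[t] == S_POLY and oend[s] == t:
        return False  # two ends of the same chain
    return st[s] == S_ACTIVE or st[t] == S_ACTIVE or st[s] == S_POLY or st[t] == S_POLY


@njit(cache=True)
def _site_enum(s, st, nb1, nb2, clen, oend, bcnt, nbr, isb, rates, r):
    """Sum the propensity anchored at site ``s``; decode an event when r >= 0.

    Returns (total, code, arg).  Codes: -1 none, 0 inject, 1 diffuse,
    2 activate, 3 latent, 4 eject-monomer, 5 bond, 6 fragment, 7 kink,
    8 end-rotate, 9 reptate, 10 eject-polymer.  ``arg`` is the event's
    secondary site (target / partner / complementary site) where relevant.
    """
    tot = 0.0
    code = np.int64(-1)
    arg = np.int64(-1)
    ss = st[s]
    if ss == EMPTY:
        if isb[s] == 1 and rates[R_IN] > 0.0:
            tot += rates[R_IN]
            if r >= 0.0 and code < 0 and r < tot:
                code = 0
        return tot, code, arg
    if ss <= S_LATENT:  # free monomer
        if rates[R_D] > 0.0:
            for d in range(6):
                n = nbr[s, d]
                if n >= 0 and st[n] == EMPTY:
                    tot += rates[R_D]
                    if r >= 0.0 and code < 0 and r < tot:
                        code = 1
                        arg = n
        if rates[R_H] > 0.0 and ss != S_LATENT:
            for di in range(3):
                n = nbr[s, 2 * di]
                if n >= 0 and st[n] != EMPTY and _pair_ok(s, n, st, nb2, oend):
                    tot += rates[R_H]
                    if r >= 0.0 and code < 0 and r < tot:
                        code = 5
                        arg = n
        if ss == S_INACTIVE and rates[R_A] > 0.0:
            tot += rates[R_A]
            if r >= 0.0 and code < 0 and r < tot:
                code = 2
        if ss == S_ACTIVE and rates[R_L] > 0.0:
            tot += rates[R_L]
            if r >= 0.0 and code < 0 and r < tot:
                code = 3
        if isb[s] == 1 and rates[R_OUT] > 0.0:
            tot += rates[R_OUT]
            if r >= 0.0 and code < 0 and r < tot:
                code = 4
        return tot, code, arg
    # polymer site
    endpoint = nb2[s] < 0
    if endpoint and rates[R_H] > 0.0:
        for di in range(3):
            n = nbr[s, 2 * di]
            if n >= 0 and st[n] != EMPTY and _pair_ok(s, n, st, nb2, oend):
                tot += rates[R_H]
                if r >= 0.0 and code < 0 and r < tot:
                    code = 5
                    arg = n
    if rates[R_F] > 0.0:
        if nb1[s] > s:
            tot += rates[R_F]
            if r >= 0.0 and code < 0 and r < tot:
                code = 6
                arg = nb1[s]
        if nb2[s] > s:
            tot += rates[R_F]
            if r >= 0.0 and code < 0 and r < tot:
                code = 6
                arg = nb2[s]
    if not endpoint and rates[R_K] > 0.0:
        a = nb1[s]
        b = nb2[s]
        da = -1
        db = -1
        for d in range(6):
            if nbr[s, d] == a and da < 0:
                da = d
            if nbr[s, d] == b and db < 0:
                db = d
        if da >= 0 and db >= 0 and (da >> 1) != (db >> 1):
            c1 = nbr[s, da]
            comp = nbr[c1, db] if c1 >= 0 else -1
            if comp >= 0 and st[comp] == EMPTY:
                tot += rates[R_K]
                if r >= 0.0 and code < 0 and r < tot:
                    code = 7
                    arg = comp
    if endpoint:
        if rates[R_E] > 0.0:
            link = nb1[s]
            for d in range(6):
                n = nbr[link, d]
                if n >= 0 and st[n] == EMPTY:
                    tot += rates[R_E]
                    if r >= 0.0 and code < 0 and r < tot:
                        code = 8
                        arg = n
        if rates[R_R] > 0.0:
            i = clen[s]
            kr = rates[R_R] / np.float64(i * i)
            for d in range(6):
                n = nbr[s, d]
                if n >= 0 and st[n] == EMPTY:
                    tot += kr
                    if r >= 0.0 and code < 0 and r < tot:
                        code = 9
                        arg = n
        if rates[R_OUT] > 0.0 and s < oend[s] and bcnt[s] > 0:
            i = clen[s]
            tot += rates[R_OUT] / np.float64(i * i * i)
            if r >= 0.0 and code < 0 and r < tot:
                code = 10
    return tot, code, arg


@njit(cache=True)
def _walk_end(prev, cur, nb1, nb2):
    """Follow the chain from ``cur`` away from ``prev``; return the far endpoint."""
    while True:
        nxt = nb1[cur] if nb1[cur] != prev else nb2[cur]
        if nxt < 0:
            return cur
        prev, cur = cur, nxt


@njit(cache=True)
def _walk_measure(start, nb1, nb2, isb):
    """From endpoint ``start``: (chain length, boundary contacts, far endpoint)."""
    L = 1
    bc = np.int64(isb[start])
    prev = start
    cur = nb1[start]
    while cur >= 0:
        L += 1
        bc += isb[cur]
        nxt = nb1[cur] if nb1[cur] != prev else nb2[cur]
        prev, cur = cur, nxt
    return L, bc, prev


@njit(cache=True)
def _drop_link(q, other, nb1, nb2):
    if nb1[q] == other:
        nb1[q] = nb2[q]
    nb2[q] = -1


@njit(cache=True)
def _replace_link(q, old, new, nb1, nb2):
    if nb1[q] == old:
        nb1[q] = new
    else:
        nb2[q] = new


@njit(cache=True)
def _apply(code, s, arg, st, nb1, nb2, clen, oend, bcnt, isb, ledger, changed):
    """Apply the decoded event; write changed sites into ``changed``; return count."""
    nch = 0
    if code == 0:  # inject
        st[s] = S_INACTIVE
        ledger[0] += 1
        changed[nch] = s
        nch += 1
    elif code == 1:  # diffuse
        st[arg] = st[s]
        st[s] = EMPTY
        changed[nch] = s
        nch += 1
        changed[nch] = arg
        nch += 1
    elif code == 2:
        st[s] = S_ACTIVE
        changed[nch] = s
        nch += 1
    elif code == 3:
        st[s] = S_LATENT
        changed[nch] = s
        nch += 1
    elif code == 4:  # eject monomer
        st[s] = EMPTY
        ledger[1] += 1
        changed[nch] = s
        nch += 1
    elif code == 5:  # bond s -- t
        t = arg
        if st[s] <= S_LATENT and st[t] <= S_LATENT:
            st[s] = S_POLY
            st[t] = S_POLY
            nb1[s] = t
            nb2[s] = -1
            nb1[t] = s
            nb2[t] = -1
            clen[s] = 2
            clen[t] = 2
            oend[s] = t
            oend[t] = s
            bc = np.int64(isb[s]) + np.int64(isb[t])
            bcnt[s] = bc
            bcnt[t] = bc
            changed[nch] = s
            nch += 1
            changed[nch] = t
            nch += 1
        elif st[s] <= S_LATENT or st[t] <= S_LATENT:
            if st[s] <= S_LATENT:
                m, e = s, t
            else:
                m, e = t, s
            o = oend[e]
            st[m] = S_POLY
            nb1[m] = e
            nb2[m] = -1
            nb2[e] = m
            L = clen[e] + 1
            bc = bcnt[e] + np.int64(isb[m])
            clen[m] = L
            clen[o] = L
            bcnt[m] = bc
            bcnt[o] = bc
            oend[m] = o
            oend[o] = m
            changed[nch] = m
            nch += 1
            changed[nch] = e
            nch += 1
            changed[nch] = o
            nch += 1
        else:  # join two chains endpoint-to-endpoint
            os_, ot = oend[s], oend[t]
            nb2[s] = t
            nb2[t] = s
            L = clen[s] + clen[t]
            bc = bcnt[s] + bcnt[t]
            clen[os_] = L
            clen[ot] = L
            bcnt[os_] = bc
            bcnt[ot] = bc
            oend[os_] = ot
            oend[ot] = os_
            changed[nch] = s
            nch += 1
            changed[nch] = t
            nch += 1
            changed[nch] = os_
            nch += 1
            changed[nch] = ot
            nch += 1
    elif code == 6:  # fragment bond s -- t
        t = arg
        _drop_link(s, t, nb1, nb2)
        _drop_link(t, s, nb1, nb2)
        for side in (s, t):
            if nb1[side] < 0:  # size-1 fragment -> active monomer
                st[side] = S_ACTIVE
                changed[nch] = side
                nch += 1
            else:
                L, bc, far = _walk_measure(side, nb1, nb2, isb)
                clen[side] = L
                bcnt[side] = bc
                oend[side] = far
                clen[far] = L
                bcnt[far] = bc
                oend[far] = side
                changed[nch] = side
                nch += 1
                changed[nch] = far
                nch += 1
    elif code == 7:  # kink flip s -> comp
        comp = arg
        a = nb1[s]
        b = nb2[s]
        st[s] = EMPTY
        nb1[s] = -1
        nb2[s] = -1
        st[comp] = S_POLY
        nb1[comp] = a
        nb2[comp] = b
        _replace_link(a, s, comp, nb1, nb2)
        _replace_link(b, s, comp, nb1, nb2)
        changed[nch] = s
        nch += 1
        changed[nch] = comp
        nch += 1
        changed[nch] = a
        nch += 1
        changed[nch] = b
        nch += 1
        if isb[comp] != isb[s]:
            delta = np.int64(isb[comp]) - np.int64(isb[s])
            e1 = _walk_end(comp, a, nb1, nb2)
            e2 = _walk_end(comp, b, nb1, nb2)
            bcnt[e1] += delta
            bcnt[e2] += delta
            changed[nch] = e1
            nch += 1
            changed[nch] = e2
            nch += 1
    elif code == 8:  # end rotation: endpoint s moves to arg
        t = arg
        n = nb1[s]
        o = oend[s]
        L = clen[s]
        bc = bcnt[s] + np.int64(isb[t]) - np.int64(isb[s])
        st[s] = EMPTY
        nb1[s] = -1
        st[t] = S_POLY
        nb1[t] = n
        nb2[t] = -1
        _replace_link(n, s, t, nb1, nb2)
        clen[t] = L
        bcnt[t] = bc
        oend[t] = o
        clen[o] = L
        bcnt[o] = bc
        oend[o] = t
        changed[nch] = s
        nch += 1
        changed[nch] = t
        nch += 1
        changed[nch] = n
        nch += 1
        changed[nch] = o
        nch += 1
    elif code == 9:  # reptation: slide toward free site arg adjacent to end s
        t = arg
        o = oend[s]
        L = clen[s]
        st[t] = S_POLY
        nb1[t] = s
        nb2[t] = -1
        nb2[s] = t
        w = nb1[o]
        st[o] = EMPTY
        nb1[o] = -1
        _drop_link(w, o, nb1, nb2)
        bc = bcnt[s] + np.int64(isb[t]) - np.int64(isb[o])
        clen[t] = L
        bcnt[t] = bc
        oend[t] = w
        clen[w] = L
        bcnt[w] = bc
        oend[w] = t
        changed[nch] = s
        nch += 1
        changed[nch] = t
        nch += 1
        changed[nch] = o
        nch += 1
        changed[nch] = w
        nch += 1
    elif code == 10:  # eject whole polymer from canonical endpoint s
        prev = np.int64(-1)
        cur = s
        L = 0
        while cur >= 0:
            nxt = nb1[cur] if nb1[cur] != prev else nb2[cur]
            st[cur] = EMPTY
            nb1[cur] = -1
            nb2[cur] = -1
            changed[nch] = cur
            nch += 1
            L += 1
            prev, cur = cur, nxt
        ledger[1] += L
    return nch


@njit(cache=True)
def _refresh(changed, nch, gen, stamp, affected, st, nb1, nb2, clen, oend, bcnt, nbr, isb, rates, p, f):
    """Recompute anchored propensities around the changed sites; return total delta."""
    na = 0
    for idx in range(nch):
        c = changed[idx]
        if stamp[c] != gen:
            stamp[c] = gen
            affected[na] = c
            na += 1
        for d in range(6):
            n = nbr[c, d]
            if n >= 0 and stamp[n] != gen:
                stamp[n] = gen
                affected[na] = n
                na += 1
            if n < 0:
                continue
            for d2 in range(6):
                if (d2 >> 1) <= (d >> 1):
                    continue
                n2 = nbr[n, d2]
                if n2 >= 0 and stamp[n2] != gen:
                    stamp[n2] = gen
                    affected[na] = n2
                    na += 1
    # endpoints linked to any affected chain site (their end-rotation slots
    # depend on the free neighbours of the linked site)
    na0 = na
    for idx in range(na0):
        a = affected[idx]
        if st[a] == S_POLY:
            for l in (nb1[a], nb2[a]):
                if l >= 0 and nb2[l] < 0 and stamp[l] != gen:
                    stamp[l] = gen
                    affected[na] = l
                    na += 1
    delta_tot = 0.0
    for idx in range(na):
        a = affected[idx]
        new, _, _ = _site_enum(a, st, nb1, nb2, clen, oend, bcnt, nbr, isb, rates, -1.0)
        d = new - p[a]
        if d != 0.0:
            p[a] = new
            _fw_add(f, a, d)
            delta_tot += d
    return delta_tot


@njit(cache=True)
def _all_propensities(st, nb1, nb2, clen, oend, bcnt, nbr, isb, rates, p):
    tot = 0.0
    for s in range(st.shape[0]):
        v, _, _ = _site_enum(s, st, nb1, nb2, clen, oend, bcnt, nbr, isb, rates, -1.0)
        p[s] = v
        tot += v
    return tot


@njit(cache=True)
def _record(k, st, nb1, nb2, clen, oend, min_size, ledger, out_counts, out_units, out_monomers, out_inj, out_ej):
    agg = 0
    units = 0
    mono = 0
    for q in range(st.shape[0]):
        sq = st[q]
        if sq == EMPTY:
            continue
        units += 1
        if sq <= S_LATENT:
            mono += 1
        elif nb2[q] < 0 and q < oend[q] and clen[q] >= min_size:
            agg += 1
    out_counts[k] = agg
    out_units[k] = units
    out_monomers[k] = mono
    out_inj[k] = ledger[0]
    out_ej[k] = ledger[1]


@njit(cache=True)
def _run_kernel(
    st,
    nb1,
    nb2,
    clen,
    oend,
    bcnt,
    nbr,
    isb,
    rates,
    t0,
    t_max,
    sample_times,
    min_size,
    seed,
    ledger,
    audit_interval,
    out_counts,
    out_units,
    out_monomers,
    out_inj,
    out_ej,
):
    N = st.shape[0]
    p = np.zeros(N, dtype=np.float64)
    f = np.zeros(N + 1, dtype=np.float64)
    total = _all_propensities(st, nb1, nb2, clen, oend, bcnt, nbr, isb, rates, p)
    _fw_build(p, f)
    rng = np.zeros(2, dtype=np.uint64)
    _seed_rng(rng, seed)
    changed = np.empty(N + 8, dtype=np.int64)
    stamp = np.zeros(N, dtype=np.int64)
    affected = np.empty(8 * (N + 8), dtype=np.int64)
    gen = np.int64(0)
    t = t0
    nsamples = sample_times.shape[0]
    k = 0
    events = 0
    audit_err = 0.0
    while True:
        if total <= 1e-13:
            while k < nsamples:
                _record(k, st, nb1, nb2, clen, oend, min_size, ledger, out_counts, out_units, out_monomers, out_inj, out_ej)
                k += 1
            return t, 1, audit_err
        dt = -np.log(_rand(rng)) / total
        tn = t + dt
        while k < nsamples and sample_times[k] <= tn:
            _record(k, st, nb1, nb2, clen, oend, min_size, ledger, out_counts, out_units, out_monomers, out_inj, out_ej)
            k += 1
        if tn >= t_max:
            return t_max, 0, audit_err
        t = tn
        r = _rand(rng) * total
        s, rem = _fw_find(f, r)
        if s >= N or p[s] <= 0.0 or rem >= p[s]:
            # floating-point drift in the tree: rebuild and redraw
            total = _all_propensities(st, nb1, nb2, clen, oend, bcnt, nbr, isb, rates, p)
            _fw_build(p, f)
            continue
        _, code, arg = _site_enum(s, st, nb1, nb2, clen, oend, bcnt, nbr, isb, rates, rem)
        if code < 0:
            total = _all_propensities(st, nb1, nb2, clen, oend, bcnt, nbr, isb, rates, p)
            _fw_build(p, f)
            continue
        nch = _apply(code, s, arg, st, nb1, nb2, clen, oend, bcnt, isb, ledger, changed)
        gen += 1
        total += _refresh(changed, nch, gen, stamp, affected, st, nb1, nb2, clen, oend, bcnt, nbr, isb, rates, p, f)
        events += 1
        if events % _REBUILD_EVERY == 0:
            total = _all_propensities(st, nb1, nb2, clen, oend, bcnt, nbr, isb, rates, p)
            _fw_build(p, f)
        if audit_interval > 0 and events % audit_interval == 0:
            ptmp = np.zeros(N, dtype=np.float64)
            tot2 = _all_propensities(st, nb1, nb2, clen, oend, bcnt, nbr, isb, rates, ptmp)
            for q in range(N):
                e = abs(ptmp[q] - p[q])
                if e > audit_err:
                    audit_err = e
            p = ptmp
            _fw_build(p, f)
            total = tot2


# ---------------------------------------------------------------------------
# Python-facing API
# ---------------------------------------------------------------------------


def site_propensities(state: SimState, rates: RateSet) -> np.ndarray:
    """Per-site anchored propensities as the kernel computes them (for testing)."""
    st, nb1, nb2, clen, oend, bcnt = state_to_arrays(state)
    nbr, isb = build_tables(state.config)
    p = np.zeros(state.config.n_sites, dtype=np.float64)
    _all_propensities(st, nb1, nb2, clen, oend, bcnt, nbr, isb, rates.as_array(), p)
    return p


def catalogue_site_sums(catalogue, state: SimState) -> np.ndarray:
    """Aggregate a Python event catalogue by the kernel's anchoring rule."""
    cfg = state.config
    p = np.zeros(cfg.n_sites, dtype=np.float64)
    occ = state.occupancy()
    del occ
    for ev in catalogue.events:
        if ev.kind == "inject":
            s = site_index(cfg, ev.info[0])
        elif ev.kind in ("diffuse", "activate", "latent"):
            s = site_index(cfg, state.monomers[ev.info[0]].position)
        elif ev.kind == "bond":
            s = site_index(cfg, ev.info[2])
        elif ev.kind == "fragment":
            j, b = ev.info
            sites = state.polymers[j].sites
            s = min(site_index(cfg, sites[b]), site_index(cfg, sites[b + 1]))
        elif ev.kind == "kink":
            j, k, _ = ev.info
            s = site_index(cfg, state.polymers[j].sites[k])
        elif ev.kind in ("end_rotate", "reptate"):
            j, end, _ = ev.info
            pos = state.polymers[j].sites[0 if end == 0 else -1]
            s = site_index(cfg, pos)
        elif ev.kind == "eject":
            ekind, idx = ev.info[0]
            if ekind == "m":
                s = site_index(cfg, state.monomers[idx].position)
            else:
                e0, e1 = state.polymers[idx].ends()
                s = min(site_index(cfg, e0), site_index(cfg, e1))
        else:  # pragma: no cover
            raise ValueError(ev.kind)
        p[s] += ev.propensity
    return p


def _kernel_seed(seed: int) -> int:
    ss = np.random.SeedSequence(seed)
    return int(ss.generate_state(1, dtype=np.uint64)[0] & np.uint64(0x7FFFFFFFFFFFFFFF))


def run_until(
    state: SimState,
    rates: RateSet,
    t_max: float,
    record_every: float,
    seed: int = 0,
    min_size: int = 10,
    audit_interval: int = 0,
) -> Trajectory:
    """Simulate until ``t >= t_max``, recording aggregate counts on a regular grid.

    The state is evolved in place (its entities are rebuilt from the kernel's
    final configuration) and the returned :class:`Trajectory` also carries the
    final state snapshot.  ``seed`` fully determines the run.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if record_every <= 0:
        raise ValueError("record_every must be positive")
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    cfg = state.config
    st, nb1, nb2, clen, oend, bcnt = state_to_arrays(state)
    nbr, isb = build_tables(cfg)
    nrec = int(np.floor(t_max / record_every + 1e-9)) + 1
    sample_times = state.t + np.arange(nrec) * record_every
    ledger = np.array([state.injected, state.ejected], dtype=np.int64)
    out = [np.zeros(nrec, dtype=np.int64) for _ in range(5)]
    t_final, status, audit_err = _run_kernel(
        st,
        nb1,
        nb2,
        clen,
        oend,
        bcnt,
        nbr,
        isb,
        rates.as_array(),
        float(state.t),
        float(state.t + t_max),
        sample_times.astype(np.float64),
        int(min_size),
        _kernel_seed(seed),
        ledger,
        int(audit_interval),
        *out,
    )
    if audit_interval > 0 and audit_err > 1e-9:
        raise RuntimeError(f"propensity audit failed: max deviation {audit_err:g}")
    final = arrays_to_state(
        cfg, st, nb1, nb2, oend, t=float(t_final), injected=int(ledger[0]), ejected=int(ledger[1])
    )
    state.monomers = final.monomers
    state.polymers = final.polymers
    state.t = final.t
    state.injected = final.injected
    state.ejected = final.ejected
    return Trajectory(
        times=sample_times,
        aggregate_counts=out[0],
        min_size=min_size,
        n_units=out[1],
        n_monomers=out[2],
        injected=out[3],
        ejected=out[4],
        absorbed=bool(status == 1),
        final_state=final,
    )


@dataclass
class SweepResult:
    """Aggregate-count statistics across a grid of clearance rates."""

    summary: pd.DataFrame  # k_out_over_k_in, min_size, mean_aggregates, sd_aggregates
    detail: pd.DataFrame  # k_out_over_k_in, replicate, t, n_aggregates


def sweep_kout(
    kout_values,
    replicates: int,
    t_obs: float,
    rates: RateSet,
    config: LatticeConfig,
    min_size=10,
    seed: int = 0,
    record_every: float | None = None,
) -> SweepResult:
    """Mean/SD of the aggregate count at ``t_obs`` across a ``k_out`` grid.

    Each (k_out, replicate) pair runs from an empty lattice with a seed
    derived deterministically from (seed, grid index, replicate index).  When
    ``min_size`` is a sequence, counts for every threshold are computed from
    the same trajectories.
    """
    kout_values = list(kout_values)
    if len(kout_values) < 3:
        raise ValueError("need at least 3 k_out values")
    if replicates < 3:
        raise ValueError("need at least 3 replicates")
    min_sizes = (min_size,) if isinstance(min_size, (int, np.integer)) else tuple(min_size)
    record_every = record_every or t_obs
    from .model import count_aggregates

    summary_rows = []
    detail_rows = []
    for gi, kout in enumerate(kout_values):
        r = rates.with_kout(float(kout))
        counts = {m: [] for m in min_sizes}
        for rep in range(replicates):
            rep_seed = int(np.random.SeedSequence((seed, gi, rep)).generate_state(1)[0])
            state = init_state(config)
            traj = run_until(state, r, t_obs, record_every, seed=rep_seed, min_size=min_sizes[0])
            for m in min_sizes:
                counts[m].append(count_aggregates(state, m))
            for tt, cc in zip(traj.times, traj.aggregate_counts):
                detail_rows.append(
                    {
                        "k_out_over_k_in": float(kout) / rates.k_in,
                        "replicate": rep,
                        "t": float(tt),
                        "n_aggregates": int(cc),
                        "min_size": min_sizes[0],
                    }
                )
        for m in min_sizes:
            arr = np.asarray(counts[m], dtype=float)
            summary_rows.append(
                {
                    "k_out_over_k_in": float(kout) / rates.k_in,
                    "min_size": m,
                    "mean_aggregates": float(arr.mean()),
                    "sd_aggregates": float(arr.std(ddof=1)),
                    "n_replicates": replicates,
                }
            )
    summary = pd.DataFrame(summary_rows).sort_values(
        ["min_size", "k_out_over_k_in"], ignore_index=True
    )
    detail = pd.DataFrame(detail_rows)
    return SweepResult(summary=summary, detail=detail)
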