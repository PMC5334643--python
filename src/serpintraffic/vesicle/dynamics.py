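"""Damped second-order dynamics for the membrane/scaffold system.

Forces are the exact negative gradient of the total conservative energy
(bending + bond penalty + adhesion + self-exclusion); a per-node viscous drag
``-gamma * v`` removes kinetic energy so the system relaxes toward quasi-
static configurations while the scaffold's preferred turn angle is ramped.
With ``gamma = 0`` the scheme reduces to plain velocity Verlet and conserves
energy, which the test-suite uses as an integrator check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import CouplingParams, ElasticChain, Protocol


@njit(cache=True)
def _chain_forces(pos, closed, b, kbond, K, th0, f):
    """Bond-penalty and bending forces of one chain; returns (energy, max_strain)."""
    n = pos.shape[0]
    e = 0.0
    max_strain = 0.0
    nb = n if closed else n - 1
    for i in range(nb):
        j = (i + 1) % n
        rx = pos[j, 0] - pos[i, 0]
        ry = pos[j, 1] - pos[i, 1]
        ln = np.sqrt(rx * rx + ry * ry)
        strain = abs(ln - b) / b
        if strain > max_strain:
            max_strain = strain
        e += 0.5 * kbond * (ln - b) * (ln - b)
        fmag = kbond * (ln - b) / ln
        f[i, 0] += fmag * rx
        f[i, 1] += fmag * ry
        f[j, 0] -= fmag * rx
        f[j, 1] -= fmag * ry
    lo = 0 if closed else 1
    hi = n if closed else n - 1
    for v in range(lo, hi):
        i0 = (v - 1) % n
        i2 = (v + 1) % n
        ux = pos[v, 0] - pos[i0, 0]
        uy = pos[v, 1] - pos[i0, 1]
        wx = pos[i2, 0] - pos[v, 0]
        wy = pos[i2, 1] - pos[v, 1]
        c = ux * wy - uy * wx
        d = ux * wx + uy * wy
        th = np.arctan2(c, d)
        dth = th - th0
        e += 0.5 * K * dth * dth
        dE = K * dth
        inv = 1.0 / (c * c + d * d)
        # dtheta/du and dtheta/dw
        tux = (d * wy - c * wx) * inv
        tuy = (-d * wx - c * wy) * inv
        twx = (-d * uy - c * ux) * inv
        twy = (d * ux - c * uy) * inv
        # forces: -grad E; u depends on (i0, v), w on (v, i2)
        f[i0, 0] += dE * tux
        f[i0, 1] += dE * tuy
        f[v, 0] += dE * (twx - tux)
        f[v, 1] += dE * (twy - tuy)
        f[i2, 0] -= dE * twx
        f[i2, 1] -= dE * twy
    return e, max_strain


@njit(cache=True)
def _lj_pair_forces(sca, mem, fs, fm, eps, sig, rcut, eps_cap, sig_cap, cap):
    """Coat-membrane forces: shifted LJ for adhesive nodes, WCA for rim caps."""
    e = 0.0
    ns = sca.shape[0]
    rc_cap = 2.0 ** (1.0 / 6.0) * sig_cap
    for i in range(ns):
        adhesive = (i >= cap) and (i < ns - cap)
        if adhesive:
            epsi, sigi, rci = eps, sig, rcut
        else:
            epsi, sigi, rci = eps_cap, sig_cap, rc_cap
        rc2 = rci * rci
        sc6 = (sigi / rci) ** 6
        ushift = 4.0 * epsi * (sc6 * sc6 - sc6)
        for j in range(mem.shape[0]):
            rx = sca[i, 0] - mem[j, 0]
            ry = sca[i, 1] - mem[j, 1]
            r2 = rx * rx + ry * ry
            if r2 >= rc2:
                continue
            s2 = sigi * sigi / r2
            s6 = s2 * s2 * s2
            e += 4.0 * epsi * (s6 * s6 - s6) - ushift
            fmag = 24.0 * epsi * (2.0 * s6 * s6 - s6) / r2
            fs[i, 0] += fmag * rx
            fs[i, 1] += fmag * ry
            fm[j, 0] -= fmag * rx
            fm[j, 1] -= fmag * ry
    return e


@njit(cache=True)
def _wca_self_forces(mem, fm, eps, sig):
    """Purely repulsive WCA between non-bonded membrane pairs (ring topology)."""
    n = mem.shape[0]
    rc2 = 2.0 ** (1.0 / 3.0) * sig * sig  # (2^{1/6} sigma)^2
    e = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            rx = mem[i, 0] - mem[j, 0]
            ry = mem[i, 1] - mem[j, 1]
            r2 = rx * rx + ry * ry
            if r2 >= rc2:
                continue
            s2 = sig * sig / r2
            s6 = s2 * s2 * s2
            e += 4.0 * eps * (s6 * s6 - s6) + eps
            fmag = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
            fm[i, 0] += fmag * rx
            fm[i, 1] += fmag * ry
            fm[j, 0] -= fmag * rx
            fm[j, 1] -= fmag * ry
    return e


@njit(cache=True)
def _all_forces(mem, sca, fm, fs, bm, bs, kbm, kbs, Km, Ks, th0m, th0s, eps, sig, rcut, epsev, sigev, sig_cap, cap):
    fm[:] = 0.0
    fs[:] = 0.0
    em, strain_m = _chain_forces(mem, True, bm, kbm, Km, th0m, fm)
    es, strain_s = _chain_forces(sca, False, bs, kbs, Ks, th0s, fs)
    elj = _lj_pair_forces(sca, mem, fs, fm, eps, sig, rcut, epsev, sig_cap, cap)
    eev = _wca_self_forces(mem, fm, epsev, sigev)
    strain = strain_m if strain_m > strain_s else strain_s
    return em + es + elj + eev, strain


@njit(cache=True)
def _build_mm_list(mem, rl2, pi, pj):
    """Membrane-membrane candidate pairs within the listed radius (ring-nonadjacent)."""
    n = mem.shape[0]
    cnt = 0
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            rx = mem[i, 0] - mem[j, 0]
            ry = mem[i, 1] - mem[j, 1]
            if rx * rx + ry * ry < rl2:
                pi[cnt] = i
                pj[cnt] = j
                cnt += 1
    return cnt


@njit(cache=True)
def _build_ms_list(sca, mem, rl2, pi, pj):
    cnt = 0
    for i in range(sca.shape[0]):
        for j in range(mem.shape[0]):
            rx = sca[i, 0] - mem[j, 0]
            ry = sca[i, 1] - mem[j, 1]
            if rx * rx + ry * ry < rl2:
                pi[cnt] = i
                pj[cnt] = j
                cnt += 1
    return cnt


@njit(cache=True)
def _wca_list_forces(mem, fm, eps, sig, pi, pj, cnt):
    rc2 = 2.0 ** (1.0 / 3.0) * sig * sig
    e = 0.0
    for k in range(cnt):
        i, j = pi[k], pj[k]
        rx = mem[i, 0] - mem[j, 0]
        ry = mem[i, 1] - mem[j, 1]
        r2 = rx * rx + ry * ry
        if r2 >= rc2:
            continue
        s2 = sig * sig / r2
        s6 = s2 * s2 * s2
        e += 4.0 * eps * (s6 * s6 - s6) + eps
        fmag = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
        fm[i, 0] += fmag * rx
        fm[i, 1] += fmag * ry
        fm[j, 0] -= fmag * rx
        fm[j, 1] -= fmag * ry
    return e


@njit(cache=True)
def _lj_list_forces(sca, mem, fs, fm, eps, sig, rcut, eps_cap, sig_cap, cap, pi, pj, cnt):
    e = 0.0
    ns = sca.shape[0]
    rc_cap = 2.0 ** (1.0 / 6.0) * sig_cap
    for k in range(cnt):
        i, j = pi[k], pj[k]
        if (i >= cap) and (i < ns - cap):
            epsi, sigi, rci = eps, sig, rcut
        else:
            epsi, sigi, rci = eps_cap, sig_cap, rc_cap
        rx = sca[i, 0] - mem[j, 0]
        ry = sca[i, 1] - mem[j, 1]
        r2 = rx * rx + ry * ry
        if r2 >= rci * rci:
            continue
        sc6 = (sigi / rci) ** 6
        s2 = sigi * sigi / r2
        s6 = s2 * s2 * s2
        e += 4.0 * epsi * (s6 * s6 - s6) - 4.0 * epsi * (sc6 * sc6 - sc6)
        fmag = 24.0 * epsi * (2.0 * s6 * s6 - s6) / r2
        fs[i, 0] += fmag * rx
        fs[i, 1] += fmag * ry
        fm[j, 0] -= fmag * rx
        fm[j, 1] -= fmag * ry
    return e


@njit(cache=True)
def _all_forces_list(
    mem, sca, fm, fs, bm, bs, kbm, kbs, Km, Ks, th0m, th0s, eps, sig, rcut,
    epsev, sigev, sig_cap, cap, mmi, mmj, nmm, msi, msj, nms
):
    fm[:] = 0.0
    fs[:] = 0.0
    em, strain_m = _chain_forces(mem, True, bm, kbm, Km, th0m, fm)
    es, strain_s = _chain_forces(sca, False, bs, kbs, Ks, th0s, fs)
    elj = _lj_list_forces(sca, mem, fs, fm, eps, sig, rcut, epsev, sig_cap, cap, msi, msj, nms)
    eev = _wca_list_forces(mem, fm, epsev, sigev, mmi, mmj, nmm)
    strain = strain_m if strain_m > strain_s else strain_s
    return em + es + elj + eev, strain


@njit(cache=True)
def _max_disp2(pos, ref):
    m = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        d2 = dx * dx + dy * dy
        if d2 > m:
            m = d2
    return m


@njit(cache=True)
def _integrate_kernel(
    mem,
    sca,
    vm,
    vs,
    bm,
    bs,
    kbm,
    kbs,
    Km,
    Ks,
    th0m,
    th0s_init,
    th0s_target,
    eps,
    sig,
    rcut,
    epsev,
    sigev,
    sig_cap,
    cap,
    dt,
    gamma,
    ramp_steps,
    hold_steps,
    record_every,
    frames_m,
    frames_s,
    e_pot,
    e_kin,
    th_rec,
    rec_steps,
):
    fm = np.zeros_like(mem)
    fs = np.zeros_like(sca)
    total = ramp_steps + hold_steps
    # Verlet neighbour lists: exact as long as no node moves more than
    # skin/2 between rebuilds
    nm, ns = mem.shape[0], sca.shape[0]
    skin = 0.5
    rl_mm = 2.0 ** (1.0 / 6.0) * sigev + skin
    rl_ms = max(rcut, 2.0 ** (1.0 / 6.0) * sig_cap) + skin
    mmi = np.empty(nm * (nm - 1) // 2, dtype=np.int64)
    mmj = np.empty_like(mmi)
    msi = np.empty(ns * nm, dtype=np.int64)
    msj = np.empty_like(msi)
    mem_ref = mem.copy()
    sca_ref = sca.copy()
    nmm = _build_mm_list(mem, rl_mm * rl_mm, mmi, mmj)
    nms = _build_ms_list(sca, mem, rl_ms * rl_ms, msi, msj)
    half_skin2 = (skin / 2.0) ** 2
    epot, max_strain = _all_forces_list(
        mem, sca, fm, fs, bm, bs, kbm, kbs, Km, Ks, th0m, th0s_init, eps, sig, rcut,
        epsev, sigev, sig_cap, cap, mmi, mmj, nmm, msi, msj, nms
    )
    half_g = 0.5 * gamma * dt
    rec = 0
    if rec_steps[rec] == 0:
        frames_m[rec] = mem
        frames_s[rec] = sca
        e_pot[rec] = epot
        e_kin[rec] = 0.5 * ((vm * vm).sum() + (vs * vs).sum())
        th_rec[rec] = th0s_init
        rec += 1
    for step in range(1, total + 1):
        vm *= 1.0 - half_g
        vm += 0.5 * dt * fm
        vs *= 1.0 - half_g
        vs += 0.5 * dt * fs
        mem += dt * vm
        sca += dt * vs
        if step < ramp_steps:
            th0s = th0s_init + (th0s_target - th0s_init) * (step / ramp_steps)
        else:
            th0s = th0s_target
        if _max_disp2(mem, mem_ref) > half_skin2 or _max_disp2(sca, sca_ref) > half_skin2:
            mem_ref[:] = mem
            sca_ref[:] = sca
            nmm = _build_mm_list(mem, rl_mm * rl_mm, mmi, mmj)
            nms = _build_ms_list(sca, mem, rl_ms * rl_ms, msi, msj)
        epot, strain = _all_forces_list(
            mem, sca, fm, fs, bm, bs, kbm, kbs, Km, Ks, th0m, th0s, eps, sig, rcut,
            epsev, sigev, sig_cap, cap, mmi, mmj, nmm, msi, msj, nms
        )
        if strain > max_strain:
            max_strain = strain
        vm += 0.5 * dt * fm
        vm /= 1.0 + half_g
        vs += 0.5 * dt * fs
        vs /= 1.0 + half_g
        if rec < rec_steps.shape[0] and rec_steps[rec] == step:
            if not (np.isfinite(mem).all() and np.isfinite(sca).all()):
                return max_strain, 1, rec
            frames_m[rec] = mem
            frames_s[rec] = sca
            e_pot[rec] = epot
            e_kin[rec] = 0.5 * ((vm * vm).sum() + (vs * vs).sum())
            th_rec[rec] = th0s
            rec += 1
    return max_strain, 0, rec


@dataclass
class VesicleTrajectory:
    """Recorded configurations and energies of one budding run."""

    times: np.ndarray
    frames_membrane: np.ndarray  # (F, N_m, 2)
    frames_scaffold: np.ndarray  # (F, N_s, 2)
    e_pot: np.ndarray
    e_kin: np.ndarray
    theta_s: np.ndarray
    max_strain: float
    ok: bool

    @property
    def final_membrane(self) -> np.ndarray:
        return self.frames_membrane[-1]

    @property
    def final_scaffold(self) -> np.ndarray:
        return self.frames_scaffold[-1]


def compute_forces(
    membrane: ElasticChain,
    scaffold: ElasticChain,
    params: CouplingParams,
    theta0_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Analytic forces on every node; returns (f_membrane, f_scaffold, E, max_strain)."""
    fm = np.zeros_like(membrane.positions)
    fs = np.zeros_like(scaffold.positions)
    e, strain = _all_forces(
        membrane.positions,
        scaffold.positions,
        fm,
        fs,
        membrane.bond_length,
        scaffold.bond_length,
        membrane.bond_stiffness,
        scaffold.bond_stiffness,
        membrane.K,
        scaffold.K,
        membrane.theta0,
        scaffold.theta0 if theta0_s is None else theta0_s,
        params.eps_LJ,
        params.sigma,
        params.r_cut,
        params.eps_excluded,
        params.sigma_excluded,
        params.sigma_cap,
        min(params.cap_nodes, scaffold.n_nodes // 2),
    )
    return fm, fs, float(e), float(strain)


def integrate(
    membrane: ElasticChain,
    scaffold: ElasticChain,
    params: CouplingParams,
    protocol: Protocol,
    seed: int = 0,
) -> VesicleTrajectory:
    """Ramp the scaffold's preferred turn angle and relax under viscous damping.

    The chains are evolved in place; the returned trajectory holds recorded
    frames (including the initial and final configurations).  The dynamics is
    deterministic — randomness enters only through the initialization jitter
    in :func:`~serpintraffic.vesicle.model.init_system` — so ``seed`` is
    accepted for interface symmetry but unused.
    """
    del seed
    dt = protocol.resolved_dt(scaffold)
    total = protocol.ramp_steps + protocol.hold_steps
    rec_steps = np.unique(
        np.concatenate([np.arange(0, total + 1, max(1, protocol.record_every)), [total]])
    ).astype(np.int64)
    nrec = rec_steps.shape[0]
    Nm, Ns = membrane.n_nodes, scaffold.n_nodes
    frames_m = np.zeros((nrec, Nm, 2))
    frames_s = np.zeros((nrec, Ns, 2))
    e_pot = np.zeros(nrec)
    e_kin = np.zeros(nrec)
    th_rec = np.zeros(nrec)
    vm = np.zeros_like(membrane.positions)
    vs = np.zeros_like(scaffold.positions)
    max_strain, status, nrec_done = _integrate_kernel(
        membrane.positions,
        scaffold.positions,
        vm,
        vs,
        membrane.bond_length,
        scaffold.bond_length,
        membrane.bond_stiffness,
        scaffold.bond_stiffness,
        membrane.K,
        scaffold.K,
        membrane.theta0,
        scaffold.theta0,
        protocol.theta_s_target,
        params.eps_LJ,
        params.sigma,
        params.r_cut,
        params.eps_excluded,
        params.sigma_excluded,
        params.sigma_cap,
        min(params.cap_nodes, scaffold.n_nodes // 2),
        dt,
        protocol.gamma,
        protocol.ramp_steps,
        protocol.hold_steps,
        protocol.record_every,
        frames_m,
        frames_s,
        e_pot,
        e_kin,
        th_rec,
        rec_steps,
    )
    scaffold.theta0 = float(th_rec[max(0, nrec_done - 1)])
    ok = status == 0 and max_strain < 0.05
    return VesicleTrajectory(
        times=rec_steps[:nrec_done] * dt,
        frames_membrane=frames_m[:nrec_done],
        frames_scaffold=frames_s[:nrec_done],
        e_pot=e_pot[:nrec_done],
        e_kin=e_kin[:nrec_done],
        theta_s=th_rec[:nrec_done],
        max_strain=float(max_strain),
        ok=bool(ok),
    )


def relax_to_equilibrium(
    membrane: ElasticChain,
    scaffold: ElasticChain,
    params: CouplingParams,
    tol: float = 1e-6,
    max_steps: int = 200_000,
) -> float:
    """FIRE quench to the nearest mechanical equilibrium.

    Fast inertial relaxation engine: velocity-Verlet steps with adaptive
    timestep and velocity mixing, restarting from rest whenever the power
    ``F . v`` turns negative.  Stops when the largest per-node force norm
    falls below ``tol``; returns that norm.
    """
    # velocity-Verlet stability for the stiffest (bond) mode caps the timestep
    dt0 = 0.25 / np.sqrt(2.0 * max(membrane.bond_stiffness, scaffold.bond_stiffness))
    dt, dt_max = dt0, 3.0 * dt0
    alpha, alpha0 = 0.1, 0.1
    n_pos = 0
    x = np.concatenate([membrane.positions.ravel(), scaffold.positions.ravel()])
    v = np.zeros_like(x)
    nm = membrane.positions.size

    def force_vec():
        fm, fs, _, _ = compute_forces(membrane, scaffold, params)
        fmax = max(np.linalg.norm(fm, axis=1).max(), np.linalg.norm(fs, axis=1).max())
        return np.concatenate([fm.ravel(), fs.ravel()]), fmax

    f, fmax = force_vec()
    for _ in range(max_steps):
        if fmax < tol:
            break
        v += dt * f
        power = float(f @ v)
        if power > 0.0:
            vn, fn = np.linalg.norm(v), np.linalg.norm(f)
            if fn > 0:
                v = (1.0 - alpha) * v + alpha * vn * f / fn
            n_pos += 1
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            v[:] = 0.0
            dt *= 0.5
            alpha = alpha0
            n_pos = 0
        x += dt * v
        membrane.positions[:] = x[:nm].reshape(-1, 2)
        scaffold.positions[:] = x[nm:].reshape(-1, 2)
        f, fmax = force_vec()
    return float(fmax)
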