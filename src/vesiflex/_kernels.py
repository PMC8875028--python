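"""Numba-compiled inner loops of the Metropolis engine.

The kernels operate on a single packed coordinate array ``pos`` of shape
(2(N+1), 2) whose first ``nv`` rows are the vesicle ring and the rest the
linear polymer.  They duplicate, in scalar form, the energy bookkeeping
of :mod:`vesiflex.model`; the two paths are held together by the
incremental-vs-full consistency tests.  All randomness comes from
numba's per-thread ``np.random`` state, seeded explicitly through
:func:`seed_rng`, which makes a block of Monte Carlo steps a pure
function of (positions, parameters, seed).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

INF = np.inf


@njit(cache=True, inline="always")
def _fene_r(r, half_kr02, l0, r0, l_min, l_max):
    if r <= l_min or r >= l_max:
        return INF
    t = (r - l0) / r0
    return -half_kr02 * math.log(1.0 - t * t)


@njit(cache=True, inline="always")
def _morse_r(r, m_eps, m_alpha, m_rmin):
    x = math.exp(-m_alpha * (r - m_rmin))
    return m_eps * (x * x - 2.0 * x)


@njit(cache=True, inline="always")
def _lj_r2(r2, eps_vp, rm2):
    t = rm2 / r2
    t3 = t * t * t
    return eps_vp * (t3 * t3 - 2.0 * t3)


@njit(cache=True, inline="always")
def _cos_vertex(ax, ay, bx, by, cx, cy):
    ux = ax - bx
    uy = ay - by
    vx = cx - bx
    vy = cy - by
    c = (ux * vx + uy * vy) / math.sqrt((ux * ux + uy * uy) * (vx * vx + vy * vy))
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def full_energy(pos, nv, fene_k, l0, l_min, l_max, r0,
                m_alpha, m_rmin, m_eps, m_cut,
                kappa, eps_vp, rm, lj_cut):
    """Six-component energy breakdown by direct double loops."""
    ntot = pos.shape[0]
    npb = ntot - nv
    half_kr02 = 0.5 * fene_k * r0 * r0
    m_cut2 = m_cut * m_cut
    rm2 = rm * rm
    lj_cut2 = lj_cut * lj_cut

    fene_v = 0.0
    for i in range(nv):
        j = i + 1 if i < nv - 1 else 0
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        fene_v += _fene_r(math.sqrt(dx * dx + dy * dy), half_kr02, l0, r0, l_min, l_max)

    fene_p = 0.0
    for i in range(nv, ntot - 1):
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        fene_p += _fene_r(math.sqrt(dx * dx + dy * dy), half_kr02, l0, r0, l_min, l_max)

    morse_v = 0.0
    morse_p = 0.0
    if m_eps > 0.0:
        for i in range(nv):
            for j in range(i + 2, nv):
                if i == 0 and j == nv - 1:
                    continue  # ring closure pair is bonded
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                r2 = dx * dx + dy * dy
                if r2 <= m_cut2:
                    morse_v += _morse_r(math.sqrt(r2), m_eps, m_alpha, m_rmin)
        for i in range(nv, ntot):
            for j in range(i + 2, ntot):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                r2 = dx * dx + dy * dy
                if r2 <= m_cut2:
                    morse_p += _morse_r(math.sqrt(r2), m_eps, m_alpha, m_rmin)

    bend = 0.0
    if kappa > 0.0:
        for v in range(nv + 1, ntot - 1):
            c = _cos_vertex(pos[v - 1, 0], pos[v - 1, 1], pos[v, 0], pos[v, 1],
                            pos[v + 1, 0], pos[v + 1, 1])
            bend += kappa * (1.0 + c)

    lj = 0.0
    if eps_vp > 0.0:
        for i in range(nv):
            for j in range(nv, ntot):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                r2 = dx * dx + dy * dy
                if r2 <= lj_cut2:
                    lj += _lj_r2(r2, eps_vp, rm2)

    return fene_v, fene_p, morse_v, morse_p, bend, lj


@njit(cache=True)
def delta_u(pos, nv, i, xn, yn, half_kr02, l0, r0, l_min, l_max,
            m_alpha, m_rmin, m_eps, m_cut2,
            kappa, eps_vp, rm2, lj_cut2):
    """Energy change of moving bead ``i`` to (xn, yn); +inf if a touched
    bond leaves its allowed interval."""
    ntot = pos.shape[0]
    npb = ntot - nv
    xo = pos[i, 0]
    yo = pos[i, 1]
    du = 0.0

    if i < nv:
        jm = i - 1 if i > 0 else nv - 1
        jp = i + 1 if i < nv - 1 else 0
        c0, c1 = 0, nv
        o0, o1 = nv, ntot
    else:
        k = i - nv
        jm = i - 1 if k > 0 else -1
        jp = i + 1 if k < npb - 1 else -1
        c0, c1 = nv, ntot
        o0, o1 = 0, nv

    # FENE bonds touching the moved bead
    if jm >= 0:
        dx = xn - pos[jm, 0]
        dy = yn - pos[jm, 1]
        en = _fene_r(math.sqrt(dx * dx + dy * dy), half_kr02, l0, r0, l_min, l_max)
        if en == INF:
            return INF
        dx = xo - pos[jm, 0]
        dy = yo - pos[jm, 1]
        du += en - _fene_r(math.sqrt(dx * dx + dy * dy), half_kr02, l0, r0, l_min, l_max)
    if jp >= 0:
        dx = xn - pos[jp, 0]
        dy = yn - pos[jp, 1]
        en = _fene_r(math.sqrt(dx * dx + dy * dy), half_kr02, l0, r0, l_min, l_max)
        if en == INF:
            return INF
        dx = xo - pos[jp, 0]
        dy = yo - pos[jp, 1]
        du += en - _fene_r(math.sqrt(dx * dx + dy * dy), half_kr02, l0, r0, l_min, l_max)

    # bending at the polymer vertices containing the moved bead
    if kappa > 0.0 and i >= nv:
        k = i - nv
        for v in range(k - 1, k + 2):
            if v < 1 or v > npb - 2:
                continue
            g = nv + v
            ax, ay = pos[g - 1, 0], pos[g - 1, 1]
            bx, by = pos[g, 0], pos[g, 1]
            cx, cy = pos[g + 1, 0], pos[g + 1, 1]
            du -= kappa * (1.0 + _cos_vertex(ax, ay, bx, by, cx, cy))
            if g - 1 == i:
                ax, ay = xn, yn
            elif g == i:
                bx, by = xn, yn
            else:
                cx, cy = xn, yn
            du += kappa * (1.0 + _cos_vertex(ax, ay, bx, by, cx, cy))

    # Morse partners on the same chain (non-bonded)
    if m_eps > 0.0:
        for j in range(c0, c1):
            if j == i or j == jm or j == jp:
                continue
            dx = xo - pos[j, 0]
            dy = yo - pos[j, 1]
            r2 = dx * dx + dy * dy
            if r2 <= m_cut2:
                du -= _morse_r(math.sqrt(r2), m_eps, m_alpha, m_rmin)
            dx = xn - pos[j, 0]
            dy = yn - pos[j, 1]
            r2 = dx * dx + dy * dy
            if r2 <= m_cut2:
                du += _morse_r(math.sqrt(r2), m_eps, m_alpha, m_rmin)

    # LJ partners on the other chain
    if eps_vp > 0.0:
        for j in range(o0, o1):
            dx = xo - pos[j, 0]
            dy = yo - pos[j, 1]
            r2 = dx * dx + dy * dy
            if r2 <= lj_cut2:
                du -= _lj_r2(r2, eps_vp, rm2)
            dx = xn - pos[j, 0]
            dy = yn - pos[j, 1]
            r2 = dx * dx + dy * dy
            if r2 <= lj_cut2:
                du += _lj_r2(r2, eps_vp, rm2)

    return du


@njit(cache=True)
def mc_block(pos, nv, n_mcs, max_disp, kBT,
             fene_k, l0, l_min, l_max, r0,
             m_alpha, m_rmin, m_eps, m_cut,
             kappa, eps_vp, rm, lj_cut,
             e_run, resync_every):
    """Advance ``n_mcs`` Monte Carlo steps in place.

    One MCS is ``2(N+1)`` attempted single-bead displacements (bead
    uniform over both chains, increments uniform on the open square of
    half-width ``max_disp``), each accepted with the Metropolis
    probability ``min(exp(-dU/kBT), 1)``.  ``e_run`` is the running
    total energy, updated by accepted dU and resynchronised against a
    full recompute every ``resync_every`` MCS.  Returns the accepted
    move count and the running energy.
    """
    ntot = pos.shape[0]
    half_kr02 = 0.5 * fene_k * r0 * r0
    m_cut2 = m_cut * m_cut
    rm2 = rm * rm
    lj_cut2 = lj_cut * lj_cut
    acc = 0
    since = 0
    for _ in range(n_mcs):
        for _ in range(ntot):
            i = np.random.randint(0, ntot)
            dx = (2.0 * np.random.random() - 1.0) * max_disp
            dy = (2.0 * np.random.random() - 1.0) * max_disp
            xn = pos[i, 0] + dx
            yn = pos[i, 1] + dy
            du = delta_u(pos, nv, i, xn, yn, half_kr02, l0, r0, l_min, l_max,
                         m_alpha, m_rmin, m_eps, m_cut2,
                         kappa, eps_vp, rm2, lj_cut2)
            ok = du <= 0.0
            if not ok and du != INF:
                ok = np.random.random() < math.exp(-du / kBT)
            if ok:
                pos[i, 0] = xn
                pos[i, 1] = yn
                acc += 1
                e_run += du
        since += 1
        if since >= resync_every:
            fv, fp, mv, mp, bb, lj = full_energy(
                pos, nv, fene_k, l0, l_min, l_max, r0,
                m_alpha, m_rmin, m_eps, m_cut, kappa, eps_vp, rm, lj_cut)
            e_run = fv + fp + mv + mp + bb + lj
            since = 0
    return acc, e_run


@njit(cache=True)
def mc_sample_distance(pos, nv, a, b, n_samples, sample_every,
                       max_disp, kBT, fene_k, l0, l_min, l_max, r0,
                       m_alpha, m_rmin, m_eps, m_cut,
                       kappa, eps_vp, rm, lj_cut):
    """Advance the chain and record the a-b bead distance every
    ``sample_every`` MCS; returns the sample array."""
    out = np.empty(n_samples)
    e = 0.0
    for s in range(n_samples):
        _, e = mc_block(pos, nv, sample_every, max_disp, kBT,
                        fene_k, l0, l_min, l_max, r0,
                        m_alpha, m_rmin, m_eps, m_cut,
                        kappa, eps_vp, rm, lj_cut, e, 1 << 30)
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        out[s] = math.sqrt(dx * dx + dy * dy)
    return out


@njit(cache=True)
def mc_sample_mean_cos(pos, nv, n_samples, sample_every,
                       max_disp, kBT, fene_k, l0, l_min, l_max, r0,
                       m_alpha, m_rmin, m_eps, m_cut,
                       kappa, eps_vp, rm, lj_cut):
    """Advance the chain and record the polymer's mean interior-vertex
    cos(theta) every ``sample_every`` MCS."""
    ntot = pos.shape[0]
    npb = ntot - nv
    out = np.empty(n_samples)
    e = 0.0
    for s in range(n_samples):
        _, e = mc_block(pos, nv, sample_every, max_disp, kBT,
                        fene_k, l0, l_min, l_max, r0,
                        m_alpha, m_rmin, m_eps, m_cut,
                        kappa, eps_vp, rm, lj_cut, e, 1 << 30)
        acc = 0.0
        for v in range(1, npb - 1):
            g = nv + v
            acc += _cos_vertex(pos[g - 1, 0], pos[g - 1, 1], pos[g, 0],
                               pos[g, 1], pos[g + 1, 0], pos[g + 1, 1])
        out[s] = acc / (npb - 2)
    return out
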