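"""Numba kernels: neighbor lists, forces, BAOAB propagation, overlap relaxation.

These are the hot loops behind `simulate.run`.  Their energies/forces are
contract-tested against the all-pairs numpy reference in `forcefield`
(agreement to better than 1e-10 relative).

Coordinates handed to the force/propagation kernels are kept within one
box length of the primary cell (they are wrapped at every neighbor-list
rebuild), which lets the minimum-image convention be applied with single
conditional corrections instead of divisions.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ERR_OK = 0
ERR_OVERFLOW = 1  # pair-list capacity exceeded
ERR_FLOOR = 2  # pair distance below the hard floor
ERR_NONFINITE = 3

_FLOOR2 = 1e-8  # (1e-4 nm)^2


@njit(cache=True, fastmath=True)
def wrap_in_place(x, box):
    """Wrap coordinates into the primary cell (-L/2, L/2]."""
    n = x.shape[0]
    for i in range(n):
        for k in range(3):
            x[i, k] -= box[k] * np.round(x[i, k] / box[k])


@njit(cache=True, fastmath=True)
def build_pairs(x, box, rlist2, chain_id, pi, pj):
    """Neighbor search with bonded (i, i+1 same chain) exclusion.

    Assumes x within ~one box of the primary cell.  Returns the pair
    count, or -1 if capacity was exceeded.
    """
    n = x.shape[0]
    cap = pi.shape[0]
    cnt = 0
    bx, by, bz = box[0], box[1], box[2]
    hx, hy, hz = 0.5 * bx, 0.5 * by, 0.5 * bz
    rl = np.sqrt(rlist2)
    for i in range(n - 1):
        xi0, xi1, xi2 = x[i, 0], x[i, 1], x[i, 2]
        ci = chain_id[i]
        for j in range(i + 1, n):
            d2c = xi2 - x[j, 2]
            if d2c > hz:
                d2c -= bz
            elif d2c < -hz:
                d2c += bz
            if d2c > rl or d2c < -rl:
                continue
            d0 = xi0 - x[j, 0]
            if d0 > hx:
                d0 -= bx
            elif d0 < -hx:
                d0 += bx
            d1 = xi1 - x[j, 1]
            if d1 > hy:
                d1 -= by
            elif d1 < -hy:
                d1 += by
            r2 = d0 * d0 + d1 * d1 + d2c * d2c
            if r2 < rlist2:
                if ci == chain_id[j] and j - i == 1:
                    continue
                if cnt >= cap:
                    return -1
                pi[cnt] = i
                pj[cnt] = j
                cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def compute_forces(x, box, pi, pj, npairs, qi, qj, nq, lam, sig, q, bonds, f,
                   eps, rc_nl, rc_el, kappa, coul_pref,
                   r0, kb, shift_nonel):
    """Total potential energy and forces into `f`.

    pi/pj is the short-range pair list (stickiness cutoff), qi/qj the
    electrostatic pair list over charged beads only.  Returns
    (energy, err); err = ERR_FLOOR flags a pair below the distance floor.
    """
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    energy = 0.0
    bx, by, bz = box[0], box[1], box[2]
    hx, hy, hz = 0.5 * bx, 0.5 * by, 0.5 * bz

    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        d0 = x[i, 0] - x[j, 0]
        if d0 > hx:
            d0 -= bx
        elif d0 < -hx:
            d0 += bx
        d1 = x[i, 1] - x[j, 1]
        if d1 > hy:
            d1 -= by
        elif d1 < -hy:
            d1 += by
        d2 = x[i, 2] - x[j, 2]
        if d2 > hz:
            d2 -= bz
        elif d2 < -hz:
            d2 += bz
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        if r2 < _FLOOR2:
            return 0.0, ERR_FLOOR
        r = np.sqrt(r2)
        dr = r - r0
        energy += 0.5 * kb * dr * dr
        fm = -kb * dr / r
        f[i, 0] += fm * d0
        f[i, 1] += fm * d1
        f[i, 2] += fm * d2
        f[j, 0] -= fm * d0
        f[j, 1] -= fm * d1
        f[j, 2] -= fm * d2

    rc_nl2 = rc_nl * rc_nl
    rmin_fac2 = 2.0 ** (1.0 / 3.0)  # (2^{1/6})^2
    irc2 = 1.0 / (rc_nl * rc_nl)
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        d0 = x[i, 0] - x[j, 0]
        if d0 > hx:
            d0 -= bx
        elif d0 < -hx:
            d0 += bx
        d1 = x[i, 1] - x[j, 1]
        if d1 > hy:
            d1 -= by
        elif d1 < -hy:
            d1 += by
        d2 = x[i, 2] - x[j, 2]
        if d2 > hz:
            d2 -= bz
        elif d2 < -hz:
            d2 += bz
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        if r2 >= rc_nl2:
            continue
        if r2 < _FLOOR2:
            return 0.0, ERR_FLOOR
        lij = 0.5 * (lam[i] + lam[j])
        sij = 0.5 * (sig[i] + sig[j])
        ir2 = 1.0 / r2
        s2 = sij * sij * ir2
        sr6 = s2 * s2 * s2
        sr12 = sr6 * sr6
        lj = 4.0 * eps * (sr12 - sr6)
        dlj_r = -24.0 * eps * (2.0 * sr12 - sr6) * ir2  # (dLJ/dr)/r
        if r2 <= rmin_fac2 * sij * sij:
            energy += lj + (1.0 - lij) * eps
            fm = -dlj_r
        else:
            energy += lij * lj
            fm = -lij * dlj_r
        if shift_nonel:
            sc2 = sij * sij * irc2
            sc6 = sc2 * sc2 * sc2
            energy -= lij * 4.0 * eps * (sc6 * sc6 - sc6)
        f[i, 0] += fm * d0
        f[i, 1] += fm * d1
        f[i, 2] += fm * d2
        f[j, 0] -= fm * d0
        f[j, 1] -= fm * d1
        f[j, 2] -= fm * d2

    rc_el2 = rc_el * rc_el
    shift_el = np.exp(-kappa * rc_el) / rc_el
    for p in range(nq):
        i = qi[p]
        j = qj[p]
        d0 = x[i, 0] - x[j, 0]
        if d0 > hx:
            d0 -= bx
        elif d0 < -hx:
            d0 += bx
        d1 = x[i, 1] - x[j, 1]
        if d1 > hy:
            d1 -= by
        elif d1 < -hy:
            d1 += by
        d2 = x[i, 2] - x[j, 2]
        if d2 > hz:
            d2 -= bz
        elif d2 < -hz:
            d2 += bz
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        if r2 >= rc_el2:
            continue
        if r2 < _FLOOR2:
            return 0.0, ERR_FLOOR
        r = np.sqrt(r2)
        pref = coul_pref * q[i] * q[j]
        ekr = np.exp(-kappa * r)
        energy += pref * (ekr / r - shift_el)
        fm = pref * ekr * (kappa * r + 1.0) / (r2 * r)  # -(dE/dr)/r
        f[i, 0] += fm * d0
        f[i, 1] += fm * d1
        f[i, 2] += fm * d2
        f[j, 0] -= fm * d0
        f[j, 1] -= fm * d1
        f[j, 2] -= fm * d2

    return energy, ERR_OK


@njit(cache=True, fastmath=True)
def build_el_pairs(x, box, rlist2, chain_id, charged_idx, qi, qj):
    """Neighbor search over charged beads only, bonded pairs excluded.

    Stores original bead indices.  Returns the count or -1 on overflow.
    """
    m = charged_idx.shape[0]
    cap = qi.shape[0]
    cnt = 0
    bx, by, bz = box[0], box[1], box[2]
    hx, hy, hz = 0.5 * bx, 0.5 * by, 0.5 * bz
    for a in range(m - 1):
        i = charged_idx[a]
        xi0, xi1, xi2 = x[i, 0], x[i, 1], x[i, 2]
        ci = chain_id[i]
        for b in range(a + 1, m):
            j = charged_idx[b]
            d0 = xi0 - x[j, 0]
            if d0 > hx:
                d0 -= bx
            elif d0 < -hx:
                d0 += bx
            d1 = xi1 - x[j, 1]
            if d1 > hy:
                d1 -= by
            elif d1 < -hy:
                d1 += by
            d2 = xi2 - x[j, 2]
            if d2 > hz:
                d2 -= bz
            elif d2 < -hz:
                d2 += bz
            r2 = d0 * d0 + d1 * d1 + d2 * d2
            if r2 < rlist2:
                if ci == chain_id[j] and j - i == 1:
                    continue
                if cnt >= cap:
                    return -1
                qi[cnt] = i
                qj[cnt] = j
                cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def _rebuild(x, box, chain_id, charged_idx, rl_nl, rl_el, pi, pj, qi, qj):
    """Wrap coordinates and rebuild both pair lists.

    Returns (n_short, n_el); either is -1 on capacity overflow.
    """
    wrap_in_place(x, box)
    n_nl = build_pairs(x, box, rl_nl * rl_nl, chain_id, pi, pj)
    if n_nl < 0:
        return -1, 0
    if charged_idx.shape[0] > 1:
        n_el = build_el_pairs(x, box, rl_el * rl_el, chain_id,
                              charged_idx, qi, qj)
        if n_el < 0:
            return n_nl, -1
    else:
        n_el = 0
    return n_nl, n_el


@njit(cache=True, fastmath=True)
def run_segment(x, v, f, ref, box, masses, lam, sig, q, chain_id,
                charged_idx, bonds, pi, pj, qi, qj, n_nl_in, n_el_in,
                dt, gamma, kt, noise,
                eps, rc_nl, rc_el, kappa, coul_pref, r0, kb,
                shift_nonel, rl_nl, rl_el, skin):
    """Propagate `noise.shape[0]` BAOAB steps in place.

    Pair lists are rebuilt (and coordinates wrapped) on a half-skin
    displacement criterion.  Returns (energy, n_nl, n_el, err, step).
    """
    n = x.shape[0]
    nsteps = noise.shape[0]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    half = 0.5 * dt
    trig2 = 0.25 * skin * skin
    n_nl = n_nl_in
    n_el = n_el_in
    energy = 0.0

    for s in range(nsteps):
        for i in range(n):
            im = half / masses[i]
            sd = c2 * np.sqrt(kt / masses[i])
            for k in range(3):
                vv = v[i, k] + im * f[i, k]
                xx = x[i, k] + half * vv
                vv = c1 * vv + sd * noise[s, i, k]
                x[i, k] = xx + half * vv
                v[i, k] = vv
        maxd2 = 0.0
        for i in range(n):
            d0 = x[i, 0] - ref[i, 0]
            d1 = x[i, 1] - ref[i, 1]
            d2 = x[i, 2] - ref[i, 2]
            dd = d0 * d0 + d1 * d1 + d2 * d2
            if dd > maxd2:
                maxd2 = dd
        if maxd2 > trig2:
            n_nl, n_el = _rebuild(x, box, chain_id, charged_idx,
                                  rl_nl, rl_el, pi, pj, qi, qj)
            if n_nl < 0 or n_el < 0:
                return 0.0, n_nl, n_el, ERR_OVERFLOW, s
            for i in range(n):
                ref[i, 0] = x[i, 0]
                ref[i, 1] = x[i, 1]
                ref[i, 2] = x[i, 2]
        energy, err = compute_forces(x, box, pi, pj, n_nl, qi, qj, n_el,
                                     lam, sig, q, bonds, f, eps, rc_nl,
                                     rc_el, kappa, coul_pref, r0, kb,
                                     shift_nonel)
        if err != ERR_OK:
            return 0.0, n_nl, n_el, err, s
        if not np.isfinite(energy):
            return 0.0, n_nl, n_el, ERR_NONFINITE, s
        for i in range(n):
            im = half / masses[i]
            for k in range(3):
                v[i, k] += im * f[i, k]

    return energy, n_nl, n_el, ERR_OK, nsteps


@njit(cache=True, fastmath=True)
def descend(x, f, ref, box, chain_id, charged_idx, bonds, pi, pj, qi, qj,
            n_nl_in, n_el_in, lam, sig, q,
            eps, rc_nl, rc_el, kappa, coul_pref, r0, kb,
            shift_nonel, rl_nl, rl_el, skin, n_iter, max_disp):
    """Steepest-descent energy minimization with a per-bead displacement cap.

    Used to drain the excess potential energy of freshly packed slabs so
    the Langevin run starts without a heat burst.  Returns
    (energy, n_nl, n_el, err).
    """
    n = x.shape[0]
    trig2 = 0.25 * skin * skin
    n_nl = n_nl_in
    n_el = n_el_in
    energy = 0.0
    for it in range(n_iter):
        energy, err = compute_forces(x, box, pi, pj, n_nl, qi, qj, n_el,
                                     lam, sig, q, bonds, f, eps, rc_nl,
                                     rc_el, kappa, coul_pref, r0, kb,
                                     shift_nonel)
        if err != ERR_OK:
            return 0.0, n_nl, n_el, err
        for i in range(n):
            fmag = np.sqrt(f[i, 0] ** 2 + f[i, 1] ** 2 + f[i, 2] ** 2)
            if fmag < 1e-12:
                continue
            step = max_disp / fmag if fmag * 1e-4 > max_disp else 1e-4
            x[i, 0] += step * f[i, 0]
            x[i, 1] += step * f[i, 1]
            x[i, 2] += step * f[i, 2]
        maxd2 = 0.0
        for i in range(n):
            d0 = x[i, 0] - ref[i, 0]
            d1 = x[i, 1] - ref[i, 1]
            d2 = x[i, 2] - ref[i, 2]
            dd = d0 * d0 + d1 * d1 + d2 * d2
            if dd > maxd2:
                maxd2 = dd
        if maxd2 > trig2:
            n_nl, n_el = _rebuild(x, box, chain_id, charged_idx,
                                  rl_nl, rl_el, pi, pj, qi, qj)
            if n_nl < 0 or n_el < 0:
                return 0.0, n_nl, n_el, ERR_OVERFLOW
            for i in range(n):
                ref[i, 0] = x[i, 0]
                ref[i, 1] = x[i, 1]
                ref[i, 2] = x[i, 2]
    return energy, n_nl, n_el, ERR_OK


@njit(cache=True)
def relax_overlaps(x, box, chain_id, bonds, d_min, bond_r0, max_iter):
    """Push nonbonded bead pairs apart to at least d_min, keep bonds near r0.

    Geometric relaxation used only to clean up initial configurations.
    Pairs below d_min are pushed out to 1.15·d_min (hysteresis, so bond
    corrections cannot cycle them across the floor forever).  Returns the
    iteration count, or -1 if max_iter was insufficient.
    """
    n = x.shape[0]
    floor2 = d_min * d_min
    target = 1.15 * d_min
    target2 = target * target
    for it in range(max_iter):
        overlaps = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                if chain_id[i] == chain_id[j] and j - i == 1:
                    continue  # bonded pairs are handled by the bond pass
                d0 = x[i, 0] - x[j, 0]
                d0 -= box[0] * np.round(d0 / box[0])
                d1 = x[i, 1] - x[j, 1]
                d1 -= box[1] * np.round(d1 / box[1])
                d2 = x[i, 2] - x[j, 2]
                d2 -= box[2] * np.round(d2 / box[2])
                r2 = d0 * d0 + d1 * d1 + d2 * d2
                if r2 >= target2:
                    continue
                if r2 < floor2:
                    overlaps = True
                r = np.sqrt(r2)
                if r < 1e-6:
                    # coincident: split along x deterministically
                    d0, d1, d2, r = 1.0, 0.0, 0.0, 1.0
                push = 0.5 * (target - r) / r
                x[i, 0] += push * d0
                x[i, 1] += push * d1
                x[i, 2] += push * d2
                x[j, 0] -= push * d0
                x[j, 1] -= push * d1
                x[j, 2] -= push * d2
        for b in range(bonds.shape[0]):
            i = bonds[b, 0]
            j = bonds[b, 1]
            d0 = x[i, 0] - x[j, 0]
            d0 -= box[0] * np.round(d0 / box[0])
            d1 = x[i, 1] - x[j, 1]
            d1 -= box[1] * np.round(d1 / box[1])
            d2 = x[i, 2] - x[j, 2]
            d2 -= box[2] * np.round(d2 / box[2])
            r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
            if abs(r - bond_r0) > 0.08:
                corr = 0.5 * (r - bond_r0) / r
                x[i, 0] -= corr * d0
                x[i, 1] -= corr * d1
                x[i, 2] -= corr * d2
                x[j, 0] += corr * d0
                x[j, 1] += corr * d1
                x[j, 2] += corr * d2
        if not overlaps:
            return it
    return -1


@njit(cache=True)
def min_pair_distance(x, box):
    n = x.shape[0]
    best = 1e30
    for i in range(n - 1):
        for j in range(i + 1, n):
            d0 = x[i, 0] - x[j, 0]
            d0 -= box[0] * np.round(d0 / box[0])
            d1 = x[i, 1] - x[j, 1]
            d1 -= box[1] * np.round(d1 / box[1])
            d2 = x[i, 2] - x[j, 2]
            d2 -= box[2] * np.round(d2 / box[2])
            r2 = d0 * d0 + d1 * d1 + d2 * d2
            if r2 < best:
                best = r2
    return np.sqrt(best)
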