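"""Compiled inner loops: pair enumeration, forces, overdamped Langevin chunks.

All kernels work in reduced units (sigma = 1, epsilon = kT = 1) on float64
position arrays of shape (n, 3). Bonds are consecutive-bead pairs encoded as
a boolean mask of length n-1 (``bond_mask[i]`` is the bond between beads i
and i+1); an angle centred on bead i exists iff both flanking bonds do.

The Verlet pair list is rebuilt whenever any bead has moved more than half
the skin since the last build, via a linked-cell binning pass (O(n) for
compact configurations). ``neighbor_pairs`` is the brute-force O(n^2)
reference enumerator; ``neighbor_pairs_cells`` must return the same pair
set (up to order) and is what the integrator uses.
"""
import numpy as np
from numba import njit


@njit(cache=True)
def neighbor_pairs(pos, rlist):
    """All unordered pairs with separation < rlist, as (i, j) index arrays."""
    n = pos.shape[0]
    r2max = rlist * rlist
    cnt = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz < r2max:
                cnt += 1
    pi = np.empty(cnt, np.int64)
    pj = np.empty(cnt, np.int64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz < r2max:
                pi[k] = i
                pj[k] = j
                k += 1
    return pi, pj


@njit(cache=True, fastmath=True)
def neighbor_pairs_cells(pos, rlist):
    """Cell-list pair enumeration; same contract as neighbor_pairs."""
    n = pos.shape[0]
    if n < 64:
        return neighbor_pairs(pos, rlist)
    minx = pos[0, 0]
    maxx = pos[0, 0]
    miny = pos[0, 1]
    maxy = pos[0, 1]
    minz = pos[0, 2]
    maxz = pos[0, 2]
    for i in range(1, n):
        if pos[i, 0] < minx:
            minx = pos[i, 0]
        elif pos[i, 0] > maxx:
            maxx = pos[i, 0]
        if pos[i, 1] < miny:
            miny = pos[i, 1]
        elif pos[i, 1] > maxy:
            maxy = pos[i, 1]
        if pos[i, 2] < minz:
            minz = pos[i, 2]
        elif pos[i, 2] > maxz:
            maxz = pos[i, 2]
    ncx = int((maxx - minx) / rlist) + 1
    ncy = int((maxy - miny) / rlist) + 1
    ncz = int((maxz - minz) / rlist) + 1
    ncells = ncx * ncy * ncz
    if ncells > 64 * n:  # very dilute: binning overhead beats the payoff
        return neighbor_pairs(pos, rlist)
    cell = np.empty(n, np.int64)
    counts = np.zeros(ncells + 1, np.int64)
    inv = 1.0 / rlist
    for i in range(n):
        cx = int((pos[i, 0] - minx) * inv)
        cy = int((pos[i, 1] - miny) * inv)
        cz = int((pos[i, 2] - minz) * inv)
        c = cx + ncx * (cy + ncy * cz)
        cell[i] = c
        counts[c + 1] += 1
    for c in range(ncells):
        counts[c + 1] += counts[c]
    order = np.empty(n, np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        c = cell[i]
        order[fill[c]] = i
        fill[c] += 1
    r2max = rlist * rlist
    cap = 16 * n
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    k = 0
    for i in range(n):
        ci = cell[i]
        cx = ci % ncx
        cy = (ci // ncx) % ncy
        cz = ci // (ncx * ncy)
        for ox in range(-1, 2):
            x = cx + ox
            if x < 0 or x >= ncx:
                continue
            for oy in range(-1, 2):
                y = cy + oy
                if y < 0 or y >= ncy:
                    continue
                for oz in range(-1, 2):
                    z = cz + oz
                    if z < 0 or z >= ncz:
                        continue
                    c = x + ncx * (y + ncy * z)
                    for idx in range(counts[c], counts[c + 1]):
                        j = order[idx]
                        if j <= i:
                            continue
                        dx = pos[j, 0] - pos[i, 0]
                        dy = pos[j, 1] - pos[i, 1]
                        dz = pos[j, 2] - pos[i, 2]
                        if dx * dx + dy * dy + dz * dz < r2max:
                            if k == cap:
                                cap *= 2
                                npi = np.empty(cap, np.int64)
                                npj = np.empty(cap, np.int64)
                                npi[:k] = pi
                                npj[:k] = pj
                                pi = npi
                                pj = npj
                            pi[k] = i
                            pj[k] = j
                            k += 1
    return pi[:k].copy(), pj[:k].copy()


@njit(cache=True, fastmath=True)
def forces_energy(pos, pi, pj, bond_mask, angle_mask, labels,
                  kb, R0, Rshift, lj_cut, ka, theta0,
                  eshift, excl12, attraction, attr_cut,
                  conf_r, conf_k, f):
    """Forces (written into f) and total energy of the chromatin Hamiltonian.

    Terms: shifted FENE on present bonds, WCA excluded volume on listed
    pairs, harmonic angles on present triples, plus two optional terms used
    only by the synthetic-structure generator: a short-range like-label
    Lennard-Jones attraction and a harmonic spherical confinement wall.

    Returns (energy, bad_bond): bad_bond >= 0 flags a FENE domain violation
    (r >= Rshift + R0) on that bond, with energy = inf.
    """
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e = 0.0

    # shifted FENE bonds: U = -kb R0^2/2 ln(1 - u^2), u = (r - Rshift)/R0,
    # zero below Rshift (overlap penalised only by excluded volume)
    for i in range(n - 1):
        if not bond_mask[i]:
            continue
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= Rshift + R0:
            return np.inf, i
        if r > Rshift:
            u = (r - Rshift) / R0
            om = 1.0 - u * u
            e += -0.5 * kb * R0 * R0 * np.log(om)
            fr = -(kb * (r - Rshift) / om) / r
            f[i + 1, 0] += fr * dx
            f[i + 1, 1] += fr * dy
            f[i + 1, 2] += fr * dz
            f[i, 0] -= fr * dx
            f[i, 1] -= fr * dy
            f[i, 2] -= fr * dz

    # nonbonded pair terms over the Verlet list
    wca2 = lj_cut * lj_cut
    at2 = attr_cut * attr_cut
    if attraction > 0.0:
        sc6 = 1.0 / (at2 * at2 * at2)
        attr_shift = 4.0 * attraction * (sc6 * sc6 - sc6)
    else:
        attr_shift = 0.0
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        bonded = (j == i + 1) and bond_mask[i]
        if excl12 and bonded:
            continue
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 <= 0.0:
            continue
        if attraction > 0.0 and labels[i] == labels[j]:
            # full cut-and-shifted LJ well between like-labelled beads
            if r2 < at2:
                inv2 = 1.0 / r2
                s6 = inv2 * inv2 * inv2
                s12 = s6 * s6
                e += 4.0 * attraction * (s12 - s6) - attr_shift
                fr = 24.0 * attraction * (2.0 * s12 - s6) * inv2
                f[j, 0] += fr * dx
                f[j, 1] += fr * dy
                f[j, 2] += fr * dz
                f[i, 0] -= fr * dx
                f[i, 1] -= fr * dy
                f[i, 2] -= fr * dz
        else:
            if r2 < wca2:
                inv2 = 1.0 / r2
                s6 = inv2 * inv2 * inv2
                s12 = s6 * s6
                ev = 4.0 * (s12 - s6)
                if eshift:
                    ev += 1.0
                e += ev
                fr = 24.0 * (2.0 * s12 - s6) * inv2
                f[j, 0] += fr * dx
                f[j, 1] += fr * dy
                f[j, 2] += fr * dz
                f[i, 0] -= fr * dx
                f[i, 1] -= fr * dy
                f[i, 2] -= fr * dz

    # harmonic angles: U = ka/2 (theta - theta0)^2
    for i in range(n):
        if not angle_mask[i]:
            continue
        ax = pos[i - 1, 0] - pos[i, 0]
        ay = pos[i - 1, 1] - pos[i, 1]
        az = pos[i - 1, 2] - pos[i, 2]
        bx = pos[i + 1, 0] - pos[i, 0]
        by = pos[i + 1, 1] - pos[i, 1]
        bz = pos[i + 1, 2] - pos[i, 2]
        la = np.sqrt(ax * ax + ay * ay + az * az)
        lb = np.sqrt(bx * bx + by * by + bz * bz)
        c = (ax * bx + ay * by + az * bz) / (la * lb)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        dth = th - theta0
        e += 0.5 * ka * dth * dth
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8  # (theta - theta0)/sin(theta) stays finite at theta0 = pi
        fac = ka * dth / s
        ilab = 1.0 / (la * lb)
        ila2 = c / (la * la)
        ilb2 = c / (lb * lb)
        f1x = fac * (bx * ilab - ax * ila2)
        f1y = fac * (by * ilab - ay * ila2)
        f1z = fac * (bz * ilab - az * ila2)
        f3x = fac * (ax * ilab - bx * ilb2)
        f3y = fac * (ay * ilab - by * ilb2)
        f3z = fac * (az * ilab - bz * ilb2)
        f[i - 1, 0] += f1x
        f[i - 1, 1] += f1y
        f[i - 1, 2] += f1z
        f[i + 1, 0] += f3x
        f[i + 1, 1] += f3y
        f[i + 1, 2] += f3z
        f[i, 0] -= f1x + f3x
        f[i, 1] -= f1y + f3y
        f[i, 2] -= f1z + f3z

    # harmonic spherical confinement (generator only; conf_r <= 0 disables)
    if conf_r > 0.0:
        for i in range(n):
            rr = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
            if rr > conf_r:
                d = rr - conf_r
                e += 0.5 * conf_k * d * d
                fr = conf_k * d / rr
                f[i, 0] -= fr * pos[i, 0]
                f[i, 1] -= fr * pos[i, 1]
                f[i, 2] -= fr * pos[i, 2]

    return e, -1


@njit(cache=True, fastmath=True)
def langevin_chunk(pos, mobile, noise, dtg, nscale,
                   rlist, move2, pos0, pi, pj,
                   bond_mask, angle_mask, labels,
                   kb, R0, Rshift, lj_cut, ka, theta0,
                   eshift, excl12, attraction, attr_cut, conf_r, conf_k):
    """Advance overdamped Langevin dynamics by noise.shape[0] steps in place.

    Update per mobile bead: x += (dt/gamma) F + sqrt(2 kT dt/gamma) xi.
    Frozen beads (mobile == 0) never move but keep exerting forces.
    Returns (pi, pj, pos0, bad_bond, steps_done).
    """
    n = pos.shape[0]
    f = np.empty((n, 3))
    nsteps = noise.shape[0]
    for t in range(nsteps):
        dmax = 0.0
        for i in range(n):
            dx = pos[i, 0] - pos0[i, 0]
            dy = pos[i, 1] - pos0[i, 1]
            dz = pos[i, 2] - pos0[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > dmax:
                dmax = d2
        if dmax > move2:
            pi, pj = neighbor_pairs_cells(pos, rlist)
            pos0 = pos.copy()
        e, bad = forces_energy(pos, pi, pj, bond_mask, angle_mask, labels,
                               kb, R0, Rshift, lj_cut, ka, theta0,
                               eshift, excl12, attraction, attr_cut,
                               conf_r, conf_k, f)
        if bad >= 0:
            return pi, pj, pos0, bad, t
        for i in range(n):
            if mobile[i] > 0.0:
                pos[i, 0] += dtg * f[i, 0] + nscale * noise[t, i, 0]
                pos[i, 1] += dtg * f[i, 1] + nscale * noise[t, i, 1]
                pos[i, 2] += dtg * f[i, 2] + nscale * noise[t, i, 2]
    return pi, pj, pos0, -1, nsteps


@njit(cache=True, fastmath=True)
def end_candidate_pairs(pos, end_beads, active, rcap):
    """Unordered pairs of distinct active free ends within capture radius."""
    m = end_beads.shape[0]
    r2 = rcap * rcap
    cnt = 0
    for a in range(m - 1):
        if not active[a]:
            continue
        ia = end_beads[a]
        for b in range(a + 1, m):
            if not active[b]:
                continue
            ib = end_beads[b]
            dx = pos[ib, 0] - pos[ia, 0]
            dy = pos[ib, 1] - pos[ia, 1]
            dz = pos[ib, 2] - pos[ia, 2]
            if dx * dx + dy * dy + dz * dz <= r2:
                cnt += 1
    ea = np.empty(cnt, np.int64)
    eb = np.empty(cnt, np.int64)
    k = 0
    for a in range(m - 1):
        if not active[a]:
            continue
        ia = end_beads[a]
        for b in range(a + 1, m):
            if not active[b]:
                continue
            ib = end_beads[b]
            dx = pos[ib, 0] - pos[ia, 0]
            dy = pos[ib, 1] - pos[ia, 1]
            dz = pos[ib, 2] - pos[ia, 2]
            if dx * dx + dy * dy + dz * dz <= r2:
                ea[k] = a
                eb[k] = b
                k += 1
    return ea, eb
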