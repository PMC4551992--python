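"""Numba kernels for the grand-canonical Metropolis engine.

Layout contract with :mod:`brushsim.gcmc`:

* particle arrays are padded to a fixed capacity; brush beads occupy
  slots ``[0, n_brush)`` and never move index; solvent occupies
  ``[n_brush, n_act)`` and is compacted with swap-with-last on deletion;
* positions are stored unwrapped; the minimum image is applied in x, y
  (and z when ``periodic_z``); cell membership uses wrapped coordinates;
* a single ``np.random`` stream seeded once drives the whole run, and
  sampling consumes no randomness, so the trajectory is bit-reproducible
  for a given seed regardless of sampling cadence.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_PER_CELL = 96

MOVE_DISP_FREE = 0
MOVE_DISP_GRAFT = 1
MOVE_INSERT = 2
MOVE_DELETE = 3


@njit(cache=True)
def _ncells(Lx, Ly, h, periodic_z):
    ncx = int(Lx)
    if ncx < 3:
        ncx = 1
    ncy = int(Ly)
    if ncy < 3:
        ncy = 1
    ncz = int(h)
    if periodic_z:
        if ncz < 3:
            ncz = 1
    else:
        if ncz < 1:
            ncz = 1
    return ncx, ncy, ncz


@njit(cache=True)
def _cell_of_xyz(x, y, z, Lx, Ly, h, ncx, ncy, ncz, periodic_z):
    xr = x - Lx * np.floor(x / Lx)
    yr = y - Ly * np.floor(y / Ly)
    cx = int(xr * ncx / Lx)
    if cx >= ncx:
        cx = ncx - 1
    cy = int(yr * ncy / Ly)
    if cy >= ncy:
        cy = ncy - 1
    if periodic_z:
        zr = z - h * np.floor(z / h)
        cz = int(zr * ncz / h)
    else:
        cz = int(z * ncz / h)
    if cz >= ncz:
        cz = ncz - 1
    if cz < 0:
        cz = 0
    return (cz * ncy + cy) * ncx + cx


@njit(cache=True)
def _cl_add(i, c, cell_cnt, cell_list, cell_of, slot_of):
    k = cell_cnt[c]
    if k >= cell_list.shape[1]:
        return False
    cell_list[c, k] = i
    cell_of[i] = c
    slot_of[i] = k
    cell_cnt[c] = k + 1
    return True


@njit(cache=True)
def _cl_remove(i, cell_cnt, cell_list, cell_of, slot_of):
    c = cell_of[i]
    s = slot_of[i]
    last = cell_cnt[c] - 1
    j = cell_list[c, last]
    cell_list[c, s] = j
    slot_of[j] = s
    cell_cnt[c] = last


@njit(cache=True)
def _point_pair_energy(px, py, pz, sp, skip_i, pos, species,
                       cell_cnt, cell_list, ncx, ncy, ncz,
                       Lx, Ly, h, periodic_z, a_mat,
                       excl, n_excl):
    """Pair energy of a (trial) point against all particles in the cell list."""
    xr = px - Lx * np.floor(px / Lx)
    yr = py - Ly * np.floor(py / Ly)
    cx = int(xr * ncx / Lx)
    if cx >= ncx:
        cx = ncx - 1
    cy = int(yr * ncy / Ly)
    if cy >= ncy:
        cy = ncy - 1
    if periodic_z:
        zr = pz - h * np.floor(pz / h)
        cz = int(zr * ncz / h)
    else:
        cz = int(pz * ncz / h)
    if cz >= ncz:
        cz = ncz - 1
    if cz < 0:
        cz = 0

    e = 0.0
    for ddz in range(-1, 2):
        if periodic_z:
            if ncz == 1:
                if ddz != 0:
                    continue
                cz2 = 0
            else:
                cz2 = (cz + ddz) % ncz
        else:
            cz2 = cz + ddz
            if cz2 < 0 or cz2 >= ncz:
                continue
        for ddy in range(-1, 2):
            if ncy == 1:
                if ddy != 0:
                    continue
                cy2 = 0
            else:
                cy2 = (cy + ddy) % ncy
            for ddx in range(-1, 2):
                if ncx == 1:
                    if ddx != 0:
                        continue
                    cx2 = 0
                else:
                    cx2 = (cx + ddx) % ncx
                c = (cz2 * ncy + cy2) * ncx + cx2
                for k in range(cell_cnt[c]):
                    j = cell_list[c, k]
                    if j == skip_i:
                        continue
                    skip = False
                    for q in range(n_excl):
                        if excl[q] == j:
                            skip = True
                            break
                    if skip:
                        continue
                    dx = pos[j, 0] - px
                    dx -= Lx * np.rint(dx / Lx)
                    dy = pos[j, 1] - py
                    dy -= Ly * np.rint(dy / Ly)
                    dz = pos[j, 2] - pz
                    if periodic_z:
                        dz -= h * np.rint(dz / h)
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < 1.0:
                        r = np.sqrt(r2)
                        aij = a_mat[sp, species[j]]
                        d = 1.0 - r
                        e += 0.5 * aij * d * d
    return e


@njit(cache=True)
def _wall_energy(z, h, aw_s, aw_t, periodic_z):
    if periodic_z:
        return 0.0
    e = 0.0
    if z < 1.0:
        d = 1.0 - z
        e += 0.5 * aw_s * d * d
    g = h - z
    if g < 1.0:
        d = 1.0 - g
        e += 0.5 * aw_t * d * d
    return e


@njit(cache=True)
def _bond_energy_at(i, px, py, pz, pos, bnb, bkap, br0, bdeg,
                    Lx, Ly, h, periodic_z):
    e = 0.0
    for k in range(bdeg[i]):
        j = bnb[i, k]
        dx = pos[j, 0] - px
        dx -= Lx * np.rint(dx / Lx)
        dy = pos[j, 1] - py
        dy -= Ly * np.rint(dy / Ly)
        dz = pos[j, 2] - pz
        if periodic_z:
            dz -= h * np.rint(dz / h)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - br0[i, k]
        e += 0.5 * bkap[i, k] * d * d
    return e


@njit(cache=True)
def _total_energy_cl(pos, species, n_act, cell_cnt, cell_list, cell_of,
                     ncx, ncy, ncz, Lx, Ly, h, periodic_z, a_mat,
                     bnb, bkap, br0, bdeg, exclude_bonded,
                     aw_s, aw_t):
    """Full energy via the cell list: unique pairs (j > i), bonds, walls."""
    e_pair = 0.0
    for i in range(n_act):
        px = pos[i, 0]
        py = pos[i, 1]
        pz = pos[i, 2]
        ci = cell_of[i]
        cx = ci % ncx
        cy = (ci // ncx) % ncy
        cz = ci // (ncx * ncy)
        for ddz in range(-1, 2):
            if periodic_z:
                if ncz == 1:
                    if ddz != 0:
                        continue
                    cz2 = 0
                else:
                    cz2 = (cz + ddz) % ncz
            else:
                cz2 = cz + ddz
                if cz2 < 0 or cz2 >= ncz:
                    continue
            for ddy in range(-1, 2):
                if ncy == 1:
                    if ddy != 0:
                        continue
                    cy2 = 0
                else:
                    cy2 = (cy + ddy) % ncy
                for ddx in range(-1, 2):
                    if ncx == 1:
                        if ddx != 0:
                            continue
                        cx2 = 0
                    else:
                        cx2 = (cx + ddx) % ncx
                    c = (cz2 * ncy + cy2) * ncx + cx2
                    for k in range(cell_cnt[c]):
                        j = cell_list[c, k]
                        if j <= i:
                            continue
                        if exclude_bonded:
                            skip = False
                            for q in range(bdeg[i]):
                                if bnb[i, q] == j:
                                    skip = True
                                    break
                            if skip:
                                continue
                        dx = pos[j, 0] - px
                        dx -= Lx * np.rint(dx / Lx)
                        dy = pos[j, 1] - py
                        dy -= Ly * np.rint(dy / Ly)
                        dz = pos[j, 2] - pz
                        if periodic_z:
                            dz -= h * np.rint(dz / h)
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 < 1.0:
                            r = np.sqrt(r2)
                            aij = a_mat[species[i], species[j]]
                            d = 1.0 - r
                            e_pair += 0.5 * aij * d * d
    e_bond = 0.0
    for i in range(n_act):
        e_bond += _bond_energy_at(i, pos[i, 0], pos[i, 1], pos[i, 2], pos,
                                  bnb, bkap, br0, bdeg, Lx, Ly, h, periodic_z)
    e_bond *= 0.5  # each bond visited from both ends
    e_wall = 0.0
    for i in range(n_act):
        e_wall += _wall_energy(pos[i, 2], h, aw_s, aw_t, periodic_z)
    return e_pair + e_bond + e_wall


@njit(cache=True)
def run_mc_kernel(pos, species, graft, bnb, bkap, br0, bdeg,
                  mobile_brush, graft_idx,
                  n_brush, n0,
                  a_mat, aw_s, aw_t,
                  Lx, Ly, h, periodic_z,
                  activity, max_disp_init, tune,  # max_disp_init: per species class

                  n_equil, n_prod, sample_interval,
                  disp_attempts, gc_attempts, gc_frac, gc_min_attempts,
                  exclude_bonded,
                  nbins, bin_width,
                  widom_per_sample,
                  store_frames, seed):
    """Run the full grand-canonical Metropolis chain.

    One sweep = one attempted displacement per mobile particle (or
    ``disp_attempts`` if >= 0) followed by insertion/deletion attempts
    (``gc_attempts`` if >= 0, else ``gc_frac`` of the current solvent count,
    each attempt choosing insert or delete with probability 1/2).
    """
    np.random.seed(seed)

    capacity = pos.shape[0]
    n_act = n0
    n_species = a_mat.shape[0]
    n_mb = mobile_brush.shape[0]
    ncx, ncy, ncz = _ncells(Lx, Ly, h, periodic_z)
    ncell = ncx * ncy * ncz
    volume = Lx * Ly * h

    cell_cnt = np.zeros(ncell, dtype=np.int64)
    cell_list = np.zeros((ncell, MAX_PER_CELL), dtype=np.int64)
    cell_of = np.zeros(capacity, dtype=np.int64)
    slot_of = np.zeros(capacity, dtype=np.int64)
    overflow = 0
    for i in range(n_act):
        c = _cell_of_xyz(pos[i, 0], pos[i, 1], pos[i, 2],
                         Lx, Ly, h, ncx, ncy, ncz, periodic_z)
        if not _cl_add(i, c, cell_cnt, cell_list, cell_of, slot_of):
            overflow = 1

    n_samples = 0
    if sample_interval > 0:
        n_samples = n_prod // sample_interval
    samp_sweep = np.zeros(n_samples, dtype=np.int64)
    samp_nsolv = np.zeros(n_samples, dtype=np.int64)
    samp_energy = np.zeros(n_samples, dtype=np.float64)
    samp_tip = np.zeros(n_samples, dtype=np.float64)
    hist = np.zeros((n_species, nbins), dtype=np.float64)
    n_graft = graft_idx.shape[0]
    graft_xy = np.zeros((n_samples, n_graft, 2), dtype=np.float64)
    if store_frames:
        frames = np.zeros((n_samples, capacity, 3), dtype=np.float64)
        frames_n = np.zeros(n_samples, dtype=np.int64)
    else:
        frames = np.zeros((1, 1, 3), dtype=np.float64)
        frames_n = np.zeros(1, dtype=np.int64)

    stats = np.zeros((4, 2), dtype=np.int64)  # [move, (attempted, accepted)]
    # one displacement amplitude per species class, tuned independently so
    # that stiff-bonded beads are not frozen by a solvent-dominated step
    max_disp = max_disp_init.copy()
    win_att = np.zeros(n_species, dtype=np.int64)
    win_acc = np.zeros(n_species, dtype=np.int64)
    widom_sum = 0.0
    widom_cnt = 0
    no_excl = np.zeros(1, dtype=np.int64)

    isample = 0
    total_sweeps = n_equil + n_prod
    for sweep in range(total_sweeps):
        equil = sweep < n_equil
        ns = n_act - n_brush
        nd = disp_attempts if disp_attempts >= 0 else (n_mb + ns)
        for _att in range(nd):
            ns_now = n_act - n_brush
            n_mobile = n_mb + ns_now
            if n_mobile == 0:
                break
            t = int(np.random.random() * n_mobile)
            if t >= n_mobile:
                t = n_mobile - 1
            if t < n_mb:
                i = mobile_brush[t]
            else:
                i = n_brush + (t - n_mb)
            is_graft = graft[i] == 1
            mtype = MOVE_DISP_GRAFT if is_graft else MOVE_DISP_FREE
            sp = species[i]
            stats[mtype, 0] += 1
            win_att[sp] += 1
            step = max_disp[sp]
            dx = (2.0 * np.random.random() - 1.0) * step
            dy = (2.0 * np.random.random() - 1.0) * step
            if is_graft:
                dz = 0.0
            else:
                dz = (2.0 * np.random.random() - 1.0) * step
            px = pos[i, 0] + dx
            py = pos[i, 1] + dy
            pz = pos[i, 2] + dz
            if not periodic_z and (pz < 0.0 or pz > h):
                continue  # hard reflection: reject moves leaving [0, h]
            if exclude_bonded:
                excl = bnb[i]
                nexcl = bdeg[i]
            else:
                excl = no_excl
                nexcl = 0
            e_old = _point_pair_energy(pos[i, 0], pos[i, 1], pos[i, 2], sp, i,
                                       pos, species, cell_cnt, cell_list,
                                       ncx, ncy, ncz, Lx, Ly, h, periodic_z,
                                       a_mat, excl, nexcl)
            e_old += _wall_energy(pos[i, 2], h, aw_s, aw_t, periodic_z)
            e_old += _bond_energy_at(i, pos[i, 0], pos[i, 1], pos[i, 2], pos,
                                     bnb, bkap, br0, bdeg, Lx, Ly, h, periodic_z)
            e_new = _point_pair_energy(px, py, pz, sp, i,
                                       pos, species, cell_cnt, cell_list,
                                       ncx, ncy, ncz, Lx, Ly, h, periodic_z,
                                       a_mat, excl, nexcl)
            e_new += _wall_energy(pz, h, aw_s, aw_t, periodic_z)
            e_new += _bond_energy_at(i, px, py, pz, pos,
                                     bnb, bkap, br0, bdeg, Lx, Ly, h, periodic_z)
            dU = e_new - e_old
            accept = False
            if dU <= 0.0:
                accept = True
            else:
                if np.random.random() < np.exp(-dU):
                    accept = True
            if accept:
                pos[i, 0] = px
                pos[i, 1] = py
                pos[i, 2] = pz
                c = _cell_of_xyz(px, py, pz, Lx, Ly, h,
                                 ncx, ncy, ncz, periodic_z)
                if c != cell_of[i]:
                    _cl_remove(i, cell_cnt, cell_list, cell_of, slot_of)
                    if not _cl_add(i, c, cell_cnt, cell_list, cell_of, slot_of):
                        overflow = 1
                stats[mtype, 1] += 1
                win_acc[sp] += 1

        ns_now = n_act - n_brush
        if gc_attempts >= 0:
            ngc = gc_attempts
        else:
            ngc = int(gc_frac * ns_now)
            if ngc < gc_min_attempts:
                ngc = gc_min_attempts
        for _att in range(ngc):
            ns_now = n_act - n_brush
            if np.random.random() < 0.5:
                # insertion of one solvent particle
                stats[MOVE_INSERT, 0] += 1
                if activity <= 0.0:
                    continue
                px = np.random.random() * Lx
                py = np.random.random() * Ly
                pz = np.random.random() * h
                dU = _point_pair_energy(px, py, pz, 0, -1,
                                        pos, species, cell_cnt, cell_list,
                                        ncx, ncy, ncz, Lx, Ly, h, periodic_z,
                                        a_mat, no_excl, 0)
                dU += _wall_energy(pz, h, aw_s, aw_t, periodic_z)
                ln_acc = np.log(activity * volume / (ns_now + 1.0)) - dU
                accept = False
                if ln_acc >= 0.0:
                    accept = True
                else:
                    r = np.random.random()
                    if r > 0.0 and np.log(r) < ln_acc:
                        accept = True
                if accept:
                    if n_act >= capacity:
                        overflow = 1
                    else:
                        pos[n_act, 0] = px
                        pos[n_act, 1] = py
                        pos[n_act, 2] = pz
                        species[n_act] = 0
                        c = _cell_of_xyz(px, py, pz, Lx, Ly, h,
                                         ncx, ncy, ncz, periodic_z)
                        if _cl_add(n_act, c, cell_cnt, cell_list,
                                   cell_of, slot_of):
                            n_act += 1
                            stats[MOVE_INSERT, 1] += 1
                        else:
                            overflow = 1
            else:
                # deletion of one solvent particle
                stats[MOVE_DELETE, 0] += 1
                if ns_now == 0:
                    continue
                k = int(np.random.random() * ns_now)
                if k >= ns_now:
                    k = ns_now - 1
                i = n_brush + k
                e_i = _point_pair_energy(pos[i, 0], pos[i, 1], pos[i, 2], 0, i,
                                         pos, species, cell_cnt, cell_list,
                                         ncx, ncy, ncz, Lx, Ly, h, periodic_z,
                                         a_mat, no_excl, 0)
                e_i += _wall_energy(pos[i, 2], h, aw_s, aw_t, periodic_z)
                dU = -e_i
                accept = False
                if activity <= 0.0:
                    accept = True  # N/(zV) -> inf dominates
                else:
                    ln_acc = np.log(ns_now / (activity * volume)) - dU
                    if ln_acc >= 0.0:
                        accept = True
                    else:
                        r = np.random.random()
                        if r > 0.0 and np.log(r) < ln_acc:
                            accept = True
                if accept:
                    _cl_remove(i, cell_cnt, cell_list, cell_of, slot_of)
                    last = n_act - 1
                    if last != i:
                        # move the tail particle into the vacated slot
                        _cl_remove(last, cell_cnt, cell_list, cell_of, slot_of)
                        pos[i, 0] = pos[last, 0]
                        pos[i, 1] = pos[last, 1]
                        pos[i, 2] = pos[last, 2]
                        species[i] = species[last]
                        c = _cell_of_xyz(pos[i, 0], pos[i, 1], pos[i, 2],
                                         Lx, Ly, h, ncx, ncy, ncz, periodic_z)
                        _cl_add(i, c, cell_cnt, cell_list, cell_of, slot_of)
                    n_act -= 1
                    stats[MOVE_DELETE, 1] += 1

        # displacement-size tuning, equilibration only (frozen for production)
        if tune and equil:
            for c in range(n_species):
                if win_att[c] >= 300:
                    acc = win_acc[c] / win_att[c]
                    f = acc / 0.4
                    if f < 0.5:
                        f = 0.5
                    if f > 1.5:
                        f = 1.5
                    max_disp[c] *= f
                    if max_disp[c] < 0.005:
                        max_disp[c] = 0.005
                    cap = 2.0
                    if not periodic_z and h / 2.0 < cap:
                        cap = h / 2.0
                    if max_disp[c] > cap:
                        max_disp[c] = cap
                    win_att[c] = 0
                    win_acc[c] = 0

        # sampling
        if not equil and sample_interval > 0:
            k = sweep - n_equil + 1
            if k % sample_interval == 0 and isample < n_samples:
                samp_sweep[isample] = k
                samp_nsolv[isample] = n_act - n_brush
                samp_energy[isample] = _total_energy_cl(
                    pos, species, n_act, cell_cnt, cell_list, cell_of,
                    ncx, ncy, ncz, Lx, Ly, h, periodic_z, a_mat,
                    bnb, bkap, br0, bdeg, exclude_bonded, aw_s, aw_t)
                f = 0.0
                if not periodic_z:
                    for i in range(n_act):
                        g = h - pos[i, 2]
                        if g < 1.0:
                            f += aw_t * (1.0 - g)
                samp_tip[isample] = f
                for i in range(n_act):
                    zz = pos[i, 2]
                    if periodic_z:
                        zz = zz - h * np.floor(zz / h)
                    b = int(zz / bin_width)
                    if b < 0:
                        b = 0
                    if b >= nbins:
                        b = nbins - 1
                    hist[species[i], b] += 1.0
                for g in range(n_graft):
                    graft_xy[isample, g, 0] = pos[graft_idx[g], 0]
                    graft_xy[isample, g, 1] = pos[graft_idx[g], 1]
                if store_frames:
                    for i in range(n_act):
                        frames[isample, i, 0] = pos[i, 0]
                        frames[isample, i, 1] = pos[i, 1]
                        frames[isample, i, 2] = pos[i, 2]
                    frames_n[isample] = n_act
                if widom_per_sample > 0:
                    for _w in range(widom_per_sample):
                        px = np.random.random() * Lx
                        py = np.random.random() * Ly
                        pz = np.random.random() * h
                        dU = _point_pair_energy(px, py, pz, 0, -1,
                                                pos, species, cell_cnt,
                                                cell_list, ncx, ncy, ncz,
                                                Lx, Ly, h, periodic_z,
                                                a_mat, no_excl, 0)
                        dU += _wall_energy(pz, h, aw_s, aw_t, periodic_z)
                        widom_sum += np.exp(-dU)
                        widom_cnt += 1
                isample += 1

    return (samp_sweep, samp_nsolv, samp_energy, samp_tip, hist, graft_xy,
            frames, frames_n, stats, n_act, max_disp, widom_sum, widom_cnt,
            overflow)
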