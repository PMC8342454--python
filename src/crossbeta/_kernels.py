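"""Numba kernels for the coarse-grained Metropolis sampler.

The surrogate potential and the restraint collection are compiled to flat
arrays (see :func:`crossbeta.sampler.compile_system`) so the inner
Monte-Carlo loop runs in machine code.  Every kernel call recomputes all
cached energies from scratch on entry and then applies per-move deltas, so
incremental bookkeeping can never drift across calls.

Surrogate terms: harmonic virtual bonds, harmonic bond angles, intrinsic
(planar peptide) torsions, soft-core excluded volume, optional Gaussian
cohesion wells, and an optional flat-bottom spherical confinement.  Bonded
terms are intra-chain and therefore invariant under rigid chain moves;
only bead moves re-evaluate them.

Restraint bookkeeping: members are stored group-contiguously; ``mem_e``
holds per-member energies at unit restraint strength, ``grp_sum`` the
selected (n_active lowest) sum per group, and the collection total is the
sum over the ``n_act_groups`` lowest group sums.  Because the replica's
restraint scale multiplies every member equally, the active-set selection
is scale-invariant and energies are cached at unit scale.
"""

import math

import numpy as np
from numba import njit

# pair-term kinds
PAIR_BOND = 0      # harmonic: 0.5*k*(r-r0)^2
PAIR_WELL = 1      # gaussian well: -depth*exp(-(r-r0)^2/(2 sigma^2))


@njit(cache=True, fastmath=True)
def _flat_bottom(d, r1, r2, r3, r4, k):
    if d < r1:
        return 0.5 * k * (r2 - r1) ** 2 + k * (r2 - r1) * (r1 - d)
    if d < r2:
        return 0.5 * k * (d - r2) ** 2
    if d <= r3:
        return 0.0
    if d <= r4:
        return 0.5 * k * (d - r3) ** 2
    return 0.5 * k * (r4 - r3) ** 2 + k * (r4 - r3) * (d - r4)


@njit(cache=True, fastmath=True)
def _dihedral_deg(coords, i0, i1, i2, i3):
    b0x = coords[i1, 0] - coords[i0, 0]
    b0y = coords[i1, 1] - coords[i0, 1]
    b0z = coords[i1, 2] - coords[i0, 2]
    b1x = coords[i2, 0] - coords[i1, 0]
    b1y = coords[i2, 1] - coords[i1, 1]
    b1z = coords[i2, 2] - coords[i1, 2]
    b2x = coords[i3, 0] - coords[i2, 0]
    b2y = coords[i3, 1] - coords[i2, 1]
    b2z = coords[i3, 2] - coords[i2, 2]
    n1x = b0y * b1z - b0z * b1y
    n1y = b0z * b1x - b0x * b1z
    n1z = b0x * b1y - b0y * b1x
    n2x = b1y * b2z - b1z * b2y
    n2y = b1z * b2x - b1x * b2z
    n2z = b1x * b2y - b1y * b2x
    nb1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    m1x = (n1y * b1z - n1z * b1y) / nb1
    m1y = (n1z * b1x - n1x * b1z) / nb1
    m1z = (n1x * b1y - n1y * b1x) / nb1
    x = n1x * n2x + n1y * n2y + n1z * n2z
    y = m1x * n2x + m1y * n2y + m1z * n2z
    return math.degrees(math.atan2(y, x))


@njit(cache=True, fastmath=True)
def _wrap_deg(a):
    a = a - 360.0 * math.floor(a / 360.0)  # -> [0, 360)
    if a > 180.0:
        a -= 360.0
    return a


@njit(cache=True, fastmath=True)
def _angle_rad(coords, i, j, k):
    ax = coords[i, 0] - coords[j, 0]
    ay = coords[i, 1] - coords[j, 1]
    az = coords[i, 2] - coords[j, 2]
    bx = coords[k, 0] - coords[j, 0]
    by = coords[k, 1] - coords[j, 1]
    bz = coords[k, 2] - coords[j, 2]
    na = math.sqrt(ax * ax + ay * ay + az * az)
    nb = math.sqrt(bx * bx + by * by + bz * bz)
    c = (ax * bx + ay * by + az * bz) / (na * nb + 1e-300)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return math.acos(c)


@njit(cache=True, fastmath=True)
def member_energy(coords, m, mem_kind, mem_param,
                  di_a, di_b, di_r, di_k,
                  dh_idx, dh_center, dh_delta, dh_k):
    p = mem_param[m]
    if mem_kind[m] == 0:
        dx = coords[di_a[p], 0] - coords[di_b[p], 0]
        dy = coords[di_a[p], 1] - coords[di_b[p], 1]
        dz = coords[di_a[p], 2] - coords[di_b[p], 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        return _flat_bottom(d, di_r[p, 0], di_r[p, 1], di_r[p, 2],
                            di_r[p, 3], di_k[p])
    ang = _dihedral_deg(coords, dh_idx[p, 0], dh_idx[p, 1],
                        dh_idx[p, 2], dh_idx[p, 3])
    dev = _wrap_deg(ang - dh_center[p])
    excess = abs(dev) - dh_delta[p]
    if excess <= 0.0:
        return 0.0
    return 0.5 * dh_k[p] * excess * excess


@njit(cache=True, fastmath=True)
def _pair_energy(r, kind, p1, p2, p3):
    if kind == PAIR_BOND:
        return 0.5 * p2 * (r - p1) ** 2
    d = r - p1
    return -p2 * math.exp(-d * d / (2.0 * p3 * p3))


@njit(cache=True, fastmath=True)
def _excl_pair(r, r_ev, k_rep):
    if r < r_ev:
        return 0.5 * k_rep * (r_ev - r) ** 2
    return 0.0


@njit(cache=True, fastmath=True)
def _confine(x, y, z, conf_r, conf_k):
    """Flat-bottom spherical wall about the origin (surrogate for the
    finite simulation volume): zero inside conf_r, harmonic outside."""
    if conf_k <= 0.0:
        return 0.0
    r = math.sqrt(x * x + y * y + z * z)
    if r <= conf_r:
        return 0.0
    return 0.5 * conf_k * (r - conf_r) ** 2


@njit(cache=True, fastmath=True)
def _dist(coords, i, j):
    dx = coords[i, 0] - coords[j, 0]
    dy = coords[i, 1] - coords[j, 1]
    dz = coords[i, 2] - coords[j, 2]
    return math.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True, fastmath=True)
def cg_total(coords,
             pair_i, pair_j, pair_kind, pair_p1, pair_p2, pair_p3,
             an_i, an_j, an_k, an_t0, an_kf,
             od_idx, od_t0, od_kf,
             chain_of, pos_of, n_excl, r_ev, k_rep, conf_r, conf_k):
    e = 0.0
    for b in range(len(pair_i)):
        r = _dist(coords, pair_i[b], pair_j[b])
        e += _pair_energy(r, pair_kind[b], pair_p1[b], pair_p2[b],
                          pair_p3[b])
    for a in range(len(an_i)):
        th = _angle_rad(coords, an_i[a], an_j[a], an_k[a])
        e += 0.5 * an_kf[a] * (th - an_t0[a]) ** 2
    for t in range(len(od_t0)):
        ang = _dihedral_deg(coords, od_idx[t, 0], od_idx[t, 1],
                            od_idx[t, 2], od_idx[t, 3])
        dev = _wrap_deg(ang - od_t0[t])
        e += 0.5 * od_kf[t] * dev * dev
    n = len(coords)
    if conf_k > 0.0:
        for i in range(n):
            e += _confine(coords[i, 0], coords[i, 1], coords[i, 2],
                          conf_r, conf_k)
    if k_rep > 0.0:
        ev2 = r_ev * r_ev
        for i in range(n):
            for j in range(i + 1, n):
                if chain_of[i] == chain_of[j] and \
                        abs(pos_of[i] - pos_of[j]) <= n_excl:
                    continue
                dx = coords[i, 0] - coords[j, 0]
                dy = coords[i, 1] - coords[j, 1]
                dz = coords[i, 2] - coords[j, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < ev2:
                    e += _excl_pair(math.sqrt(d2), r_ev, k_rep)
    return e


@njit(cache=True, fastmath=True)
def _atom_local_cg(coords, i,
                   apair_off, apair_id,
                   pair_i, pair_j, pair_kind, pair_p1, pair_p2, pair_p3,
                   aang_off, aang_id, an_i, an_j, an_k, an_t0, an_kf,
                   aod_off, aod_id, od_idx, od_t0, od_kf,
                   chain_of, pos_of, n_excl, r_ev, k_rep, conf_r, conf_k):
    """Sum of all surrogate terms that involve atom i, at the current
    coordinates."""
    e = _confine(coords[i, 0], coords[i, 1], coords[i, 2], conf_r, conf_k)
    for t in range(apair_off[i], apair_off[i + 1]):
        b = apair_id[t]
        e += _pair_energy(_dist(coords, pair_i[b], pair_j[b]), pair_kind[b],
                          pair_p1[b], pair_p2[b], pair_p3[b])
    for t in range(aang_off[i], aang_off[i + 1]):
        a = aang_id[t]
        th = _angle_rad(coords, an_i[a], an_j[a], an_k[a])
        e += 0.5 * an_kf[a] * (th - an_t0[a]) ** 2
    for t in range(aod_off[i], aod_off[i + 1]):
        d = aod_id[t]
        ang = _dihedral_deg(coords, od_idx[d, 0], od_idx[d, 1],
                            od_idx[d, 2], od_idx[d, 3])
        dev = _wrap_deg(ang - od_t0[d])
        e += 0.5 * od_kf[d] * dev * dev
    if k_rep > 0.0:
        ev2 = r_ev * r_ev
        for j in range(len(coords)):
            if j == i:
                continue
            if chain_of[i] == chain_of[j] and \
                    abs(pos_of[i] - pos_of[j]) <= n_excl:
                continue
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < ev2:
                e += _excl_pair(math.sqrt(d2), r_ev, k_rep)
    return e


@njit(cache=True, fastmath=True)
def member_energies(coords, mem_kind, mem_param,
                    di_a, di_b, di_r, di_k,
                    dh_idx, dh_center, dh_delta, dh_k, mem_e):
    for m in range(len(mem_kind)):
        mem_e[m] = member_energy(coords, m, mem_kind, mem_param,
                                 di_a, di_b, di_r, di_k,
                                 dh_idx, dh_center, dh_delta, dh_k)


@njit(cache=True, fastmath=True)
def group_sum(mem_e, grp_off, g, nact):
    a = grp_off[g]
    b = grp_off[g + 1]
    m = b - a
    if nact >= m:
        s = 0.0
        for i in range(a, b):
            s += mem_e[i]
        return s
    tmp = np.sort(mem_e[a:b].copy())
    s = 0.0
    for i in range(nact):
        s += tmp[i]
    return s


@njit(cache=True, fastmath=True)
def collection_total(grp_sum_arr, n_act_groups):
    g = len(grp_sum_arr)
    if n_act_groups >= g:
        s = 0.0
        for i in range(g):
            s += grp_sum_arr[i]
        return s
    tmp = np.sort(grp_sum_arr.copy())
    s = 0.0
    for i in range(n_act_groups):
        s += tmp[i]
    return s


@njit(cache=True, fastmath=True)
def run_sweeps(coords, n_sweeps, beta, alpha,
               sigma_bead, sigma_trans, sigma_rot,
               # surrogate potential
               pair_i, pair_j, pair_kind, pair_p1, pair_p2, pair_p3,
               apair_off, apair_id, cpair_off, cpair_id,
               an_i, an_j, an_k, an_t0, an_kf, aang_off, aang_id,
               od_idx, od_t0, od_kf, aod_off, aod_id,
               chain_of, pos_of, n_excl, r_ev, k_rep, conf_r, conf_k,
               chain_first, chain_last,
               # restraint members (group-contiguous)
               mem_kind, mem_param,
               di_a, di_b, di_r, di_k,
               dh_idx, dh_center, dh_delta, dh_k,
               grp_of_mem, grp_off, grp_nact, n_act_groups,
               amem_off, amem_id, cmem_off, cmem_id,
               seed):
    """Run ``n_sweeps`` Metropolis sweeps at inverse temperature ``beta``
    (mol/kJ) and restraint scale ``alpha``; returns cached energies and
    acceptance counters.  One sweep = one displacement attempt per bead
    plus one rigid translate+rotate attempt per chain."""
    np.random.seed(seed)
    n_atoms = len(coords)
    n_chains = len(chain_first)
    n_groups = len(grp_off) - 1
    full_act = n_act_groups >= n_groups

    e_cg = cg_total(coords, pair_i, pair_j, pair_kind, pair_p1, pair_p2,
                    pair_p3, an_i, an_j, an_k, an_t0, an_kf,
                    od_idx, od_t0, od_kf,
                    chain_of, pos_of, n_excl, r_ev, k_rep, conf_r, conf_k)
    mem_e = np.empty(len(mem_kind))
    member_energies(coords, mem_kind, mem_param, di_a, di_b, di_r, di_k,
                    dh_idx, dh_center, dh_delta, dh_k, mem_e)
    grp_sum_arr = np.empty(n_groups)
    for g in range(n_groups):
        grp_sum_arr[g] = group_sum(mem_e, grp_off, g, grp_nact[g])
    e_rest = collection_total(grp_sum_arr, n_act_groups)

    # scratch buffers
    max_mem = 1
    for i in range(n_atoms):
        max_mem = max(max_mem, amem_off[i + 1] - amem_off[i])
    for c in range(n_chains):
        max_mem = max(max_mem, cmem_off[c + 1] - cmem_off[c])
    old_mem = np.empty(max_mem)
    touched = np.empty(max_mem, dtype=np.int64)
    grp_old = np.empty(max_mem)
    max_chain = 1
    for c in range(n_chains):
        max_chain = max(max_chain, chain_last[c] - chain_first[c])
    old_xyz = np.empty((max_chain, 3))

    acc_bead = 0
    att_bead = 0
    acc_chain = 0
    att_chain = 0

    for _ in range(n_sweeps):
        # ---- single-bead displacements --------------------------------
        for i in range(n_atoms):
            att_bead += 1
            xo0, xo1, xo2 = coords[i, 0], coords[i, 1], coords[i, 2]
            e_loc_old = _atom_local_cg(
                coords, i, apair_off, apair_id, pair_i, pair_j, pair_kind,
                pair_p1, pair_p2, pair_p3, aang_off, aang_id, an_i, an_j,
                an_k, an_t0, an_kf, aod_off, aod_id, od_idx, od_t0, od_kf,
                chain_of, pos_of, n_excl, r_ev, k_rep, conf_r, conf_k)
            coords[i, 0] = xo0 + sigma_bead * np.random.normal()
            coords[i, 1] = xo1 + sigma_bead * np.random.normal()
            coords[i, 2] = xo2 + sigma_bead * np.random.normal()
            e_loc_new = _atom_local_cg(
                coords, i, apair_off, apair_id, pair_i, pair_j, pair_kind,
                pair_p1, pair_p2, pair_p3, aang_off, aang_id, an_i, an_j,
                an_k, an_t0, an_kf, aod_off, aod_id, od_idx, od_t0, od_kf,
                chain_of, pos_of, n_excl, r_ev, k_rep, conf_r, conf_k)
            d_cg = e_loc_new - e_loc_old
            nm = amem_off[i + 1] - amem_off[i]
            ng = 0
            for t in range(nm):
                m = amem_id[amem_off[i] + t]
                old_mem[t] = mem_e[m]
                g = grp_of_mem[m]
                seen = False
                for u in range(ng):
                    if touched[u] == g:
                        seen = True
                        break
                if not seen:
                    touched[ng] = g
                    grp_old[ng] = grp_sum_arr[g]
                    ng += 1
                mem_e[m] = member_energy(coords, m, mem_kind, mem_param,
                                         di_a, di_b, di_r, di_k,
                                         dh_idx, dh_center, dh_delta, dh_k)
            d_rest = 0.0
            if nm > 0:
                for u in range(ng):
                    g = touched[u]
                    grp_sum_arr[g] = group_sum(mem_e, grp_off, g,
                                               grp_nact[g])
                if full_act:
                    for u in range(ng):
                        d_rest += grp_sum_arr[touched[u]] - grp_old[u]
                else:
                    d_rest = collection_total(grp_sum_arr,
                                              n_act_groups) - e_rest
            delta = d_cg + alpha * d_rest
            accept = delta <= 0.0
            if not accept:
                arg = beta * delta
                if arg < 50.0 and np.random.random() < math.exp(-arg):
                    accept = True
            if accept:
                acc_bead += 1
                e_cg += d_cg
                e_rest += d_rest
            else:
                coords[i, 0] = xo0
                coords[i, 1] = xo1
                coords[i, 2] = xo2
                for t in range(nm):
                    m = amem_id[amem_off[i] + t]
                    mem_e[m] = old_mem[t]
                for u in range(ng):
                    grp_sum_arr[touched[u]] = grp_old[u]

        # ---- rigid chain moves ----------------------------------------
        # bonded terms are intra-chain and rigid-invariant; only wells,
        # excluded volume, confinement and cross-chain restraints change
        for c in range(n_chains):
            att_chain += 1
            a0 = chain_first[c]
            a1 = chain_last[c]
            nc = a1 - a0
            for t in range(nc):
                old_xyz[t, 0] = coords[a0 + t, 0]
                old_xyz[t, 1] = coords[a0 + t, 1]
                old_xyz[t, 2] = coords[a0 + t, 2]
            e_old = 0.0
            for t in range(cpair_off[c], cpair_off[c + 1]):
                b = cpair_id[t]
                e_old += _pair_energy(_dist(coords, pair_i[b], pair_j[b]),
                                      pair_kind[b], pair_p1[b], pair_p2[b],
                                      pair_p3[b])
            if conf_k > 0.0:
                for t in range(nc):
                    e_old += _confine(coords[a0 + t, 0], coords[a0 + t, 1],
                                      coords[a0 + t, 2], conf_r, conf_k)
            if k_rep > 0.0:
                ev2 = r_ev * r_ev
                for t in range(nc):
                    i = a0 + t
                    for j in range(n_atoms):
                        if chain_of[j] == c:
                            continue
                        dx = coords[i, 0] - coords[j, 0]
                        dy = coords[i, 1] - coords[j, 1]
                        dz = coords[i, 2] - coords[j, 2]
                        d2 = dx * dx + dy * dy + dz * dz
                        if d2 < ev2:
                            e_old += _excl_pair(math.sqrt(d2), r_ev, k_rep)
            cx = 0.0
            cy = 0.0
            cz = 0.0
            for t in range(nc):
                cx += coords[a0 + t, 0]
                cy += coords[a0 + t, 1]
                cz += coords[a0 + t, 2]
            cx /= nc
            cy /= nc
            cz /= nc
            ax = np.random.normal()
            ay = np.random.normal()
            az = np.random.normal()
            an = math.sqrt(ax * ax + ay * ay + az * az) + 1e-300
            ax /= an
            ay /= an
            az /= an
            theta = sigma_rot * np.random.normal()
            ct = math.cos(theta)
            st = math.sin(theta)
            tx = sigma_trans * np.random.normal()
            ty = sigma_trans * np.random.normal()
            tz = sigma_trans * np.random.normal()
            for t in range(nc):
                px = coords[a0 + t, 0] - cx
                py = coords[a0 + t, 1] - cy
                pz = coords[a0 + t, 2] - cz
                dot = ax * px + ay * py + az * pz
                rx = px * ct + (ay * pz - az * py) * st + ax * dot * (1 - ct)
                ry = py * ct + (az * px - ax * pz) * st + ay * dot * (1 - ct)
                rz = pz * ct + (ax * py - ay * px) * st + az * dot * (1 - ct)
                coords[a0 + t, 0] = cx + rx + tx
                coords[a0 + t, 1] = cy + ry + ty
                coords[a0 + t, 2] = cz + rz + tz
            e_new = 0.0
            for t in range(cpair_off[c], cpair_off[c + 1]):
                b = cpair_id[t]
                e_new += _pair_energy(_dist(coords, pair_i[b], pair_j[b]),
                                      pair_kind[b], pair_p1[b], pair_p2[b],
                                      pair_p3[b])
            if conf_k > 0.0:
                for t in range(nc):
                    e_new += _confine(coords[a0 + t, 0], coords[a0 + t, 1],
                                      coords[a0 + t, 2], conf_r, conf_k)
            if k_rep > 0.0:
                ev2 = r_ev * r_ev
                for t in range(nc):
                    i = a0 + t
                    for j in range(n_atoms):
                        if chain_of[j] == c:
                            continue
                        dx = coords[i, 0] - coords[j, 0]
                        dy = coords[i, 1] - coords[j, 1]
                        dz = coords[i, 2] - coords[j, 2]
                        d2 = dx * dx + dy * dy + dz * dz
                        if d2 < ev2:
                            e_new += _excl_pair(math.sqrt(d2), r_ev, k_rep)
            d_cg = e_new - e_old
            nm = cmem_off[c + 1] - cmem_off[c]
            ng = 0
            for t in range(nm):
                m = cmem_id[cmem_off[c] + t]
                old_mem[t] = mem_e[m]
                g = grp_of_mem[m]
                seen = False
                for u in range(ng):
                    if touched[u] == g:
                        seen = True
                        break
                if not seen:
                    touched[ng] = g
                    grp_old[ng] = grp_sum_arr[g]
                    ng += 1
                mem_e[m] = member_energy(coords, m, mem_kind, mem_param,
                                         di_a, di_b, di_r, di_k,
                                         dh_idx, dh_center, dh_delta, dh_k)
            d_rest = 0.0
            if nm > 0:
                for u in range(ng):
                    g = touched[u]
                    grp_sum_arr[g] = group_sum(mem_e, grp_off, g,
                                               grp_nact[g])
                if full_act:
                    for u in range(ng):
                        d_rest += grp_sum_arr[touched[u]] - grp_old[u]
                else:
                    d_rest = collection_total(grp_sum_arr,
                                              n_act_groups) - e_rest
            delta = d_cg + alpha * d_rest
            accept = delta <= 0.0
            if not accept:
                arg = beta * delta
                if arg < 50.0 and np.random.random() < math.exp(-arg):
                    accept = True
            if accept:
                acc_chain += 1
                e_cg += d_cg
                e_rest += d_rest
            else:
                for t in range(nc):
                    coords[a0 + t, 0] = old_xyz[t, 0]
                    coords[a0 + t, 1] = old_xyz[t, 1]
                    coords[a0 + t, 2] = old_xyz[t, 2]
                for t in range(nm):
                    m = cmem_id[cmem_off[c] + t]
                    mem_e[m] = old_mem[t]
                for u in range(ng):
                    grp_sum_arr[touched[u]] = grp_old[u]

    return e_cg, e_rest, acc_bead, att_bead, acc_chain, att_chain
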