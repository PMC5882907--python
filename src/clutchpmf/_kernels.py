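"""Numba-compiled numerical kernels.

Everything here works on plain arrays in internal units (nm, kBT, m = 1,
time unit nm*sqrt(m/kBT)).  The integrator is Gronbech-Jensen/Farago (GJF) Langevin with an
optional holonomic distance constraint between the core centroids of two
bead groups (SHAKE position projection + RATTLE velocity projection, exact
to machine precision for a single distance constraint).

Status codes returned by :func:`run_md`:
  0 ok, 1 divergent pair (r <= r0), 2 FENE overstretch, 3 neighbor-list
  overflow, 4 infeasible constraint.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DIVERGED = 1
STATUS_OVERSTRETCH = 2
STATUS_NL_OVERFLOW = 3
STATUS_CONSTRAINT = 4


# ----------------------------------------------------------------------
# neighbor list
# ----------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _neighbor_pairs(coords, species, box, list_range, range2_mat,
                    ideal_crowders, pair_i, pair_j):
    """Build a Verlet pair list; ranges per species pair include the skin.

    Returns the number of pairs, or -1 on capacity overflow.
    ``list_range`` is the largest per-pair list range (cell size);
    ``range2_mat`` holds squared per-species-pair list ranges.
    """
    n = coords.shape[0]
    cap = pair_i.shape[0]
    count = 0
    pbc = box > 0.0

    use_cells = n >= 250
    ncell = 0
    if use_cells:
        if pbc:
            ncell = int(box / list_range)
            if ncell < 3:
                use_cells = False
        # open boundary handled below with its own grid

    if not use_cells and not pbc:
        pass  # brute force path below

    if not use_cells:
        for i in range(n - 1):
            xi_, yi, zi = coords[i, 0], coords[i, 1], coords[i, 2]
            si = species[i]
            for j in range(i + 1, n):
                sj = species[j]
                if ideal_crowders and si == 2 and sj == 2:
                    continue
                dx = xi_ - coords[j, 0]
                dy = yi - coords[j, 1]
                dz = zi - coords[j, 2]
                if pbc:
                    dx -= box * np.rint(dx / box)
                    dy -= box * np.rint(dy / box)
                    dz -= box * np.rint(dz / box)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < range2_mat[si, sj]:
                    if count >= cap:
                        return -1
                    pair_i[count] = i
                    pair_j[count] = j
                    count += 1
        return count

    # --- cell-list build ---------------------------------------------
    if pbc:
        lo0 = 0.0
        lo1 = 0.0
        lo2 = 0.0
        n0 = ncell
        n1 = ncell
        n2 = ncell
        cs0 = box / n0
        cs1 = cs0
        cs2 = cs0
    else:
        lo0 = coords[0, 0]
        hi0 = lo0
        lo1 = coords[0, 1]
        hi1 = lo1
        lo2 = coords[0, 2]
        hi2 = lo2
        for i in range(n):
            if coords[i, 0] < lo0:
                lo0 = coords[i, 0]
            elif coords[i, 0] > hi0:
                hi0 = coords[i, 0]
            if coords[i, 1] < lo1:
                lo1 = coords[i, 1]
            elif coords[i, 1] > hi1:
                hi1 = coords[i, 1]
            if coords[i, 2] < lo2:
                lo2 = coords[i, 2]
            elif coords[i, 2] > hi2:
                hi2 = coords[i, 2]
        n0 = min(max(int((hi0 - lo0) / list_range) + 1, 1), 80)
        n1 = min(max(int((hi1 - lo1) / list_range) + 1, 1), 80)
        n2 = min(max(int((hi2 - lo2) / list_range) + 1, 1), 80)
        cs0 = max((hi0 - lo0) / n0, list_range)
        cs1 = max((hi1 - lo1) / n1, list_range)
        cs2 = max((hi2 - lo2) / n2, list_range)

    ntot = n0 * n1 * n2
    cell_of = np.empty(n, np.int32)
    counts = np.zeros(ntot + 1, np.int32)
    for i in range(n):
        x = coords[i, 0]
        y = coords[i, 1]
        z = coords[i, 2]
        if pbc:
            x -= box * np.floor(x / box)
            y -= box * np.floor(y / box)
            z -= box * np.floor(z / box)
        c0 = min(int((x - lo0) / cs0), n0 - 1)
        c1 = min(int((y - lo1) / cs1), n1 - 1)
        c2 = min(int((z - lo2) / cs2), n2 - 1)
        if c0 < 0:
            c0 = 0
        if c1 < 0:
            c1 = 0
        if c2 < 0:
            c2 = 0
        cid = (c0 * n1 + c1) * n2 + c2
        cell_of[i] = cid
        counts[cid + 1] += 1
    for c in range(ntot):
        counts[c + 1] += counts[c]
    order = np.empty(n, np.int32)
    fill = counts[:ntot].copy()
    for i in range(n):
        cid = cell_of[i]
        order[fill[cid]] = i
        fill[cid] += 1

    for c0 in range(n0):
        for c1 in range(n1):
            for c2 in range(n2):
                cid = (c0 * n1 + c1) * n2 + c2
                for d0 in range(-1, 2):
                    e0 = c0 + d0
                    if pbc:
                        e0 = e0 % n0
                    elif e0 < 0 or e0 >= n0:
                        continue
                    for d1 in range(-1, 2):
                        e1 = c1 + d1
                        if pbc:
                            e1 = e1 % n1
                        elif e1 < 0 or e1 >= n1:
                            continue
                        for d2 in range(-1, 2):
                            e2 = c2 + d2
                            if pbc:
                                e2 = e2 % n2
                            elif e2 < 0 or e2 >= n2:
                                continue
                            nid = (e0 * n1 + e1) * n2 + e2
                            if nid < cid:
                                continue
                            same = nid == cid
                            for a in range(counts[cid], counts[cid + 1]):
                                i = order[a]
                                si = species[i]
                                b0 = counts[nid] if not same else a + 1
                                for b in range(b0, counts[nid + 1]):
                                    j = order[b]
                                    sj = species[j]
                                    if ideal_crowders and si == 2 and sj == 2:
                                        continue
                                    dx = coords[i, 0] - coords[j, 0]
                                    dy = coords[i, 1] - coords[j, 1]
                                    dz = coords[i, 2] - coords[j, 2]
                                    if pbc:
                                        dx -= box * np.rint(dx / box)
                                        dy -= box * np.rint(dy / box)
                                        dz -= box * np.rint(dz / box)
                                    r2 = dx * dx + dy * dy + dz * dz
                                    if r2 < range2_mat[si, sj]:
                                        if count >= cap:
                                            return -1
                                        ii = i
                                        jj = j
                                        if ii > jj:
                                            ii, jj = jj, ii
                                        pair_i[count] = ii
                                        pair_j[count] = jj
                                        count += 1
    return count


# ----------------------------------------------------------------------
# forces
# ----------------------------------------------------------------------

@njit(cache=True, inline="always", fastmath=True)
def _wca_fmag(rr, sigma, eps):
    """Magnitude of the repulsive WCA force, -dU/d(rr) > 0 for rr < rc."""
    s2 = (sigma / rr) ** 2
    s6 = s2 * s2 * s2
    s12 = s6 * s6
    return 4.0 * eps * (12.0 * s12 - 6.0 * s6) / rr


@njit(cache=True, fastmath=True)
def _forces(coords, species, box, r0_mat, sigma, eps, rc,
            pair_i, pair_j, npairs,
            bonds, kfene, rb,
            angles, k_angle,
            hr_idx, hr_k, hr_r0,
            col_off, col_cores, col_rt, col_k,
            forces, pair_cap):
    """Fill ``forces`` with -grad U.  Returns a status code.

    ``pair_cap`` > 0 switches to a capped, never-failing force law used
    only for initial overlap relaxation.
    """
    n = coords.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    pbc = box > 0.0

    # nonbonded WCA over the pair list
    for p in range(npairs):
        i = pair_i[p]
        j = pair_j[p]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        if pbc:
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        r0 = r0_mat[species[i], species[j]]
        rng = r0 + rc
        if r2 >= rng * rng:
            continue
        r = np.sqrt(r2)
        rr = r - r0
        if rr <= 0.0:
            if pair_cap <= 0.0:
                return STATUS_DIVERGED
            fmag = pair_cap
            if r < 1e-9:
                continue
        else:
            fmag = _wca_fmag(rr, sigma, eps)
            if pair_cap > 0.0 and fmag > pair_cap:
                fmag = pair_cap
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz

    # FENE bonds (attractive part; WCA part comes from the pair list)
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= rb:
            if pair_cap <= 0.0:
                return STATUS_OVERSTRETCH
            r_eff = 0.99 * rb
        else:
            r_eff = r
        fmag = -kfene * r_eff / (1.0 - (r_eff / rb) ** 2)
        if pair_cap > 0.0 and fmag < -pair_cap:
            fmag = -pair_cap
        if r > 1e-12:
            fx = fmag * dx / r
            fy = fmag * dy / r
            fz = fmag * dz / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz

    # harmonic angle on consecutive bond vectors, theta0 = 0
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[k, 0] - coords[j, 0]
        b2y = coords[k, 1] - coords[j, 1]
        b2z = coords[k, 2] - coords[j, 2]
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1 < 1e-12 or n2 < 1e-12:
            continue
        ct = (b1x * b2x + b1y * b2y + b1z * b2z) / (n1 * n2)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        st = np.sqrt(1.0 - ct * ct)
        if st < 1e-8:
            coef = k_angle  # theta/sin(theta) -> 1 near straight
        else:
            coef = k_angle * theta / st
        # d(cos)/db1 and d(cos)/db2
        d1x = b2x / (n1 * n2) - ct * b1x / (n1 * n1)
        d1y = b2y / (n1 * n2) - ct * b1y / (n1 * n1)
        d1z = b2z / (n1 * n2) - ct * b1z / (n1 * n1)
        d2x = b1x / (n1 * n2) - ct * b2x / (n2 * n2)
        d2y = b1y / (n1 * n2) - ct * b2y / (n2 * n2)
        d2z = b1z / (n1 * n2) - ct * b2z / (n2 * n2)
        # F = -dU/dr;  dU/d(cos) = -coef
        fi_x = -coef * d1x
        fi_y = -coef * d1y
        fi_z = -coef * d1z
        fk_x = coef * d2x
        fk_y = coef * d2y
        fk_z = coef * d2z
        forces[i, 0] += fi_x
        forces[i, 1] += fi_y
        forces[i, 2] += fi_z
        forces[k, 0] += fk_x
        forces[k, 1] += fk_y
        forces[k, 2] += fk_z
        forces[j, 0] -= fi_x + fk_x
        forces[j, 1] -= fi_y + fk_y
        forces[j, 2] -= fi_z + fk_z

    # harmonic pair restraints (wrap + loop-parallel), U = k/2 (r - r0)^2
    for m in range(hr_idx.shape[0]):
        i = hr_idx[m, 0]
        j = hr_idx[m, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        fmag = -hr_k[m] * (r - hr_r0[m])
        if pair_cap > 0.0:
            if fmag > pair_cap:
                fmag = pair_cap
            elif fmag < -pair_cap:
                fmag = -pair_cap
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz

    # flat-bottom collapse restraints toward the instantaneous core centroid
    for c in range(col_off.shape[0] - 1):
        a0 = col_off[c]
        a1 = col_off[c + 1]
        nc = a1 - a0
        if nc == 0:
            continue
        cx = 0.0
        cy = 0.0
        cz = 0.0
        for a in range(a0, a1):
            i = col_cores[a]
            cx += coords[i, 0]
            cy += coords[i, 1]
            cz += coords[i, 2]
        cx /= nc
        cy /= nc
        cz /= nc
        rx = 0.0
        ry = 0.0
        rz = 0.0
        for a in range(a0, a1):
            i = col_cores[a]
            dx = coords[i, 0] - cx
            dy = coords[i, 1] - cy
            dz = coords[i, 2] - cz
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d <= col_rt[c] or d < 1e-12:
                continue
            fmag = -col_k[c] * (d - col_rt[c])
            if pair_cap > 0.0 and fmag < -pair_cap:
                fmag = -pair_cap
            fx = fmag * dx / d
            fy = fmag * dy / d
            fz = fmag * dz / d
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            rx -= fx
            ry -= fy
            rz -= fz
        # reaction on the mobile centroid, spread over all cores
        rx /= nc
        ry /= nc
        rz /= nc
        for a in range(a0, a1):
            i = col_cores[a]
            forces[i, 0] += rx
            forces[i, 1] += ry
            forces[i, 2] += rz

    return STATUS_OK


# ----------------------------------------------------------------------
# energies (used for reporting and gradient checks; mirrors _forces)
# ----------------------------------------------------------------------

@njit(cache=True)
def _energy_terms(coords, species, box, r0_mat, sigma, eps, rc,
                  pair_i, pair_j, npairs,
                  bonds, kfene, rb,
                  angles, k_angle,
                  hr_idx, hr_k, hr_r0,
                  col_off, col_cores, col_rt, col_k):
    """Return (e_pair, e_fene, e_angle, e_restraint, status)."""
    e_pair = 0.0
    e_fene = 0.0
    e_angle = 0.0
    e_rest = 0.0
    pbc = box > 0.0
    for p in range(npairs):
        i = pair_i[p]
        j = pair_j[p]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        if pbc:
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        r0 = r0_mat[species[i], species[j]]
        rr = r - r0
        if rr <= 0.0:
            return np.inf, e_fene, e_angle, e_rest, STATUS_DIVERGED
        if rr < rc:
            s6 = (sigma / rr) ** 6
            e_pair += 4.0 * eps * (s6 * s6 - s6) + eps
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= rb:
            return e_pair, np.inf, e_angle, e_rest, STATUS_OVERSTRETCH
        e_fene += -0.5 * kfene * rb * rb * np.log(1.0 - (r / rb) ** 2)
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[k, 0] - coords[j, 0]
        b2y = coords[k, 1] - coords[j, 1]
        b2z = coords[k, 2] - coords[j, 2]
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        ct = (b1x * b2x + b1y * b2y + b1z * b2z) / (n1 * n2)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        e_angle += 0.5 * k_angle * theta * theta
    for m in range(hr_idx.shape[0]):
        i = hr_idx[m, 0]
        j = hr_idx[m, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        e_rest += 0.5 * hr_k[m] * (r - hr_r0[m]) ** 2
    for c in range(col_off.shape[0] - 1):
        a0 = col_off[c]
        a1 = col_off[c + 1]
        nc = a1 - a0
        if nc == 0:
            continue
        cx = 0.0
        cy = 0.0
        cz = 0.0
        for a in range(a0, a1):
            i = col_cores[a]
            cx += coords[i, 0]
            cy += coords[i, 1]
            cz += coords[i, 2]
        cx /= nc
        cy /= nc
        cz /= nc
        for a in range(a0, a1):
            i = col_cores[a]
            dx = coords[i, 0] - cx
            dy = coords[i, 1] - cy
            dz = coords[i, 2] - cz
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d > col_rt[c]:
                e_rest += 0.5 * col_k[c] * (d - col_rt[c]) ** 2
    return e_pair, e_fene, e_angle, e_rest, STATUS_OK


@njit(cache=True)
def _cross_pair_energy(ca, sa, cb, sb, shift_x, r0_mat, sigma, eps, rc):
    """WCA energy across two bead sets, B displaced by ``shift_x`` along x.

    Open boundary (used for conformer-pair insertion).  Returns +inf when
    any cross pair is inside the divergent region.
    """
    e = 0.0
    for i in range(ca.shape[0]):
        xi_ = ca[i, 0]
        yi = ca[i, 1]
        zi = ca[i, 2]
        si = sa[i]
        for j in range(cb.shape[0]):
            r0 = r0_mat[si, sb[j]]
            rng = r0 + rc
            dx = xi_ - (cb[j, 0] + shift_x)
            if dx > rng or dx < -rng:
                continue
            dy = yi - cb[j, 1]
            dz = zi - cb[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rng * rng:
                continue
            rr = np.sqrt(r2) - r0
            if rr <= 0.0:
                return np.inf
            s6 = (sigma / rr) ** 6
            e += 4.0 * eps * (s6 * s6 - s6) + eps
    return e


# ----------------------------------------------------------------------
# Langevin MD
# ----------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def run_md(coords, vel, species, mobile, box,
           r0_mat, sigma, eps, rc,
           bonds, kfene, rb,
           angles, k_angle,
           hr_idx, hr_k, hr_r0,
           col_off, col_cores, col_rt, col_k,
           ideal_crowders,
           dt, gamma, kT,
           noise, step0, skin,
           xi, grp_a, grp_b,
           snap_every, snaps, n_snap0,
           fc_every, fc_buf, n_fc0,
           ke_every, ke_buf, n_ke0,
           pair_cap):
    """Integrate one chunk of GJF Langevin dynamics in place.

    ``noise`` holds pre-scaled thermal impulses (chunk_steps, n, 3) drawn
    outside the kernel; ``step0`` is the global index of the chunk's
    first step (sampling intervals are phased globally).  Returns
    (status, info, n_snaps, n_fc, n_ke) with cumulative counters; ``info``
    is the failing global step index on error.  ``xi`` > 0 activates the
    centroid-distance constraint between bead groups ``grp_a``/``grp_b``.
    """
    n = coords.shape[0]
    n_steps = noise.shape[0]

    # per-pair list ranges include the skin
    range2 = np.empty((3, 3))
    rmax = 0.0
    for s1 in range(3):
        for s2 in range(3):
            rng = r0_mat[s1, s2] + rc + skin
            range2[s1, s2] = rng * rng
            if rng > rmax:
                rmax = rng

    cap = 80 * n + 1024
    pair_i = np.empty(cap, np.int32)
    pair_j = np.empty(cap, np.int32)
    npairs = _neighbor_pairs(coords, species, box, rmax, range2,
                             ideal_crowders, pair_i, pair_j)
    if npairs < 0:
        return STATUS_NL_OVERFLOW, step0, n_snap0, n_fc0, n_ke0
    ref = coords.copy()

    forces = np.empty((n, 3))
    status = _forces(coords, species, box, r0_mat, sigma, eps, rc,
                     pair_i, pair_j, npairs, bonds, kfene, rb,
                     angles, k_angle, hr_idx, hr_k, hr_r0,
                     col_off, col_cores, col_rt, col_k, forces, pair_cap)
    if status != STATUS_OK:
        return status, step0, n_snap0, n_fc0, n_ke0

    # Gronbech-Jensen / Farago coefficients
    gj_b = 1.0 / (1.0 + 0.5 * gamma * dt)
    gj_a = gj_b * (1.0 - 0.5 * gamma * dt)
    half = 0.5 * dt
    fnew = np.empty((n, 3))

    constrained = xi > 0.0 and grp_a.shape[0] > 0 and grp_b.shape[0] > 0
    na = grp_a.shape[0]
    nb = grp_b.shape[0]
    mu = 0.0
    if constrained:
        mu = (na * nb) / float(na + nb)

    n_snap = n_snap0
    n_fc = n_fc0
    n_ke = n_ke0
    trigger = 0.25 * skin * skin

    for local in range(n_steps):
        step = step0 + local
        # position update with this step's thermal impulses
        for i in range(n):
            if mobile[i]:
                for d in range(3):
                    coords[i, d] += (gj_b * dt * vel[i, d]
                                     + gj_b * half * dt * forces[i, d]
                                     + gj_b * half * noise[local, i, d])

        if constrained:
            # SHAKE: project the centroid distance back to xi (exact for a
            # single distance constraint; correction is collinear with the
            # centroid separation)
            ax = 0.0
            ay = 0.0
            az = 0.0
            for a in range(na):
                i = grp_a[a]
                ax += coords[i, 0]
                ay += coords[i, 1]
                az += coords[i, 2]
            ax /= na
            ay /= na
            az /= na
            bx = 0.0
            by = 0.0
            bz = 0.0
            for a in range(nb):
                i = grp_b[a]
                bx += coords[i, 0]
                by += coords[i, 1]
                bz += coords[i, 2]
            bx /= nb
            by /= nb
            bz /= nb
            dxc = bx - ax
            dyc = by - ay
            dzc = bz - az
            dist = np.sqrt(dxc * dxc + dyc * dyc + dzc * dzc)
            if dist < 1e-9:
                return STATUS_CONSTRAINT, step, n_snap, n_fc, n_ke
            nx = dxc / dist
            ny = dyc / dist
            nz = dzc / dist
            delta = xi - dist
            sa_ = -delta * mu / na
            sb_ = delta * mu / nb
            for a in range(na):
                i = grp_a[a]
                coords[i, 0] += sa_ * nx
                coords[i, 1] += sa_ * ny
                coords[i, 2] += sa_ * nz
                vel[i, 0] += sa_ * nx / dt
                vel[i, 1] += sa_ * ny / dt
                vel[i, 2] += sa_ * nz / dt
            for a in range(nb):
                i = grp_b[a]
                coords[i, 0] += sb_ * nx
                coords[i, 1] += sb_ * ny
                coords[i, 2] += sb_ * nz
                vel[i, 0] += sb_ * nx / dt
                vel[i, 1] += sb_ * ny / dt
                vel[i, 2] += sb_ * nz / dt

        # neighbor refresh on displacement trigger
        maxd2 = 0.0
        for i in range(n):
            dx = coords[i, 0] - ref[i, 0]
            dy = coords[i, 1] - ref[i, 1]
            dz = coords[i, 2] - ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > trigger:
            npairs = _neighbor_pairs(coords, species, box, rmax, range2,
                                     ideal_crowders, pair_i, pair_j)
            if npairs < 0:
                return STATUS_NL_OVERFLOW, step, n_snap, n_fc, n_ke
            for i in range(n):
                ref[i, 0] = coords[i, 0]
                ref[i, 1] = coords[i, 1]
                ref[i, 2] = coords[i, 2]

        status = _forces(coords, species, box, r0_mat, sigma, eps, rc,
                         pair_i, pair_j, npairs, bonds, kfene, rb,
                         angles, k_angle, hr_idx, hr_k, hr_r0,
                         col_off, col_cores, col_rt, col_k, fnew, pair_cap)
        if status != STATUS_OK:
            return status, step, n_snap, n_fc, n_ke

        # velocity update from old and new forces plus the same impulses
        for i in range(n):
            if mobile[i]:
                for d in range(3):
                    vel[i, d] = (gj_a * vel[i, d]
                                 + half * (gj_a * forces[i, d] + fnew[i, d])
                                 + gj_b * noise[local, i, d])
                    forces[i, d] = fnew[i, d]
            else:
                forces[i, 0] = fnew[i, 0]
                forces[i, 1] = fnew[i, 1]
                forces[i, 2] = fnew[i, 2]

        if constrained:
            # RATTLE: remove the radial component of the relative
            # centroid velocity
            wx = 0.0
            wy = 0.0
            wz = 0.0
            for a in range(nb):
                i = grp_b[a]
                wx += vel[i, 0]
                wy += vel[i, 1]
                wz += vel[i, 2]
            wx /= nb
            wy /= nb
            wz /= nb
            for a in range(na):
                i = grp_a[a]
                wx -= vel[i, 0] / na
                wy -= vel[i, 1] / na
                wz -= vel[i, 2] / na
            wr = wx * nx + wy * ny + wz * nz
            va = wr * mu / na
            vb = -wr * mu / nb
            for a in range(na):
                i = grp_a[a]
                vel[i, 0] += va * nx
                vel[i, 1] += va * ny
                vel[i, 2] += va * nz
            for a in range(nb):
                i = grp_b[a]
                vel[i, 0] += vb * nx
                vel[i, 1] += vb * ny
                vel[i, 2] += vb * nz

            # blue-moon constraint-force sample: potential force projected
            # on the constraint plus the measured centrifugal term
            if fc_every > 0 and (step + 1) % fc_every == 0 and n_fc < fc_buf.shape[0]:
                fax = 0.0
                fay = 0.0
                faz = 0.0
                for a in range(na):
                    i = grp_a[a]
                    fax += forces[i, 0]
                    fay += forces[i, 1]
                    faz += forces[i, 2]
                fbx = 0.0
                fby = 0.0
                fbz = 0.0
                for a in range(nb):
                    i = grp_b[a]
                    fbx += forces[i, 0]
                    fby += forces[i, 1]
                    fbz += forces[i, 2]
                frel = mu * ((fbx / nb - fax / na) * nx
                             + (fby / nb - fay / na) * ny
                             + (fbz / nb - faz / na) * nz)
                # perpendicular relative centroid velocity (radial part
                # was just removed by RATTLE)
                wx2 = 0.0
                wy2 = 0.0
                wz2 = 0.0
                for a in range(nb):
                    i = grp_b[a]
                    wx2 += vel[i, 0]
                    wy2 += vel[i, 1]
                    wz2 += vel[i, 2]
                wx2 /= nb
                wy2 /= nb
                wz2 /= nb
                for a in range(na):
                    i = grp_a[a]
                    wx2 -= vel[i, 0] / na
                    wy2 -= vel[i, 1] / na
                    wz2 -= vel[i, 2] / na
                wr2 = wx2 * nx + wy2 * ny + wz2 * nz
                wperp2 = wx2 * wx2 + wy2 * wy2 + wz2 * wz2 - wr2 * wr2
                fc_buf[n_fc] = -frel - mu * wperp2 / xi
                n_fc += 1

        if snap_every > 0 and (step + 1) % snap_every == 0 and n_snap < snaps.shape[0]:
            for i in range(n):
                snaps[n_snap, i, 0] = coords[i, 0]
                snaps[n_snap, i, 1] = coords[i, 1]
                snaps[n_snap, i, 2] = coords[i, 2]
            n_snap += 1

        if ke_every > 0 and (step + 1) % ke_every == 0 and n_ke < ke_buf.shape[0]:
            ke = 0.0
            nm = 0
            for i in range(n):
                if mobile[i]:
                    ke += (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
                    nm += 1
            ke_buf[n_ke] = 0.5 * ke / nm  # per mobile bead
            n_ke += 1

    return STATUS_OK, step0 + n_steps, n_snap, n_fc, n_ke


# ----------------------------------------------------------------------
# insertion averaging (Widom-style exponential average over conformer pairs)
# ----------------------------------------------------------------------

@njit(cache=True, inline="always")
def _rand_rotmat(out):
    """Uniform random rotation matrix from a normalized Gaussian quaternion."""
    q0 = np.random.normal()
    q1 = np.random.normal()
    q2 = np.random.normal()
    q3 = np.random.normal()
    nq = np.sqrt(q0 * q0 + q1 * q1 + q2 * q2 + q3 * q3)
    q0 /= nq
    q1 /= nq
    q2 /= nq
    q3 /= nq
    out[0, 0] = 1.0 - 2.0 * (q2 * q2 + q3 * q3)
    out[0, 1] = 2.0 * (q1 * q2 - q0 * q3)
    out[0, 2] = 2.0 * (q1 * q3 + q0 * q2)
    out[1, 0] = 2.0 * (q1 * q2 + q0 * q3)
    out[1, 1] = 1.0 - 2.0 * (q1 * q1 + q3 * q3)
    out[1, 2] = 2.0 * (q2 * q3 - q0 * q1)
    out[2, 0] = 2.0 * (q1 * q3 - q0 * q2)
    out[2, 1] = 2.0 * (q2 * q3 + q0 * q1)
    out[2, 2] = 1.0 - 2.0 * (q1 * q1 + q2 * q2)


@njit(cache=True, fastmath=True)
def insertion_average(confs_a, confs_b, sp_a, sp_b,
                      r0_mat, sigma, eps, rc, xi, n_pairs, seed,
                      rotate, u_max=46.0):
    """Monte-Carlo estimate of <exp(-U_inter/kBT)> at separation ``xi``.

    Draws ``n_pairs`` (conformer, conformer, rotation, rotation) samples;
    conformer B is displaced by +xi along x.  Overlapping pairs (any cross
    pair with r <= r0) contribute exactly 0.  Returns (sum_w, sum_w2).
    """
    np.random.seed(seed)
    nca = confs_a.shape[0]
    ncb = confs_b.shape[0]
    na = confs_a.shape[1]
    nb = confs_b.shape[1]

    rot = np.empty((3, 3))
    xa = np.empty((na, 3))
    xb = np.empty((nb, 3))
    sub_a = np.empty(na, np.int32)
    sub_b = np.empty(nb, np.int32)

    # loosest interaction reach of each species against any partner
    reach_a = np.zeros(3)
    reach_b = np.zeros(3)
    for s1 in range(3):
        for s2 in range(3):
            rng = r0_mat[s1, s2] + rc
            if rng > reach_a[s1]:
                reach_a[s1] = rng
            if rng > reach_b[s2]:
                reach_b[s2] = rng

    sum_w = 0.0
    sum_w2 = 0.0
    for _ in range(n_pairs):
        ia = np.random.randint(0, nca)
        ib = np.random.randint(0, ncb)
        if rotate:
            _rand_rotmat(rot)
            for i in range(na):
                x = confs_a[ia, i, 0]
                y = confs_a[ia, i, 1]
                z = confs_a[ia, i, 2]
                xa[i, 0] = rot[0, 0] * x + rot[0, 1] * y + rot[0, 2] * z
                xa[i, 1] = rot[1, 0] * x + rot[1, 1] * y + rot[1, 2] * z
                xa[i, 2] = rot[2, 0] * x + rot[2, 1] * y + rot[2, 2] * z
            _rand_rotmat(rot)
            for i in range(nb):
                x = confs_b[ib, i, 0]
                y = confs_b[ib, i, 1]
                z = confs_b[ib, i, 2]
                xb[i, 0] = rot[0, 0] * x + rot[0, 1] * y + rot[0, 2] * z
                xb[i, 1] = rot[1, 0] * x + rot[1, 1] * y + rot[1, 2] * z
                xb[i, 2] = rot[2, 0] * x + rot[2, 1] * y + rot[2, 2] * z
        else:
            for i in range(na):
                xa[i, 0] = confs_a[ia, i, 0]
                xa[i, 1] = confs_a[ia, i, 1]
                xa[i, 2] = confs_a[ia, i, 2]
            for i in range(nb):
                xb[i, 0] = confs_b[ib, i, 0]
                xb[i, 1] = confs_b[ib, i, 1]
                xb[i, 2] = confs_b[ib, i, 2]

        min_bx = xb[0, 0]
        max_bx = xb[0, 0]
        for i in range(1, nb):
            if xb[i, 0] < min_bx:
                min_bx = xb[i, 0]
            elif xb[i, 0] > max_bx:
                max_bx = xb[i, 0]
        max_ax = xa[0, 0]
        for i in range(1, na):
            if xa[i, 0] > max_ax:
                max_ax = xa[i, 0]

        # subset of beads that can possibly reach across the gap;
        # cores first so overlaps are found early
        n_sub_a = 0
        for i in range(na):
            if sp_a[i] != 0 and xa[i, 0] >= xi + min_bx - reach_a[sp_a[i]]:
                sub_a[n_sub_a] = i
                n_sub_a += 1
        for i in range(na):
            if sp_a[i] == 0 and xa[i, 0] >= xi + min_bx - reach_a[0]:
                sub_a[n_sub_a] = i
                n_sub_a += 1
        n_sub_b = 0
        for j in range(nb):
            if sp_b[j] != 0 and xb[j, 0] + xi <= max_ax + reach_b[sp_b[j]]:
                sub_b[n_sub_b] = j
                n_sub_b += 1
        for j in range(nb):
            if sp_b[j] == 0 and xb[j, 0] + xi <= max_ax + reach_b[0]:
                sub_b[n_sub_b] = j
                n_sub_b += 1

        u = 0.0
        ok = True
        for a in range(n_sub_a):
            i = sub_a[a]
            axx = xa[i, 0]
            ay = xa[i, 1]
            az = xa[i, 2]
            si = sp_a[i]
            for b in range(n_sub_b):
                j = sub_b[b]
                r0 = r0_mat[si, sp_b[j]]
                rng = r0 + rc
                dx = axx - xb[j, 0] - xi
                if dx > rng or dx < -rng:
                    continue
                dy = ay - xb[j, 1]
                if dy > rng or dy < -rng:
                    continue
                dz = az - xb[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 >= rng * rng:
                    continue
                rr = np.sqrt(r2) - r0
                if rr <= 0.0:
                    ok = False
                    break
                s6 = (sigma / rr) ** 6
                u += 4.0 * eps * (s6 * s6 - s6) + eps
                if u > u_max:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            w = np.exp(-u)
            sum_w += w
            sum_w2 += w * w
    return sum_w, sum_w2
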