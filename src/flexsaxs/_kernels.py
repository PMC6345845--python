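"""Numba kernels for the inner loops of energy evaluation.

These are the only hot paths of the package: full and incremental
nonbonded sums, bonded terms, and membrane terms.  Everything here takes
plain float64/int64 arrays; the object-level API lives in energy.py.
"""

import numba
import numpy as np

#: kcal*A/(mol*e^2) — Coulomb constant in the package's internal units
COULOMB_KCAL = 332.0637
#: hard floor on pair separations: overlapping beads get a large finite energy
R_FLOOR = 0.1


@numba.njit(cache=True)
def pair_energy(r, eps, qq_scaled, r_ex, r_cut, rep_k, lam):
    """Energy of one nonbonded pair at separation r.

    qq_scaled is q_i*q_j*COULOMB_KCAL/dielectric.  The contact term is a
    square well of depth eps between the excluded-volume radius and the
    contact range, with harmonic repulsion below the excluded radius.
    """
    rc = r if r > R_FLOOR else R_FLOOR
    e = 0.0
    if r < r_ex:
        d = r_ex - rc
        e += rep_k * d * d
    elif r < r_cut:
        e -= eps
    if qq_scaled != 0.0:
        e += qq_scaled * np.exp(-rc / lam) / rc
    return e


@numba.njit(cache=True)
def nonbonded_total(coords, eps_mat, qq_mat, allowed, r_ex, r_cut, rep_k, lam):
    n = coords.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if not allowed[i, j]:
                continue
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            total += pair_energy(r, eps_mat[i, j], qq_mat[i, j], r_ex, r_cut, rep_k, lam)
    return total


@numba.njit(cache=True)
def nonbonded_delta(coords, new_moved, moved_idx, is_moved, eps_mat, qq_mat,
                    allowed, r_ex, r_cut, rep_k, lam):
    """Change in nonbonded energy when the beads in moved_idx take the
    coordinates new_moved.  Valid for moves that displace the moved set
    rigidly or move a single bead (intra-set distances unchanged)."""
    n = coords.shape[0]
    delta = 0.0
    for k in range(moved_idx.shape[0]):
        i = moved_idx[k]
        for j in range(n):
            if is_moved[j] or not allowed[i, j]:
                continue
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r_old = np.sqrt(dx * dx + dy * dy + dz * dz)
            dx = new_moved[k, 0] - coords[j, 0]
            dy = new_moved[k, 1] - coords[j, 1]
            dz = new_moved[k, 2] - coords[j, 2]
            r_new = np.sqrt(dx * dx + dy * dy + dz * dz)
            delta += pair_energy(r_new, eps_mat[i, j], qq_mat[i, j], r_ex, r_cut, rep_k, lam)
            delta -= pair_energy(r_old, eps_mat[i, j], qq_mat[i, j], r_ex, r_cut, rep_k, lam)
    return delta


@numba.njit(cache=True)
def bonded_total(coords, bond_pairs, bond_b0, bond_k,
                 angle_triples, angle_0, angle_k,
                 torsion_quads, torsion_amp):
    """Harmonic bonds + harmonic angles + 1+cos(phi) torsions."""
    e = 0.0
    for b in range(bond_pairs.shape[0]):
        i = bond_pairs[b, 0]
        j = bond_pairs[b, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - bond_b0[b]
        e += 0.5 * bond_k * d * d
    for a in range(angle_triples.shape[0]):
        i = angle_triples[a, 0]
        j = angle_triples[a, 1]
        k = angle_triples[a, 2]
        v1 = coords[i] - coords[j]
        v2 = coords[k] - coords[j]
        n1 = np.sqrt(v1[0] ** 2 + v1[1] ** 2 + v1[2] ** 2)
        n2 = np.sqrt(v2[0] ** 2 + v2[1] ** 2 + v2[2] ** 2)
        if n1 < 1e-12 or n2 < 1e-12:
            continue
        c = (v1[0] * v2[0] + v1[1] * v2[1] + v1[2] * v2[2]) / (n1 * n2)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        dth = np.arccos(c) - angle_0
        e += 0.5 * angle_k * dth * dth
    if torsion_amp != 0.0:
        for t in range(torsion_quads.shape[0]):
            i = torsion_quads[t, 0]
            j = torsion_quads[t, 1]
            k = torsion_quads[t, 2]
            l = torsion_quads[t, 3]
            b1 = coords[j] - coords[i]
            b2 = coords[k] - coords[j]
            b3 = coords[l] - coords[k]
            # phi from the two plane normals
            n1x = b1[1] * b2[2] - b1[2] * b2[1]
            n1y = b1[2] * b2[0] - b1[0] * b2[2]
            n1z = b1[0] * b2[1] - b1[1] * b2[0]
            n2x = b2[1] * b3[2] - b2[2] * b3[1]
            n2y = b2[2] * b3[0] - b2[0] * b3[2]
            n2z = b2[0] * b3[1] - b2[1] * b3[0]
            nn1 = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
            nn2 = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
            if nn1 < 1e-12 or nn2 < 1e-12:
                continue
            c = (n1x * n2x + n1y * n2y + n1z * n2z) / (nn1 * nn2)
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            phi = np.arccos(c)
            e += torsion_amp * (1.0 + np.cos(phi))
    return e


@numba.njit(cache=True)
def membrane_terms(z, depths, z_m, mem_range, wall_k):
    """Per-bead membrane attraction (linear ramp) and impenetrability wall."""
    e = 0.0
    for i in range(z.shape[0]):
        zi = z[i]
        if zi < z_m:
            d = z_m - zi
            e += wall_k * d * d
        elif zi < z_m + mem_range:
            e -= depths[i] * (1.0 - (zi - z_m) / mem_range)
    return e


@numba.njit(cache=True)
def restraint_terms(z, restraint_idx, restraint_z, restraint_k):
    e = 0.0
    for r in range(restraint_idx.shape[0]):
        d = z[restraint_idx[r]] - restraint_z[r]
        e += 0.5 * restraint_k[r] * d * d
    return e


@numba.njit(cache=True)
def total_delta(coords, trial, new_moved, moved_idx, is_moved,
                eps_mat, qq_mat, allowed, r_ex, r_cut, rep_k, lam,
                bond_pairs, bond_b0, bond_k,
                angle_triples, angle_0, angle_k,
                torsion_quads, torsion_amp,
                membrane, bead_depths, z_m, mem_range, wall_k,
                restraint_idx, restraint_z, restraint_k):
    """Fused energy change for one MC move (nonbonded + bonded + membrane).

    trial is a scratch (N, 3) buffer; it is left holding the trial
    coordinates on return so the caller can commit without recomputing.
    """
    d = nonbonded_delta(coords, new_moved, moved_idx, is_moved, eps_mat,
                        qq_mat, allowed, r_ex, r_cut, rep_k, lam)
    n = coords.shape[0]
    for i in range(n):
        trial[i, 0] = coords[i, 0]
        trial[i, 1] = coords[i, 1]
        trial[i, 2] = coords[i, 2]
    for k in range(moved_idx.shape[0]):
        i = moved_idx[k]
        trial[i, 0] = new_moved[k, 0]
        trial[i, 1] = new_moved[k, 1]
        trial[i, 2] = new_moved[k, 2]
    if bond_pairs.shape[0] > 0:
        d += bonded_total(trial, bond_pairs, bond_b0, bond_k,
                          angle_triples, angle_0, angle_k,
                          torsion_quads, torsion_amp)
        d -= bonded_total(coords, bond_pairs, bond_b0, bond_k,
                          angle_triples, angle_0, angle_k,
                          torsion_quads, torsion_amp)
    if membrane:
        for k in range(moved_idx.shape[0]):
            i = moved_idx[k]
            z_new = new_moved[k, 2]
            z_old = coords[i, 2]
            depth = bead_depths[i]
            if z_new < z_m:
                dz = z_m - z_new
                d += wall_k * dz * dz
            elif z_new < z_m + mem_range:
                d -= depth * (1.0 - (z_new - z_m) / mem_range)
            if z_old < z_m:
                dz = z_m - z_old
                d -= wall_k * dz * dz
            elif z_old < z_m + mem_range:
                d += depth * (1.0 - (z_old - z_m) / mem_range)
        for r in range(restraint_idx.shape[0]):
            i = restraint_idx[r]
            if is_moved[i]:
                dz_new = trial[i, 2] - restraint_z[r]
                dz_old = coords[i, 2] - restraint_z[r]
                d += 0.5 * restraint_k[r] * (dz_new * dz_new - dz_old * dz_old)
    return d


@numba.njit(cache=True, inline="always")
def _quat_mul(a, b, out):
    out[0] = a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3]
    out[1] = a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2]
    out[2] = a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1]
    out[3] = a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0]


@numba.njit(cache=True, inline="always")
def _rotvec_quat(v, out):
    angle = np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    if angle < 1e-15:
        out[0] = 1.0
        out[1] = out[2] = out[3] = 0.0
        return
    half = 0.5 * angle
    s = np.sin(half) / angle
    out[0] = np.cos(half)
    out[1] = v[0] * s
    out[2] = v[1] * s
    out[3] = v[2] * s


@numba.njit(cache=True, inline="always")
def _quat_matrix(q, rot):
    w, x, y, z = q[0], q[1], q[2], q[3]
    rot[0, 0] = 1 - 2 * (y * y + z * z)
    rot[0, 1] = 2 * (x * y - w * z)
    rot[0, 2] = 2 * (x * z + w * y)
    rot[1, 0] = 2 * (x * y + w * z)
    rot[1, 1] = 1 - 2 * (x * x + z * z)
    rot[1, 2] = 2 * (y * z - w * x)
    rot[2, 0] = 2 * (x * z - w * y)
    rot[2, 1] = 2 * (y * z + w * x)
    rot[2, 2] = 1 - 2 * (x * x + y * y)


@numba.njit(cache=True)
def sweep_kernel(coords, quats, body_indices, body_offsets, body_refs,
                 chain_indices, chain_offsets,
                 eps_mat, qq_mat, allowed, r_ex, r_cut, rep_k, lam,
                 bond_pairs, bond_b0, bond_k,
                 angle_triples, angle_0, angle_k,
                 torsion_quads, torsion_amp,
                 membrane, bead_depths, z_m, mem_range, wall_k,
                 restraint_idx, restraint_z, restraint_k,
                 beta, trans_amp, rot_amp, linker_amp, pivot_amp,
                 energy_in, rng, trial, is_moved, scratch_moved):
    """One full MC sweep over all mobile degrees of freedom, in-place.

    Returns (energy, n_attempted, n_accepted).  Mutates coords and quats.
    trial is an (N, 3) scratch buffer, is_moved an N bool buffer,
    scratch_moved an (N,) int64 index buffer.
    """
    energy = energy_in
    n_attempted = 0
    n_accepted = 0
    dq = np.empty(4)
    new_q = np.empty(4)
    rot = np.empty((3, 3))
    n_bodies = body_offsets.shape[0] - 1

    for b in range(n_bodies):
        start = body_offsets[b]
        stop = body_offsets[b + 1]
        nb = stop - start
        moved_idx = scratch_moved[:nb]
        for k in range(nb):
            moved_idx[k] = body_indices[start + k]
        new_moved = np.empty((nb, 3))
        rotated = False
        if rng.random() < 0.5:
            kick = rng.standard_normal(3)
            for k in range(nb):
                i = moved_idx[k]
                new_moved[k, 0] = coords[i, 0] + trans_amp * kick[0]
                new_moved[k, 1] = coords[i, 1] + trans_amp * kick[1]
                new_moved[k, 2] = coords[i, 2] + trans_amp * kick[2]
        else:
            rotated = True
            kick = rng.standard_normal(3) * rot_amp
            _rotvec_quat(kick, dq)
            _quat_mul(dq, quats[b], new_q)
            norm = np.sqrt(new_q[0] ** 2 + new_q[1] ** 2 + new_q[2] ** 2
                           + new_q[3] ** 2)
            for k in range(4):
                new_q[k] /= norm
            _quat_matrix(new_q, rot)
            cx = cy = cz = 0.0
            for k in range(nb):
                i = moved_idx[k]
                cx += coords[i, 0]
                cy += coords[i, 1]
                cz += coords[i, 2]
            cx /= nb
            cy /= nb
            cz /= nb
            mx = my = mz = 0.0
            for k in range(nb):
                rx = body_refs[start + k, 0]
                ry = body_refs[start + k, 1]
                rz = body_refs[start + k, 2]
                px = rot[0, 0] * rx + rot[0, 1] * ry + rot[0, 2] * rz
                py = rot[1, 0] * rx + rot[1, 1] * ry + rot[1, 2] * rz
                pz = rot[2, 0] * rx + rot[2, 1] * ry + rot[2, 2] * rz
                new_moved[k, 0] = px
                new_moved[k, 1] = py
                new_moved[k, 2] = pz
                mx += px
                my += py
                mz += pz
            mx /= nb
            my /= nb
            mz /= nb
            for k in range(nb):
                new_moved[k, 0] += cx - mx
                new_moved[k, 1] += cy - my
                new_moved[k, 2] += cz - mz
        for k in range(nb):
            is_moved[moved_idx[k]] = True
        d_e = total_delta(coords, trial, new_moved, moved_idx, is_moved,
                          eps_mat, qq_mat, allowed, r_ex, r_cut, rep_k, lam,
                          bond_pairs, bond_b0, bond_k,
                          angle_triples, angle_0, angle_k,
                          torsion_quads, torsion_amp,
                          membrane, bead_depths, z_m, mem_range, wall_k,
                          restraint_idx, restraint_z, restraint_k)
        for k in range(nb):
            is_moved[moved_idx[k]] = False
        n_attempted += 1
        if not np.isfinite(d_e):
            return np.nan, n_attempted, n_accepted
        if d_e <= 0.0 or rng.random() < np.exp(-beta * d_e):
            for k in range(nb):
                i = moved_idx[k]
                coords[i, 0] = new_moved[k, 0]
                coords[i, 1] = new_moved[k, 1]
                coords[i, 2] = new_moved[k, 2]
            if rotated:
                for k in range(4):
                    quats[b, k] = new_q[k]
            energy += d_e
            n_accepted += 1

    n_chains = chain_offsets.shape[0] - 1
    for c in range(n_chains):
        start = chain_offsets[c]
        stop = chain_offsets[c + 1]
        nc = stop - start
        for k in range(nc):
            bead = chain_indices[start + k]
            if nc == 1 or rng.random() < 0.5:
                kick = rng.standard_normal(3)
                moved_idx = scratch_moved[:1]
                moved_idx[0] = bead
                new_moved = np.empty((1, 3))
                new_moved[0, 0] = coords[bead, 0] + linker_amp * kick[0]
                new_moved[0, 1] = coords[bead, 1] + linker_amp * kick[1]
                new_moved[0, 2] = coords[bead, 2] + linker_amp * kick[2]
            else:
                # pivot the shorter chain arm about this bead
                if k >= nc // 2:
                    arm_start = k + 1
                    arm_stop = nc
                else:
                    arm_start = 0
                    arm_stop = k
                na = arm_stop - arm_start
                if na == 0:
                    # still consume the move's randomness deterministically
                    rng.standard_normal(3)
                    continue
                kick = rng.standard_normal(3) * pivot_amp
                _rotvec_quat(kick, dq)
                _quat_matrix(dq, rot)
                moved_idx = scratch_moved[:na]
                new_moved = np.empty((na, 3))
                px = coords[bead, 0]
                py = coords[bead, 1]
                pz = coords[bead, 2]
                for a in range(na):
                    i = chain_indices[start + arm_start + a]
                    moved_idx[a] = i
                    vx = coords[i, 0] - px
                    vy = coords[i, 1] - py
                    vz = coords[i, 2] - pz
                    new_moved[a, 0] = rot[0, 0] * vx + rot[0, 1] * vy + rot[0, 2] * vz + px
                    new_moved[a, 1] = rot[1, 0] * vx + rot[1, 1] * vy + rot[1, 2] * vz + py
                    new_moved[a, 2] = rot[2, 0] * vx + rot[2, 1] * vy + rot[2, 2] * vz + pz
            for a in range(moved_idx.shape[0]):
                is_moved[moved_idx[a]] = True
            d_e = total_delta(coords, trial, new_moved, moved_idx, is_moved,
                              eps_mat, qq_mat, allowed, r_ex, r_cut, rep_k, lam,
                              bond_pairs, bond_b0, bond_k,
                              angle_triples, angle_0, angle_k,
                              torsion_quads, torsion_amp,
                              membrane, bead_depths, z_m, mem_range, wall_k,
                              restraint_idx, restraint_z, restraint_k)
            for a in range(moved_idx.shape[0]):
                is_moved[moved_idx[a]] = False
            n_attempted += 1
            if not np.isfinite(d_e):
                return np.nan, n_attempted, n_accepted
            if d_e <= 0.0 or rng.random() < np.exp(-beta * d_e):
                for a in range(moved_idx.shape[0]):
                    i = moved_idx[a]
                    coords[i, 0] = new_moved[a, 0]
                    coords[i, 1] = new_moved[a, 1]
                    coords[i, 2] = new_moved[a, 2]
                energy += d_e
                n_accepted += 1
    return energy, n_attempted, n_accepted


@numba.njit(cache=True)
def debye_sum(dists, ff_prod, q_grid, self_term):
    """Orientation-averaged Debye intensity over unique pairs.

    dists/ff_prod are the condensed upper-triangle pair distances and form
    factor products; self_term is sum(f_i^2).  The q=0 and r=0 limits of
    sin(qr)/(qr) are taken as 1.
    """
    nq = q_grid.shape[0]
    out = np.empty(nq)
    for iq in range(nq):
        q = q_grid[iq]
        acc = 0.0
        if q == 0.0:
            for p in range(dists.shape[0]):
                acc += ff_prod[p]
        else:
            for p in range(dists.shape[0]):
                x = q * dists[p]
                if x < 1e-12:
                    acc += ff_prod[p]
                else:
                    acc += ff_prod[p] * np.sin(x) / x
        out[iq] = self_term + 2.0 * acc
    return out
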