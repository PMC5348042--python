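"""Numba kernels for pair search, forces, and energies.

Everything operates on flat numpy arrays in reduced units.  Kernels return
(energy, flag) pairs where flags count capped/diverging events; callers
decide whether to raise.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO16 = 2.0 ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# neighbour search (cell grid, per-kind-pair cutoffs, exclusion keys)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _in_sorted(keys, key):
    lo, hi = 0, keys.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if keys[mid] < key:
            lo = mid + 1
        else:
            hi = mid
    return lo < keys.shape[0] and keys[lo] == key


@njit(cache=True)
def build_pairs(pos, kind, rlist2, cell_size, excl_keys, out_i, out_j):
    """Fill out_i/out_j with pairs closer than the per-kind list radius.

    rlist2[ki, kj] is (cutoff + skin)^2.  Returns the pair count, or -1 if
    the output arrays are too small.
    """
    n = pos.shape[0]
    xmin = pos[0, 0]
    ymin = pos[0, 1]
    zmin = pos[0, 2]
    xmax, ymax, zmax = xmin, ymin, zmin
    for i in range(n):
        if pos[i, 0] < xmin:
            xmin = pos[i, 0]
        if pos[i, 0] > xmax:
            xmax = pos[i, 0]
        if pos[i, 1] < ymin:
            ymin = pos[i, 1]
        if pos[i, 1] > ymax:
            ymax = pos[i, 1]
        if pos[i, 2] < zmin:
            zmin = pos[i, 2]
        if pos[i, 2] > zmax:
            zmax = pos[i, 2]
    nx = max(1, int((xmax - xmin) / cell_size) + 1)
    ny = max(1, int((ymax - ymin) / cell_size) + 1)
    nz = max(1, int((zmax - zmin) / cell_size) + 1)
    ncell = nx * ny * nz

    head = np.full(ncell, -1, np.int64)
    nxt = np.full(n, -1, np.int64)
    cx = np.empty(n, np.int64)
    cy = np.empty(n, np.int64)
    cz = np.empty(n, np.int64)
    for i in range(n):
        ix = int((pos[i, 0] - xmin) / cell_size)
        iy = int((pos[i, 1] - ymin) / cell_size)
        iz = int((pos[i, 2] - zmin) / cell_size)
        if ix >= nx:
            ix = nx - 1
        if iy >= ny:
            iy = ny - 1
        if iz >= nz:
            iz = nz - 1
        cx[i], cy[i], cz[i] = ix, iy, iz
        c = (ix * ny + iy) * nz + iz
        nxt[i] = head[c]
        head[c] = i

    cap = out_i.shape[0]
    count = 0
    for i in range(n):
        ki = kind[i]
        for dx in range(-1, 2):
            ix = cx[i] + dx
            if ix < 0 or ix >= nx:
                continue
            for dy in range(-1, 2):
                iy = cy[i] + dy
                if iy < 0 or iy >= ny:
                    continue
                for dz in range(-1, 2):
                    iz = cz[i] + dz
                    if iz < 0 or iz >= nz:
                        continue
                    j = head[(ix * ny + iy) * nz + iz]
                    while j >= 0:
                        if j > i:
                            rx = pos[i, 0] - pos[j, 0]
                            ry = pos[i, 1] - pos[j, 1]
                            rz = pos[i, 2] - pos[j, 2]
                            r2 = rx * rx + ry * ry + rz * rz
                            if r2 < rlist2[ki, kind[j]]:
                                key = i * n + j
                                if not _in_sorted(excl_keys, key):
                                    if count >= cap:
                                        return -1
                                    out_i[count] = i
                                    out_j[count] = j
                                    count += 1
                        j = nxt[j]
    return count


# ---------------------------------------------------------------------------
# pairwise steric repulsion (shifted LJ, cutoff at the minimum)
# ---------------------------------------------------------------------------


@njit(cache=True)
def steric_forces(pos, kind, pi_, pj_, npair, sig_t, eps_t, forces):
    e = 0.0
    for p in range(npair):
        i = pi_[p]
        j = pj_[p]
        sp = sig_t[kind[i], kind[j]]
        rc2 = (TWO16 * sp) ** 2
        rx = pos[i, 0] - pos[j, 0]
        ry = pos[i, 1] - pos[j, 1]
        rz = pos[i, 2] - pos[j, 2]
        r2 = rx * rx + ry * ry + rz * rz
        if r2 >= rc2 or r2 <= 0.0:
            continue
        ep = eps_t[kind[i], kind[j]]
        s2 = sp * sp / r2
        s6 = s2 * s2 * s2
        e += 4.0 * ep * (s6 * s6 - s6) + ep
        fr = 24.0 * ep * (2.0 * s6 * s6 - s6) / r2
        fx = fr * rx
        fy = fr * ry
        fz = fr * rz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return e


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------


@njit(cache=True)
def bond_forces(pos, bonds, bond_k, bond_r0, forces):
    e = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        rx = pos[i, 0] - pos[j, 0]
        ry = pos[i, 1] - pos[j, 1]
        rz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(rx * rx + ry * ry + rz * rz)
        dr = r - bond_r0[b]
        e += 0.5 * bond_k[b] * dr * dr
        if r > 0.0:
            fr = -bond_k[b] * dr / r
            fx = fr * rx
            fy = fr * ry
            fz = fr * rz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return e


@njit(cache=True)
def angle_forces(pos, angles, kb, theta0, dth_max, forces):
    """FENE bending on consecutive triples; returns (energy, n_diverging)."""
    e = 0.0
    nbad = 0
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if nu == 0.0 or nv == 0.0:
            continue
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        u = (theta - theta0) / dth_max
        if u >= 1.0 or u <= -1.0:
            nbad += 1
            u = 0.999 if u > 0.0 else -0.999
            e += -0.5 * kb * dth_max * np.log(1.0 - u * u)
        else:
            e += -0.5 * kb * dth_max * np.log(1.0 - u * u)
        dUdtheta = kb * u / (1.0 - u * u)
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        # F_i = -dU/dr_i = -(dU/dtheta)(dtheta/dc)(dc/dr_i) = +(dU/dtheta)/sin(theta) * dc/dr_i
        coef = dUdtheta / s
        # d(cos theta)/dr_i and /dr_k
        gix = (vx / (nu * nv)) - c * ux / (nu * nu)
        giy = (vy / (nu * nv)) - c * uy / (nu * nu)
        giz = (vz / (nu * nv)) - c * uz / (nu * nu)
        gkx = (ux / (nu * nv)) - c * vx / (nv * nv)
        gky = (uy / (nu * nv)) - c * vy / (nv * nv)
        gkz = (uz / (nu * nv)) - c * vz / (nv * nv)
        fix = coef * gix
        fiy = coef * giy
        fiz = coef * giz
        fkx = coef * gkx
        fky = coef * gky
        fkz = coef * gkz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
    return e, nbad


# ---------------------------------------------------------------------------
# breakable actin-spectrin association
# ---------------------------------------------------------------------------


@njit(cache=True)
def as_forces(
    pos, pairs, state, recapture_ok, global_recapture, sigma_as, eps, forces
):
    """Breakable LJ junctions; mutates ``state`` in place.

    Break when an intact pair is stretched past the inflexion point
    (26/7)^(1/6) * sigma_as; recapture when a broken pair comes within
    2.5 * sigma_as (if allowed).  The repulsive core below the potential
    minimum is always active.
    """
    r_eq = TWO16 * sigma_as
    r_inf = (26.0 / 7.0) ** (1.0 / 6.0) * sigma_as
    r_capt = 2.5 * sigma_as
    e = 0.0
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        rx = pos[i, 0] - pos[j, 0]
        ry = pos[i, 1] - pos[j, 1]
        rz = pos[i, 2] - pos[j, 2]
        r2 = rx * rx + ry * ry + rz * rz
        r = np.sqrt(r2)
        if state[p] == 1:
            if r > r_inf:
                state[p] = 0
        else:
            if global_recapture == 1 and recapture_ok[p] == 1 and r < r_capt:
                state[p] = 1
        if state[p] == 1:
            s2 = sigma_as * sigma_as / r2
            s6 = s2 * s2 * s2
            e += 4.0 * eps * (s6 * s6 - s6)
            fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
        else:
            if r < r_eq:
                s2 = sigma_as * sigma_as / r2
                s6 = s2 * s2 * s2
                e += 4.0 * eps * (s6 * s6 - s6) + eps
                fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
            else:
                continue
        fx = fr * rx
        fy = fr * ry
        fz = fr * rz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return e


# ---------------------------------------------------------------------------
# confinement and expansion wall
# ---------------------------------------------------------------------------


@njit(cache=True)
def confinement_forces(pos, kind, r0_s, r0_k, kc, forces):
    """Bilayer confinement: one-sided (outward) for spectrin, two-sided for ankyrin."""
    e = 0.0
    for i in range(pos.shape[0]):
        k = kind[i]
        if k == 0:  # actin: no confinement
            continue
        ri = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2)
        if ri == 0.0:
            continue
        if k == 1:
            dr = ri - r0_s
            if dr <= 0.0:
                continue
        else:
            dr = ri - r0_k
        e += 0.5 * kc * dr * dr
        fr = -kc * dr / ri
        forces[i, 0] += fr * pos[i, 0]
        forces[i, 1] += fr * pos[i, 1]
    return e


@njit(cache=True)
def wall_forces(pos, kind, rc, sig_w, r_off, eps, forces, wall_rad):
    """Expanding cylindrical repulsion; fills wall_rad with outward force magnitudes.

    For kind k the potential argument is x = r_i - (rc - r_off[k]) with length
    scale sig_w[k]; cutoff at the minimum 2^(1/6) sig_w[k].  Particles at or
    inside the singularity get a clipped (capped) force and are counted in
    the returned flag.
    """
    e = 0.0
    nclip = 0
    for i in range(pos.shape[0]):
        k = kind[i]
        sw = sig_w[k]
        if sw <= 0.0:
            wall_rad[i] = 0.0
            continue
        ri = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2)
        x = ri - (rc - r_off[k])
        xmin = 0.2 * sw
        if x <= xmin:
            x = xmin
            nclip += 1
        if x >= TWO16 * sw:
            wall_rad[i] = 0.0
            continue
        s2 = sw * sw / (x * x)
        s6 = s2 * s2 * s2
        e += 4.0 * eps * (s6 * s6 - s6) + eps
        fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / x  # > 0: outward
        wall_rad[i] = fr
        if ri > 0.0:
            forces[i, 0] += fr * pos[i, 0] / ri
            forces[i, 1] += fr * pos[i, 1] / ri
    return e, nclip


# ---------------------------------------------------------------------------
# inter-ring FENE coupling through ring centres (mean z of each ring)
# ---------------------------------------------------------------------------


@njit(cache=True)
def ring_coupling_forces(pos, ring_of_actin, n_rings, n_per_ring, kmt, d_eq, dd_max, forces):
    """FENE restraint on consecutive ring-centre spacings, distributed evenly."""
    e = 0.0
    nbad = 0
    zbar = np.zeros(n_rings)
    for a in range(ring_of_actin.shape[0]):
        zbar[ring_of_actin[a]] += pos[a, 2]
    for g in range(n_rings):
        zbar[g] /= n_per_ring
    fz = np.zeros(n_rings)
    for g in range(n_rings - 1):
        d = zbar[g + 1] - zbar[g]
        u = (d - d_eq) / dd_max
        if u >= 1.0 or u <= -1.0:
            nbad += 1
            u = 0.999 if u > 0.0 else -0.999
        e += -0.5 * kmt * dd_max * np.log(1.0 - u * u)
        dUdd = kmt * u / (1.0 - u * u)
        fz[g + 1] -= dUdd
        fz[g] += dUdd
    for a in range(ring_of_actin.shape[0]):
        forces[a, 2] += fz[ring_of_actin[a]] / n_per_ring
    return e, nbad


@njit(cache=True)
def beeman_positions(pos, vel, acc, acc_prev, mobile, dt):
    c = dt * dt / 6.0
    for i in range(pos.shape[0]):
        if mobile[i]:
            for d in range(3):
                pos[i, d] += vel[i, d] * dt + (4.0 * acc[i, d] - acc_prev[i, d]) * c
    return 0


@njit(cache=True)
def beeman_velocities(vel, acc_new, acc, acc_prev, mobile, dt):
    c = dt / 6.0
    for i in range(vel.shape[0]):
        if mobile[i]:
            for d in range(3):
                vel[i, d] += (2.0 * acc_new[i, d] + 5.0 * acc[i, d] - acc_prev[i, d]) * c
    return 0


@njit(cache=True)
def kinetic_sum(vel, mobile):
    s = 0.0
    for i in range(vel.shape[0]):
        if mobile[i]:
            s += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
    return s


@njit(cache=True)
def scale_velocities(vel, mobile, lam):
    for i in range(vel.shape[0]):
        if mobile[i]:
            vel[i, 0] *= lam
            vel[i, 1] *= lam
            vel[i, 2] *= lam
    return 0


@njit(cache=True)
def all_finite(pos):
    for i in range(pos.shape[0]):
        for d in range(3):
            if not np.isfinite(pos[i, d]):
                return False
    return True


@njit(cache=True)
def max_disp2(pos, ref):
    m = 0.0
    for i in range(pos.shape[0]):
        d2 = (
            (pos[i, 0] - ref[i, 0]) ** 2
            + (pos[i, 1] - ref[i, 1]) ** 2
            + (pos[i, 2] - ref[i, 2]) ** 2
        )
        if d2 > m:
            m = d2
    return m


@njit(cache=True)
def cap_forces(forces, fmax):
    """Clip per-particle force norms at fmax; returns the number clipped."""
    n = 0
    for i in range(forces.shape[0]):
        f2 = forces[i, 0] ** 2 + forces[i, 1] ** 2 + forces[i, 2] ** 2
        if f2 > fmax * fmax:
            s = fmax / np.sqrt(f2)
            forces[i, 0] *= s
            forces[i, 1] *= s
            forces[i, 2] *= s
            n += 1
    return n
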