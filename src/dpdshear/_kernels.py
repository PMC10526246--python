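"""Numba kernels: counter-based pair noise and the full force evaluation.

The random pair force uses a counter-based construction: the noise value for
pair (i, j) at a given step is a pure hash of (seed, step, min(i,j),
max(i,j)).  This guarantees ζ_ij == ζ_ji (required for exact momentum
conservation), makes trajectories independent of pair-enumeration order, and
reproduces bitwise for a fixed seed.

The default ζ is uniform, scaled to unit variance (sqrt(3) * U(-1, 1)); a
Gaussian variant (Box-Muller on two hashed uniforms) is selectable.  Both
have zero mean and unit variance, which is all the DPD thermostat requires.

``compute_forces`` keeps the pair loop monolithic on purpose: beads are
gathered into cell-sorted scratch arrays and the interaction arithmetic is
written inline, which measures several times faster than a factored helper.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_S30 = np.uint64(30)
_S27 = np.uint64(27)
_S31 = np.uint64(31)
_S11 = np.uint64(11)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53
_SQRT3 = 1.7320508075688772


@njit(cache=True, inline="always")
def _mix(z):
    z = (z ^ (z >> _S30)) * _MIX1
    z = (z ^ (z >> _S27)) * _MIX2
    return z ^ (z >> _S31)


@njit(cache=True, inline="always")
def pair_noise(seed, step, i, j, gaussian):
    """Symmetric unit-variance noise for the ordered pair (i < j)."""
    h = _mix(np.uint64(seed) + _GOLDEN * np.uint64(step))
    h = _mix(h ^ (np.uint64(i) * _MIX1))
    h = _mix(h ^ (np.uint64(j) * _MIX2))
    if gaussian:
        h2 = _mix(h ^ _GOLDEN)
        u1 = (float(h >> _S11) + 0.5) * _INV53
        u2 = float(h2 >> _S11) * _INV53
        return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)
    u = float(h >> _S11) * _INV53
    return _SQRT3 * (2.0 * u - 1.0)


@njit(cache=True, inline="always")
def _min_image(d, L):
    # positions are wrapped, so one correction suffices
    if d > 0.5 * L:
        return d - L
    if d < -0.5 * L:
        return d + L
    return d


# 13 half-space neighbor offsets; the self cell is handled as offset index 13
_OFFSETS = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)


@njit(cache=True, fastmath=True)
def compute_forces(
    pos,
    vel,
    species,
    L,
    a,
    gamma,
    sigma,
    rc,
    ks,
    rs,
    ktheta,
    theta0,
    inv_sqrt_dt,
    bonds,
    angles,
    seed,
    step,
    gaussian,
):
    """All forces (DPD pair + bond + angle) and potential-energy terms.

    Returns (forces, e_pair, e_bond, e_angle, err) with err != 0 on a
    degenerate bond or angle geometry.
    """
    N = pos.shape[0]
    f = np.zeros((N, 3))
    e_pair = 0.0
    err = 0
    rc2 = rc * rc

    ncx = int(L / rc)
    if ncx < 3:
        # box too small for a cell list: all-pairs loop
        for i in range(N):
            for j in range(i + 1, N):
                dx = _min_image(pos[i, 0] - pos[j, 0], L)
                dy = _min_image(pos[i, 1] - pos[j, 1], L)
                dz = _min_image(pos[i, 2] - pos[j, 2], L)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 >= rc2 or r2 == 0.0:
                    continue
                r = np.sqrt(r2)
                wr = 1.0 - r / rc
                ex = dx / r
                ey = dy / r
                ez = dz / r
                vdotr = (
                    (vel[i, 0] - vel[j, 0]) * ex
                    + (vel[i, 1] - vel[j, 1]) * ey
                    + (vel[i, 2] - vel[j, 2]) * ez
                )
                aij = a[species[i], species[j]]
                zeta = pair_noise(seed, step, i, j, gaussian)
                fmag = aij * wr - gamma * wr * wr * vdotr + sigma * wr * zeta * inv_sqrt_dt
                f[i, 0] += fmag * ex
                f[i, 1] += fmag * ey
                f[i, 2] += fmag * ez
                f[j, 0] -= fmag * ex
                f[j, 1] -= fmag * ey
                f[j, 2] -= fmag * ez
                e_pair += 0.5 * aij * rc * wr * wr
    else:
        cell_w = L / ncx
        ncell = ncx * ncx * ncx
        cell_idx = np.empty(N, np.int64)
        for i in range(N):
            cx = int(pos[i, 0] / cell_w)
            cy = int(pos[i, 1] / cell_w)
            cz = int(pos[i, 2] / cell_w)
            if cx >= ncx:
                cx = ncx - 1
            if cy >= ncx:
                cy = ncx - 1
            if cz >= ncx:
                cz = ncx - 1
            if cx < 0:
                cx = 0
            if cy < 0:
                cy = 0
            if cz < 0:
                cz = 0
            cell_idx[i] = (cx * ncx + cy) * ncx + cz
        start = np.zeros(ncell + 1, np.int64)
        for i in range(N):
            start[cell_idx[i] + 1] += 1
        for c in range(ncell):
            start[c + 1] += start[c]
        order = np.empty(N, np.int64)
        fill = start[:-1].copy()
        for i in range(N):
            c = cell_idx[i]
            order[fill[c]] = i
            fill[c] += 1

        # gather into cell-sorted working arrays for cache locality
        spos = np.empty((N, 3))
        svel = np.empty((N, 3))
        sspec = np.empty(N, np.int64)
        for u in range(N):
            i = order[u]
            spos[u, 0] = pos[i, 0]
            spos[u, 1] = pos[i, 1]
            spos[u, 2] = pos[i, 2]
            svel[u, 0] = vel[i, 0]
            svel[u, 1] = vel[i, 1]
            svel[u, 2] = vel[i, 2]
            sspec[u] = species[i]
        sf = np.zeros((N, 3))

        offs = _OFFSETS
        for cx in range(ncx):
            for cy in range(ncx):
                for cz in range(ncx):
                    c = (cx * ncx + cy) * ncx + cz
                    b0 = start[c]
                    b1 = start[c + 1]
                    for o in range(14):
                        if o == 13:
                            d0 = b0
                            d1 = b1
                        else:
                            nx = (cx + offs[o, 0]) % ncx
                            ny = (cy + offs[o, 1]) % ncx
                            nz = (cz + offs[o, 2]) % ncx
                            c2 = (nx * ncx + ny) * ncx + nz
                            d0 = start[c2]
                            d1 = start[c2 + 1]
                        for u in range(b0, b1):
                            v0 = u + 1 if o == 13 else d0
                            for v in range(v0, d1):
                                dx = _min_image(spos[u, 0] - spos[v, 0], L)
                                dy = _min_image(spos[u, 1] - spos[v, 1], L)
                                dz = _min_image(spos[u, 2] - spos[v, 2], L)
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 >= rc2 or r2 == 0.0:
                                    continue
                                r = np.sqrt(r2)
                                wr = 1.0 - r / rc
                                ex = dx / r
                                ey = dy / r
                                ez = dz / r
                                vdotr = (
                                    (svel[u, 0] - svel[v, 0]) * ex
                                    + (svel[u, 1] - svel[v, 1]) * ey
                                    + (svel[u, 2] - svel[v, 2]) * ez
                                )
                                aij = a[sspec[u], sspec[v]]
                                oi = order[u]
                                oj = order[v]
                                if oi < oj:
                                    zeta = pair_noise(seed, step, oi, oj, gaussian)
                                else:
                                    zeta = pair_noise(seed, step, oj, oi, gaussian)
                                fmag = (
                                    aij * wr
                                    - gamma * wr * wr * vdotr
                                    + sigma * wr * zeta * inv_sqrt_dt
                                )
                                sf[u, 0] += fmag * ex
                                sf[u, 1] += fmag * ey
                                sf[u, 2] += fmag * ez
                                sf[v, 0] -= fmag * ex
                                sf[v, 1] -= fmag * ey
                                sf[v, 2] -= fmag * ez
                                e_pair += 0.5 * aij * rc * wr * wr
        # scatter forces back to original bead order
        for u in range(N):
            i = order[u]
            f[i, 0] = sf[u, 0]
            f[i, 1] = sf[u, 1]
            f[i, 2] = sf[u, 2]

    # bonds: F = ks (1 - r/rs) rhat, U = ks/(2 rs) (r - rs)^2
    e_bond = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], L)
        dy = _min_image(pos[i, 1] - pos[j, 1], L)
        dz = _min_image(pos[i, 2] - pos[j, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-24:
            err = 1
            continue
        r = np.sqrt(r2)
        fmag = ks * (1.0 - r / rs)
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        f[i, 0] += fx
        f[i, 1] += fy
        f[i, 2] += fz
        f[j, 0] -= fx
        f[j, 1] -= fy
        f[j, 2] -= fz
        e_bond += 0.5 * ks / rs * (r - rs) * (r - rs)

    # angles: U = ktheta (theta - theta0)^2 on consecutive triples
    e_angle = 0.0
    for t in range(angles.shape[0]):
        i = angles[t, 0]
        j = angles[t, 1]
        k = angles[t, 2]
        d1x = _min_image(pos[i, 0] - pos[j, 0], L)
        d1y = _min_image(pos[i, 1] - pos[j, 1], L)
        d1z = _min_image(pos[i, 2] - pos[j, 2], L)
        d2x = _min_image(pos[k, 0] - pos[j, 0], L)
        d2y = _min_image(pos[k, 1] - pos[j, 1], L)
        d2z = _min_image(pos[k, 2] - pos[j, 2], L)
        rsq1 = d1x * d1x + d1y * d1y + d1z * d1z
        rsq2 = d2x * d2x + d2y * d2y + d2z * d2z
        if rsq1 < 1e-24 or rsq2 < 1e-24:
            err = 2
            continue
        r1 = np.sqrt(rsq1)
        r2_ = np.sqrt(rsq2)
        c = (d1x * d2x + d1y * d2y + d1z * d2z) / (r1 * r2_)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        s = np.sqrt(1.0 - c * c)
        if s < 1e-12:
            s = 1e-12
        theta = np.arccos(c)
        dtheta = theta - theta0
        e_angle += ktheta * dtheta * dtheta
        acoef = -2.0 * ktheta * dtheta / s
        a11 = acoef * c / rsq1
        a12 = -acoef / (r1 * r2_)
        a22 = acoef * c / rsq2
        f1x = a11 * d1x + a12 * d2x
        f1y = a11 * d1y + a12 * d2y
        f1z = a11 * d1z + a12 * d2z
        f3x = a22 * d2x + a12 * d1x
        f3y = a22 * d2y + a12 * d1y
        f3z = a22 * d2z + a12 * d1z
        f[i, 0] += f1x
        f[i, 1] += f1y
        f[i, 2] += f1z
        f[k, 0] += f3x
        f[k, 1] += f3y
        f[k, 2] += f3z
        f[j, 0] -= f1x + f3x
        f[j, 1] -= f1y + f3y
        f[j, 2] -= f1z + f3z

    return f, e_pair, e_bond, e_angle, err
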