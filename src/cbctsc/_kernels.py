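"""Numba kernels: ray marching, backprojection, dose superposition, gamma search.

All kernels work in (z, y, x) world coordinates (mm) consistent with array
axis order.  Volumes are sampled trilinearly with voxel-centre addressing;
samples outside the grid contribute zero.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True, inline="always")
def _trilinear(vol, fz, fy, fx):
    nz, ny, nx = vol.shape
    z0 = int(np.floor(fz))
    y0 = int(np.floor(fy))
    x0 = int(np.floor(fx))
    wz = fz - z0
    wy = fy - y0
    wx = fx - x0
    acc = 0.0
    for dz in range(2):
        iz = z0 + dz
        if iz < 0 or iz >= nz:
            continue
        cz = wz if dz == 1 else 1.0 - wz
        for dy in range(2):
            iy = y0 + dy
            if iy < 0 or iy >= ny:
                continue
            cy = wy if dy == 1 else 1.0 - wy
            for dx in range(2):
                ix = x0 + dx
                if ix < 0 or ix >= nx:
                    continue
                cx = wx if dx == 1 else 1.0 - wx
                acc += vol[iz, iy, ix] * cz * cy * cx
    return acc


@njit(cache=True, fastmath=True, inline="always")
def _ray_integral(vol, oz, oy, ox, sz, sy, sx, p0z, p0y, p0x, p1z, p1y, p1x, step):
    """Line integral of ``vol`` between world points p0 and p1 (midpoint rule).

    The segment is clipped to the volume's bounding box first.
    """
    dz = p1z - p0z
    dy = p1y - p0y
    dx = p1x - p0x
    length = np.sqrt(dz * dz + dy * dy + dx * dx)
    if length <= 0.0:
        return 0.0
    # slab clipping in normalised ray parameter t in [0, 1]
    t0 = 0.0
    t1 = 1.0
    nzv, nyv, nxv = vol.shape
    for axis in range(3):
        if axis == 0:
            o, s, n, p, d = oz, sz, nzv, p0z, dz
        elif axis == 1:
            o, s, n, p, d = oy, sy, nyv, p0y, dy
        else:
            o, s, n, p, d = ox, sx, nxv, p0x, dx
        lo = o - 0.5 * s
        hi = o + (n - 0.5) * s
        if d == 0.0:
            if p < lo or p > hi:
                return 0.0
        else:
            ta = (lo - p) / d
            tb = (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t1 <= t0:
        return 0.0
    seg = (t1 - t0) * length
    n_steps = int(np.ceil(seg / step))
    if n_steps < 1:
        n_steps = 1
    h = seg / n_steps
    acc = 0.0
    for k in range(n_steps):
        t = t0 + (t1 - t0) * (k + 0.5) / n_steps
        fz = (p0z + t * dz - oz) / sz
        fy = (p0y + t * dy - oy) / sy
        fx = (p0x + t * dx - ox) / sx
        acc += _trilinear(vol, fz, fy, fx)
    return acc * h


@njit(cache=True, fastmath=True)
def forward_view(
    vol, oz, oy, ox, sz, sy, sx,
    src, det00, ustep, vstep, out, step,
):
    """Line integrals for one view: source point to every detector pixel.

    ``det00`` is the world position of pixel (iv=0, iu=0); ``ustep`` and
    ``vstep`` are the world offsets per detector column/row.  ``out`` has
    shape (nv, nu).
    """
    nv, nu = out.shape
    for iv in range(nv):
        for iu in range(nu):
            pz = det00[0] + iv * vstep[0] + iu * ustep[0]
            py = det00[1] + iv * vstep[1] + iu * ustep[1]
            px = det00[2] + iv * vstep[2] + iu * ustep[2]
            out[iv, iu] = _ray_integral(
                vol, oz, oy, ox, sz, sy, sx,
                src[0], src[1], src[2], pz, py, px, step,
            )


@njit(cache=True, fastmath=True)
def backproject_view(
    out, oz, oy, ox, sz, sy, sx,
    q, cosb, sinb, sad, sdd, du, dv, u0, v0, weight,
):
    """Distance-weighted voxel-driven backprojection of one filtered view.

    ``q`` (nv, nu) is the filtered projection; pixel (iv, iu) sits at
    detector coordinates (v0 + iv*dv, u0 + iu*du).  ``weight`` carries the
    angular increment factor.
    """
    nz, ny, nx = out.shape
    nv, nu = q.shape
    for iz in range(nz):
        z = oz + iz * sz
        for iy in range(ny):
            y = oy + iy * sy
            for ix in range(nx):
                x = ox + ix * sx
                t = sad - (x * cosb + y * sinb)
                if t <= 1.0:  # behind or at the source: outside usable FOV
                    continue
                u = sdd * (-x * sinb + y * cosb) / t
                v = sdd * z / t
                fu = (u - u0) / du
                fv = (v - v0) / dv
                iu0 = int(np.floor(fu))
                iv0 = int(np.floor(fv))
                wu = fu - iu0
                wv = fv - iv0
                acc = 0.0
                for dv_i in range(2):
                    jv = iv0 + dv_i
                    if jv < 0 or jv >= nv:
                        continue
                    cv = wv if dv_i == 1 else 1.0 - wv
                    for du_i in range(2):
                        ju = iu0 + du_i
                        if ju < 0 or ju >= nu:
                            continue
                        cu = wu if du_i == 1 else 1.0 - wu
                        acc += q[jv, ju] * cv * cu
                out[iz, iy, ix] += weight * (sad * sad) / (t * t) * acc


@njit(cache=True, fastmath=True)
def dose_superposition(
    dose, doz, doy, dox, dsz, dsy, dsx,
    lac, loz, loy, lox, lsz, lsy, lsx,
    dwell_pos, dwell_scale, dmin2, step,
):
    """Point-source dose with inverse-square and primary attenuation.

    ``dwell_pos`` (n, 3) world points, ``dwell_scale`` (n) = strength * time.
    """
    nz, ny, nx = dose.shape
    nd = dwell_pos.shape[0]
    for iz in range(nz):
        z = doz + iz * dsz
        for iy in range(ny):
            y = doy + iy * dsy
            for ix in range(nx):
                x = dox + ix * dsx
                acc = 0.0
                for j in range(nd):
                    dz = z - dwell_pos[j, 0]
                    dy = y - dwell_pos[j, 1]
                    dx = x - dwell_pos[j, 2]
                    d2 = dz * dz + dy * dy + dx * dx
                    if d2 < dmin2:
                        d2 = dmin2
                    path = _ray_integral(
                        lac, loz, loy, lox, lsz, lsy, lsx,
                        dwell_pos[j, 0], dwell_pos[j, 1], dwell_pos[j, 2],
                        z, y, x, step,
                    )
                    acc += dwell_scale[j] / d2 * np.exp(-path)
                dose[iz, iy, ix] = acc


@njit(cache=True, fastmath=True)
def gamma_search(
    ref, evl, threshold, dd_frac,
    off_fz, off_fy, off_fx, dist2_over_dta2,
    gamma_map,
):
    """Local 3D gamma via sorted-offset search with early termination.

    Offsets are in fractional-index units (same grid for ref and eval),
    sorted by ascending distance; ``dist2_over_dta2`` is the corresponding
    squared distance-to-agreement term.  Voxels below ``threshold`` get NaN.
    Returns (n_evaluated, n_passed).
    """
    nz, ny, nx = ref.shape
    n_off = off_fz.shape[0]
    n_eval = 0
    n_pass = 0
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                dref = ref[iz, iy, ix]
                if dref < threshold:
                    gamma_map[iz, iy, ix] = np.nan
                    continue
                denom = dd_frac * dref
                g2min = 1e300
                for k in range(n_off):
                    d2 = dist2_over_dta2[k]
                    if d2 >= g2min:
                        break
                    fz = iz + off_fz[k]
                    fy = iy + off_fy[k]
                    fx = ix + off_fx[k]
                    if fz < 0.0 or fz > nz - 1.0:
                        continue
                    if fy < 0.0 or fy > ny - 1.0:
                        continue
                    if fx < 0.0 or fx > nx - 1.0:
                        continue
                    dd = _trilinear(evl, fz, fy, fx) - dref
                    g2 = d2 + (dd / denom) ** 2
                    if g2 < g2min:
                        g2min = g2
                g = np.sqrt(g2min)
                gamma_map[iz, iy, ix] = g
                n_eval += 1
                if g <= 1.0:
                    n_pass += 1
    return n_eval, n_pass
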