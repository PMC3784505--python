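"""Numba-compiled inner loops.

These kernels carry the per-sample hot paths of the simulator: quasistatic
whisker bending against oriented rectangles (a bisection on a caudal curvature
offset), the inside-or-shadow obstacle raster, and cut-off Gaussian blob
deposits onto the head-centric grid.  All operate on plain float64 arrays;
the object-level API lives in :mod:`vibrisim.plane` and
:mod:`vibrisim.attention`.

Conventions: an obstacle row is ``(cx, cy, hw, hh, cos a, sin a)`` (center,
half extents, orientation); a whisker shaft is a constant-curvature arc whose
heading evolves as ``alpha(s) = alpha0 + kappa_eff * s`` with ``kappa_eff``
the standard plane curvature (d alpha / d s).
"""

import numpy as np
from numba import njit

_DEG = np.pi / 180.0


@njit(cache=True)
def _point_in_rect(px, py, ob):
    dx = px - ob[0]
    dy = py - ob[1]
    qx = ob[4] * dx + ob[5] * dy
    qy = -ob[5] * dx + ob[4] * dy
    return (-ob[2] < qx < ob[2]) and (-ob[3] < qy < ob[3])


@njit(cache=True)
def _rect_signed_depth(px, py, ob):
    """Penetration depth into the rectangle (positive inside, negative outside)."""
    dx = px - ob[0]
    dy = py - ob[1]
    qx = abs(ob[4] * dx + ob[5] * dy) - ob[2]
    qy = abs(-ob[5] * dx + ob[4] * dy) - ob[3]
    if qx <= 0.0 and qy <= 0.0:
        return -max(qx, qy)          # inside: distance to nearest face
    ox = qx if qx > 0.0 else 0.0
    oy = qy if qy > 0.0 else 0.0
    return -np.sqrt(ox * ox + oy * oy)


@njit(cache=True)
def _arc_point(bx, by, alpha0, kap, s):
    """Point at arc length s of a constant-curvature arc from (bx, by)."""
    if abs(kap) < 1e-12:
        return bx + s * np.cos(alpha0), by + s * np.sin(alpha0)
    a1 = alpha0 + kap * s
    return (bx + (np.sin(a1) - np.sin(alpha0)) / kap,
            by + (np.cos(alpha0) - np.cos(a1)) / kap)


@njit(cache=True)
def _fill_arc(out, bx, by, alpha0, kap, length, step):
    """Vertices at spacing <= step along the arc; returns the vertex count."""
    n = int(np.ceil(length / step)) + 1
    ds = length / (n - 1)
    for k in range(n):
        x, y = _arc_point(bx, by, alpha0, kap, k * ds)
        out[k, 0] = x
        out[k, 1] = y
    return n


@njit(cache=True)
def _arc_hits(verts, nv, obstacles, nob, mask):
    """Index of a penetrated obstacle (deepest), or -1 if the arc is clear."""
    best = -1
    depth = 0.0
    for j in range(nob):
        if not mask[j]:
            continue
        for k in range(nv):
            if _point_in_rect(verts[k, 0], verts[k, 1], obstacles[j]):
                d = _rect_signed_depth(verts[k, 0], verts[k, 1], obstacles[j])
                if d > depth:
                    depth = d
                    best = j
    return best


@njit(cache=True)
def bend_whiskers(theta_base, base_head, side, kappa_rest, lengths, gains,
                  fovea, cos_b, sin_b, obstacles,
                  deform_dist, arc_step, dk_max, dk_tol,
                  kappa_out, delta_out, contact_out, cpoint_out, clamped_out):
    """Resolve quasistatic bending for all whiskers at the current pose.

    The perturbed curvature is ``kappa_rest - dk`` with ``dk`` the smallest
    caudal offset (found by bisection to ``dk_tol``) at which no arc vertex
    lies strictly inside any obstacle.  ``delta`` is the displacement of the
    shaft point at arc length ``deform_dist``; the contact signal is
    ``tanh(gain * delta)``; the contact point is the point on the constraining
    obstacle's boundary nearest the perturbed shaft.
    """
    nw = theta_base.shape[0]
    nob = obstacles.shape[0]
    verts = np.empty((80, 2))
    mask = np.empty(nob, np.bool_)
    for i in range(nw):
        L = lengths[i]
        # whisker base in world frame
        hx = base_head[i, 0]
        hy = base_head[i, 1]
        bx = fovea[0] + cos_b * hx - sin_b * hy
        by = fovea[1] + sin_b * hx + cos_b * hy
        # shaft heading in world frame (base-angle convention: measured from
        # the caudal direction of the midline, increasing rostrally)
        th = theta_base[i] * _DEG
        if side[i] > 0:
            alpha_h = np.pi - th
        else:
            alpha_h = th - np.pi
        alpha0 = alpha_h + np.arctan2(sin_b, cos_b)
        kap_eff0 = -side[i] * kappa_rest[i]

        # quick reject: obstacle farther than the whisker could ever reach
        any_near = False
        for j in range(nob):
            near = _rect_signed_depth(bx, by, obstacles[j]) >= -(L + 1.0)
            mask[j] = near
            if near:
                any_near = True

        kappa_out[i] = kappa_rest[i]
        delta_out[i] = 0.0
        contact_out[i] = 0.0
        cpoint_out[i, 0] = np.nan
        cpoint_out[i, 1] = np.nan
        clamped_out[i] = False
        if not any_near:
            continue

        nv = _fill_arc(verts, bx, by, alpha0, kap_eff0, L, arc_step)
        if _arc_hits(verts, nv, obstacles, nob, mask) < 0:
            continue  # unperturbed arc is clear

        # caudal bend: dk subtracts from the signed rest curvature, which in
        # world heading terms adds side * dk to kappa_eff
        hi = dk_max
        nv = _fill_arc(verts, bx, by, alpha0, kap_eff0 + side[i] * hi, L, arc_step)
        if _arc_hits(verts, nv, obstacles, nob, mask) >= 0:
            dk = dk_max            # deep penetration: clamp and flag
            clamped_out[i] = True
        else:
            lo = 0.0
            while hi - lo > dk_tol:
                mid = 0.5 * (lo + hi)
                nv = _fill_arc(verts, bx, by, alpha0,
                               kap_eff0 + side[i] * mid, L, arc_step)
                if _arc_hits(verts, nv, obstacles, nob, mask) >= 0:
                    lo = mid
                else:
                    hi = mid
            dk = hi                # guaranteed clear at vertex resolution

        kap_eff = kap_eff0 + side[i] * dk
        kappa_out[i] = kappa_rest[i] - dk
        # deviation of the measurement point at arc length deform_dist
        x0, y0 = _arc_point(bx, by, alpha0, kap_eff0, deform_dist)
        x1, y1 = _arc_point(bx, by, alpha0, kap_eff, deform_dist)
        delta = np.sqrt((x1 - x0) ** 2 + (y1 - y0) ** 2)
        delta_out[i] = delta
        contact_out[i] = np.tanh(gains[i] * delta)

        # constraining obstacle: nearest to the perturbed shaft
        nv = _fill_arc(verts, bx, by, alpha0, kap_eff, L, arc_step)
        best_j = -1
        best_k = -1
        best_d = 1e30
        for j in range(nob):
            if not mask[j]:
                continue
            for k in range(nv):
                d = -_rect_signed_depth(verts[k, 0], verts[k, 1], obstacles[j])
                if d < best_d:
                    best_d = d
                    best_j = j
                    best_k = k
        if best_j >= 0:
            ob = obstacles[best_j]
            px = verts[best_k, 0]
            py = verts[best_k, 1]
            dx = px - ob[0]
            dy = py - ob[1]
            qx = ob[4] * dx + ob[5] * dy
            qy = -ob[5] * dx + ob[4] * dy
            if abs(qx) <= ob[2] and abs(qy) <= ob[3]:
                # inside: push to the nearest face
                if ob[2] - abs(qx) < ob[3] - abs(qy):
                    qx = ob[2] if qx >= 0 else -ob[2]
                else:
                    qy = ob[3] if qy >= 0 else -ob[3]
            else:
                qx = min(max(qx, -ob[2]), ob[2])
                qy = min(max(qy, -ob[3]), ob[3])
            cpoint_out[i, 0] = ob[0] + ob[4] * qx - ob[5] * qy
            cpoint_out[i, 1] = ob[1] + ob[5] * qx + ob[4] * qy


@njit(cache=True)
def obstacle_shadow(cells_world, fovea, obstacles, out):
    """1 where a cell center is inside an obstacle or occluded by one.

    A cell is occluded when the open segment from the fovea to the cell
    center crosses an obstacle interior (Liang-Barsky slab clipping in the
    obstacle frame).
    """
    n = cells_world.shape[0]
    nob = obstacles.shape[0]
    for e in range(n):
        out[e] = 0.0
        px = cells_world[e, 0]
        py = cells_world[e, 1]
        for j in range(nob):
            ob = obstacles[j]
            # endpoints in the obstacle frame
            dx0 = fovea[0] - ob[0]
            dy0 = fovea[1] - ob[1]
            ax = ob[4] * dx0 + ob[5] * dy0
            ay = -ob[5] * dx0 + ob[4] * dy0
            dx1 = px - ob[0]
            dy1 = py - ob[1]
            bx_ = ob[4] * dx1 + ob[5] * dy1
            by_ = -ob[5] * dx1 + ob[4] * dy1
            t0 = 0.0
            t1 = 1.0
            ok = True
            for axis in range(2):
                if axis == 0:
                    p0 = ax
                    d = bx_ - ax
                    h = ob[2]
                else:
                    p0 = ay
                    d = by_ - ay
                    h = ob[3]
                if abs(d) < 1e-12:
                    if abs(p0) >= h:
                        ok = False
                        break
                else:
                    ta = (-h - p0) / d
                    tb = (h - p0) / d
                    if ta > tb:
                        ta, tb = tb, ta
                    if ta > t0:
                        t0 = ta
                    if tb < t1:
                        t1 = tb
                    if t0 >= t1:
                        ok = False
                        break
            if ok:
                out[e] = 1.0
                break


@njit(cache=True)
def deposit_gaussians(field, centers, amps, sigma, x0, y0, cell):
    """Add cut-off Gaussian blobs (head-frame centers, mm) onto the grid.

    ``field`` has shape (nx, ny); cell centers are at
    ``x = x0 + cell*(ix + 0.5)`` and likewise for y.  Blobs are truncated at
    four standard deviations.  Centers outside the grid extent are ignored.
    """
    nx = field.shape[0]
    ny = field.shape[1]
    cut = 4.0 * sigma
    inv = 1.0 / (2.0 * sigma * sigma)
    for m in range(centers.shape[0]):
        cx = centers[m, 0]
        cy = centers[m, 1]
        if not (x0 <= cx <= x0 + nx * cell and y0 <= cy <= y0 + ny * cell):
            continue
        ix_lo = max(0, int((cx - cut - x0) / cell - 0.5))
        ix_hi = min(nx - 1, int((cx + cut - x0) / cell - 0.5) + 1)
        iy_lo = max(0, int((cy - cut - y0) / cell - 0.5))
        iy_hi = min(ny - 1, int((cy + cut - y0) / cell - 0.5) + 1)
        a = amps[m]
        for ix in range(ix_lo, ix_hi + 1):
            xc = x0 + cell * (ix + 0.5)
            for iy in range(iy_lo, iy_hi + 1):
                yc = y0 + cell * (iy + 0.5)
                r2 = (xc - cx) ** 2 + (yc - cy) ** 2
                if r2 <= cut * cut:
                    field[ix, iy] += a * np.exp(-r2 * inv)
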