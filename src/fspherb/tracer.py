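"""Numba kernels for forward path tracing and backward R:FR gathering.

The scene triangles are binned into a 2-D uniform grid over the plot
footprint.  Torus periodicity is exact: triangles whose footprint crosses a
plot edge are registered as shifted instances, and a ray that leaves the
plot side re-enters at the opposite side.  Rays terminate on the absorbing
ground plane (z = 0) or by escaping above the canopy.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_EPS = 1e-9
_OFFSET = 1e-6


# ---------------------------------------------------------------------------
# grid construction (plain numpy)


class TraceGrid:
    """Uniform 2-D grid of (possibly shifted) triangle instances."""

    __slots__ = ("v0", "v1", "v2", "inst_tri", "cell_start", "cell_items",
                 "nx", "ny", "period", "z_top")

    def __init__(self, tri_v: np.ndarray, period: float, z_top: float,
                 wrap: bool = True, target_cell: float = 0.08):
        n_tri = len(tri_v)
        nx = max(4, min(64, int(round(period / target_cell))))
        self.nx = self.ny = nx
        self.period = period
        self.z_top = z_top
        cs = period / nx
        if n_tri == 0:
            self.v0 = np.zeros((0, 3)); self.v1 = np.zeros((0, 3)); self.v2 = np.zeros((0, 3))
            self.inst_tri = np.zeros(0, np.int32)
            self.cell_start = np.zeros(nx * nx + 1, np.int64)
            self.cell_items = np.zeros(0, np.int32)
            return
        shifts = ((-period, 0.0, period) if wrap else (0.0,))
        iv0, iv1, iv2, itri, cells = [], [], [], [], []
        lo = tri_v.min(axis=1)  # (n,3)
        hi = tri_v.max(axis=1)
        for sx in shifts:
            for sy in shifts:
                xlo = lo[:, 0] + sx
                xhi = hi[:, 0] + sx
                ylo = lo[:, 1] + sy
                yhi = hi[:, 1] + sy
                keep = (xhi > 0) & (xlo < period) & (yhi > 0) & (ylo < period)
                idx = np.nonzero(keep)[0]
                if len(idx) == 0:
                    continue
                shift = np.array([sx, sy, 0.0])
                for t in idx:
                    cx0 = max(0, int(math.floor((lo[t, 0] + sx) / cs)))
                    cx1 = min(nx - 1, int(math.floor((hi[t, 0] + sx) / cs)))
                    cy0 = max(0, int(math.floor((lo[t, 1] + sy) / cs)))
                    cy1 = min(nx - 1, int(math.floor((hi[t, 1] + sy) / cs)))
                    inst = len(itri)
                    iv0.append(tri_v[t, 0] + shift)
                    iv1.append(tri_v[t, 1] + shift)
                    iv2.append(tri_v[t, 2] + shift)
                    itri.append(t)
                    for cx in range(cx0, cx1 + 1):
                        for cy in range(cy0, cy1 + 1):
                            cells.append((cy * nx + cx, inst))
        self.v0 = np.asarray(iv0)
        self.v1 = np.asarray(iv1)
        self.v2 = np.asarray(iv2)
        self.inst_tri = np.asarray(itri, np.int32)
        n_cells = nx * nx
        if cells:
            carr = np.asarray(cells, np.int64)
            order = np.argsort(carr[:, 0], kind="stable")
            carr = carr[order]
            counts = np.bincount(carr[:, 0], minlength=n_cells)
            self.cell_start = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
            self.cell_items = carr[:, 1].astype(np.int32)
        else:
            self.cell_start = np.zeros(n_cells + 1, np.int64)
            self.cell_items = np.zeros(0, np.int32)


# ---------------------------------------------------------------------------
# numba device functions


@njit(cache=True, inline="always")
def _tri_t(ox, oy, oz, dx, dy, dz, v0, v1, v2):
    """Moller-Trumbore; returns hit distance t or -1."""
    e1x = v1[0] - v0[0]; e1y = v1[1] - v0[1]; e1z = v1[2] - v0[2]
    e2x = v2[0] - v0[0]; e2y = v2[1] - v0[1]; e2z = v2[2] - v0[2]
    px = dy * e2z - dz * e2y
    py = dz * e2x - dx * e2z
    pz = dx * e2y - dy * e2x
    det = e1x * px + e1y * py + e1z * pz
    if -1e-14 < det < 1e-14:
        return -1.0
    inv = 1.0 / det
    tx = ox - v0[0]; ty = oy - v0[1]; tz = oz - v0[2]
    u = (tx * px + ty * py + tz * pz) * inv
    if u < 0.0 or u > 1.0:
        return -1.0
    qx = ty * e1z - tz * e1y
    qy = tz * e1x - tx * e1z
    qz = tx * e1y - ty * e1x
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < 0.0 or u + v > 1.0:
        return -1.0
    t = (e2x * qx + e2y * qy + e2z * qz) * inv
    return t


@njit(cache=True, inline="always")
def _normal(v0, v1, v2):
    ax = v1[0] - v0[0]; ay = v1[1] - v0[1]; az = v1[2] - v0[2]
    bx = v2[0] - v0[0]; by = v2[1] - v0[1]; bz = v2[2] - v0[2]
    nx = ay * bz - az * by
    ny = az * bx - ax * bz
    nz = ax * by - ay * bx
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    if norm < 1e-30:
        return 0.0, 0.0, 1.0
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _cosine_dir(nx, ny, nz):
    """Cosine-weighted direction in the hemisphere around (nx, ny, nz)."""
    r1 = np.random.random()
    r2 = np.random.random()
    sq = math.sqrt(r1)
    phi = 2.0 * math.pi * r2
    x = sq * math.cos(phi)
    y = sq * math.sin(phi)
    z = math.sqrt(max(0.0, 1.0 - r1))
    # build tangent frame around the normal
    if abs(nx) < 0.9:
        tx, ty, tz = 1.0, 0.0, 0.0
    else:
        tx, ty, tz = 0.0, 1.0, 0.0
    ux = ny * tz - nz * ty
    uy = nz * tx - nx * tz
    uz = nx * ty - ny * tx
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux /= un; uy /= un; uz /= un
    vx = ny * uz - nz * uy
    vy = nz * ux - nx * uz
    vz = nx * uy - ny * ux
    dx = x * ux + y * vx + z * nx
    dy = x * uy + y * vy + z * ny
    dz = x * uz + y * vz + z * nz
    return dx, dy, dz


# ---------------------------------------------------------------------------
# forward PAR tracing


@njit(cache=True)
def trace_kernel(v0, v1, v2, inst_tri, tri_organ, organ_rho, organ_tau,
                 cell_start, cell_items, nx, period, z_top, wrap,
                 ray_o, ray_d, ray_w, max_bounces, seed, organ_absorb):
    """Returns (ground_absorbed, escaped); organ tallies accumulate in place."""
    np.random.seed(seed)
    ground = 0.0
    escaped = 0.0
    cs = period / nx
    n_rays = ray_o.shape[0]
    for r in range(n_rays):
        ox = ray_o[r, 0]; oy = ray_o[r, 1]; oz = ray_o[r, 2]
        dx = ray_d[r, 0]; dy = ray_d[r, 1]; dz = ray_d[r, 2]
        w = ray_w[r]
        bounce = 0
        guard = 0
        while True:
            guard += 1
            if guard > 500:
                escaped += w
                break
            if wrap:
                ox -= period * math.floor(ox / period)
                oy -= period * math.floor(oy / period)
            # vertical termination distances
            t_ground = 1e30
            t_top = 1e30
            if dz < -1e-12:
                t_ground = -oz / dz
            elif dz > 1e-12:
                t_top = (z_top - oz) / dz
            t_z = min(t_ground, t_top)
            inside = (0.0 <= ox < period) and (0.0 <= oy < period)
            if not inside:
                # advance to the plot footprint (non-wrap scenes only)
                t_in = -1.0
                t_enter = 0.0
                t_leave = t_z
                ok = True
                if abs(dx) > 1e-12:
                    ta = (0.0 - ox) / dx
                    tb = (period - ox) / dx
                    if ta > tb:
                        ta, tb = tb, ta
                    t_enter = max(t_enter, ta)
                    t_leave = min(t_leave, tb)
                elif ox < 0.0 or ox >= period:
                    ok = False
                if abs(dy) > 1e-12:
                    ta = (0.0 - oy) / dy
                    tb = (period - oy) / dy
                    if ta > tb:
                        ta, tb = tb, ta
                    t_enter = max(t_enter, ta)
                    t_leave = min(t_leave, tb)
                elif oy < 0.0 or oy >= period:
                    ok = False
                if ok and t_enter < t_leave and t_enter < t_z:
                    t_in = t_enter
                if t_in < 0.0:
                    if t_ground < t_top:
                        ground += w
                    else:
                        escaped += w
                    break
                ox += dx * (t_in + _OFFSET)
                oy += dy * (t_in + _OFFSET)
                oz += dz * (t_in + _OFFSET)
                continue
            # --- DDA within the footprint
            ix = int(ox / cs)
            iy = int(oy / cs)
            if ix >= nx:
                ix = nx - 1
            if iy >= nx:
                iy = nx - 1
            if dx > 1e-12:
                step_x = 1
                tmax_x = ((ix + 1) * cs - ox) / dx
                tdel_x = cs / dx
            elif dx < -1e-12:
                step_x = -1
                tmax_x = (ix * cs - ox) / dx
                tdel_x = -cs / dx
            else:
                step_x = 0
                tmax_x = 1e30
                tdel_x = 1e30
            if dy > 1e-12:
                step_y = 1
                tmax_y = ((iy + 1) * cs - oy) / dy
                tdel_y = cs / dy
            elif dy < -1e-12:
                step_y = -1
                tmax_y = (iy * cs - oy) / dy
                tdel_y = -cs / dy
            else:
                step_y = 0
                tmax_y = 1e30
                tdel_y = 1e30
            best_t = 1e30
            best_inst = -1
            t_side = 1e30
            while True:
                cell = iy * nx + ix
                for k in range(cell_start[cell], cell_start[cell + 1]):
                    inst = cell_items[k]
                    t = _tri_t(ox, oy, oz, dx, dy, dz,
                               v0[inst], v1[inst], v2[inst])
                    if _OFFSET < t < best_t:
                        best_t = t
                    else:
                        continue
                    best_inst = inst
                t_next = tmax_x if tmax_x < tmax_y else tmax_y
                if best_t <= t_next or t_next > t_z:
                    break
                if tmax_x < tmax_y:
                    ix += step_x
                    tmax_x += tdel_x
                    if ix < 0 or ix >= nx:
                        t_side = t_next
                        break
                else:
                    iy += step_y
                    tmax_y += tdel_y
                    if iy < 0 or iy >= nx:
                        t_side = t_next
                        break
            # --- resolve
            if best_inst >= 0 and best_t < t_z and best_t < t_side:
                tri = inst_tri[best_inst]
                organ = tri_organ[tri]
                rho = organ_rho[organ]
                tau = organ_tau[organ]
                u = np.random.random()
                hx = ox + dx * best_t
                hy = oy + dy * best_t
                hz = oz + dz * best_t
                if u < rho + tau:
                    nxn, nyn, nzn = _normal(v0[best_inst], v1[best_inst],
                                            v2[best_inst])
                    ddot = nxn * dx + nyn * dy + nzn * dz
                    if u < rho:
                        # reflect: hemisphere on the incident side
                        if ddot > 0.0:
                            nxn = -nxn; nyn = -nyn; nzn = -nzn
                    else:
                        # transmit: hemisphere on the far side
                        if ddot < 0.0:
                            nxn = -nxn; nyn = -nyn; nzn = -nzn
                    dx, dy, dz = _cosine_dir(nxn, nyn, nzn)
                    ox = hx + dx * _OFFSET
                    oy = hy + dy * _OFFSET
                    oz = hz + dz * _OFFSET
                    bounce += 1
                    if bounce >= max_bounces:
                        if np.random.random() < 0.5:
                            w *= 2.0
                        else:
                            break
                    continue
                organ_absorb[organ] += w
                break
            if t_side < t_z:
                if wrap:
                    ox += dx * (t_side + _OFFSET)
                    oy += dy * (t_side + _OFFSET)
                    oz += dz * (t_side + _OFFSET)
                    continue
                # outside the footprint there is nothing left to hit
                if t_ground < t_top:
                    ground += w
                else:
                    escaped += w
                break
            if t_ground < t_top:
                ground += w
            else:
                escaped += w
            break
    return ground, escaped


# ---------------------------------------------------------------------------
# backward R:FR gathering


@njit(cache=True)
def first_hit_organ(v0, v1, v2, inst_tri, tri_organ, cell_start, cell_items,
                    nx, period, z_top, wrap, ox, oy, oz, dx, dy, dz, skip_organ):
    """Nearest organ hit by a probe ray, or -1 (ground/sky/none)."""
    cs = period / nx
    guard = 0
    while True:
        guard += 1
        if guard > 200:
            return -1
        if wrap:
            ox -= period * math.floor(ox / period)
            oy -= period * math.floor(oy / period)
        t_ground = 1e30
        t_top = 1e30
        if dz < -1e-12:
            t_ground = -oz / dz
        elif dz > 1e-12:
            t_top = (z_top - oz) / dz
        t_z = min(t_ground, t_top)
        if not ((0.0 <= ox < period) and (0.0 <= oy < period)):
            return -1
        ix = int(ox / cs)
        iy = int(oy / cs)
        if ix >= nx:
            ix = nx - 1
        if iy >= nx:
            iy = nx - 1
        if dx > 1e-12:
            step_x = 1; tmax_x = ((ix + 1) * cs - ox) / dx; tdel_x = cs / dx
        elif dx < -1e-12:
            step_x = -1; tmax_x = (ix * cs - ox) / dx; tdel_x = -cs / dx
        else:
            step_x = 0; tmax_x = 1e30; tdel_x = 1e30
        if dy > 1e-12:
            step_y = 1; tmax_y = ((iy + 1) * cs - oy) / dy; tdel_y = cs / dy
        elif dy < -1e-12:
            step_y = -1; tmax_y = (iy * cs - oy) / dy; tdel_y = -cs / dy
        else:
            step_y = 0; tmax_y = 1e30; tdel_y = 1e30
        best_t = 1e30
        best_organ = -1
        t_side = 1e30
        while True:
            cell = iy * nx + ix
            for k in range(cell_start[cell], cell_start[cell + 1]):
                inst = cell_items[k]
                organ = tri_organ[inst_tri[inst]]
                if organ == skip_organ:
                    continue
                t = _tri_t(ox, oy, oz, dx, dy, dz,
                           v0[inst], v1[inst], v2[inst])
                if _OFFSET < t < best_t:
                    best_t = t
                    best_organ = organ
            t_next = tmax_x if tmax_x < tmax_y else tmax_y
            if best_t <= t_next or t_next > t_z:
                break
            if tmax_x < tmax_y:
                ix += step_x
                tmax_x += tdel_x
                if ix < 0 or ix >= nx:
                    t_side = t_next
                    break
            else:
                iy += step_y
                tmax_y += tdel_y
                if iy < 0 or iy >= nx:
                    t_side = t_next
                    break
        if best_organ >= 0 and best_t < t_z and best_t < t_side:
            return best_organ
        if t_side < t_z:
            if not wrap:
                return -1
            ox += dx * (t_side + _OFFSET)
            oy += dy * (t_side + _OFFSET)
            oz += dz * (t_side + _OFFSET)
            continue
        return -1


@njit(cache=True)
def sense_kernel(v0, v1, v2, inst_tri, tri_organ, tau_red, tau_fr,
                 cell_start, cell_items, nx, period, z_top, wrap,
                 sensors, sensor_organ, src_dir, src_red, src_fr,
                 ambient_rfr, refl_dirs, rho_red, rho_fr, organ_rel,
                 organ_is_leaf, reflect_gain, out_rfr):
    """Transmission-attenuated source visibility per sensor, plus an optional
    scattered-light term.

    Each sensor casts one shadow ray toward every source; each leaf crossed
    multiplies the red and far-red transmissions by its band transmittance
    (opaque organs end the ray).  If probe directions are supplied, each
    sensor also probes its surroundings: foliage hit by a probe contributes
    reflected flux proportional to its band reflectance and its relative
    irradiance, scaled by ``reflect_gain`` (a stand-in for multiple
    scattering, which enriches far-red near foliage long before overt
    shading).  tip R:FR = summed red / summed far-red.
    """
    cs = period / nx
    n_sensors = sensors.shape[0]
    n_src = src_dir.shape[0]
    for si in range(n_sensors):
        red = 0.0
        fr = 0.0
        own = sensor_organ[si]
        for k in range(n_src):
            dx = -src_dir[k, 0]
            dy = -src_dir[k, 1]
            dz = -src_dir[k, 2]
            if dz <= 1e-9:
                continue
            ox = sensors[si, 0]
            oy = sensors[si, 1]
            oz = sensors[si, 2] + 0.004
            tr = 1.0
            tf = 1.0
            guard = 0
            while tr > 1e-7 or tf > 1e-7:
                guard += 1
                if guard > 500:
                    break
                if wrap:
                    ox -= period * math.floor(ox / period)
                    oy -= period * math.floor(oy / period)
                t_top = (z_top - oz) / dz
                inside = (0.0 <= ox < period) and (0.0 <= oy < period)
                if not inside:
                    break  # non-wrap scenes: clear sky outside the footprint
                ix = int(ox / cs)
                iy = int(oy / cs)
                if ix >= nx:
                    ix = nx - 1
                if iy >= nx:
                    iy = nx - 1
                if dx > 1e-12:
                    step_x = 1
                    tmax_x = ((ix + 1) * cs - ox) / dx
                    tdel_x = cs / dx
                elif dx < -1e-12:
                    step_x = -1
                    tmax_x = (ix * cs - ox) / dx
                    tdel_x = -cs / dx
                else:
                    step_x = 0
                    tmax_x = 1e30
                    tdel_x = 1e30
                if dy > 1e-12:
                    step_y = 1
                    tmax_y = ((iy + 1) * cs - oy) / dy
                    tdel_y = cs / dy
                elif dy < -1e-12:
                    step_y = -1
                    tmax_y = (iy * cs - oy) / dy
                    tdel_y = -cs / dy
                else:
                    step_y = 0
                    tmax_y = 1e30
                    tdel_y = 1e30
                t_side = 1e30
                t_cell_in = 0.0
                done = False
                while True:
                    cell = iy * nx + ix
                    t_next = tmax_x if tmax_x < tmax_y else tmax_y
                    t_cell_out = min(t_next, t_top)
                    for kk in range(cell_start[cell], cell_start[cell + 1]):
                        inst = cell_items[kk]
                        tri = inst_tri[inst]
                        organ = tri_organ[tri]
                        if organ == own:
                            continue
                        t = _tri_t(ox, oy, oz, dx, dy, dz,
                                   v0[inst], v1[inst], v2[inst])
                        # count each crossing exactly once: in this cell's span
                        if t_cell_in - _OFFSET < t <= t_cell_out and t > _OFFSET:
                            tr *= tau_red[organ]
                            tf *= tau_fr[organ]
                    if t_next >= t_top:
                        done = True
                        break
                    if tmax_x < tmax_y:
                        t_cell_in = tmax_x
                        ix += step_x
                        tmax_x += tdel_x
                        if ix < 0 or ix >= nx:
                            t_side = t_cell_in
                            break
                    else:
                        t_cell_in = tmax_y
                        iy += step_y
                        tmax_y += tdel_y
                        if iy < 0 or iy >= nx:
                            t_side = t_cell_in
                            break
                if done:
                    break
                if t_side < 1e29:
                    if not wrap:
                        break
                    ox += dx * (t_side + _OFFSET)
                    oy += dy * (t_side + _OFFSET)
                    oz += dz * (t_side + _OFFSET)
                    continue
                break
            red += src_red[k] * tr
            fr += src_fr[k] * tf
        n_probe = refl_dirs.shape[0]
        if n_probe > 0:
            e_red = 0.0
            e_fr = 0.0
            for k in range(src_red.shape[0]):
                e_red += src_red[k]
                e_fr += src_fr[k]
            sr = 0.0
            sf = 0.0
            for j in range(n_probe):
                organ = first_hit_organ(
                    v0, v1, v2, inst_tri, tri_organ, cell_start, cell_items,
                    nx, period, z_top, wrap,
                    sensors[si, 0], sensors[si, 1], sensors[si, 2] + 0.004,
                    refl_dirs[j, 0], refl_dirs[j, 1], refl_dirs[j, 2], own)
                if organ >= 0 and organ_is_leaf[organ] == 1:
                    sr += rho_red[organ] * organ_rel[organ]
                    sf += rho_fr[organ] * organ_rel[organ]
            red += reflect_gain * sr / n_probe * e_red
            fr += reflect_gain * sf / n_probe * e_fr
        if fr <= 0.0:
            out_rfr[si] = ambient_rfr
        else:
            out_rfr[si] = red / fr
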