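"""Triangulated canopy scenes with torus-periodic plots.

Leaves are ovate planar polygons (fixed template, blade area =
k_shape * length * width); internodes are rendered as two crossed vertical
rectangles of width twice the pipe radius, which intercept a comparable
amount of light to a thin cylinder at a fraction of the triangle count.
Instead of replicating the plot many times to remove border effects, the
plot is wrapped on a torus: rays leaving one side re-enter at the opposite
side, which is equivalent in expectation to an infinite periodic canopy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .architecture import (GOLDEN_ANGLE, Plant, axis_direction,
                           axis_node_positions)
from .params import LightParameters

# Ovate leaf template: stations along the midrib (x in [0,1]) and half-width
# profile; the polygon area ratio is rescaled to k_shape exactly.
_TPL_X = np.array([0.0, 0.15, 0.45, 0.80, 1.0])
_TPL_H = np.array([0.0, 0.35, 0.50, 0.35, 0.0])
_TPL_AREA = float(np.trapezoid(2 * _TPL_H, _TPL_X))  # ~0.675

BAND_PAR, BAND_RED, BAND_FR = 0, 1, 2
KIND_LEAF, KIND_INTERNODE = 0, 1


@dataclass
class Surface:
    """One organ's facets plus its optical coefficients."""

    triangles: np.ndarray          # (n, 3, 3) metres, z up
    organ_ref: tuple               # (plant_id, axis_index, rank, kind)
    rho: np.ndarray                # (3,) per band
    tau: np.ndarray                # (3,) per band
    area: float
    sensor: np.ndarray | None = None   # leaf-tip sensor point

    def __post_init__(self) -> None:
        if np.any(self.rho < 0) or np.any(self.tau < 0) or np.any(self.rho + self.tau > 1 + 1e-12):
            raise ValueError("need rho, tau >= 0 and rho + tau <= 1")


@dataclass
class Scene:
    """Flat triangle arrays for the tracer plus per-organ metadata."""

    tri_v: np.ndarray              # (n_tris, 3, 3)
    tri_organ: np.ndarray          # (n_tris,) int32
    organ_refs: list               # per-organ (plant_id, axis, rank, kind)
    organ_area: np.ndarray         # (n_organs,)
    organ_rho: np.ndarray          # (n_organs, 3)
    organ_tau: np.ndarray          # (n_organs, 3)
    sensors: np.ndarray            # (n_sensors, 3)
    sensor_organ: np.ndarray       # (n_sensors,) int32, own-leaf organ index
    period: float                  # torus period (plot side, m)
    wrap: bool = True
    z_top: float = 0.0

    @property
    def n_organs(self) -> int:
        return len(self.organ_refs)

    def leaf_area(self) -> float:
        kinds = np.array([ref[3] for ref in self.organ_refs], dtype=int) \
            if self.organ_refs else np.zeros(0, dtype=int)
        return float(self.organ_area[kinds == KIND_LEAF].sum()) if len(kinds) else 0.0

    def lai(self) -> float:
        return self.leaf_area() / self.period ** 2


def layout_plot(density: float, n_plants: int) -> tuple[np.ndarray, float]:
    """Square-grid planting positions and the plot side length.

    Spacing is 1/sqrt(density) m; returns (positions (n,3), side).
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    side_count = int(round(math.sqrt(n_plants)))
    if side_count * side_count != n_plants:
        raise ValueError("n_plants must be a perfect square")
    spacing = 1.0 / math.sqrt(density)
    extent = side_count * spacing
    pos = []
    for i in range(side_count):
        for j in range(side_count):
            pos.append(((i + 0.5) * spacing, (j + 0.5) * spacing, 0.0))
    return np.array(pos), extent


def leaf_mesh(length: float, width: float, elevation_angle: float,
              azimuth: float, base_point, consumed_fraction: float = 0.0,
              rho: np.ndarray | None = None, tau: np.ndarray | None = None,
              organ_ref: tuple = (0, 0, 0, KIND_LEAF),
              k_shape: float = 0.7) -> Surface:
    """Planar ovate blade pitched ``elevation_angle`` degrees above horizontal.

    Herbivory is represented by uniformly scaling the blade toward its tip so
    that the remaining area is (1 - consumed_fraction) * k_shape * L * W; the
    tip sensor is retained even at full consumption.
    """
    if length < 0 or width < 0:
        raise ValueError("length and width must be >= 0")
    if not 0 <= consumed_fraction <= 1:
        raise ValueError("consumed_fraction must be within [0, 1]")
    rho = np.zeros(3) if rho is None else np.asarray(rho, float)
    tau = np.zeros(3) if tau is None else np.asarray(tau, float)
    base = np.asarray(base_point, float)
    el = math.radians(elevation_angle)
    az = math.radians(azimuth)
    mid = np.array([math.cos(el) * math.cos(az),
                    math.cos(el) * math.sin(az),
                    math.sin(el)])
    across = np.array([-math.sin(az), math.cos(az), 0.0])
    h = _TPL_H * (k_shape / _TPL_AREA)
    pts_r = [base + x * length * mid + hh * width * across
             for x, hh in zip(_TPL_X, h)]
    pts_l = [base + x * length * mid - hh * width * across
             for x, hh in zip(_TPL_X, h)]
    tip = base + length * mid
    tris = []
    # base cap, two quads, tip cap
    tris.append([pts_r[0], pts_r[1], pts_l[1]])
    for i in (1, 2):
        tris.append([pts_r[i], pts_r[i + 1], pts_l[i + 1]])
        tris.append([pts_r[i], pts_l[i + 1], pts_l[i]])
    tris.append([pts_r[3], pts_r[4], pts_l[3]])
    tris = np.array(tris)
    if consumed_fraction > 0:
        s = math.sqrt(1.0 - consumed_fraction)
        tris = tip[None, None, :] + (tris - tip[None, None, :]) * s
    area = (1.0 - consumed_fraction) * k_shape * length * width
    return Surface(tris, organ_ref, rho, tau, area, sensor=tip)


def internode_mesh(base, top, radius: float, azimuth: float,
                   organ_ref: tuple = (0, 0, 0, KIND_INTERNODE)) -> Surface | None:
    """Crossed-plane billboard standing in for a thin stem cylinder."""
    base = np.asarray(base, float)
    top = np.asarray(top, float)
    if radius <= 0 or np.allclose(base, top):
        return None
    az = math.radians(azimuth)
    tris = []
    for a in (az, az + math.pi / 2):
        u = np.array([math.cos(a), math.sin(a), 0.0]) * radius
        p0, p1, p2, p3 = base - u, base + u, top + u, top - u
        tris.append([p0, p1, p2])
        tris.append([p0, p2, p3])
    tris = np.array(tris)
    area = float(2 * 2 * radius * np.linalg.norm(top - base))
    # internodes absorb in every band
    return Surface(tris, organ_ref, np.zeros(3), np.zeros(3), area, None)


def plant_surfaces(plant: Plant, light: LightParameters) -> list[Surface]:
    """Realise all live organs of one plant as surfaces."""
    p = plant.params
    lma, wd, ks = p.lma, p.wood_density, p.k_shape
    rho = np.array([light.par_rho, light.red_rho, light.fr_rho])
    tau = np.array([light.par_tau, light.red_tau, light.fr_tau])
    out: list[Surface] = []
    origins = {0: plant.position}
    for axis in plant.axes:
        origin = origins.get(axis.index)
        if origin is None:
            continue
        nodes = axis_node_positions(plant, axis, origin)
        for i, ph in enumerate(axis.phytomers):
            node = nodes[i]
            base = origin if i == 0 else nodes[i - 1]
            r = ph.internode.radius
            surf = internode_mesh(base, node, r, axis.azimuth,
                                  (plant.id, axis.index, i, KIND_INTERNODE))
            if surf is not None and not axis.aborted:
                out.append(surf)
            if ph.meristem.branch_axis >= 0:
                origins[ph.meristem.branch_axis] = node
            leaf = ph.leaf
            if leaf.senesced or leaf.grown_mass <= 0:
                continue
            length = leaf.length(lma, ks)
            width = length / leaf.lw_ratio if leaf.lw_ratio > 0 else 0.0
            leaf_az = axis.azimuth + GOLDEN_ANGLE * ph.rank
            elevation = 90.0 - leaf.angle  # leaf.angle is from the vertical
            cf = leaf.consumed_fraction(lma)
            out.append(leaf_mesh(length, width, elevation, leaf_az, node, cf,
                                 rho, tau, (plant.id, axis.index, i, KIND_LEAF),
                                 ks))
    return out


def assemble_scene(plants: list[Plant], wrap: bool = True,
                   period: float | None = None,
                   light: LightParameters | None = None) -> Scene:
    """Build the tracer-ready scene for a list of plants.

    ``period`` is the torus period (the plot side); it must be given when the
    plant list is empty.
    """
    light = light or LightParameters()
    ids = [pl.id for pl in plants]
    if len(set(ids)) != len(ids):
        raise ValueError("overlapping plant ids")
    surfaces: list[Surface] = []
    for pl in plants:
        surfaces.extend(plant_surfaces(pl, light))
    if period is None:
        if not plants:
            raise ValueError("period required for an empty scene")
        xy = np.array([pl.position[:2] for pl in plants])
        period = float(2 * xy.max()) if xy.size else 1.0
    return scene_from_surfaces(surfaces, period, wrap)


def scene_from_surfaces(surfaces: list[Surface], period: float,
                        wrap: bool = True) -> Scene:
    tris, tri_organ = [], []
    refs, areas, rhos, taus = [], [], [], []
    sensors, sensor_organ = [], []
    for k, s in enumerate(surfaces):
        if len(s.triangles):
            tris.append(s.triangles)
            tri_organ.append(np.full(len(s.triangles), k, dtype=np.int32))
        refs.append(s.organ_ref)
        areas.append(s.area)
        rhos.append(s.rho)
        taus.append(s.tau)
        if s.sensor is not None:
            sensors.append(s.sensor)
            sensor_organ.append(k)
    tri_v = np.concatenate(tris) if tris else np.zeros((0, 3, 3))
    z_top = float(tri_v[:, :, 2].max()) + 0.05 if len(tri_v) else 0.05
    return Scene(
        tri_v=tri_v,
        tri_organ=np.concatenate(tri_organ) if tri_organ else np.zeros(0, np.int32),
        organ_refs=refs,
        organ_area=np.array(areas) if areas else np.zeros(0),
        organ_rho=np.array(rhos) if rhos else np.zeros((0, 3)),
        organ_tau=np.array(taus) if taus else np.zeros((0, 3)),
        sensors=np.array(sensors) if sensors else np.zeros((0, 3)),
        sensor_organ=np.array(sensor_organ, np.int32) if sensor_organ else np.zeros(0, np.int32),
        period=float(period),
        wrap=wrap,
        z_top=z_top,
    )


def assemble_scene_fast(plants: list[Plant], period: float,
                        light: LightParameters | None = None,
                        wrap: bool = True) -> Scene:
    """Vectorised equivalent of :func:`assemble_scene` for the daily loop.

    Produces the same leaf template and crossed-plane internodes, but builds
    all triangles in batched numpy operations.
    """
    light = light or LightParameters()
    leaf_rho = np.array([light.par_rho, light.red_rho, light.fr_rho])
    leaf_tau = np.array([light.par_tau, light.red_tau, light.fr_tau])
    # gather per-organ scalars
    lb, ll, lw, lel, laz, lcf = [], [], [], [], [], []
    ib, it_, ir, iaz = [], [], [], []
    refs, areas, rhos, taus = [], [], [], []
    sensors, sensor_organ = [], []
    leaf_organ_idx, int_organ_idx = [], []
    for pl in plants:
        p = pl.params
        lma, wd, ks = p.lma, p.wood_density, p.k_shape
        origins = {0: pl.position}
        for axis in pl.axes:
            origin = origins.get(axis.index)
            if origin is None:
                continue
            nodes = axis_node_positions(pl, axis, origin)
            for i, ph in enumerate(axis.phytomers):
                node = nodes[i]
                base = origin if i == 0 else nodes[i - 1]
                if ph.meristem.branch_axis >= 0:
                    origins[ph.meristem.branch_axis] = node
                r = ph.internode.radius
                ilen = np.linalg.norm(node - base)
                if not axis.aborted and r > 0 and ilen > 1e-9:
                    int_organ_idx.append(len(refs))
                    refs.append((pl.id, axis.index, i, KIND_INTERNODE))
                    areas.append(4 * r * ilen)
                    rhos.append(np.zeros(3))
                    taus.append(np.zeros(3))
                    ib.append(base); it_.append(node)
                    ir.append(r); iaz.append(math.radians(axis.azimuth))
                leaf = ph.leaf
                if axis.aborted or leaf.senesced or leaf.grown_mass <= 0:
                    continue
                length = leaf.length(lma, ks)
                if length <= 0:
                    continue
                width = length / leaf.lw_ratio
                cf = leaf.consumed_fraction(lma)
                organ = len(refs)
                leaf_organ_idx.append(organ)
                refs.append((pl.id, axis.index, i, KIND_LEAF))
                areas.append((1.0 - cf) * ks * length * width)
                rhos.append(leaf_rho)
                taus.append(leaf_tau)
                lb.append(node); ll.append(length); lw.append(width)
                lel.append(math.radians(90.0 - leaf.angle))
                laz.append(math.radians(axis.azimuth + GOLDEN_ANGLE * ph.rank))
                lcf.append(cf)
                sensor_organ.append(organ)
    tri_blocks, organ_blocks = [], []
    n_leaves = len(lb)
    if n_leaves:
        base = np.array(lb); L = np.array(ll); W = np.array(lw)
        el = np.array(lel); az = np.array(laz); cf = np.array(lcf)
        mid = np.stack([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az),
                        np.sin(el)], axis=1)
        across = np.stack([-np.sin(az), np.cos(az),
                           np.zeros(n_leaves)], axis=1)
        # k_shape is shared by all plants of a run (single params object)
        ks = plants[0].params.k_shape if plants else 0.7
        h = _TPL_H * (ks / _TPL_AREA)
        # unique template points: B, R1..R3, T, L1..L3
        tx = np.array([0.0, _TPL_X[1], _TPL_X[2], _TPL_X[3], 1.0,
                       _TPL_X[1], _TPL_X[2], _TPL_X[3]])
        ty = np.array([0.0, h[1], h[2], h[3], 0.0, -h[1], -h[2], -h[3]])
        # (n_leaves, 8, 3)
        pts = (base[:, None, :]
               + tx[None, :, None] * L[:, None, None] * mid[:, None, :]
               + ty[None, :, None] * W[:, None, None] * across[:, None, :])
        tip = pts[:, 4, :]
        s = np.sqrt(1.0 - cf)
        pts = tip[:, None, :] + (pts - tip[:, None, :]) * s[:, None, None]
        faces = np.array([[0, 1, 5], [1, 2, 6], [1, 6, 5],
                          [2, 3, 7], [2, 7, 6], [3, 4, 7]])
        tri_blocks.append(pts[:, faces, :].reshape(-1, 3, 3))
        organ_blocks.append(np.repeat(np.array(leaf_organ_idx, np.int32), 6))
        sensors = list(tip)
    n_ints = len(ib)
    if n_ints:
        b = np.array(ib); t = np.array(it_)
        r = np.array(ir); a = np.array(iaz)
        tris = np.empty((n_ints, 4, 3, 3))
        for k, ang in enumerate((0.0, math.pi / 2)):
            u = np.stack([np.cos(a + ang), np.sin(a + ang),
                          np.zeros(n_ints)], axis=1) * r[:, None]
            p0 = b - u; p1 = b + u; p2 = t + u; p3 = t - u
            tris[:, 2 * k, 0] = p0; tris[:, 2 * k, 1] = p1; tris[:, 2 * k, 2] = p2
            tris[:, 2 * k + 1, 0] = p0; tris[:, 2 * k + 1, 1] = p2; tris[:, 2 * k + 1, 2] = p3
        tri_blocks.append(tris.reshape(-1, 3, 3))
        organ_blocks.append(np.repeat(np.array(int_organ_idx, np.int32), 4))
    tri_v = np.concatenate(tri_blocks) if tri_blocks else np.zeros((0, 3, 3))
    tri_organ = (np.concatenate(organ_blocks) if organ_blocks
                 else np.zeros(0, np.int32))
    z_top = float(tri_v[:, :, 2].max()) + 0.05 if len(tri_v) else 0.05
    return Scene(
        tri_v=tri_v, tri_organ=tri_organ, organ_refs=refs,
        organ_area=np.array(areas) if areas else np.zeros(0),
        organ_rho=np.array(rhos) if rhos else np.zeros((0, 3)),
        organ_tau=np.array(taus) if taus else np.zeros((0, 3)),
        sensors=np.array(sensors) if len(sensors) else np.zeros((0, 3)),
        sensor_organ=(np.array(sensor_organ, np.int32) if sensor_organ
                      else np.zeros(0, np.int32)),
        period=float(period), wrap=wrap, z_top=z_top)


def export_obj(scene: Scene, path) -> None:
    """Write the scene as a Wavefront OBJ file, one object per organ."""
    with open(path, "w") as fh:
        fh.write("# fspherb scene export\n")
        v_count = 0
        current = -1
        for t in range(len(scene.tri_v)):
            organ = int(scene.tri_organ[t])
            if organ != current:
                ref = scene.organ_refs[organ]
                fh.write(f"o plant{ref[0]}_axis{ref[1]}_rank{ref[2]}_kind{ref[3]}\n")
                current = organ
            for v in scene.tri_v[t]:
                fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            fh.write(f"f {v_count + 1} {v_count + 2} {v_count + 3}\n")
            v_count += 3
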