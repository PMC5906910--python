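"""Daily light computation: absorbed PAR per organ and R:FR per leaf tip.

``trace`` is a forward Monte-Carlo path tracer in the PAR band: rays are
sampled from the source set proportional to power, enter uniformly over the
(torus) plot top, and are absorbed, reflected or transmitted (Lambertian)
at each surface according to the organ's optical coefficients.  ``sense_rfr``
gathers backward from each leaf-tip sensor: per-band source fluxes are
attenuated by the transmittances of every leaf crossed on the way to the
sky, which depresses red far more than far-red inside a canopy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import LightSource
from .scene import Scene
from .tracer import TraceGrid, sense_kernel, trace_kernel


@dataclass
class LightResult:
    absorbed_par: np.ndarray     # mol m-2 leaf d-1 per organ
    absorbed_total: np.ndarray   # mol d-1 per organ (tally)
    tip_rfr: np.ndarray          # per sensor
    ground_absorbed: float       # mol m-2 ground d-1
    escaped: float               # mol m-2 ground d-1
    incident: float              # mol m-2 ground d-1


def _source_arrays(sources: list[LightSource]):
    if not sources:
        return (np.zeros((0, 3)), np.zeros(0), np.zeros(0), np.zeros(0))
    dirs = np.array([s.direction for s in sources], float)
    par = np.array([s.band_power["PAR"] for s in sources], float)
    red = np.array([s.band_power["red"] for s in sources], float)
    fr = np.array([s.band_power["far_red"] for s in sources], float)
    return dirs, par, red, fr


def build_grid(scene: Scene) -> TraceGrid:
    return TraceGrid(scene.tri_v, scene.period, scene.z_top, scene.wrap)


def trace(scene: Scene, sources: list[LightSource], n_rays: int,
          rng_seed: int, max_bounces: int = 5,
          grid: TraceGrid | None = None) -> LightResult:
    """Monte-Carlo PAR transport; deterministic for a fixed seed and scene."""
    if n_rays < 1000:
        raise ValueError("n_rays must be >= 1000")
    dirs, par, red, fr = _source_arrays(sources)
    incident = float(par.sum())
    n_organs = scene.n_organs
    absorb = np.zeros(n_organs)
    if incident <= 0:
        return LightResult(np.zeros(n_organs), absorb, np.array([]), 0.0, 0.0, 0.0)
    grid = grid or build_grid(scene)
    rng = np.random.default_rng(rng_seed)
    area = scene.period ** 2
    P = scene.period
    # Importance sampling of entry points: for each source, rays are drawn
    # uniformly over the canopy footprint swept along the source direction
    # (clipped to one plot period); entry points outside that window cannot
    # reach any surface before the ground, so their energy is added to the
    # ground tally analytically.  This is exact and keeps sparse early-season
    # canopies well sampled.
    if len(scene.tri_v):
        x0, y0 = scene.tri_v[:, :, 0].min(), scene.tri_v[:, :, 1].min()
        x1, y1 = scene.tri_v[:, :, 0].max(), scene.tri_v[:, :, 1].max()
    else:
        x0 = y0 = 0.0
        x1 = y1 = P
    direct_ground = 0.0
    win = np.empty((len(par), 4))   # xlo, ylo, wx, wy per source
    eff = np.empty(len(par))        # energy entering each window
    for k in range(len(par)):
        dz = min(dirs[k, 2], -1e-6)
        c = scene.z_top / abs(dz)
        wx = min(P, (x1 - x0) + abs(dirs[k, 0]) * c)
        wy = min(P, (y1 - y0) + abs(dirs[k, 1]) * c)
        xlo = x0 - max(0.0, dirs[k, 0]) * c
        ylo = y0 - max(0.0, dirs[k, 1]) * c
        win[k] = (xlo, ylo, wx, wy)
        eff[k] = par[k] * (wx * wy) / area
        direct_ground += par[k] - eff[k]
    eff_total = eff.sum()
    if eff_total <= 0:
        return LightResult(np.zeros(n_organs), absorb, np.array([]),
                           incident, 0.0, incident)
    src_idx = rng.choice(len(par), size=n_rays, p=eff / eff_total)
    ray_d = dirs[src_idx]
    ray_o = np.empty((n_rays, 3))
    u = rng.random((n_rays, 2))
    ray_o[:, 0] = win[src_idx, 0] + u[:, 0] * win[src_idx, 2]
    ray_o[:, 1] = win[src_idx, 1] + u[:, 1] * win[src_idx, 3]
    ray_o[:, 2] = scene.z_top - 1e-6
    ray_w = np.full(n_rays, eff_total * area / n_rays)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    ground, escaped = trace_kernel(
        grid.v0, grid.v1, grid.v2, grid.inst_tri, scene.tri_organ,
        np.ascontiguousarray(scene.organ_rho[:, 0]),
        np.ascontiguousarray(scene.organ_tau[:, 0]),
        grid.cell_start, grid.cell_items, grid.nx, scene.period,
        scene.z_top, scene.wrap, ray_o, ray_d, ray_w,
        max_bounces, kernel_seed, absorb)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_area = np.where(scene.organ_area > 0, absorb / scene.organ_area, 0.0)
    return LightResult(per_area, absorb, np.array([]),
                       ground / area + direct_ground, escaped / area, incident)


def _probe_directions(n_reflect: int) -> np.ndarray:
    """Deterministic sideways/downward probe fan for neighbour detection."""
    if n_reflect <= 0:
        return np.zeros((0, 3))
    n_az = max(4, n_reflect // 3)
    dirs = []
    # three elevation rings approximating the sphere around the sensor: the
    # upward ring mostly sees sky, diluting the foliage solid angle for an
    # exposed tip, while crowded sensors find foliage in every ring
    for j, el_deg in enumerate((25.0, -15.0, -50.0)):
        for k in range(n_az):
            az = 2 * np.pi * (k + j / 3.0) / n_az
            el = np.radians(el_deg)
            dirs.append([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az),
                         np.sin(el)])
    return np.asarray(dirs)


def sense_rfr(scene: Scene, sources: list[LightSource],
              ambient_rfr: float = 1.2,
              grid: TraceGrid | None = None,
              organ_rel: np.ndarray | None = None,
              n_reflect: int = 0,
              reflect_gain: float = 4.0) -> np.ndarray:
    """Tip R:FR per scene sensor by backward transmission gathering.

    With ``n_reflect`` > 0, each sensor additionally probes its surroundings
    with a deterministic fan of sideways/downward rays; foliage found there
    contributes scattered flux weighted by its band reflectance and relative
    irradiance (``organ_rel``), which enriches far-red near neighbours before
    any overt shading occurs.
    """
    n_sensors = len(scene.sensors)
    if n_sensors == 0:
        return np.zeros(0)
    dirs, par, red, fr = _source_arrays(sources)
    if len(dirs) == 0 or fr.sum() <= 0:
        return np.full(n_sensors, ambient_rfr)
    grid = grid or build_grid(scene)
    out = np.empty(n_sensors)
    if organ_rel is None:
        organ_rel = np.ones(scene.n_organs)
    is_leaf = np.array([1 if ref[3] == 0 else 0 for ref in scene.organ_refs],
                       dtype=np.uint8)
    sense_kernel(grid.v0, grid.v1, grid.v2, grid.inst_tri, scene.tri_organ,
                 np.ascontiguousarray(scene.organ_tau[:, 1]),
                 np.ascontiguousarray(scene.organ_tau[:, 2]),
                 grid.cell_start, grid.cell_items, grid.nx, scene.period,
                 scene.z_top, scene.wrap, scene.sensors, scene.sensor_organ,
                 dirs, red, fr, ambient_rfr, _probe_directions(n_reflect),
                 np.ascontiguousarray(scene.organ_rho[:, 1]),
                 np.ascontiguousarray(scene.organ_rho[:, 2]),
                 np.asarray(organ_rel, float), is_leaf,
                 float(reflect_gain), out)
    return out
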