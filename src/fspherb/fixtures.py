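"""Synthetic scenes and closed-form oracles for the physical submodels.

These generators live in the installed package (not only in the test suite)
so the command-line self-checks can run them for users: a homogeneous layered
canopy carries a Beer's-law interception expectation, and a fine-step
caterpillar integrator provides the reference trajectory for the engine's
1-gdd Euler stepping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import HerbivoreParameters
from .scene import Scene, Surface, scene_from_surfaces


def _square_leaf(cx: float, cy: float, z: float, side: float,
                 rho: np.ndarray, tau: np.ndarray, organ_id: int) -> Surface:
    h = side / 2.0
    p = np.array([[cx - h, cy - h, z], [cx + h, cy - h, z],
                  [cx + h, cy + h, z], [cx - h, cy + h, z]])
    tris = np.array([[p[0], p[1], p[2]], [p[0], p[2], p[3]]])
    return Surface(tris, (organ_id, 0, 0, 0), rho, tau, side * side,
                   sensor=np.array([cx, cy, z]))


def layered_canopy(lai: float, n_layers: int = 5, plot: float = 1.0,
                   leaf_side: float = 0.05, rho: float = 0.0,
                   tau: float = 0.0, seed: int = 0,
                   z_base: float = 0.3, dz: float = 0.1) -> tuple[Scene, float]:
    """Horizontally uniform canopy of small horizontal leaves on a torus plot.

    Leaves are placed uniformly at random in each layer, so gap frequency
    under a vertical beam is Poisson and the expected interception of a
    black canopy is the Beer's-law value 1 - exp(-LAI), which is returned
    alongside the scene.
    """
    if lai < 0:
        raise ValueError("lai must be >= 0")
    rng = np.random.default_rng(seed)
    rho_b = np.full(3, rho)
    tau_b = np.full(3, tau)
    surfaces = []
    if lai > 0:
        per_layer = lai * plot * plot / n_layers
        n_leaves = max(1, int(round(per_layer / leaf_side ** 2)))
        organ = 0
        for layer in range(n_layers):
            z = z_base + layer * dz
            for _ in range(n_leaves):
                cx = rng.uniform(0, plot)
                cy = rng.uniform(0, plot)
                surfaces.append(_square_leaf(cx, cy, z, leaf_side,
                                             rho_b, tau_b, organ))
                organ += 1
    expected = 1.0 - math.exp(-lai)
    return scene_from_surfaces(surfaces, plot, wrap=True), expected


def single_leaf_scene(coverage: float, plot: float = 1.0, z: float = 0.5,
                      rho: float = 0.0, tau: float = 0.0) -> Scene:
    """One horizontal leaf covering ``coverage`` of the plot footprint."""
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    side = math.sqrt(coverage) * plot
    s = _square_leaf(plot / 2, plot / 2, z, side, np.full(3, rho),
                     np.full(3, tau), 0)
    return scene_from_surfaces([s], plot, wrap=True)


def layered_sensor_scene(n_layers: int, tau_red: float, tau_fr: float,
                         plot: float = 1.0) -> Scene:
    """Plot-filling horizontal layers above a ground-level sensor.

    Under direct vertical light and no reflection the tip R:FR below the
    stack is ambient * (tau_red / tau_fr)^n_layers exactly.
    """
    rho = np.zeros(3)
    tau = np.array([0.0, tau_red, tau_fr])
    surfaces = []
    for k in range(n_layers):
        s = _square_leaf(plot / 2, plot / 2, 0.4 + 0.1 * k, plot * 0.999,
                         rho, tau, k)
        s.sensor = None
        surfaces.append(s)
    # keep the sensor off the quad diagonals of the layers above
    sensor_holder = _square_leaf(plot / 2 + 0.0137, plot / 2 - 0.0071, 0.05,
                                 1e-4, rho, np.zeros(3), n_layers)
    surfaces.append(sensor_holder)
    return scene_from_surfaces(surfaces, plot, wrap=True)


def two_plant_scene(heights=(0.6, 0.3), areas=(0.04, 0.04),
                    separation: float = 0.4, plot: float = 2.0) -> Scene:
    """Two opaque single-leaf 'plants' with hand-computable shading bounds."""
    rho = np.zeros(3)
    tau = np.zeros(3)
    x0 = plot / 2 - separation / 2
    x1 = plot / 2 + separation / 2
    s0 = _square_leaf(x0, plot / 2, heights[0], math.sqrt(areas[0]), rho, tau, 0)
    s1 = _square_leaf(x1, plot / 2, heights[1], math.sqrt(areas[1]), rho, tau, 1)
    return scene_from_surfaces([s0, s1], plot, wrap=True)


@dataclass
class CaterpillarOracle:
    time_to_pupation: float   # gdd
    final_weight: float       # g
    final_area: float         # m2 consumed
    rule: str                 # "weight" | "age"


def caterpillar_oracle(params: HerbivoreParameters | None = None,
                       dt: float = 0.01) -> CaterpillarOracle:
    """Fine-step integration of unlimited-food caterpillar growth.

    dC/dt = a_f * w(C) with w = min(w_max, max(w0, a_w * C^b)); pupation at
    weight w_max or age ``lifespan``, whichever fires first.
    """
    p = params or HerbivoreParameters()
    c = 0.0
    t = 0.0
    w = p.w0
    while True:
        if w >= p.w_max:
            return CaterpillarOracle(t, p.w_max, c, "weight")
        if t >= p.lifespan:
            return CaterpillarOracle(t, w, c, "age")
        c += p.a_f * w * dt
        w = min(p.w_max, max(p.w0, p.a_w * c ** p.b))
        t += dt
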