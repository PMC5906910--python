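"""Agent-based caterpillars: leaf choice, feeding, growth and pupation.

Each herbivore lives on a single host plant.  On instantiation and on every
movement event it picks a leaf by weighted random selection over the plant's
live leaves, with relative probability a logistic function of leaf thermal
age shaped by its feeding preference h (h > 0.5 favours young leaves,
h < 0.5 old leaves).  Feeding demand is linear in body weight; weight follows
a saturating power law of cumulative consumed area.  Pupation fires at the
age threshold or at the weight ceiling and removes the agent from the scene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .architecture import Phytomer, Plant
from .params import HerbivoreParameters


@dataclass
class Herbivore:
    id: int
    params: HerbivoreParameters
    host_plant: int                     # plant id
    weight: float = 1.86e-5
    cum_area: float = 0.0               # m2 consumed over life
    age: float = 0.0                    # gdd
    instar: int = 1
    current_leaf: tuple | None = None   # (axis_index, rank)
    state: str = "feeding"              # feeding | pupated
    pupation_cause: str = ""            # age | weight | starved
    events: list = field(default_factory=list)


def selection_weight(leaf_age: float, params: HerbivoreParameters) -> float:
    """Relative selection probability of a leaf of the given thermal age.

    rP = rP_max / (1 + exp(s * (2h - 1) * (leaf_age - m))); for h = 0.5 or
    leaf_age = m this is rP_max / 2, and rP(age; h) + rP(age; 1-h) = rP_max.
    """
    if leaf_age < 0:
        raise ValueError("leaf_age must be >= 0")
    x = params.s * (2.0 * params.h - 1.0) * (leaf_age - params.m)
    if x > 500:
        return 0.0
    if x < -500:
        return params.rp_max
    return params.rp_max / (1.0 + math.exp(x))


def _live_leaves(plant: Plant) -> list[tuple[tuple[int, int], Phytomer]]:
    lma = plant.params.lma
    out = []
    for ax, ph in plant.phytomer_iter(live_only=True):
        if not ph.leaf.senesced and ph.leaf.live_area(lma) > 0:
            out.append(((ax.index, ph.rank), ph))
    return out


def choose_leaf(plant: Plant, herbivore: Herbivore,
                rng: np.random.Generator) -> tuple[int, int] | None:
    """Sample a live leaf of the host plant with probability rP_i / sum rP.

    Returns None (and pupates the herbivore at its current weight) when the
    plant has no live leaf left -- the starvation exit.
    """
    leaves = _live_leaves(plant)
    if not leaves:
        pupate(herbivore, "starved")
        return None
    weights = np.array([selection_weight(ph.age, herbivore.params)
                        for _, ph in leaves])
    total = weights.sum()
    if total <= 0:
        idx = int(rng.integers(len(leaves)))
    else:
        idx = int(rng.choice(len(leaves), p=weights / total))
    herbivore.current_leaf = leaves[idx][0]
    return herbivore.current_leaf


def pupate(herbivore: Herbivore, cause: str) -> None:
    herbivore.state = "pupated"
    herbivore.pupation_cause = cause
    herbivore.current_leaf = None


def feed_and_grow(herbivore: Herbivore, plant: Plant, leaf: Phytomer,
                  dgdd: float) -> float:
    """Consume leaf area over one thermal step and update body weight.

    Demand is a_f * weight * dgdd, capped by the remaining live leaf area;
    weight tracks the saturating power law of cumulative consumed area.
    Returns the area removed; flags a movement when the leaf ran short.
    """
    p = herbivore.params
    if dgdd <= 0:
        return 0.0
    lma = plant.params.lma
    available = leaf.leaf.live_area(lma)
    demand = p.a_f * herbivore.weight * dgdd
    removed = min(demand, available)
    if removed > 0:
        leaf.leaf.consumed_area += removed
        plant.eaten_mass += removed * lma
        herbivore.cum_area += removed
        herbivore.weight = min(p.w_max,
                               max(p.w0, p.a_w * herbivore.cum_area ** p.b))
    if removed < demand - 1e-15:
        herbivore.events.append("shortfall")
    return removed


def step_herbivore(herbivore: Herbivore, plant: Plant, dgdd: float,
                   rng: np.random.Generator) -> float:
    """One daily step: age, moult, feed, move, pupate.  Returns area eaten.

    The day's thermal time is integrated in substeps so the explicit
    weight/feeding recursion stays close to the continuous growth law."""
    if herbivore.state != "feeding" or dgdd <= 0:
        return 0.0
    p = herbivore.params
    if dgdd > p.substep:
        n = int(math.ceil(dgdd / p.substep))
        total = 0.0
        for _ in range(n):
            total += step_herbivore(herbivore, plant, dgdd / n, rng)
            if herbivore.state != "feeding":
                break
        return total
    herbivore.age += dgdd
    new_instar = min(5, 1 + int(4 * herbivore.age / p.lifespan))
    moulted = new_instar > herbivore.instar
    herbivore.instar = new_instar
    # movement cues evaluated before feeding: senesced/exhausted leaf, moult
    lma = plant.params.lma
    leaf = _resolve_leaf(plant, herbivore.current_leaf)
    need_move = (leaf is None or leaf.leaf.senesced
                 or leaf.leaf.live_area(lma) <= 0 or moulted)
    if need_move:
        if choose_leaf(plant, herbivore, rng) is None:
            return 0.0
        leaf = _resolve_leaf(plant, herbivore.current_leaf)
    removed = feed_and_grow(herbivore, plant, leaf, dgdd)
    if herbivore.events and herbivore.events[-1] == "shortfall":
        herbivore.events.pop()
        if choose_leaf(plant, herbivore, rng) is not None:
            extra = _resolve_leaf(plant, herbivore.current_leaf)
            # finish the day's demand on the new leaf
            deficit_gdd = dgdd * (1.0 - removed / max(1e-30, p.a_f * herbivore.weight * dgdd))
            removed += feed_and_grow(herbivore, plant, extra,
                                     max(0.0, deficit_gdd))
    if herbivore.state == "feeding":
        if herbivore.age >= p.lifespan:
            pupate(herbivore, "age")
        elif herbivore.weight >= p.w_max:
            pupate(herbivore, "weight")
    return removed


def _resolve_leaf(plant: Plant, ref: tuple | None) -> Phytomer | None:
    if ref is None:
        return None
    axis_index, rank = ref
    if axis_index >= len(plant.axes):
        return None
    axis = plant.axes[axis_index]
    if axis.aborted or rank >= len(axis.phytomers):
        return None
    return axis.phytomers[rank]


def infest(plants: list[Plant], pattern: str, n_per_plant: int,
           grid_side: int, rng: np.random.Generator,
           h_old: float = 0.2, h_young: float = 0.8,
           base_params: HerbivoreParameters | None = None,
           homogeneous_h: float | None = None) -> list[Herbivore]:
    """Create the herbivore cohort for a plot laid out on a square grid.

    Patterns: ``homogeneous`` infests every plant with the same type;
    ``heterogeneous`` infests the even checkerboard parity and leaves the
    other half clean; ``alternating`` gives one parity young-leaf feeders
    (h_young) and the other old-leaf feeders (h_old).  Plants are assumed in
    row-major grid order.  Parity is (row + col) mod 2.
    """
    if pattern not in ("homogeneous", "heterogeneous", "alternating", "none"):
        raise ValueError(f"unknown pattern {pattern!r}")
    if pattern == "none" or n_per_plant == 0:
        return []
    if pattern in ("heterogeneous", "alternating") and (grid_side * grid_side) % 2:
        raise ValueError("checkerboard patterns need an even number of plants")
    base = base_params or HerbivoreParameters()
    cohort: list[Herbivore] = []
    hid = 0
    from dataclasses import replace
    for k, plant in enumerate(plants):
        row, col = divmod(k, grid_side)
        parity = (row + col) % 2
        if pattern == "homogeneous":
            h = homogeneous_h if homogeneous_h is not None else base.h
        elif pattern == "heterogeneous":
            if parity == 1:
                continue
            h = homogeneous_h if homogeneous_h is not None else base.h
        else:  # alternating
            h = h_young if parity == 0 else h_old
        params = replace(base, h=h)
        for _ in range(n_per_plant):
            herb = Herbivore(id=hid, params=params, host_plant=plant.id,
                             weight=params.w0)
            choose_leaf(plant, herb, rng)
            cohort.append(herb)
            hid += 1
    return cohort
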