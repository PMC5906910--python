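"""Phytomer-based plant architecture and meristem dynamics.

A plant is a tree of axes; axis 0 is the main stem and every other axis is a
branch borne by an axillary meristem.  Each axis is a sequence of phytomers
(internode + leaf + axillary meristem) produced one per phyllochron until the
axis reaches its phytomer target and flowers, appending an aggregate seed
sink.  Branch initiation needs release from apical dominance, surplus
assimilates and sufficient R:FR; immature branches abort under deep shade
(R:FR below the abortion threshold) or sustained reserve starvation.
Internode radii follow the pipe model: a parent's cross-section equals the
sum of its daughters' cross-sections, and radii never shrink.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import PlantParameters
from .physiology import CarbonPool

GOLDEN_ANGLE = 137.5  # degrees, main-stem phyllotaxis


@dataclass
class LeafState:
    """One leaf blade; areas in m2, masses in g, lengths in m."""

    grown_mass: float = 0.0       # cumulative structural mass allocated
    consumed_area: float = 0.0    # removed by herbivores (monotone)
    senesced: bool = False
    low_light_days: int = 0
    rel_light: float = 1.0        # latest relative absorbed irradiance
    abs_par: float = 0.0          # latest absorbed PAR, mol m-2 leaf d-1
    angle: float = 70.0           # degrees from vertical
    lw_ratio: float = 1.756
    base_len: float = 0.285       # drawn potential length before modifiers
    pot_length: float = 0.285     # instantaneous potential length (modified)
    wmax_acc: float = 0.0         # g, accumulated potential mass: the beta
    #   growth increments integrated with the shade modifiers of each day

    def grown_area(self, lma: float) -> float:
        return self.grown_mass / lma

    def live_area(self, lma: float) -> float:
        if self.senesced:
            return 0.0
        return max(0.0, self.grown_area(lma) - self.consumed_area)

    def length(self, lma: float, k_shape: float) -> float:
        """Length of the (undamaged) grown blade."""
        area = self.grown_area(lma)
        if area <= 0:
            return 0.0
        return math.sqrt(area * self.lw_ratio / k_shape)

    def consumed_fraction(self, lma: float) -> float:
        area = self.grown_area(lma)
        if area <= 0:
            return 0.0
        return min(1.0, self.consumed_area / area)


@dataclass
class InternodeState:
    """One internode; the pipe model owns ``radius``."""

    mass: float = 0.0
    radius: float = 0.0008        # m, pipe-model cross-section radius
    base_len: float = 0.045       # drawn potential length before modifiers
    pot_length: float = 0.045     # instantaneous potential length (modified)
    potmass_acc: float = 0.0      # g, accumulated potential mass (see leaf)
    len_acc: float = 0.0          # m, accumulated potential length
    length_real: float = 0.0      # m, realised length (monotone)
    n_distal: int = 1             # phytomers fed through this internode

    def volume(self, wood_density: float) -> float:
        return self.mass / wood_density

    def length(self, wood_density: float) -> float:
        return self.length_real

    def extend(self, wood_density: float, r0: float,
               vasc_frac: float = 1.0) -> None:
        """Extension toward the accumulated potential length.  Stretching a
        young internode costs only the thin-stem (initial radius) volume;
        the vascular cross-section that follows the distal phytomer count
        is a mass sink (thickening) that does not gate extension."""
        a = math.pi * r0 ** 2
        if a > 0:
            self.length_real = max(self.length_real,
                                   min(self.len_acc,
                                       self.volume(wood_density) / a))


@dataclass
class MeristemState:
    state: str = "dormant"        # dormant | branch | aborted
    branch_axis: int = -1         # axis index once broken


@dataclass
class Phytomer:
    rank: int                     # 0-based position on its axis
    age: float = 0.0              # gdd since appearance
    leaf: LeafState = field(default_factory=LeafState)
    internode: InternodeState = field(default_factory=InternodeState)
    meristem: MeristemState = field(default_factory=MeristemState)
    tip_rfr: float = 1.2          # latest R:FR sensed at the leaf tip


@dataclass
class SeedSink:
    """Aggregate inflorescence sink of one flowering axis."""

    start_gdd: float
    wmax: float                   # g, sink capacity
    mass: float = 0.0             # g seed accumulated


@dataclass
class Axis:
    index: int
    parent_axis: int              # -1 for the main stem
    parent_rank: int
    azimuth: float                # degrees
    target_n: int                 # phytomer number before flowering
    created_gdd: float = 0.0
    phytomers: list = field(default_factory=list)
    apical: str = "vegetative"    # vegetative | flowering
    aborted: bool = False
    progress: float = 0.0         # phyllochron accumulator (gdd)
    low_rfr_days: int = 0         # consecutive days below the abort threshold
    seed: SeedSink | None = None

    @property
    def flowering(self) -> bool:
        return self.apical == "flowering"


@dataclass
class Plant:
    id: int
    position: np.ndarray
    params: PlantParameters
    # per-plant phenotype draws
    n_target_open: int = 29
    n_target_shade: int = 27
    leaf_len_pot: float = 0.285
    int_len_pot: float = 0.045
    axes: list = field(default_factory=list)
    rng: np.random.Generator | None = None
    carbon: CarbonPool = field(default_factory=CarbonPool)
    last_surplus: float = 0.0
    last_satisfaction: float = 1.0
    systemic_latched: bool = False
    starve_days: int = 0
    litter_mass: float = 0.0      # g, senesced structural mass
    eaten_mass: float = 0.0       # g, removed by herbivores
    senesced_area: float = 0.0    # m2, leaf area lost to senescence
    age_gdd: float = 0.0

    # ------------------------------------------------------------------ state
    @property
    def main(self) -> Axis:
        return self.axes[0]

    @property
    def target_n(self) -> int:
        return self.n_target_shade if self.systemic_latched else self.n_target_open

    def live_axes(self):
        return [a for a in self.axes if not a.aborted]

    def phytomer_iter(self, live_only: bool = False):
        for ax in self.axes:
            if live_only and ax.aborted:
                continue
            for ph in ax.phytomers:
                yield ax, ph

    def leaf_area(self) -> float:
        lma = self.params.lma
        return sum(ph.leaf.live_area(lma) for _, ph in self.phytomer_iter())

    def standing_mass(self) -> float:
        """Live structural mass: leaves + internodes + seed (g)."""
        lma = self.params.lma
        leaf = sum(ph.leaf.live_area(lma) * lma for _, ph in self.phytomer_iter())
        stem = sum(ph.internode.mass for _, ph in self.phytomer_iter())
        seed = sum(ax.seed.mass for ax in self.axes if ax.seed is not None)
        return leaf + stem + seed

    def biomass(self) -> float:
        """Harvestable above-ground dry biomass (g): standing organs plus
        seed.  Shed (senesced or aborted) leaf tissue is tracked separately
        in ``litter_mass``; total tissue produced is their sum."""
        return self.standing_mass()

    def seed_yield(self) -> float:
        return sum(ax.seed.mass for ax in self.axes if ax.seed is not None)

    def peduncle_length(self) -> float:
        """Length of the main-axis flowering raceme, saturating with the
        seed mass it carries (bolting)."""
        p = self.params
        seed = self.main.seed
        if seed is None or seed.mass <= 0:
            return 0.0
        return p.ped_max * seed.mass / (seed.mass + p.ped_half)

    def height(self) -> float:
        wd = self.params.wood_density
        stem = sum(ph.internode.length(wd) for ph in self.main.phytomers)
        return stem + self.peduncle_length()

    def branch_count(self) -> int:
        """Non-aborted branches emerging from the main stem."""
        n = 0
        for ph in self.main.phytomers:
            if ph.meristem.state == "branch":
                ax = self.axes[ph.meristem.branch_axis]
                if not ax.aborted:
                    n += 1
        return n

    def gross_leaf_area(self) -> float:
        lma = self.params.lma
        return sum(ph.leaf.grown_area(lma) for _, ph in self.phytomer_iter())


# ---------------------------------------------------------------------------
# construction


def new_plant(plant_id: int, position, params: PlantParameters,
              rng: np.random.Generator, ambient_rfr: float = 1.2) -> Plant:
    """Seedling with per-plant phenotype draws (truncated at zero)."""
    def draw(mean, sd, lo=1e-6):
        return max(lo, float(rng.normal(mean, sd)))

    n_open = max(1, int(round(rng.normal(params.n_phytomers_mean,
                                         params.n_phytomers_sd))))
    n_shade = max(1, int(round(rng.normal(params.n_phytomers_high_mean,
                                          params.n_phytomers_high_sd))))
    plant = Plant(
        id=plant_id,
        position=np.asarray(position, dtype=float),
        params=params,
        n_target_open=n_open,
        n_target_shade=min(n_shade, n_open),
        leaf_len_pot=params.leaf_len_mean,
        int_len_pot=params.int_len_mean,
        rng=np.random.default_rng(int(rng.integers(0, 2**63))),
    )
    main = Axis(index=0, parent_axis=-1, parent_rank=-1, azimuth=0.0,
                target_n=n_open)
    plant.axes.append(main)
    plant.carbon.reserves = params.init_reserves
    for r in range(params.init_phytomers):
        ph = _make_phytomer(plant, main, r, ambient_rfr)
        ph.leaf.grown_mass = params.init_leaf_mass
        main.phytomers.append(ph)
    return plant


def _make_phytomer(plant: Plant, axis: Axis, rank: int, ambient_rfr: float) -> Phytomer:
    p = plant.params
    rng = plant.rng or np.random.default_rng(0)
    ph = Phytomer(rank=rank, tip_rfr=ambient_rfr)
    ph.leaf.angle = p.leaf_angle
    ph.leaf.lw_ratio = p.lw_ratio
    leaf_base = max(1e-4, float(rng.normal(p.leaf_len_mean, p.leaf_len_sd)))
    int_base = max(1e-4, float(rng.normal(p.int_len_mean, p.int_len_sd)))
    if axis.index != 0:
        leaf_base *= p.branch_leaf_factor
        int_base *= p.branch_int_factor
    ph.leaf.base_len = leaf_base
    pot = leaf_base
    if plant.systemic_latched:
        pot *= p.leaf_red_factor
    ph.leaf.pot_length = pot
    ph.internode.radius = p.r0
    ph.internode.base_len = int_base
    ph.internode.pot_length = int_base
    return ph


# ---------------------------------------------------------------------------
# operations


def produce_phytomers(plant: Plant, dgdd: float, ambient_rfr: float = 1.2) -> None:
    """Advance every active axis by dgdd of thermal time.

    One phytomer appears per full phyllochron; when an axis reaches its
    (possibly R:FR-advanced) phytomer target its apex flowers and an
    aggregate seed sink is appended.  Flowering is irreversible.
    """
    p = plant.params
    for axis in plant.axes:
        if axis.aborted or axis.flowering:
            continue
        axis.progress += dgdd
        target = plant.target_n if axis.index == 0 else axis.target_n
        while axis.progress >= p.phyllochron and len(axis.phytomers) < target:
            axis.progress -= p.phyllochron
            axis.phytomers.append(
                _make_phytomer(plant, axis, len(axis.phytomers), ambient_rfr))
        if len(axis.phytomers) >= target:
            _flower(plant, axis)


def _flower(plant: Plant, axis: Axis) -> None:
    p = plant.params
    axis.apical = "flowering"
    lma = p.lma
    # sink capacity follows the axis's assimilate status at flowering: its
    # undamaged grown leaf area weighted by each leaf's relative irradiance.
    # Herbivore damage therefore acts on yield through the carbon budget
    # (and light competition), not by amputating the sink itself.
    area = sum(ph.leaf.grown_area(lma) * min(1.0, max(0.0, ph.leaf.rel_light))
               for ph in axis.phytomers if not ph.leaf.senesced)
    axis.seed = SeedSink(start_gdd=plant.age_gdd, wmax=p.k_seed * area)


def update_branching(plant: Plant, surplus: float, ambient_rfr: float = 1.2) -> None:
    """Break or abort axillary meristems on the main stem.

    A dormant meristem breaks into a branch when (the main apex is flowering
    OR the meristem has outgrown apical dominance) AND there was an
    assimilate surplus AND the local R:FR is at or above the abortion
    threshold.  An immature branch aborts when its R:FR signal drops below
    the threshold, or one immature branch per day aborts while the reserve
    pool has been empty for ``n_starve`` consecutive days.  Abortion is
    terminal.
    """
    p = plant.params
    main = plant.main
    # --- initiation: buds break one at a time (acropetal order), so a single
    # favourable day does not commit the whole bud bank at once
    breaks_left = p.breaks_per_day
    for ph in main.phytomers:
        if breaks_left <= 0:
            break
        mer = ph.meristem
        if mer.state != "dormant":
            continue
        if ph.rank < p.basal_dormant_ranks or ph.leaf.senesced:
            continue
        target = int((plant.target_n - (ph.rank + 1)) * p.branch_target_factor)
        if target < 1:
            continue  # too close to the apex to support a branch
        released = main.flowering or ph.age >= p.dominance_age
        # before flowering, outgrowth additionally needs favourable carbon;
        # afterwards apical dominance is gone and R:FR/starvation abortion
        # regulate the branch complement
        favourable = (main.flowering or surplus > 0
                      or plant.last_satisfaction >= p.break_satisfaction)
        if released and favourable and ph.tip_rfr >= p.rfr_abort:
            mer.state = "branch"
            mer.branch_axis = len(plant.axes)
            leaf_az = main.azimuth + GOLDEN_ANGLE * ph.rank
            branch = Axis(index=len(plant.axes), parent_axis=0,
                          parent_rank=ph.rank, azimuth=leaf_az % 360.0,
                          target_n=target, created_gdd=plant.age_gdd)
            plant.axes.append(branch)
            breaks_left -= 1
    # --- abortion by sustained deep shade
    for axis in plant.axes[1:]:
        if axis.aborted or not _immature(plant, axis):
            continue
        rfr = _branch_signal(plant, axis)
        if rfr < p.rfr_abort:
            axis.low_rfr_days += 1
            if axis.low_rfr_days >= p.abort_days:
                _abort(plant, axis)
        else:
            axis.low_rfr_days = 0
    # --- abortion by starvation: youngest immature branch per starved day
    if plant.starve_days >= p.n_starve:
        candidates = [a for a in plant.axes[1:]
                      if not a.aborted and _immature(plant, a)]
        if candidates:
            _abort(plant, max(candidates, key=lambda a: a.created_gdd))
            plant.starve_days = 0  # one abortion per starvation window


def _immature(plant: Plant, axis: Axis) -> bool:
    p = plant.params
    return (not axis.flowering
            and plant.age_gdd - axis.created_gdd < p.branch_mature_age)


def _branch_signal(plant: Plant, axis: Axis) -> float:
    """R:FR signal governing a branch: its bearer phytomer's leaf tip.

    The axillary meristem sits in the bearer leaf's axil, so the locally
    sensed signal is the bearer's, not that of the young branch leaves still
    buried inside the canopy."""
    bearer = plant.axes[axis.parent_axis].phytomers[axis.parent_rank]
    return bearer.tip_rfr


def _abort(plant: Plant, axis: Axis) -> None:
    axis.aborted = True
    bearer = plant.axes[axis.parent_axis].phytomers[axis.parent_rank]
    if bearer.meristem.branch_axis == axis.index:
        bearer.meristem.state = "aborted"
    # standing branch tissue senesces into litter
    lma = plant.params.lma
    for ph in axis.phytomers:
        leaf = ph.leaf
        if not leaf.senesced:
            area = leaf.live_area(lma)
            plant.litter_mass += area * lma
            plant.senesced_area += area
            leaf.senesced = True


def senesce_leaves(plant: Plant) -> None:
    """Age- and light-triggered leaf senescence (monotone)."""
    p = plant.params
    lma = p.lma
    for ax, ph in plant.phytomer_iter():
        leaf = ph.leaf
        if leaf.senesced:
            continue
        if leaf.rel_light < p.senes_light:
            leaf.low_light_days += 1
        else:
            leaf.low_light_days = 0
        if ph.age > p.senes_age or (ph.age > p.senes_min_age
                                    and leaf.low_light_days >= p.senes_light_days):
            area = leaf.live_area(lma)
            plant.litter_mass += area * lma
            plant.senesced_area += area
            leaf.senesced = True


def pipe_model(plant: Plant) -> None:
    """Leaf-to-base pass setting internode radii by cross-section additivity.

    Terminal internodes carry the initial cross-section pi*r0^2; every other
    internode's cross-section is the sum of its daughters' (the next
    internode on the same axis, or the apex, plus the base of any branch it
    subtends).  Radii never shrink between days.
    """
    p = plant.params
    a0 = math.pi * p.r0 ** 2
    areas: dict[tuple[int, int], float] = {}

    def axis_base_area(axis: Axis) -> float:
        if not axis.phytomers:
            return a0
        return _area(axis, 0)

    def _area(axis: Axis, i: int) -> float:
        key = (axis.index, i)
        if key in areas:
            return areas[key]
        n = len(axis.phytomers)
        above = _area(axis, i + 1) if i + 1 < n else a0
        total = above
        ph = axis.phytomers[i]
        if ph.meristem.state in ("branch", "aborted") and ph.meristem.branch_axis >= 0:
            total += axis_base_area(plant.axes[ph.meristem.branch_axis])
        areas[key] = total
        return total

    for axis in plant.axes:
        if any(True for _ in axis.phytomers):
            _area(axis, 0)
    for axis in plant.axes:
        for i, ph in enumerate(axis.phytomers):
            r = math.sqrt(areas[(axis.index, i)] / math.pi)
            if r > ph.internode.radius:
                ph.internode.radius = r
    # unit-pipe counts: phytomers supported by each internode (self + distal
    # on the axis + any subtended branch subtree); drives the stem mass sink
    counts: dict[tuple[int, int], int] = {}

    def axis_count(axis: Axis) -> int:
        return _count(axis, 0) if axis.phytomers else 0

    def _count(axis: Axis, i: int) -> int:
        key = (axis.index, i)
        if key in counts:
            return counts[key]
        n = len(axis.phytomers)
        total = 1 + (_count(axis, i + 1) if i + 1 < n else 0)
        ph = axis.phytomers[i]
        if ph.meristem.branch_axis >= 0:
            total += axis_count(plant.axes[ph.meristem.branch_axis])
        counts[key] = total
        return total

    for axis in plant.axes:
        for i, ph in enumerate(axis.phytomers):
            ph.internode.n_distal = _count(axis, i)


# ---------------------------------------------------------------------------
# geometry helpers (used by the scene builder)


def axis_direction(plant: Plant, axis: Axis) -> np.ndarray:
    if axis.index == 0:
        return np.array([0.0, 0.0, 1.0])
    p = plant.params
    b = math.radians(p.branch_angle)
    az = math.radians(axis.azimuth)
    return np.array([math.sin(b) * math.cos(az),
                     math.sin(b) * math.sin(az),
                     math.cos(b)])


def axis_node_positions(plant: Plant, axis: Axis, origin: np.ndarray) -> np.ndarray:
    """Positions of the node above each internode, from the axis origin."""
    wd = plant.params.wood_density
    d = axis_direction(plant, axis)
    lengths = np.array([ph.internode.length(wd) for ph in axis.phytomers])
    if len(lengths) == 0:
        return np.zeros((0, 3))
    return origin[None, :] + np.cumsum(lengths)[:, None] * d[None, :]
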