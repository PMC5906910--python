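"""The daily simulation loop wiring all submodels together.

Fixed within-day order: (1) weather and thermal time; (2) scene assembly on
the morning structure; (3) PAR tracing and tip R:FR sensing; (4) shade-
avoidance modifiers; (5) herbivore steps (leaf areas shrink before carbon
gain is computed); (6) photosynthesis on the post-herbivory areas; (7)
maintenance, sink registration, allocation and organ growth; (8)
architectural development (phytomer production, branching, senescence, pipe
model).  Three independent RNG streams (plant draws, light, herbivores) make
runs bit-reproducible under a seed triple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import architecture as arch
from . import physiology as phys
from .environment import (ThermalClock, WeatherSeries, daily_sources,
                          daylength_hours, default_weather, thermal_time)
from .herbivory import Herbivore, infest, step_herbivore
from .light import build_grid, sense_rfr, trace
from .params import (HerbivoreParameters, LightParameters, PlantParameters,
                     WeatherParameters)
from .scene import KIND_LEAF, assemble_scene_fast, layout_plot
from .shade import local_modifiers, shade_fraction, systemic_signal


@dataclass
class Treatment:
    """Herbivore treatment of one run."""

    pattern: str = "none"            # none|homogeneous|heterogeneous|alternating
    n_per_plant: int = 0
    h: float = 0.8                   # type used by homogeneous/heterogeneous
    h_old: float = 0.2
    h_young: float = 0.8
    intro_gdd: float = 230.0


@dataclass
class RunConfig:
    density: float = 1.0             # plants m-2
    n_plants: int = 4                # perfect square
    duration_days: int = 124
    seed_plants: int = 1
    seed_light: int = 2
    seed_herbivores: int = 3
    plant: PlantParameters = field(default_factory=PlantParameters)
    herbivore: HerbivoreParameters = field(default_factory=HerbivoreParameters)
    light: LightParameters = field(default_factory=LightParameters)
    weather_params: WeatherParameters = field(default_factory=WeatherParameters)
    weather: WeatherSeries | None = None
    treatment: Treatment = field(default_factory=Treatment)

    def seeds(self) -> dict:
        return {"plants": self.seed_plants, "light": self.seed_light,
                "herbivores": self.seed_herbivores}


@dataclass
class RunResult:
    plants: pd.DataFrame             # one row per plant at the final day
    daily: pd.DataFrame              # one row per day
    leaf_profile: pd.DataFrame       # main-stem leaf length by rank per plant
    config: RunConfig
    herbivores: pd.DataFrame | None = None


@dataclass
class SimState:
    config: RunConfig
    weather: WeatherSeries
    clock: ThermalClock
    plants: list
    period: float
    grid_side: int
    day: int = 0
    herbivores: list = field(default_factory=list)
    infested: bool = False
    rng_light: np.random.Generator = None
    rng_herb: np.random.Generator = None
    daily_records: list = field(default_factory=list)


def init_state(config: RunConfig) -> SimState:
    wp = config.weather_params
    weather = config.weather or default_weather(
        config.duration_days, wp, config.light.ambient_rfr)
    if len(weather) < config.duration_days:
        raise ValueError("weather series shorter than the simulation")
    clock = thermal_time(weather, wp.base_temp)
    positions, period = layout_plot(config.density, config.n_plants)
    rng_plants = np.random.default_rng(config.seed_plants)
    plants = [arch.new_plant(i, positions[i], config.plant, rng_plants,
                             config.light.ambient_rfr)
              for i in range(config.n_plants)]
    return SimState(
        config=config, weather=weather, clock=clock, plants=plants,
        period=period, grid_side=int(round(math.sqrt(config.n_plants))),
        rng_light=np.random.default_rng(config.seed_light),
        rng_herb=np.random.default_rng(config.seed_herbivores))


def step_day(state: SimState) -> None:
    cfg = state.config
    p = cfg.plant
    lp = cfg.light
    d = state.day
    temp = float(state.weather.mean_temp[d])
    insol = float(state.weather.insolation[d])
    doy = int(state.weather.day_of_year[d])
    dgdd = float(state.clock.daily_increment[d])
    ambient = state.weather.ambient_rfr

    # (2-3) light on the morning structure
    scene = assemble_scene_fast(state.plants, state.period, lp)
    organ_by_leaf = {}
    has_leaves = scene.leaf_area() > 0
    if has_leaves and insol > 0:
        sources = daily_sources(insol, doy, cfg.weather_params.latitude,
                                lp.n_direct, lp.n_diffuse,
                                lp.diffuse_fraction, ambient, lp.sky_model)
        grid = build_grid(scene)
        light_seed = int(state.rng_light.integers(0, 2**31 - 1))
        # boost the ray budget while the canopy is sparse so every leaf
        # receives an adequate expected hit count
        boost = min(64.0, max(1.0, 0.03 * state.period ** 2 / scene.leaf_area()))
        n_day = int(lp.n_rays * boost)
        res = trace(scene, sources, n_day, light_seed, lp.max_bounces,
                    grid=grid)
        full_abs0 = insol * (1.0 - lp.par_rho - lp.par_tau)
        organ_rel = np.clip(res.absorbed_par / full_abs0, 0.0, 1.0) \
            if full_abs0 > 0 else np.zeros(scene.n_organs)
        tips = sense_rfr(scene, sources, ambient, grid=grid,
                         organ_rel=organ_rel, n_reflect=lp.n_reflect,
                         reflect_gain=lp.reflect_gain)
        tip_by_organ = dict(zip(scene.sensor_organ.tolist(), tips.tolist()))
        full_abs = insol * (1.0 - lp.par_rho - lp.par_tau)
        plants_by_id = {pl.id: pl for pl in state.plants}
        for organ, ref in enumerate(scene.organ_refs):
            if ref[3] != KIND_LEAF:
                continue
            pl = plants_by_id[ref[0]]
            ph = pl.axes[ref[1]].phytomers[ref[2]]
            ph.leaf.abs_par = float(res.absorbed_par[organ])
            today = min(1.0, ph.leaf.abs_par / full_abs) if full_abs > 0 else 0.0
            w = p.rel_light_ema
            ph.leaf.rel_light = (1.0 - w) * ph.leaf.rel_light + w * today
            if organ in tip_by_organ:
                we = p.rfr_ema
                ph.tip_rfr = (1.0 - we) * ph.tip_rfr + we * tip_by_organ[organ]
    else:
        for pl in state.plants:
            for _, ph in pl.phytomer_iter():
                ph.leaf.abs_par = 0.0

    # (4) shade-avoidance modifiers on still-growing organs
    for pl in state.plants:
        if not pl.systemic_latched:
            # signals weighted by sunlit (undamaged) leaf area: exposed
            # leaves dominate the systemic integration, so neither an
            # isolated plant's self-shaded interior nor herbivore bite marks
            # on top leaves can trigger the crowding switch
            pairs = [(ph.leaf.grown_area(p.lma)
                      * min(1.0, max(0.0, ph.leaf.rel_light)), ph.tip_rfr)
                     for ph in pl.main.phytomers
                     if not ph.leaf.senesced and ph.leaf.grown_mass > 0]
            tot = sum(a for a, _ in pairs)
            if pairs and tot > 0:
                mean_rfr = sum(a * r for a, r in pairs) / tot
                if mean_rfr < p.rfr_flower_threshold:
                    pl.systemic_latched = True
        latch = p.leaf_red_factor if pl.systemic_latched else 1.0
        lma, ks = p.lma, p.k_shape
        for ax, ph in pl.phytomer_iter(live_only=True):
            S = shade_fraction(max(ph.tip_rfr, 1e-6), p)
            mods = local_modifiers(S, p)
            leaf = ph.leaf
            if not leaf.senesced and ph.age < p.leaf_te:
                leaf.lw_ratio = mods.lw_ratio
                leaf.angle = mods.leaf_angle
                len_mult = mods.leaf_len_mult if p.leaf_len_local else 1.0
                leaf.pot_length = leaf.base_len * len_mult * latch
                # integrate the day's potential growth at today's phenotype
                dfrac = phys.beta_increment(ph.age, dgdd, p.leaf_te,
                                            p.leaf_tm, 1.0)
                leaf.wmax_acc += dfrac * lma * ks \
                    * leaf.pot_length ** 2 / leaf.lw_ratio
            inter = ph.internode
            if ph.age < p.int_te:
                inter.pot_length = min(p.int_len_max,
                                       inter.base_len * mods.internode_len_mult)
                dfrac = phys.beta_increment(ph.age, dgdd, p.int_te,
                                            p.int_tm, 1.0)
                inter.len_acc += dfrac * inter.pot_length
                a_vasc = (math.pi * p.r0 ** 2
                          * max(1.0, p.vasc_frac * inter.n_distal))
                inter.potmass_acc += dfrac * p.wood_density \
                    * a_vasc * inter.pot_length

    # (5) herbivores
    if (not state.infested and cfg.treatment.pattern != "none"
            and cfg.treatment.n_per_plant > 0
            and state.clock.cumulative_gdd[d] >= cfg.treatment.intro_gdd):
        base = replace(cfg.herbivore, h=cfg.treatment.h)
        state.herbivores = infest(
            state.plants, cfg.treatment.pattern, cfg.treatment.n_per_plant,
            state.grid_side, state.rng_herb, cfg.treatment.h_old,
            cfg.treatment.h_young, base_params=base,
            homogeneous_h=cfg.treatment.h)
        state.infested = True
    if state.herbivores and dgdd > 0:
        plants_by_id = {pl.id: pl for pl in state.plants}
        for herb in state.herbivores:
            if herb.state == "feeding":
                step_herbivore(herb, plants_by_id[herb.host_plant], dgdd,
                               state.rng_herb)

    # (6-7) carbon: photosynthesis, maintenance, allocation, growth
    photoperiod = daylength_hours(cfg.weather_params.latitude, doy) * 3600.0
    for pl in state.plants:
        lma, ks = p.lma, p.k_shape
        assim = 0.0
        for ax, ph in pl.phytomer_iter(live_only=True):
            leaf = ph.leaf
            area = leaf.live_area(lma)
            if area <= 0 or leaf.senesced:
                continue
            assim += area * phys.leaf_photosynthesis(
                leaf.abs_par, leaf.rel_light, photoperiod,
                p.amax_base, p.alpha, p.q_accl, p.f_min)
        pl.carbon.assimilates_today = assim
        maint = phys.maintenance_cost(pl.standing_mass(), temp, p.m_coef, p.q10)
        sinks = []
        for ax in pl.live_axes():
            for ph in ax.phytomers:
                leaf = ph.leaf
                if not leaf.senesced and ph.age < p.leaf_te:
                    # demand is the backlog to the accumulated potential; it
                    # closes with the growth window (determinate growth)
                    pg = max(0.0, leaf.wmax_acc - leaf.grown_mass)
                    if pg > 0:
                        sinks.append(phys.SinkRecord(("leaf", ax.index, ph.rank),
                                                     pg, pg * p.grf))
                inter = ph.internode
                pg = max(0.0, inter.potmass_acc - inter.mass)
                if pg > 0:
                    sinks.append(phys.SinkRecord(("internode", ax.index, ph.rank),
                                                 pg, pg * p.grf))
            if ax.seed is not None:
                t_seed = pl.age_gdd - ax.seed.start_gdd
                target = ax.seed.wmax * phys.beta_mass(
                    min(t_seed + dgdd, p.seed_te), p.seed_te, p.seed_tm, 1.0)
                pg = max(0.0, target - ax.seed.mass)
                if pg > 0:
                    sinks.append(phys.SinkRecord(("seed", ax.index, -1),
                                                 pg, pg * p.grf))
        reserves_before = pl.carbon.reserves
        result = phys.allocate(pl.carbon, sinks, maint, p.grf)
        granted = 0.0
        for sink, g in zip(sinks, result.growth):
            kind, ax_i, rank = sink.organ_ref
            axis = pl.axes[ax_i]
            if kind == "leaf":
                axis.phytomers[rank].leaf.grown_mass += g
            elif kind == "internode":
                inter = axis.phytomers[rank].internode
                inter.mass += g
                inter.extend(p.wood_density, p.r0, p.vasc_frac)
            else:
                axis.seed.mass += g
            granted += g
        # daily carbon bookkeeping identity (abort on violation)
        balance = (assim + reserves_before - result.maintenance_paid
                   - granted * p.grf - pl.carbon.reserves)
        if abs(balance) > 1e-8 * max(1.0, assim + reserves_before):
            raise RuntimeError(
                f"carbon conservation violated on day {d} plant {pl.id}: "
                f"residual {balance:.3e}")
        if pl.carbon.reserves <= 1e-12 and result.surplus <= 0:
            pl.starve_days += 1
        else:
            pl.starve_days = 0
        pl.last_surplus = result.surplus
        pl.last_satisfaction = result.satisfaction

    # (8) architecture
    for pl in state.plants:
        pl.age_gdd += dgdd
        for _, ph in pl.phytomer_iter():
            ph.age += dgdd
        arch.produce_phytomers(pl, dgdd, ambient)
        arch.update_branching(pl, pl.last_surplus, ambient)
        arch.senesce_leaves(pl)
        arch.pipe_model(pl)

    # daily record
    lai = sum(pl.leaf_area() for pl in state.plants) / state.period ** 2
    live_tips = [ph.tip_rfr for pl in state.plants
                 for _, ph in pl.phytomer_iter(live_only=True)
                 if not ph.leaf.senesced and ph.leaf.grown_mass > 0]
    state.daily_records.append({
        "day": d + 1,
        "gdd": float(state.clock.cumulative_gdd[d]),
        "lai": lai,
        "mean_tip_rfr": float(np.mean(live_tips)) if live_tips else ambient,
        "assimilation": sum(pl.carbon.cumulative_assimilation
                            for pl in state.plants),
    })
    state.day += 1


def run(config: RunConfig) -> RunResult:
    """Run one plot for the configured duration and collect the outputs."""
    state = init_state(config)
    for _ in range(config.duration_days):
        step_day(state)
    return collect_results(state)


def collect_results(state: SimState) -> RunResult:
    cfg = state.config
    lma = cfg.plant.lma
    ks = cfg.plant.k_shape
    h_class = _plant_classes(state)
    rows = []
    profile = []
    for pl in state.plants:
        rows.append({
            "plant": pl.id,
            "class": h_class[pl.id],
            "biomass": pl.biomass(),
            "yield": pl.seed_yield(),
            "height": pl.height(),
            "branches": pl.branch_count(),
            "leaf_area": pl.leaf_area(),
            "damage": sum(ph.leaf.consumed_area
                          for _, ph in pl.phytomer_iter()),
            "n_phytomers": len(pl.main.phytomers),
            "eaten_mass": pl.eaten_mass,
            "litter_mass": pl.litter_mass,
        })
        for ph in pl.main.phytomers:
            profile.append({"plant": pl.id, "rank": ph.rank + 1,
                            "leaf_length": ph.leaf.length(lma, ks)})
    herb_rows = None
    if state.herbivores:
        herb_rows = pd.DataFrame([{
            "id": h.id, "plant": h.host_plant, "h": h.params.h,
            "weight": h.weight, "cum_area": h.cum_area, "age": h.age,
            "instar": h.instar, "state": h.state, "cause": h.pupation_cause,
        } for h in state.herbivores])
    return RunResult(pd.DataFrame(rows), pd.DataFrame(state.daily_records),
                     pd.DataFrame(profile), cfg, herb_rows)


def _plant_classes(state: SimState) -> dict:
    """Label plants by their herbivore treatment class."""
    cfg = state.config
    t = cfg.treatment
    out = {}
    for k, pl in enumerate(state.plants):
        row, col = divmod(k, state.grid_side)
        parity = (row + col) % 2
        if t.pattern == "none" or t.n_per_plant == 0:
            out[pl.id] = "clean"
        elif t.pattern == "homogeneous":
            out[pl.id] = _h_label(t.h)
        elif t.pattern == "heterogeneous":
            out[pl.id] = _h_label(t.h) if parity == 0 else "clean"
        else:
            out[pl.id] = _h_label(t.h_young) if parity == 0 else _h_label(t.h_old)
    return out


def _h_label(h: float) -> str:
    return "young-feeder" if h > 0.5 else "old-feeder"
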