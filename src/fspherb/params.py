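"""Parameter sets for the plant, the herbivores, the light model and the weather.

The plant and herbivore tables hold the measured/optimized field values for
*Brassica nigra* and *Pieris rapae*; everything else is a declared model
default that can be overridden through the run configuration.  Values given
"(in parentheses)" in the field study are the high-density phenotype and are
engaged through the red:far-red (R:FR) response machinery, never by a
hard-coded density switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass
class PlantParameters:
    """Architectural, developmental and growth parameters of one plant.

    Thermal-time quantities are in growing degree days (gdd), lengths in
    metres, masses in grams.
    """

    # -- measured architectural/developmental values -------------------------
    leaf_te: float = 234.0        # gdd, leaf growth period (end of expansion)
    leaf_tm: float = 167.0        # gdd, age of maximal leaf growth rate
    lw_ratio: float = 1.756       # leaf length/width ratio, open-grown
    lw_ratio_high: float = 2.5    # idem, high-density (shade) phenotype
    lma: float = 65.8             # g m-2, leaf mass per unit area
    int_te: float = 258.0         # gdd, internode growth period
    int_tm: float = 216.0         # gdd, age of maximal internode growth rate
    r0: float = 0.0008            # m, initial internode radius
    wood_density: float = 176142.0  # g m-3, internode tissue density
    phyllochron: float = 12.0     # gdd between successive leaf appearances
    n_phytomers_mean: float = 29.0  # main-stem phytomer number, open-grown
    n_phytomers_sd: float = 5.0
    n_phytomers_high_mean: float = 27.0  # idem, shade phenotype
    n_phytomers_high_sd: float = 1.0
    branch_angle: float = 40.0    # degrees from vertical
    leaf_angle: float = 70.0      # degrees from vertical (spreading leaves)
    leaf_angle_high: float = 15.0  # degrees from vertical (erect, shade)
    amax_base: float = 30.0       # umol m-2 s-1, base photosynthetic capacity

    # -- optimized growth/response values ------------------------------------
    leaf_len_mean: float = 0.285  # m, potential leaf length (per-plant draw)
    leaf_len_sd: float = 0.026
    leaf_red_factor: float = 0.55  # systemic potential-leaf-length reduction
    int_len_mean: float = 0.045   # m, potential internode length (draw)
    int_len_sd: float = 0.01
    int_elong_factor: float = 3.5  # max internode elongation under low R:FR
    int_len_max: float = 0.050    # m, mechanical cap on internode length
    vasc_frac: float = 0.5        # unit-pipe vascular cross-section per
    #   distal phytomer, as a multiple of pi*r0^2 (stem mass sink)
    leaf_len_local: bool = False  # if True the dose-response also shortens
    #   leaf potential length locally; default is systemic-only reduction
    rfr_mid: float = 0.85         # midpoint of the R:FR dose-response
    rfr_steep: float = 30.0       # steepness of the R:FR dose-response
    rfr_abort: float = 0.65       # R:FR threshold for branch abortion

    # -- declared model defaults (config-exposed calibration knobs) ----------
    branch_target_factor: float = 0.55  # branch phytomer target as a
    #   fraction of (main target - bearing rank), acropetal decline
    branch_leaf_factor: float = 0.68    # potential leaf length on branches
    branch_int_factor: float = 0.6      # potential internode length on branches
    dominance_age: float = 60.0   # gdd before an axillary meristem escapes
    #   apical dominance on a still-vegetative main stem
    basal_dormant_ranks: int = 3  # basal main-stem axils that never branch
    breaks_per_day: int = 1       # axillary buds breaking per plant per day
    break_satisfaction: float = 0.35 # sink-satisfaction ratio counted as
    #   'favourable conditions' for bud break when there is no strict surplus
    abort_days: int = 5           # consecutive days below rfr_abort that
    #   abort an immature branch (persistence filters sensing noise)
    rfr_ema: float = 0.5          # new-sample weight of the smoothed tip R:FR
    ped_max: float = 0.20         # m, maximum raceme (peduncle) length
    ped_half: float = 1.0         # g main-axis seed mass at half raceme length
    n_starve: int = 5             # consecutive reserve-depleted days that
    #   trigger abortion of an immature branch
    senes_age: float = 720.0      # gdd, leaf senescence age
    senes_light: float = 0.02     # relative irradiance below which a leaf
    senes_light_days: int = 8     # ... for this many days senesces
    senes_min_age: float = 100.0  # gdd before light-triggered senescence
    rel_light_ema: float = 0.4    # new-sample weight of the smoothed
    #   relative-irradiance signal (tames Monte-Carlo noise on small leaves)
    rfr_flower_threshold: float = 0.8  # systemic threshold switching the
    #   main-stem phytomer target and potential leaf length
    k_shape: float = 0.7          # leaf blade area / (length x width)
    grf: float = 1.39             # g CH2O per g structural growth
    m_coef: float = 0.035         # g g-1 d-1 maintenance at 20 degC
    q10: float = 2.0
    alpha: float = 0.018          # umol CO2 per umol absorbed photons
    q_accl: float = 0.5           # exponent of Amax light acclimation
    f_min: float = 0.1            # floor of the acclimation factor
    k_seed: float = 108.0         # g seed sink capacity per m2 of axis leaf
    #   area at flowering (yield calibration knob)
    seed_te: float = 500.0        # gdd, seed-fill period per inflorescence
    seed_tm: float = 300.0
    seed_mass_per_seed: float = 0.002  # g, report-only mean seed weight divisor
    init_reserves: float = 0.2    # g CH2O in the transplanted seedling
    init_phytomers: int = 3       # phytomers present at the start
    init_leaf_mass: float = 0.01   # g per initial leaf
    branch_mature_age: float = 100.0  # gdd below which a branch can abort
    second_order_branching: bool = False

    def __post_init__(self) -> None:
        for name in ("leaf_te", "leaf_tm", "int_te", "int_tm", "lma", "r0",
                     "wood_density", "phyllochron", "lw_ratio", "grf",
                     "k_shape", "leaf_len_mean", "int_len_mean"):
            _positive(name, getattr(self, name))
        if not self.leaf_te > self.leaf_tm:
            raise ValueError("leaf_te must exceed leaf_tm")
        if not self.int_te > self.int_tm:
            raise ValueError("int_te must exceed int_tm")
        if not 0 < self.leaf_red_factor <= 1:
            raise ValueError("leaf_red_factor must be in (0, 1]")
        if self.int_elong_factor < 1:
            raise ValueError("int_elong_factor must be >= 1")


@dataclass
class HerbivoreParameters:
    """Feeding, growth and development parameters of one caterpillar type.

    Weight gain follows the power law w = a_w * C**b of cumulative consumed
    leaf area C (m2); the feeding rate is a_f * w per gdd.  The leaf-selection
    preference ``h`` spans old-leaf feeders (h < 0.5, generalist-like) to
    young-leaf feeders (h > 0.5, specialist-like).
    """

    a_w: float = 10.61        # g m-2
    b: float = 0.7747         # dimensionless, 0 < b < 1
    a_f: float = 7.68e-4      # m2 g-1 gdd-1
    w0: float = 1.86e-5       # g, initial weight
    w_max: float = 0.178      # g, pupation weight threshold
    lifespan: float = 210.0   # gdd, pupation age threshold
    h: float = 0.5            # feeding preference
    rp_max: float = 1.0       # leaf-selection curve ceiling (only ratios matter)
    substep: float = 0.25     # gdd, internal feeding substep of a daily step
    #   (keeps the explicit integration within 1% of the fine-step oracle)
    s: float = 0.03           # gdd-1, selection curve steepness
    m: float = 150.0          # gdd, selection curve midpoint

    def __post_init__(self) -> None:
        for name in ("a_w", "a_f", "w0", "w_max", "lifespan", "rp_max"):
            _positive(name, getattr(self, name))
        if not 0 < self.b < 1:
            raise ValueError("b must be in (0, 1)")
        if not 0 <= self.h <= 1:
            raise ValueError("h must be in [0, 1]")


@dataclass
class LightParameters:
    """Ray budget, sky discretisation and dual-band optical coefficients."""

    n_rays: int = 4000
    n_direct: int = 8
    n_diffuse: int = 16
    diffuse_fraction: float = 0.5
    sky_model: str = "uniform"      # or "soc" (standard overcast sky)
    ambient_rfr: float = 1.2
    par_rho: float = 0.10
    par_tau: float = 0.05
    red_rho: float = 0.05
    red_tau: float = 0.05
    fr_rho: float = 0.40
    fr_tau: float = 0.40
    n_reflect: int = 16             # probe rays for the scattered R:FR term
    reflect_gain: float = 2.5       # multiple-scattering gain of that term
    max_bounces: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.diffuse_fraction <= 1:
            raise ValueError("diffuse_fraction must be in [0, 1]")
        for pre in ("par", "red", "fr"):
            rho = getattr(self, f"{pre}_rho")
            tau = getattr(self, f"{pre}_tau")
            if rho < 0 or tau < 0 or rho + tau > 1:
                raise ValueError(f"{pre} optics need rho,tau >= 0, rho+tau <= 1")
        if self.ambient_rfr <= 0:
            raise ValueError("ambient_rfr must be > 0")


@dataclass
class WeatherParameters:
    """Synthetic Netherlands weather: sinusoidal temperature and insolation.

    The defaults accumulate ~236 gdd over the 60 days following 31 March
    (day of year 90), anchoring herbivore introduction at 230 gdd ~ day 60.
    """

    base_temp: float = 7.0        # degC, thermal-time base
    temp_mean: float = 9.5        # degC, annual mean
    temp_amp: float = 7.5         # degC, annual amplitude
    temp_peak_doy: int = 199      # warmest day of year
    insol_peak: float = 45.0      # mol PAR m-2 d-1 at midsummer
    insol_min: float = 3.0        # mol PAR m-2 d-1 at midwinter
    insol_peak_doy: int = 172     # sunniest day of year
    start_doy: int = 90           # 31 March (non-leap year)
    latitude: float = 52.0        # degrees north


def params_to_dict(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in fields(obj)}
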