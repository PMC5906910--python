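"""Carbon physiology: photosynthesis, the central pool, sinks and growth.

All organs draw from one central carbon pool with no allocation hierarchy:
each day every growing organ registers a demand equal to its potential
beta-function growth increment times the growth-respiration factor, and the
pool is divided in proportion to demand when it cannot satisfy everything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

# grams of CH2O per umol of CO2 fixed
_G_PER_UMOL = 30.0e-6


@dataclass
class CarbonPool:
    """Daily assimilate bookkeeping of one plant (g CH2O)."""

    assimilates_today: float = 0.0
    reserves: float = 0.0
    litter: float = 0.0               # g structural mass shed (monotone)
    cumulative_assimilation: float = 0.0
    stress_days: int = 0              # days maintenance could not be paid


@dataclass
class SinkRecord:
    """One organ's demand on the pool for the current day."""

    organ_ref: object
    potential_growth: float   # g structural mass d-1
    demand: float             # g CH2O d-1 (= potential_growth * grf)


@dataclass
class AllocationResult:
    growth: list              # g structural mass granted per sink (same order)
    surplus: float            # g CH2O left after all demands were met (else 0)
    maintenance_paid: float
    shortfall: bool           # True when maintenance could not be fully paid
    satisfaction: float = 1.0  # available / summed demand, capped at 1


def beta_mass(t: float, te: float, tm: float, wmax: float) -> float:
    """Determinate sigmoid growth: expected organ mass at thermal age t.

    w(t) = wmax * (1 + (te - t)/(te - tm)) * (t/te)^(te/(te-tm)) for t <= te,
    and wmax thereafter.  te is the growth duration, tm the age of maximal
    growth rate (0 < tm < te), both in gdd.
    """
    if te <= tm or tm <= 0:
        raise ValueError("need te > tm > 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    if t >= te:
        return wmax
    if t == 0:
        return 0.0
    return wmax * (1.0 + (te - t) / (te - tm)) * (t / te) ** (te / (te - tm))


def beta_increment(t: float, dt: float, te: float, tm: float, wmax: float) -> float:
    """Potential growth over one thermal step [t, t+dt]."""
    return max(0.0, beta_mass(min(t + dt, te), te, tm, wmax) - beta_mass(min(t, te), te, tm, wmax))


def leaf_photosynthesis(absorbed_par: float, rel_light: float, photoperiod: float,
                        amax_base: float = 30.0, alpha: float = 0.05,
                        q: float = 0.5, f_min: float = 0.2) -> float:
    """Daily gross assimilation per unit leaf area (g CH2O m-2 leaf d-1).

    ``absorbed_par`` is mol photons m-2 leaf d-1; ``rel_light`` the leaf's
    mean absorbed irradiance relative to a fully exposed leaf, which
    acclimates photosynthetic capacity as Amax = amax_base * clamp^q;
    ``photoperiod`` in seconds.  The light response is the saturating
    exponential A = Amax (1 - exp(-alpha I / Amax)).
    """
    if absorbed_par <= 0 or photoperiod <= 0:
        return 0.0
    amax = amax_base * min(1.0, max(f_min, rel_light)) ** q
    if amax <= 0:
        return 0.0
    i_flux = absorbed_par * 1e6 / photoperiod      # umol m-2 s-1 mean
    a = amax * (1.0 - math.exp(-alpha * i_flux / amax))
    return a * photoperiod * _G_PER_UMOL


def maintenance_cost(live_mass: float, mean_temp: float,
                     m_coef: float = 0.015, q10: float = 2.0) -> float:
    """Temperature-adjusted maintenance respiration (g CH2O d-1)."""
    if live_mass <= 0:
        return 0.0
    return m_coef * live_mass * q10 ** ((mean_temp - 20.0) / 10.0)


def allocate(pool: CarbonPool, sinks: list[SinkRecord], maintenance: float,
             grf: float = 1.39) -> AllocationResult:
    """Divide today's assimilates (plus reserves) over the registered sinks.

    Maintenance is paid first (reserves drain before a shortfall is recorded
    as a stress day).  If the remainder covers the summed demand, every organ
    realises its potential growth and the surplus is stored; otherwise each
    organ receives its proportional share, converted to structural mass by
    1/grf, and reserves are exhausted.
    """
    for s in sinks:
        if s.demand < 0 or s.potential_growth < 0:
            raise ValueError("sink demands must be >= 0")
    supply = pool.assimilates_today + pool.reserves
    paid = min(maintenance, supply)
    shortfall = paid < maintenance - 1e-12
    if shortfall:
        pool.stress_days += 1
    available = supply - paid
    total_demand = sum(s.demand for s in sinks)
    if available >= total_demand:
        growth = [s.potential_growth for s in sinks]
        surplus = available - total_demand
        pool.reserves = surplus
    else:
        if total_demand > 0:
            growth = [available * s.demand / total_demand / grf for s in sinks]
        else:
            growth = [0.0 for _ in sinks]
        surplus = 0.0
        pool.reserves = 0.0
    pool.cumulative_assimilation += pool.assimilates_today
    pool.assimilates_today = 0.0
    satisfaction = 1.0 if total_demand <= 0 else min(1.0, available / total_demand)
    return AllocationResult(growth, surplus, paid, shortfall, satisfaction)
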