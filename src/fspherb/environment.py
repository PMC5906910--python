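"""Thermal time, daily weather series and the discretised sky.

Light is carried in three bands -- total PAR (mol m-2 ground d-1), plus red
and far-red fluxes in relative units whose ratio equals the ambient incident
R:FR.  Direct sources sit on the solar path for the given latitude and day of
year; diffuse sources tile the upper hemisphere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .params import WeatherParameters


@dataclass
class WeatherSeries:
    """Daily weather over the simulation: parallel per-day arrays."""

    day_of_year: np.ndarray   # int
    mean_temp: np.ndarray     # degC
    insolation: np.ndarray    # mol PAR m-2 ground d-1
    ambient_rfr: float = 1.2

    def __post_init__(self) -> None:
        if len(self.day_of_year) == 0:
            raise ValueError("weather series must be non-empty")
        if np.any(self.insolation < 0):
            raise ValueError("insolation must be >= 0")
        if self.ambient_rfr <= 0:
            raise ValueError("ambient_rfr must be > 0")

    def __len__(self) -> int:
        return len(self.day_of_year)


@dataclass
class ThermalClock:
    """Cumulative growing-degree-day (gdd) bookkeeping for a weather series."""

    base_temp: float
    daily_increment: np.ndarray  # gdd contributed by each day
    cumulative_gdd: np.ndarray   # inclusive cumulative sum


def thermal_time(weather: WeatherSeries, base_temp: float) -> ThermalClock:
    """Accumulate max(0, T - base_temp) over the series."""
    inc = np.maximum(0.0, weather.mean_temp - base_temp)
    return ThermalClock(base_temp, inc, np.cumsum(inc))


def default_weather(duration_days: int,
                    wp: WeatherParameters | None = None,
                    ambient_rfr: float = 1.2) -> WeatherSeries:
    """Sinusoidal Netherlands-like temperature and insolation series."""
    wp = wp or WeatherParameters()
    doy = wp.start_doy + np.arange(duration_days)
    temp = wp.temp_mean + wp.temp_amp * np.cos(
        2 * np.pi * (doy - wp.temp_peak_doy) / 365.0)
    mid = 0.5 * (wp.insol_peak + wp.insol_min)
    amp = 0.5 * (wp.insol_peak - wp.insol_min)
    insol = mid + amp * np.cos(2 * np.pi * (doy - wp.insol_peak_doy) / 365.0)
    return WeatherSeries(doy % 365, temp, np.maximum(insol, 0.0), ambient_rfr)


def read_weather_csv(path, ambient_rfr: float = 1.2) -> WeatherSeries:
    """Load a weather series from CSV columns day_of_year, mean_temp, insolation."""
    import pandas as pd

    df = pd.read_csv(path)
    return WeatherSeries(df["day_of_year"].to_numpy(int),
                         df["mean_temp"].to_numpy(float),
                         df["insolation"].to_numpy(float),
                         ambient_rfr)


# ---------------------------------------------------------------------------
# sky discretisation


@dataclass
class LightSource:
    """One sky sector: direction points from the sky toward the ground."""

    direction: np.ndarray           # unit 3-vector, z component < 0
    band_power: dict                # {"PAR", "red", "far_red"} mol m-2 d-1
    kind: str                       # "direct" | "diffuse"


def solar_declination(day_of_year: int) -> float:
    """Declination in radians (simple cosine form)."""
    return math.radians(-23.44) * math.cos(2 * math.pi * (day_of_year + 10) / 365.0)


def daylength_hours(latitude: float, day_of_year: int) -> float:
    """Astronomical daylength (h) from the sunset hour angle."""
    phi = math.radians(latitude)
    dec = solar_declination(day_of_year)
    x = -math.tan(phi) * math.tan(dec)
    if x >= 1.0:
        return 0.0
    if x <= -1.0:
        return 24.0
    return 24.0 / math.pi * math.acos(x)


def solar_path(latitude: float, day_of_year: int, n_direct: int) -> list[LightSource]:
    """Direct sources at equal daytime intervals along the solar path.

    Relative weights are proportional to sin(solar elevation) and normalised
    to 1; callers scale them by the direct energy for the day.
    """
    if n_direct < 1:
        raise ValueError("n_direct must be >= 1")
    if abs(latitude) > 90:
        raise ValueError("latitude must be within [-90, 90]")
    phi = math.radians(latitude)
    dec = solar_declination(day_of_year)
    dl = daylength_hours(latitude, day_of_year)
    if dl <= 0:
        warnings.warn("polar night: no direct light sources")
        return []
    w0 = math.pi * dl / 24.0  # sunset hour angle (rad)
    # midpoints of n_direct equal daytime intervals
    hours = (np.arange(n_direct) + 0.5) / n_direct * 2 * w0 - w0
    sources = []
    weights = []
    dirs = []
    for w in hours:
        sin_el = math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.cos(w)
        if sin_el <= 0:
            continue
        el = math.asin(sin_el)
        cos_el = math.cos(el)
        # azimuth measured from south, positive to west
        saz = math.cos(dec) * math.sin(w) / cos_el if cos_el > 1e-12 else 0.0
        saz = min(1.0, max(-1.0, saz))
        caz = ((math.sin(phi) * sin_el - math.sin(dec)) / (math.cos(phi) * cos_el)
               if cos_el > 1e-12 else 1.0)
        caz = min(1.0, max(-1.0, caz))
        az = math.atan2(saz, caz)
        # direction of travel of the light: from sun toward the ground
        d = np.array([-cos_el * math.cos(az), -cos_el * math.sin(az), -sin_el])
        dirs.append(d / np.linalg.norm(d))
        weights.append(sin_el)
    if not dirs:
        warnings.warn("sun never rises above the horizon on this day")
        return []
    weights = np.asarray(weights)
    weights = weights / weights.sum()
    for d, w in zip(dirs, weights):
        sources.append(LightSource(d, {"PAR": w, "red": 0.0, "far_red": 0.0},
                                   "direct"))
    return sources


def sky_dome(n_diffuse: int, diffuse_fraction: float, insolation: float,
             model: str = "uniform") -> list[LightSource]:
    """Diffuse sources stratified over the upper hemisphere.

    Directions are placed on rings of equal solid angle; weights follow a
    uniform-luminance sky or the standard overcast sky (``model="soc"``),
    summing to ``diffuse_fraction * insolation``.
    """
    if not 0 <= diffuse_fraction <= 1:
        raise ValueError("diffuse_fraction must be within [0, 1]")
    if diffuse_fraction == 0 or insolation == 0:
        return []
    if n_diffuse < 6:
        raise ValueError("n_diffuse must be >= 6")
    # rings of equal solid angle: 3 elevation bands with counts prop. to area
    n_rings = 3
    ring_counts = np.full(n_rings, n_diffuse // n_rings)
    ring_counts[: n_diffuse % n_rings] += 1
    sources = []
    dirs = []
    lum = []
    mu_edges = np.linspace(0, 1, n_rings + 1)  # cos(zenith) band edges
    for r in range(n_rings):
        mu = 0.5 * (mu_edges[r] + mu_edges[r + 1])  # cos zenith of ring
        sin_z = math.sqrt(max(0.0, 1 - mu * mu))
        n_r = int(ring_counts[r])
        for k in range(n_r):
            az = 2 * math.pi * (k + 0.5 * (r % 2)) / n_r
            d = np.array([-sin_z * math.cos(az), -sin_z * math.sin(az), -mu])
            dirs.append(d)
            if model == "soc":
                lum.append(mu * (1 + 2 * mu) / 3.0)   # SOC radiance x cos factor
            else:
                lum.append(mu)                         # uniform radiance
    lum = np.asarray(lum)
    w = lum / lum.sum() * diffuse_fraction * insolation
    for d, wi in zip(dirs, w):
        sources.append(LightSource(d, {"PAR": wi, "red": 0.0, "far_red": 0.0},
                                   "diffuse"))
    return sources


def daily_sources(insolation: float, day_of_year: int, latitude: float,
                  n_direct: int, n_diffuse: int, diffuse_fraction: float,
                  ambient_rfr: float, sky_model: str = "uniform") -> list[LightSource]:
    """Full source set for one day; PAR powers sum to the day's insolation.

    Red and far-red band powers are proportional to PAR with
    red / far_red == ambient_rfr for every source.
    """
    direct = solar_path(latitude, day_of_year, n_direct)
    direct_energy = (1 - diffuse_fraction) * insolation
    for s in direct:
        s.band_power["PAR"] *= direct_energy
    diffuse = sky_dome(n_diffuse, diffuse_fraction, insolation, sky_model)
    if not direct and insolation > 0:
        # hand the direct share to the diffuse dome to conserve energy
        for s in diffuse:
            s.band_power["PAR"] *= 1.0 / diffuse_fraction if diffuse_fraction else 1.0
    sources = direct + diffuse
    for s in sources:
        s.band_power["red"] = s.band_power["PAR"]
        s.band_power["far_red"] = s.band_power["PAR"] / ambient_rfr
    return sources
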