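"""Hourly environmental forcing: validation, synthesis and future climate.

The simulator is driven by hourly records of solar radiation, air
temperature, humidity, atmospheric CO2, soil water content and soil mineral
nitrogen.  This module builds those series three ways: from a CSV file, from
a synthetic weather generator (a stand-in for greenhouse/pot experiment
forcing), and as multi-year future-climate scenarios with a linear CO2 ramp
and warming trend applied on top of a baseline season.

Time convention: local solar time, hour-of-day in [0, 24); days after
anthesis (daa) is fractional and advances 1/24 per hourly record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnvForcing",
    "SeasonConfig",
    "interpolate_diurnal_temperature",
    "compute_vpd",
    "saturation_vapour_pressure",
    "generate_synthetic_season",
    "build_future_climate",
    "read_forcing",
    "write_forcing",
]

#: fraction of total solar radiation intercepted by the canopy when a
#: net-radiation column is not supplied
DEFAULT_INTERCEPTION = 0.75


@dataclass(slots=True)
class EnvForcing:
    """One hour of environmental drivers."""

    doy: int                 # day of year
    hour: float              # hour of day [0, 24)
    daa: float               # days after anthesis (fractional, >= 0)
    Rs: float                # total solar radiation, MJ m-2 h-1
    Rn_prime: float          # net radiation intercepted by canopy, MJ m-2 h-1
    Ta: float                # air temperature, degC
    RH: float                # relative humidity, % [0, 100]
    VPD: float               # vapour pressure deficit, kPa
    CO2: float               # atmospheric CO2, umol mol-1
    theta: float             # soil volumetric water content, cm3 cm-3
    N: float                 # soil mineral N, mg kg-1

    def validate(self) -> None:
        vals = (self.doy, self.hour, self.daa, self.Rs, self.Rn_prime,
                self.Ta, self.RH, self.VPD, self.CO2, self.theta, self.N)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite forcing value")
        if not 0 <= self.hour < 24:
            raise ValueError("hour must be in [0, 24)")
        if self.daa < 0:
            raise ValueError("daa must be >= 0")
        if not 0 <= self.RH <= 100:
            raise ValueError("RH must be in [0, 100]")
        if self.VPD < 0 or self.Rs < 0 or self.N < 0:
            raise ValueError("Rs, VPD and N must be >= 0")
        if self.CO2 <= 0:
            raise ValueError("CO2 must be > 0")
        if not 0 <= self.theta <= 1:
            raise ValueError("theta must be in [0, 1]")


@dataclass
class SeasonConfig:
    """Configuration of the synthetic season generator."""

    n_days: int = 90
    anthesis_doy: int = 150       # series starts at anthesis
    latitude: float = 38.0        # deg N (daylength + radiation amplitude)
    Tmin_mean: float = 16.0       # degC mean daily minimum
    Tmax_mean: float = 28.0       # degC mean daily maximum
    T_seasonal_amp: float = 3.0   # degC seasonal modulation amplitude
    T_noise_sd: float = 1.5       # degC day-to-day noise on Tmin/Tmax
    RH_day: float = 55.0          # % typical daytime relative humidity
    RH_night: float = 85.0        # % typical night-time relative humidity
    Rs_max: float = 2.8           # MJ m-2 h-1 clear-sky noon radiation
    cloud_noise: float = 0.15     # relative radiation noise (lognormal sd)
    co2_baseline: float = 413.38  # umol mol-1
    theta_mean: float = 0.32      # cm3 cm-3 (well-irrigated)
    theta_amp: float = 0.02       # irrigation-cycle amplitude
    N_mean: float = 120.0         # mg kg-1 soil mineral N
    N_decline: float = 0.30       # mg kg-1 day-1 depletion between doses
    interception: float = DEFAULT_INTERCEPTION
    seed: int = 0
    theta_series: list[float] | None = None   # optional daily overrides
    N_series: list[float] | None = None

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")


def saturation_vapour_pressure(Ta: float) -> float:
    """Magnus saturation vapour pressure (kPa), FAO-56 constants."""
    return 0.6108 * math.exp(17.27 * Ta / (Ta + 237.3))


def compute_vpd(Ta: float, RH: float) -> float:
    """Vapour pressure deficit (kPa) from air temperature and RH (%)."""
    if not 0 <= RH <= 100:
        raise ValueError("RH must be in [0, 100]")
    return saturation_vapour_pressure(Ta) * (1.0 - RH / 100.0)


def interpolate_diurnal_temperature(Tmin: float, Tmax: float, hour: float) -> float:
    """Hourly air temperature from daily extremes via a sinusoid.

    The maximum occurs at 13:00 and the minimum at 01:00 (solar time);
    the curve is periodic with period 24 h and spans [Tmin, Tmax].
    """
    if Tmax < Tmin:
        raise ValueError("Tmax must be >= Tmin")
    if not 0 <= hour < 24:
        raise ValueError("hour must be in [0, 24)")
    mid = 0.5 * (Tmax + Tmin)
    amp = 0.5 * (Tmax - Tmin)
    return mid + amp * math.sin(2.0 * math.pi * (hour - 7.0) / 24.0)


def _daylength_hours(latitude: float, doy: int) -> float:
    # standard solar declination / sunset-hour-angle formula
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    lat = math.radians(latitude)
    x = -math.tan(lat) * math.tan(decl)
    x = min(1.0, max(-1.0, x))
    return 24.0 / math.pi * math.acos(x)


def generate_synthetic_season(cfg: SeasonConfig) -> list[EnvForcing]:
    """Generate an hourly forcing series for one post-anthesis season.

    Deterministic under a fixed ``cfg.seed``.  Radiation follows a truncated
    sinusoid between sunrise and sunset (zero at night) with multiplicative
    lognormal "cloudiness" noise per day; daily temperature extremes carry
    seasonal modulation plus Gaussian noise and are interpolated to hours
    with the 13:00/01:00 sinusoid; humidity swings between a night-time high
    and a daytime low so that VPD peaks in early afternoon.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[EnvForcing] = []
    for d in range(cfg.n_days):
        doy = (cfg.anthesis_doy + d - 1) % 365 + 1
        seasonal = cfg.T_seasonal_amp * math.sin(2.0 * math.pi * d / max(cfg.n_days, 1))
        tmin = cfg.Tmin_mean + seasonal + rng.normal(0.0, cfg.T_noise_sd)
        tmax = cfg.Tmax_mean + seasonal + rng.normal(0.0, cfg.T_noise_sd)
        if tmax < tmin + 2.0:
            tmax = tmin + 2.0
        cloud = math.exp(rng.normal(0.0, cfg.cloud_noise) - 0.5 * cfg.cloud_noise**2)
        daylen = _daylength_hours(cfg.latitude, doy)
        sunrise = 12.0 - daylen / 2.0
        sunset = 12.0 + daylen / 2.0
        if cfg.theta_series is not None:
            theta_day = cfg.theta_series[min(d, len(cfg.theta_series) - 1)]
        else:
            theta_day = cfg.theta_mean + cfg.theta_amp * math.sin(2.0 * math.pi * d / 7.0)
        if cfg.N_series is not None:
            n_day = cfg.N_series[min(d, len(cfg.N_series) - 1)]
        else:
            # sawtooth: fertigation every 14 days, depletion in between
            n_day = max(0.0, cfg.N_mean + cfg.N_decline * (7.0 - (d % 14)))
        for h in range(24):
            ta = interpolate_diurnal_temperature(tmin, tmax, float(h))
            if sunrise < h < sunset:
                rs = cfg.Rs_max * cloud * math.sin(math.pi * (h - sunrise) / daylen)
                rs = max(0.0, rs)
            else:
                rs = 0.0
            # humidity tracks the inverse of the temperature sinusoid
            w = 0.5 * (1.0 + math.sin(2.0 * math.pi * (h - 7.0) / 24.0))
            rh = cfg.RH_night + (cfg.RH_day - cfg.RH_night) * w
            rh = min(100.0, max(0.0, rh))
            rec = EnvForcing(
                doy=doy,
                hour=float(h),
                daa=d + h / 24.0,
                Rs=rs,
                Rn_prime=cfg.interception * rs,
                Ta=ta,
                RH=rh,
                VPD=compute_vpd(ta, rh),
                CO2=cfg.co2_baseline,
                theta=theta_day,
                N=n_day,
            )
            rec.validate()
            records.append(rec)
    return records


def build_future_climate(
    baseline: list[EnvForcing],
    start_year: int,
    end_year: int,
    co2_end: float = 550.0,
    warming_rate: float = 0.18,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[int, list[EnvForcing]]:
    """Per-year forcing under a monotone CO2 ramp and linear warming.

    Each year's season is the baseline season with a constant temperature
    offset ``warming_rate`` (degC per decade) times elapsed decades (plus
    optional Gaussian inter-annual noise) and the CO2 mole fraction linearly
    interpolated from the baseline value to ``co2_end`` at ``end_year``.
    VPD is recomputed from the shifted temperature at unchanged RH.
    """
    if end_year <= start_year:
        raise ValueError("end_year must be > start_year")
    if co2_end <= 0:
        raise ValueError("co2_end must be > 0")
    if not baseline:
        raise ValueError("baseline forcing is empty")
    co2_start = baseline[0].CO2
    rng = np.random.default_rng(seed)
    years: dict[int, list[EnvForcing]] = {}
    span = end_year - start_year
    for year in range(start_year, end_year + 1):
        frac = (year - start_year) / span
        co2 = co2_start + (co2_end - co2_start) * frac
        dT = warming_rate * (year - start_year) / 10.0
        if noise_sd > 0:
            dT += float(rng.normal(0.0, noise_sd))
        season = []
        for rec in baseline:
            ta = rec.Ta + dT
            season.append(
                EnvForcing(
                    doy=rec.doy, hour=rec.hour, daa=rec.daa,
                    Rs=rec.Rs, Rn_prime=rec.Rn_prime,
                    Ta=ta, RH=rec.RH, VPD=compute_vpd(ta, rec.RH),
                    CO2=co2, theta=rec.theta, N=rec.N,
                )
            )
        years[year] = season
    return years


# ---------------------------------------------------------------------------
# CSV I/O

_COLUMNS = ["doy", "hour", "daa", "Rs", "Rn_prime", "Ta", "RH", "VPD",
            "CO2", "theta", "N"]


def write_forcing(records: list[EnvForcing], path: str) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in records])
    df.to_csv(path, index=False)


def read_forcing(path: str, interception: float = DEFAULT_INTERCEPTION) -> list[EnvForcing]:
    """Read an hourly forcing CSV.

    Missing ``VPD`` is computed from Ta and RH; missing ``Rn_prime`` is taken
    as a fixed interception fraction of Rs; missing ``daa`` counts hours from
    the first record.  Daily-resolution ``theta``/``N`` (NaN gaps) are
    forward-filled to hourly.
    """
    df = pd.read_csv(path)
    required = {"doy", "hour", "Rs", "Ta", "CO2", "theta", "N"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"forcing CSV missing columns: {sorted(missing)}")
    for col in ("theta", "N"):
        df[col] = df[col].ffill()
    if "RH" not in df.columns:
        if "VPD" not in df.columns:
            raise ValueError("forcing CSV needs RH or VPD")
        es = df["Ta"].map(saturation_vapour_pressure)
        df["RH"] = (100.0 * (1.0 - df["VPD"] / es)).clip(0.0, 100.0)
    if "VPD" not in df.columns or df["VPD"].isna().any():
        df["VPD"] = [compute_vpd(t, rh) for t, rh in zip(df["Ta"], df["RH"])]
    if "Rn_prime" not in df.columns:
        df["Rn_prime"] = interception * df["Rs"]
    if "daa" not in df.columns:
        df["daa"] = np.arange(len(df)) / 24.0
    if not df["daa"].is_monotonic_increasing or df["daa"].duplicated().any():
        raise ValueError("forcing time steps must be strictly increasing")
    records = []
    for row in df.itertuples(index=False):
        rec = EnvForcing(doy=int(row.doy), hour=float(row.hour),
                         daa=float(row.daa), Rs=float(row.Rs),
                         Rn_prime=float(row.Rn_prime), Ta=float(row.Ta),
                         RH=float(row.RH), VPD=float(row.VPD),
                         CO2=float(row.CO2), theta=float(row.theta),
                         N=float(row.N))
        rec.validate()
        records.append(rec)
    return records
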