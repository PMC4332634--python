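"""Synthetic daily weather and weather-driven ignitions.

The generator emulates a multi-decadal record from a single southern-Alpine
valley station: a seasonal temperature cycle with AR(1) day-to-day
persistence, rain occurrence as a two-state Markov chain with a summer wet
peak and gamma-distributed wet-day amounts, humidity tied to rain with
episodic dry foehn drops, log-normal wind (stronger during foehn), cloud
cover tracking rain, and snow cover on cold winter days after
precipitation. Ignitions are conditionally independent across days given
the weather: each in-regime day is a fire day with probability
logistic(intercept + coefficients . variables), the intercept calibrated
by bisection so the expected prevalence hits a target.

Defaults are chosen to resemble an Insubrian climate record (mild dry
winters, wet warm summers, ~1,800 mm rain per year concentrated in
June-September, foehn episodes cutting humidity to ~20-30%).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .regimes import RegimeSpec
from .weather_io import SiteParams, WeatherSeries

__all__ = [
    "WeatherGenConfig",
    "IgnitionGenConfig",
    "generate_weather",
    "generate_fires",
    "default_site",
]


@dataclasses.dataclass(frozen=True)
class WeatherGenConfig:
    """Parameters of the stochastic daily weather generator."""

    years: int = 22
    start_year: int = 1991
    # temperature: annual harmonic + AR(1) anomaly
    t_mean: float = 12.0  # °C, annual mean
    t_amplitude: float = 9.0  # °C, half the seasonal swing
    t_peak_doy: int = 200  # day of year of the warmest day
    t_ar1: float = 0.7
    t_noise_sd: float = 1.8  # °C, innovation SD
    diurnal_range_mean: float = 8.0  # °C, Tmax - Tmin
    diurnal_range_sd: float = 2.0
    # humidity (%): dry-day base with seasonal swing; uplift on wet days
    h_base: float = 62.0
    h_seasonal_amplitude: float = 8.0  # higher in summer, lower in winter
    h_wet_uplift: float = 22.0
    h_noise_sd: float = 8.0
    # rain occurrence Markov chain, with a summer seasonal modulation
    p_wet_given_dry: float = 0.22
    p_wet_given_wet: float = 0.52
    wet_seasonal_amplitude: float = 0.10  # added in summer, subtracted in winter
    rain_gamma_shape: float = 0.8
    rain_gamma_scale_mm: float = 16.0
    # wind (m/s), log-normal
    wind_log_mean: float = 0.5
    wind_log_sd: float = 0.5
    # foehn episodes: sudden dry, windy spells
    foehn_rate_per_year: float = 10.0
    foehn_mean_duration_days: float = 2.0
    foehn_humidity_factor: float = 0.45  # multiplies humidity
    foehn_wind_boost: float = 2.5  # m/s added
    snow_t_threshold: float = 0.0  # °C


def default_site(cfg: WeatherGenConfig | None = None) -> SiteParams:
    """Site parameters consistent with the generator's climate."""
    cfg = cfg or WeatherGenConfig()
    doy_mid = np.array([15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])
    monthly_t = cfg.t_mean + cfg.t_amplitude * np.cos(
        2.0 * np.pi * (doy_mid - cfg.t_peak_doy) / 365.25
    )
    return SiteParams(
        elevation_m=380.0,
        latitude_deg=46.2,
        mean_annual_precip_mm=1800.0,
        mean_monthly_t=tuple(round(float(x), 2) for x in monthly_t),
    )


def generate_weather(cfg: WeatherGenConfig, seed: int) -> WeatherSeries:
    """Generate a reproducible multi-year daily weather series."""
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(year=cfg.start_year, month=1, day=1)
    end = pd.Timestamp(year=cfg.start_year + cfg.years - 1, month=12, day=31)
    dates = pd.date_range(start, end, freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    season = np.cos(2.0 * np.pi * (doy - cfg.t_peak_doy) / 365.25)  # +1 mid-summer

    # temperature: harmonic + AR(1) anomaly
    anom = np.empty(n)
    anom[0] = rng.normal(0.0, cfg.t_noise_sd / np.sqrt(1.0 - cfg.t_ar1**2))
    eps = rng.normal(0.0, cfg.t_noise_sd, size=n)
    for i in range(1, n):
        anom[i] = cfg.t_ar1 * anom[i - 1] + eps[i]
    t = cfg.t_mean + cfg.t_amplitude * season + anom
    dtr = np.maximum(rng.normal(cfg.diurnal_range_mean, cfg.diurnal_range_sd, size=n), 1.0)
    split = rng.uniform(0.35, 0.65, size=n)
    tmax = t + dtr * split
    tmin = t - dtr * (1.0 - split)

    # rain occurrence (Markov) and amounts (gamma)
    p_wd = np.clip(cfg.p_wet_given_dry + cfg.wet_seasonal_amplitude * season, 0.0, 0.99)
    p_ww = np.clip(cfg.p_wet_given_wet + cfg.wet_seasonal_amplitude * season, 0.0, 0.99)
    wet = np.zeros(n, dtype=bool)
    u01 = rng.uniform(size=n)
    wet[0] = u01[0] < p_wd[0]
    for i in range(1, n):
        wet[i] = u01[i] < (p_ww[i] if wet[i - 1] else p_wd[i])
    p = np.where(wet, rng.gamma(cfg.rain_gamma_shape, cfg.rain_gamma_scale_mm, size=n), 0.0)
    p = np.round(p, 1)
    wet = p >= 0.1  # a drawn amount that rounds to zero is a dry day

    # foehn episodes
    foehn = np.zeros(n, dtype=bool)
    n_events = rng.poisson(cfg.foehn_rate_per_year * cfg.years)
    starts = rng.integers(0, n, size=n_events)
    durations = 1 + rng.geometric(1.0 / cfg.foehn_mean_duration_days, size=n_events)
    for s, d in zip(starts, durations):
        foehn[s : s + d] = True
    foehn &= ~wet  # foehn days are dry

    # humidity
    h = (
        cfg.h_base
        + cfg.h_seasonal_amplitude * season
        + cfg.h_wet_uplift * wet
        + rng.normal(0.0, cfg.h_noise_sd, size=n)
    )
    h = np.where(foehn, h * cfg.foehn_humidity_factor, h)
    h = np.clip(h, 5.0, 100.0)

    # wind, cloud, snow
    u = rng.lognormal(cfg.wind_log_mean, cfg.wind_log_sd, size=n)
    u = np.where(foehn, u + cfg.foehn_wind_boost, u)
    cloud = np.clip(
        0.25 + 0.55 * wet + 0.003 * (h - cfg.h_base) + rng.normal(0.0, 0.12, size=n), 0.0, 1.0
    )
    # snow: cold-season days below threshold shortly after precipitation
    snow = np.zeros(n)
    cover = 0.0
    for i in range(n):
        if wet[i] and t[i] <= cfg.snow_t_threshold:
            cover = 1.0
        elif t[i] > cfg.snow_t_threshold + 2.0:
            cover = 0.0
        snow[i] = cover

    frame = pd.DataFrame(
        {
            "t": np.round(t, 1),
            "tmax": np.round(tmax, 1),
            "tmin": np.round(tmin, 1),
            "h": np.round(h, 0),
            "p": p,
            "u": np.round(u, 1),
            "cloud": np.round(cloud, 2),
            "snow": snow,
        },
        index=pd.DatetimeIndex(dates, name="date"),
    )
    # enforce ordering invariant after rounding
    frame["tmax"] = np.maximum(frame["tmax"], frame["t"])
    frame["tmin"] = np.minimum(frame["tmin"], frame["t"])
    return WeatherSeries(frame, site=default_site(cfg))


@dataclasses.dataclass(frozen=True)
class IgnitionGenConfig:
    """Weather-conditioned ignition process for one regime."""

    regime: RegimeSpec
    coefficients: Mapping[str, float] = dataclasses.field(default_factory=dict)
    target_prevalence: float = 0.1
    cause: str | None = None  # defaults to the regime's cause

    @property
    def cause_label(self) -> str:
        if self.cause:
            return self.cause
        return self.regime.cause if self.regime.cause != "any" else "anthropogenic"


def calibrate_intercept(
    eta_no_intercept: np.ndarray, target: float, tol: float = 1e-10
) -> float:
    """Bisection on the intercept so mean(logistic(a + eta)) = target."""
    if not 0.0 < target < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    lo, hi = -50.0, 50.0
    f = lambda a: float(np.mean(expit(a + eta_no_intercept))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            "target prevalence unreachable; feasible range "
            f"[{np.mean(expit(lo + eta_no_intercept)):.4g}, "
            f"{np.mean(expit(hi + eta_no_intercept)):.4g}]"
        )
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return (lo + hi) / 2.0


def generate_fires(
    variables: pd.DataFrame,
    cfg: IgnitionGenConfig,
    seed: int,
) -> pd.DataFrame:
    """Draw fire events for the in-regime days of a daily variable frame.

    ``variables`` must be indexed by date and contain every variable named
    in ``cfg.coefficients`` (standardised internally so coefficients are
    per-SD effects). Returns a fire-event frame (date, cause) with one
    event per ignition day.
    """
    rng = np.random.default_rng(seed)
    y0, y1 = cfg.regime.period
    mask = variables.index.month.isin(cfg.regime.months) & variables.index.year.isin(
        range(y0, y1 + 1)
    )
    days = variables.index[mask]
    if len(days) == 0:
        raise ValueError("variable frame does not cover the regime months/period")
    eta = np.zeros(len(days))
    for name, coef in cfg.coefficients.items():
        col = variables.loc[days, name].to_numpy(float)
        if np.isnan(col).any():
            raise ValueError(f"variable {name!r} has missing values on regime days")
        sd = col.std()
        z = (col - col.mean()) / (sd if sd > 0 else 1.0)
        eta += coef * z
    intercept = calibrate_intercept(eta, cfg.target_prevalence)
    prob = expit(intercept + eta)
    ignite = rng.uniform(size=len(days)) < prob
    return pd.DataFrame({"date": days[ignite], "cause": cfg.cause_label})
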