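"""Reading, validating and deriving daily meteorological station data.

A weather series is one record per calendar day from a single station:
mean/max/min air temperature (°C), relative humidity (%), precipitation
(mm/day), wind speed (m/s), cloud cover (fraction) and snow cover (0/1).
From these we derive the moisture variables used as model inputs: dew-point
temperature, vapour pressure deficit, trailing-week rainfall, days since the
last rain day, and the total of the most recent consecutive-rain spell.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteParams",
    "WeatherSeries",
    "WeatherValidationError",
    "read_weather",
    "read_fires",
    "derive_variables",
    "MAGNUS_A",
    "MAGNUS_B",
]

#: Magnus coefficients for saturation vapour pressure over water.
MAGNUS_A = 17.27
MAGNUS_B = 237.3  # °C

#: canonical column order for a weather frame
WEATHER_COLUMNS = ("t", "tmax", "tmin", "h", "p", "u", "cloud", "snow")
REQUIRED_COLUMNS = ("t", "h", "p", "u")

DERIVED_COLUMNS = (
    "tdew",
    "vpd",
    "week_rain",
    "days_since_rain",
    "last_rain_sum",
    "burn_in",
)


class WeatherValidationError(ValueError):
    """Raised when a weather or fire table violates its invariants.

    ``rows`` holds the offending row labels (dates or positional indices)
    so callers can report exactly which records failed.
    """

    def __init__(self, message: str, rows: Sequence | None = None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


@dataclasses.dataclass(frozen=True)
class SiteParams:
    """Station-level constants needed by some fire-weather indices.

    Parameters
    ----------
    elevation_m : float
        Station elevation, m above sea level.
    latitude_deg : float
        Station latitude in decimal degrees (positive north).
    mean_annual_precip_mm : float
        Climatological mean annual precipitation sum, mm.
    mean_monthly_t : tuple of 12 floats
        Climatological mean air temperature per calendar month, °C
        (January first).
    """

    elevation_m: float
    latitude_deg: float
    mean_annual_precip_mm: float
    mean_monthly_t: tuple[float, ...]

    def __post_init__(self):
        if len(self.mean_monthly_t) != 12:
            raise ValueError("mean_monthly_t must have 12 entries (Jan..Dec)")

    @property
    def latitude_rad(self) -> float:
        return float(np.deg2rad(self.latitude_deg))

    @classmethod
    def from_mapping(cls, d: Mapping) -> "SiteParams":
        return cls(
            elevation_m=float(d["elevation_m"]),
            latitude_deg=float(d["latitude_deg"]),
            mean_annual_precip_mm=float(d["mean_annual_precip_mm"]),
            mean_monthly_t=tuple(float(x) for x in d["mean_monthly_t"]),
        )


class WeatherSeries:
    """A validated, gap-free daily weather table plus site parameters.

    ``frame`` is indexed by calendar date (``DatetimeIndex``, daily,
    strictly increasing) with columns ``t, tmax, tmin, h, p, u, cloud,
    snow``; optional columns that were absent from the source are all-NaN.
    """

    def __init__(self, frame: pd.DataFrame, site: SiteParams | None = None):
        self.frame = frame
        self.site = site
        self._validate()

    # -- container sugar -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    def has_column(self, name: str) -> bool:
        return name in self.frame.columns and not self.frame[name].isna().all()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        df = self.frame
        if not isinstance(df.index, pd.DatetimeIndex):
            raise WeatherValidationError("weather frame must be indexed by date")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique()
            raise WeatherValidationError(
                f"duplicate dates: {[str(d.date()) for d in dups]}", rows=list(dups)
            )
        if len(df) > 1:
            deltas = np.diff(df.index.values).astype("timedelta64[D]").astype(int)
            if (deltas <= 0).any():
                raise WeatherValidationError("dates must be strictly increasing")
            gaps = np.nonzero(deltas != 1)[0]
            if gaps.size:
                missing = []
                for i in gaps:
                    lo = df.index[i] + pd.Timedelta(days=1)
                    hi = df.index[i + 1] - pd.Timedelta(days=1)
                    missing.extend(pd.date_range(lo, hi, freq="D"))
                raise WeatherValidationError(
                    "calendar gap; missing days: "
                    + ", ".join(str(d.date()) for d in missing[:20]),
                    rows=missing,
                )
        bad = _invariant_violations(df)
        if bad:
            rows = sorted({r for _, r in bad})
            msgs = "; ".join(f"{m} at {r.date()}" for m, r in bad[:20])
            raise WeatherValidationError(f"invariant violations: {msgs}", rows=rows)


def _invariant_violations(df: pd.DataFrame) -> list[tuple[str, pd.Timestamp]]:
    out: list[tuple[str, pd.Timestamp]] = []

    def check(mask: pd.Series, msg: str) -> None:
        for ts in df.index[mask.fillna(False)]:
            out.append((msg, ts))

    check((df["h"] < 0) | (df["h"] > 100), "H outside [0, 100]")
    check(df["p"] < 0, "P < 0")
    check(df["u"] < 0, "U < 0")
    if "cloud" in df:
        check((df["cloud"] < 0) | (df["cloud"] > 1), "CloudCover outside [0, 1]")
    if "snow" in df:
        check(~df["snow"].isin([0, 1]) & df["snow"].notna(), "SnowCover not in {0, 1}")
    if "tmax" in df and "tmin" in df:
        full = df["tmin"].notna() & df["t"].notna() & df["tmax"].notna()
        check(full & ((df["tmin"] > df["t"]) | (df["t"] > df["tmax"])), "Tmin <= T <= Tmax violated")
    return out


DEFAULT_SCHEMA = {
    "date": "date",
    "t": "t",
    "tmax": "tmax",
    "tmin": "tmin",
    "h": "h",
    "p": "p",
    "u": "u",
    "cloud": "cloud",
    "snow": "snow",
}


def read_weather(
    source,
    schema: Mapping[str, str] | None = None,
    site: SiteParams | Mapping | None = None,
    gap_policy: str = "reject",
) -> WeatherSeries:
    """Read a daily weather CSV into a validated :class:`WeatherSeries`.

    Parameters
    ----------
    source : path or file-like
        CSV with a header row; must contain at least the ``date, t, h, p,
        u`` columns (under the names given by ``schema``).
    schema : mapping, optional
        Maps canonical names (``date, t, tmax, tmin, h, p, u, cloud,
        snow``) to the column names used in the file.
    site : SiteParams or mapping, optional
    gap_policy : {"reject", "interpolate"}
        ``reject`` raises on calendar gaps; ``interpolate`` fills gaps by
        linear interpolation and marks the filled rows in a ``gap_filled``
        column.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    raw = pd.read_csv(source)
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = [schema[c] for c in ("date",) + REQUIRED_COLUMNS if schema[c] not in raw.columns]
    if missing:
        raise WeatherValidationError(f"missing required columns: {missing}")

    df = pd.DataFrame(index=pd.DatetimeIndex(pd.to_datetime(raw[schema["date"]]), name="date"))
    for canon in WEATHER_COLUMNS:
        col = schema.get(canon, canon)
        df[canon] = (
            pd.to_numeric(raw[col], errors="coerce").to_numpy() if col in raw.columns else np.nan
        )
    df = df.sort_index()
    df["gap_filled"] = False

    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise WeatherValidationError(
            f"duplicate dates: {[str(d.date()) for d in dups]}", rows=list(dups)
        )
    if gap_policy == "interpolate" and len(df) > 1:
        full = pd.date_range(df.index[0], df.index[-1], freq="D", name="date")
        if len(full) != len(df):
            observed = df.index
            df = df.reindex(full)
            df["gap_filled"] = ~df.index.isin(observed)
            num_cols = list(WEATHER_COLUMNS)
            df[num_cols] = df[num_cols].interpolate(method="linear", limit_direction="both")
    elif gap_policy != "reject":
        raise ValueError(f"unknown gap_policy {gap_policy!r}")

    if site is not None and not isinstance(site, SiteParams):
        site = SiteParams.from_mapping(site)
    return WeatherSeries(df, site=site)


def read_fires(source, causes: Iterable[str] = ("anthropogenic", "natural")) -> pd.DataFrame:
    """Read a fire-event CSV with columns ``date, cause``.

    Returns a DataFrame with ``date`` (datetime) and ``cause`` columns,
    sorted by date. Unknown cause labels raise.
    """
    raw = pd.read_csv(source)
    raw.columns = [c.strip().lower() for c in raw.columns]
    if "date" not in raw.columns or "cause" not in raw.columns:
        raise WeatherValidationError("fire CSV must have 'date' and 'cause' columns")
    df = pd.DataFrame(
        {
            "date": pd.to_datetime(raw["date"]),
            "cause": raw["cause"].str.strip().str.lower(),
        }
    ).sort_values("date", ignore_index=True)
    bad = ~df["cause"].isin(list(causes))
    if bad.any():
        raise WeatherValidationError(
            f"unknown fire causes: {sorted(df.loc[bad, 'cause'].unique())}",
            rows=list(df.index[bad]),
        )
    return df


# ---------------------------------------------------------------------------
# derived variables


def saturation_vapour_pressure(t_c):
    """Saturation vapour pressure es(T) in kPa (Magnus form over water)."""
    t_c = np.asarray(t_c, dtype=float)
    return 0.6108 * np.exp(MAGNUS_A * t_c / (t_c + MAGNUS_B))


def dew_point(t_c, rh):
    """Dew-point temperature (°C) from air temperature and RH via Magnus."""
    t_c = np.asarray(t_c, dtype=float)
    rh = np.clip(np.asarray(rh, dtype=float), 1e-3, 100.0)
    gamma = np.log(rh / 100.0) + MAGNUS_A * t_c / (t_c + MAGNUS_B)
    return MAGNUS_B * gamma / (MAGNUS_A - gamma)


def derive_variables(
    series: WeatherSeries,
    rain_day_threshold: float = 0.2,
    week_window_includes_today: bool = False,
) -> pd.DataFrame:
    """Compute the derived moisture variables for every day of a series.

    Returns a frame aligned with ``series.frame`` with columns ``tdew``
    (°C), ``vpd`` (kPa), ``week_rain`` (mm summed over the trailing 7-day
    window, by default the 7 days strictly before the current day),
    ``days_since_rain`` (0 on a rain day), ``last_rain_sum`` (total
    precipitation of the most recent run of consecutive rain days) and a
    boolean ``burn_in`` flag for the days whose trailing window or rain
    history is incomplete. A rain day is a day with P >= rain_day_threshold
    (default 0.2 mm, typical gauge resolution). Burn-in days carry NaN for
    window/history quantities rather than fabricated values.
    """
    if rain_day_threshold < 0:
        raise ValueError("rain_day_threshold must be >= 0")
    df = series.frame
    t = df["t"].to_numpy(float)
    h = df["h"].to_numpy(float)
    p = df["p"].to_numpy(float)
    n = len(df)

    tdew = dew_point(t, h)
    es = saturation_vapour_pressure(t)
    vpd = np.maximum(es * (1.0 - h / 100.0), 0.0)

    roll = pd.Series(p, index=df.index).rolling(7, min_periods=7).sum()
    week_rain = roll.to_numpy() if week_window_includes_today else roll.shift(1).to_numpy()

    is_rain = p >= rain_day_threshold
    days_since = np.empty(n)
    last_sum = np.full(n, np.nan)
    counter = 0
    run_sum = np.nan
    prev_rain = False
    seen_rain = False
    for i in range(n):
        if is_rain[i]:
            counter = 0
            run_sum = (run_sum + p[i]) if prev_rain else p[i]
            seen_rain = True
        else:
            counter += 1
        days_since[i] = counter
        last_sum[i] = run_sum if seen_rain else np.nan
        prev_rain = bool(is_rain[i])

    burn_in = np.zeros(n, dtype=bool)
    k = 7 if not week_window_includes_today else 6
    burn_in[: min(k, n)] = True
    burn_in |= np.isnan(week_rain)
    # days-since-rain counts assume no rain before the series; flag until
    # the first observed rain day
    if seen_rain:
        first_rain = int(np.argmax(is_rain))
        burn_in[:first_rain] = True
    else:
        burn_in[:] = True

    return pd.DataFrame(
        {
            "tdew": tdew,
            "vpd": vpd,
            "week_rain": week_rain,
            "days_since_rain": days_since,
            "last_rain_sum": last_sum,
            "burn_in": burn_in,
        },
        index=df.index,
    )
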