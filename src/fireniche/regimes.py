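"""Fire regimes: splitting the timeline and assembling modelling datasets.

A fire regime is a (season months, ignition cause, year period) triple.
The default regimes follow the seasonal split used for the Insubrian
southern Alps: winter ``w`` (December-April, anthropogenic), summer
anthropogenic ``sa`` (May-November) and summer natural ``sn``
(May-November, lightning). The *background* of a regime is every calendar
day of its months within the period; a *fire day* is a background day with
at least one ignition of the regime's cause. Prevalence p = fire days /
background days bounds the achievable presence-vs-background AUC at
1 − p/2.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RegimeSpec",
    "RegimeDataset",
    "DEFAULT_REGIMES",
    "assign_regime_days",
    "label_fire_days",
    "theoretical_max_auc",
    "build_dataset",
]

WINTER_MONTHS = frozenset({12, 1, 2, 3, 4})
SUMMER_MONTHS = frozenset({5, 6, 7, 8, 9, 10, 11})


@dataclasses.dataclass(frozen=True)
class RegimeSpec:
    """One fire regime: name, months, cause filter and year period."""

    name: str
    months: frozenset[int]
    cause: str  # "anthropogenic" | "natural" | "any"
    period: tuple[int, int]  # (first year, last year), inclusive

    def __post_init__(self):
        if not self.months or not self.months <= set(range(1, 13)):
            raise ValueError("months must be a non-empty subset of 1..12")
        if self.cause not in ("anthropogenic", "natural", "any"):
            raise ValueError(f"unknown cause filter {self.cause!r}")
        if self.period[0] > self.period[1]:
            raise ValueError("period must be (first_year, last_year)")

    @property
    def is_winter(self) -> bool:
        return 12 in self.months and 1 in self.months


def default_regimes(
    winter_period: tuple[int, int] = (1991, 2012),
    summer_anthropogenic_period: tuple[int, int] = (1991, 2012),
    summer_natural_period: tuple[int, int] = (1981, 2012),
) -> dict[str, RegimeSpec]:
    return {
        "w": RegimeSpec("w", WINTER_MONTHS, "anthropogenic", winter_period),
        "sa": RegimeSpec("sa", SUMMER_MONTHS, "anthropogenic", summer_anthropogenic_period),
        "sn": RegimeSpec("sn", SUMMER_MONTHS, "natural", summer_natural_period),
    }


DEFAULT_REGIMES = default_regimes()


def assign_regime_days(spec: RegimeSpec, available: pd.DatetimeIndex | None = None) -> pd.DatetimeIndex:
    """All calendar days of the regime's months within its period.

    Membership is by calendar month and year: December of the period's
    final year belongs to the winter background even though its season
    extends into the following year (the day set is identical under either
    season-labelling convention).

    If ``available`` is given it must cover the period, else an error is
    raised; the returned days are always the full calendar enumeration.
    """
    y0, y1 = spec.period
    start, end = pd.Timestamp(year=y0, month=1, day=1), pd.Timestamp(year=y1, month=12, day=31)
    if available is not None and (available.min() > start or available.max() < end):
        raise ValueError(
            f"weather data {available.min().date()}..{available.max().date()} "
            f"does not cover regime period {y0}-{y1}"
        )
    days = pd.date_range(start, end, freq="D")
    return days[days.month.isin(spec.months)]


@dataclasses.dataclass
class RegimeDataset:
    """Background days with fire-day labels and a variable matrix."""

    spec: RegimeSpec
    frame: pd.DataFrame  # indexed by date; 'fire_day' bool + variable columns
    n_excluded_events: int = 0

    @property
    def labels(self) -> np.ndarray:
        return self.frame["fire_day"].to_numpy(bool)

    @property
    def n_fire_days(self) -> int:
        return int(self.frame["fire_day"].sum())

    @property
    def n_background(self) -> int:
        return len(self.frame)

    @property
    def prevalence(self) -> float:
        return self.n_fire_days / self.n_background

    @property
    def prevalence_reported(self) -> float:
        """Prevalence rounded to 3 decimals, the reporting convention."""
        return round(self.prevalence, 3)

    def variables(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        cols = [c for c in self.frame.columns if c not in ("fire_day", "fold")]
        if names is not None:
            missing = [v for v in names if v not in cols]
            if missing:
                raise KeyError(f"unknown variables: {missing}")
            cols = list(names)
        return self.frame[cols]

    def summary(self) -> dict:
        return {
            "regime": self.spec.name,
            "period": list(self.spec.period),
            "n_fire_days": self.n_fire_days,
            "n_background": self.n_background,
            "prevalence": self.prevalence_reported,
            "max_auc_bg": round(theoretical_max_auc(self.prevalence), 4)
            if self.n_fire_days
            else None,
        }


def label_fire_days(
    background: pd.DatetimeIndex, events: pd.DataFrame, spec: RegimeSpec
) -> tuple[pd.Series, int]:
    """Binary fire-day label per background day from a fire-event table.

    Events are filtered to the regime's cause; several same-day events
    collapse to one fire day. Events dated outside the background (wrong
    month or year) are excluded with a warning and counted.
    """
    ev = events
    if spec.cause != "any":
        ev = ev[ev["cause"] == spec.cause]
    dates = pd.DatetimeIndex(ev["date"]).normalize()
    inside = dates.isin(background)
    n_excluded = int((~inside).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} fire events outside the {spec.name} background were excluded",
            stacklevel=2,
        )
    labels = pd.Series(background.isin(dates[inside]), index=background, name="fire_day")
    return labels, n_excluded


def theoretical_max_auc(p: float) -> float:
    """Prevalence ceiling of presence-vs-background AUC: 1 − p/2.

    With presences included in the background, even a perfect score
    function ties each presence with itself among the background, capping
    the AUC below 1.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("prevalence must be in (0, 1]")
    return 1.0 - p / 2.0


def build_dataset(
    variables: pd.DataFrame,
    events: pd.DataFrame,
    spec: RegimeSpec,
    drop_burn_in: bool = True,
) -> RegimeDataset:
    """Assemble the modelling dataset for one regime.

    ``variables`` is a daily frame (weather + derived + indices) indexed by
    date and covering the regime period; rows flagged ``burn_in`` are
    dropped by default. The result holds the in-regime background with the
    fire-day label column first.
    """
    background = assign_regime_days(spec, available=variables.index)
    missing = background.difference(variables.index)
    if len(missing):
        raise ValueError(f"variables missing for {len(missing)} background days")
    sub = variables.loc[background].copy()
    if drop_burn_in and "burn_in" in sub.columns:
        n_before = len(sub)
        sub = sub[~sub["burn_in"].astype(bool)]
        dropped = n_before - len(sub)
        if dropped:
            logger.info("dropped %d burn-in days from %s background", dropped, spec.name)
    sub = sub.drop(columns=[c for c in ("burn_in",) if c in sub.columns])
    labels, n_excl = label_fire_days(pd.DatetimeIndex(sub.index), events, spec)
    frame = pd.concat([labels, sub], axis=1)
    return RegimeDataset(spec=spec, frame=frame, n_excluded_events=n_excl)
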