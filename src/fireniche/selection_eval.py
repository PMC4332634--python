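"""Variable selection, blocked cross-validation and model comparison.

Candidate variable subsets are filtered for redundancy: only subsets whose
pairwise Spearman rank correlations over the regime background are all
strictly below a threshold (default 0.9) are admissible. Each admissible
subset is evaluated by blocked k-fold cross-validation whose folds are
consecutive two-year sub-periods, scoring test folds with the
presence-vs-background AUC (AUC.bg, the Mann-Whitney rank estimate of
P(score of a fire day > score of a background day), ties counted half).
Because the presences sit inside the background, AUC.bg is capped at
1 − p/2 for prevalence p. Paired model comparison uses the two-sided
Wilcoxon signed-rank test on the per-fold AUC.bg values, exact null
distribution (with Pratt handling of zero differences) for small fold
counts.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
import warnings
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .models import LogisticModel, MaxentModel, build_feature_basis, fit_logistic, fit_maxent
from .regimes import RegimeDataset, theoretical_max_auc

logger = logging.getLogger(__name__)

__all__ = [
    "VariablePool",
    "ModelSpec",
    "EvaluationResult",
    "admissible_subsets",
    "year_block_folds",
    "fold_index",
    "auc_bg",
    "roc_bg",
    "cross_validate",
    "wilcoxon_signed_rank",
    "significance_class",
    "compare",
    "best_model_search",
    "METEO_VARIABLES",
    "MIXED_EXCLUDED_METEO",
]

#: the meteorological variable pool (raw + derived station variables)
METEO_VARIABLES = (
    "t",
    "tdew",
    "p",
    "u",
    "h",
    "vpd",
    "cloud",
    "week_rain",
    "last_rain_sum",
    "days_since_rain",
    "snow",
)

#: meteo variables left out of the default mixed pool
MIXED_EXCLUDED_METEO = ("vpd", "last_rain_sum", "days_since_rain")


@dataclasses.dataclass
class VariablePool:
    """A named pool of candidate variables with their Spearman matrix."""

    name: str
    variables: list[str]
    correlation: pd.DataFrame

    @classmethod
    def from_background(cls, name: str, background: pd.DataFrame, variables: Sequence[str]) -> "VariablePool":
        missing = [v for v in variables if v not in background.columns]
        if missing:
            raise KeyError(f"pool {name}: variables not in background: {missing}")
        cm = background[list(variables)].corr(method="spearman")
        return cls(name=name, variables=list(variables), correlation=cm)


def admissible_subsets(
    pool: VariablePool,
    rho_max: float = 0.9,
    size_range: tuple[int, int] = (2, 10),
) -> list[tuple[str, ...]]:
    """Enumerate variable subsets with all pairwise |rho_S| < rho_max.

    The inequality is strict: a pair at exactly rho_max is excluded. If no
    subset is admissible a warning lists the blocking pairs.
    """
    lo, hi = size_range
    lo = max(lo, 1)
    hi = min(hi, len(pool.variables))
    corr = pool.correlation.abs()
    compat = {
        (a, b): corr.loc[a, b] < rho_max
        for a, b in itertools.combinations(pool.variables, 2)
    }
    out: list[tuple[str, ...]] = []
    for size in range(lo, hi + 1):
        for sub in itertools.combinations(pool.variables, size):
            if all(compat[a, b] for a, b in itertools.combinations(sub, 2)):
                out.append(sub)
    if not out:
        blocking = sorted(k for k, ok in compat.items() if not ok)
        warnings.warn(f"no admissible subsets; blocking pairs: {blocking}", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# folds


def year_block_folds(period: tuple[int, int], block_years: int = 2) -> list[tuple[int, ...]]:
    """Consecutive non-overlapping blocks of whole years.

    Returns one tuple of years per fold; the period length must divide
    evenly by ``block_years``.
    """
    y0, y1 = period
    n_years = y1 - y0 + 1
    if n_years % block_years:
        raise ValueError(
            f"period {y0}-{y1} ({n_years} years) is not divisible into "
            f"{block_years}-year blocks; adjust the period or block size"
        )
    return [tuple(range(y, y + block_years)) for y in range(y0, y1 + 1, block_years)]


def fold_index(
    dates: pd.DatetimeIndex,
    folds: Sequence[tuple[int, ...]],
    december_policy: str = "season",
) -> np.ndarray:
    """Assign each date to a fold by year.

    ``december_policy="season"`` attaches December to the following
    winter's year (so Dec 1991 evaluates with Jan-Apr 1992); December of
    the final year stays in the last fold. ``"calendar"`` uses the
    calendar year as-is.
    """
    years = dates.year.to_numpy().copy()
    if december_policy == "season":
        last = max(y for f in folds for y in f)
        years = np.where(dates.month.to_numpy() == 12, np.minimum(years + 1, last), years)
    elif december_policy != "calendar":
        raise ValueError(f"unknown december_policy {december_policy!r}")
    idx = np.full(len(dates), -1)
    for k, fold_years in enumerate(folds):
        idx[np.isin(years, fold_years)] = k
    if (idx < 0).any():
        bad = dates[idx < 0][:5]
        raise ValueError(f"dates outside all folds, e.g. {[str(d.date()) for d in bad]}")
    return idx


# ---------------------------------------------------------------------------
# AUC.bg


def auc_bg(presence_scores, background_scores) -> float:
    """Presence-vs-background AUC (Mann-Whitney with half-tie credit).

    ``background_scores`` is the whole background including the presences;
    the value is P(s_presence > s_background) + P(tie)/2 over all presence
    x background pairs, capped at 1 − p/2 by construction.
    """
    s_p = np.asarray(presence_scores, float)
    s_b = np.asarray(background_scores, float)
    if s_p.size == 0:
        raise ValueError("need at least one presence score")
    ranks = rankdata(np.concatenate([s_p, s_b]))
    r_p = ranks[: s_p.size]
    # Mann-Whitney identity: rank sum of the presence sample in the pooled
    # array, minus its within-sample rank sum n(n+1)/2 (midranks preserve
    # it under ties), counts presence-vs-background wins + half-ties
    u = r_p.sum() - s_p.size * (s_p.size + 1) / 2.0
    return float(u / (s_p.size * s_b.size))


def roc_bg(presence_scores, background_scores, n_points: int = 512) -> pd.DataFrame:
    """ROC curve of presence fraction vs background fraction.

    Returns a frame with ``background_fraction`` (x) and
    ``true_positive_rate`` (y) at every distinct threshold, suitable for
    plotting against the 1 − p/2 ceiling.
    """
    s_p = np.asarray(presence_scores, float)
    s_b = np.asarray(background_scores, float)
    thr = np.unique(np.concatenate([s_p, s_b]))[::-1]
    if thr.size > n_points:
        thr = thr[np.linspace(0, thr.size - 1, n_points).astype(int)]
    x = [(s_b >= t).mean() for t in thr]
    y = [(s_p >= t).mean() for t in thr]
    return pd.DataFrame(
        {"background_fraction": [0.0] + x + [1.0], "true_positive_rate": [0.0] + y + [1.0]}
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """What to fit: model family, variable subset, and fit options."""

    family: str  # "maxent" | "logistic" | "constant"
    variables: tuple[str, ...]
    pool: str = ""
    feature_classes: str | frozenset = "auto"
    n_knots: int = 50
    reg_multiplier: float = 1.0

    def fit(self, train: pd.DataFrame):
        y = train["fire_day"].to_numpy(bool)
        X = train[list(self.variables)]
        if self.family == "maxent":
            classes = self.feature_classes
            if isinstance(classes, frozenset):
                classes = set(classes)
            return fit_maxent(
                X[y], X, classes=classes, n_knots=self.n_knots, reg_multiplier=self.reg_multiplier
            )
        if self.family == "logistic":
            return fit_logistic(y, X)
        if self.family == "constant":
            return _ConstantModel()
        raise ValueError(f"unknown model family {self.family!r}")

    def score(self, model, rows: pd.DataFrame) -> np.ndarray:
        if isinstance(model, MaxentModel):
            return model.scores(rows[list(self.variables)], output="raw")
        if isinstance(model, _ConstantModel):
            return model.scores(rows)
        return model.scores(rows[list(self.variables)])

    def label(self) -> str:
        return f"{self.family}:{self.pool or '-'}:{'+'.join(self.variables)}"


class _ConstantModel:
    """Fold-independent constant score; the no-skill reference."""

    def scores(self, rows) -> np.ndarray:
        return np.zeros(len(rows))

    def to_dict(self) -> dict:
        return {"family": "constant"}


@dataclasses.dataclass
class EvaluationResult:
    """Per-fold and summary test AUC.bg for one model specification."""

    spec: ModelSpec
    fold_aucs: list[float]
    fold_years: list[tuple[int, ...]]
    skipped_folds: list[int]
    prevalence: float

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def min_auc(self) -> float:
        return float(np.min(self.fold_aucs))

    @property
    def max_auc(self) -> float:
        return float(np.max(self.fold_aucs))

    @property
    def max_achievable_auc(self) -> float:
        return theoretical_max_auc(self.prevalence)

    def summary(self) -> dict:
        return {
            "model": self.spec.label(),
            "family": self.spec.family,
            "pool": self.spec.pool,
            "variables": list(self.spec.variables),
            "n_folds": len(self.fold_aucs),
            "fold_aucs": [round(a, 4) for a in self.fold_aucs],
            "mean_auc_bg": round(self.mean_auc, 4),
            "min_auc_bg": round(self.min_auc, 4),
            "max_auc_bg": round(self.max_auc, 4),
            "max_achievable_auc_bg": round(self.max_achievable_auc, 4),
            "skipped_folds": self.skipped_folds,
        }


def cross_validate(
    dataset: RegimeDataset,
    spec: ModelSpec,
    folds: Sequence[tuple[int, ...]] | None = None,
    block_years: int = 2,
    december_policy: str = "season",
) -> EvaluationResult:
    """Blocked k-fold cross-validation of one model specification.

    Each fold's block of years is held out in turn: the model is fitted on
    the remaining days and the test block is scored, with test AUC.bg
    computed against the test block's own background. Folds whose test
    block contains no fire day cannot define an AUC and are excluded from
    the summary with a warning.
    """
    if folds is None:
        folds = year_block_folds(dataset.spec.period, block_years)
    df = dataset.frame
    idx = fold_index(pd.DatetimeIndex(df.index), folds, december_policy)
    aucs: list[float] = []
    used_years: list[tuple[int, ...]] = []
    skipped: list[int] = []
    for k in range(len(folds)):
        test = df[idx == k]
        train = df[idx != k]
        if not test["fire_day"].any():
            skipped.append(k)
            continue
        model = spec.fit(train)
        scores = spec.score(model, test)
        pres = scores[test["fire_day"].to_numpy(bool)]
        aucs.append(auc_bg(pres, scores))
        used_years.append(folds[k])
    if skipped:
        warnings.warn(
            f"{len(skipped)} folds without test presences excluded: {skipped}", stacklevel=2
        )
    if not aucs:
        raise ValueError("no fold had a test presence; cannot evaluate")
    return EvaluationResult(
        spec=spec,
        fold_aucs=aucs,
        fold_years=used_years,
        skipped_folds=skipped,
        prevalence=dataset.prevalence,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (paired, two-sided, Pratt zeros, exact small-n null)


def wilcoxon_signed_rank(diffs, exact_limit: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of zero median difference.

    Zero differences are handled by Pratt's method: they take part in the
    ranking, then drop out of the statistic. For up to ``exact_limit``
    non-zero differences the p-value comes from the exact null (all sign
    assignments of the non-zero ranks equally likely), computed by
    convolution; beyond that a normal approximation with tie and zero
    corrections is used. Returns (W+, p).
    """
    d = np.asarray(diffs, float)
    if d.size == 0:
        raise ValueError("need at least one difference")
    nz = d != 0.0
    if not nz.any():
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))  # zeros included in the ranking (Pratt)
    r_nz = ranks[nz]
    w_plus = float(r_nz[d[nz] > 0].sum())
    n = int(nz.sum())
    if n <= exact_limit:
        p = _exact_signed_rank_p(r_nz, w_plus)
    else:
        zero_ranks = ranks[~nz]
        mu = r_nz.sum() / 2.0
        var = (ranks**2).sum() / 4.0 - (zero_ranks**2).sum() / 4.0
        # tie correction is already implicit in using the actual ranks
        if var <= 0:
            return w_plus, 1.0
        z = (w_plus - mu) / math.sqrt(var)
        from scipy.stats import norm

        p = 2.0 * norm.sf(abs(z))
    return w_plus, min(p, 1.0)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by convolution over all sign assignments.

    Average ranks can be half-integers, so everything is doubled to work
    on an integer lattice.
    """
    r2 = np.round(ranks * 2.0).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w_plus * 2.0))
    mu = total / 2.0
    dev = abs(w2 - mu)
    lo_mask = np.arange(total + 1) <= mu - dev
    hi_mask = np.arange(total + 1) >= mu + dev
    return float(dist[lo_mask | hi_mask].sum())


def significance_class(p: float) -> str:
    """Map a p-value to the conventional stars: ***, **, *, ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare(result_a: EvaluationResult, result_b: EvaluationResult) -> dict:
    """Paired Wilcoxon comparison of two evaluations on the same folds."""
    if result_a.fold_years != result_b.fold_years:
        raise ValueError("results must come from the same folds to be paired")
    diffs = np.asarray(result_a.fold_aucs) - np.asarray(result_b.fold_aucs)
    w, p = wilcoxon_signed_rank(diffs)
    return {
        "model_a": result_a.spec.label(),
        "model_b": result_b.spec.label(),
        "statistic": w,
        "p_value": p,
        "significance": significance_class(p),
        "mean_diff": float(diffs.mean()),
    }


# ---------------------------------------------------------------------------
# best-model search


def best_model_search(
    dataset: RegimeDataset,
    pools: dict[str, Sequence[str]],
    families: Sequence[str] = ("maxent", "logistic"),
    folds: Sequence[tuple[int, ...]] | None = None,
    rho_max: float = 0.9,
    size_range: tuple[int, int] = (2, 10),
    max_subsets_per_pool: int | None = None,
    top_k: int = 10,
    december_policy: str = "season",
    **spec_kwargs,
) -> dict:
    """Evaluate admissible subsets per pool and family, rank by mean AUC.bg.

    Returns ``{"results": all EvaluationResults sorted best-first,
    "best": {(pool, family): EvaluationResult}, "top": first top_k}``.
    Ties in mean test AUC.bg break toward fewer variables, then
    lexicographically, so the ranking is invariant to pool ordering.
    """
    if folds is None:
        folds = year_block_folds(dataset.spec.period)
    bg_vars = dataset.variables()
    results: list[EvaluationResult] = []
    for pool_name, variables in pools.items():
        pool = VariablePool.from_background(pool_name, bg_vars, variables)
        subsets = admissible_subsets(pool, rho_max=rho_max, size_range=size_range)
        if max_subsets_per_pool is not None and len(subsets) > max_subsets_per_pool:
            logger.warning(
                "pool %s: %d subsets exceeds budget %d; evaluating the first %d by size",
                pool_name,
                len(subsets),
                max_subsets_per_pool,
                max_subsets_per_pool,
            )
            subsets = sorted(subsets, key=lambda s: (len(s), s))[:max_subsets_per_pool]
        for family in families:
            for sub in subsets:
                spec = ModelSpec(family=family, variables=tuple(sub), pool=pool_name, **spec_kwargs)
                try:
                    results.append(
                        cross_validate(dataset, spec, folds, december_policy=december_policy)
                    )
                except Exception as exc:  # a failed subset should not kill the search
                    logger.warning("skipping %s: %s", spec.label(), exc)
    results.sort(key=lambda r: (-r.mean_auc, len(r.spec.variables), r.spec.variables))
    best: dict[tuple[str, str], EvaluationResult] = {}
    for r in results:
        key = (r.spec.pool, r.spec.family)
        if key not in best:
            best[key] = r
    return {"results": results, "best": best, "top": results[:top_k]}
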