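"""Subset filtering, folds, AUC.bg, cross-validation and Wilcoxon."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import wilcoxon as scipy_wilcoxon

from fireniche.regimes import RegimeDataset, RegimeSpec, assign_regime_days
from fireniche.selection_eval import (
    ModelSpec,
    VariablePool,
    admissible_subsets,
    auc_bg,
    best_model_search,
    compare,
    cross_validate,
    fold_index,
    roc_bg,
    significance_class,
    wilcoxon_signed_rank,
    year_block_folds,
)


def brute_force_auc(pres, bg):
    """Pair-counting oracle: wins + half-ties over presence x background."""
    wins = sum((p > b) + 0.5 * (p == b) for p in pres for b in bg)
    return wins / (len(pres) * len(bg))


def brute_force_wilcoxon_p(diffs):
    """Exact two-sided p by enumerating all sign assignments of the
    non-zero ranks (zeros ranked first, Pratt)."""
    d = np.asarray(diffs, float)
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    r_nz = ranks[d != 0]
    w_obs = r_nz[d[d != 0] > 0].sum()
    total = r_nz.sum()
    n = len(r_nz)
    dev = abs(w_obs - total / 2.0)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(r_nz, signs) if s)
        if abs(w - total / 2.0) >= dev - 1e-12:
            count += 1
    return count / 2.0**n


class TestAdmissibleSubsets:
    def _pool(self, corr, names):
        cm = pd.DataFrame(corr, index=names, columns=names)
        return VariablePool(name="test", variables=list(names), correlation=cm)

    def test_perfectly_correlated_never_coselected(self):
        pool = self._pool([[1.0, 1.0], [1.0, 1.0]], ["a", "b"])
        subs = admissible_subsets(pool, size_range=(1, 2))
        assert ("a", "b") not in subs
        assert ("a",) in subs and ("b",) in subs

    def test_exactly_at_threshold_excluded(self):
        pool = self._pool([[1.0, 0.9], [0.9, 1.0]], ["a", "b"])
        assert ("a", "b") not in admissible_subsets(pool, rho_max=0.9, size_range=(2, 2))
        pool2 = self._pool([[1.0, 0.8999], [0.8999, 1.0]], ["a", "b"])
        assert ("a", "b") in admissible_subsets(pool2, rho_max=0.9, size_range=(2, 2))

    def test_uncorrelated_triple_gives_power_set(self):
        eye = np.eye(3)
        pool = self._pool(eye, ["a", "b", "c"])
        subs = admissible_subsets(pool, size_range=(1, 3))
        assert len(subs) == 7

    def test_negative_correlation_counts_via_absolute_value(self):
        pool = self._pool([[1.0, -0.95], [-0.95, 1.0]], ["a", "b"])
        assert ("a", "b") not in admissible_subsets(pool, size_range=(2, 2))

    def test_empty_result_warns_with_blocking_pairs(self):
        pool = self._pool([[1.0, 0.99], [0.99, 1.0]], ["a", "b"])
        with pytest.warns(UserWarning, match="blocking"):
            subs = admissible_subsets(pool, size_range=(2, 2))
        assert subs == []


class TestYearBlockFolds:
    @pytest.mark.parametrize(
        "period,expected", [((1991, 2012), 11), ((1981, 2012), 16), ((2001, 2004), 2)]
    )
    def test_fold_counts(self, period, expected):
        folds = year_block_folds(period)
        assert len(folds) == expected
        # blocks are consecutive, non-overlapping, two whole years each
        flat = [y for f in folds for y in f]
        assert flat == list(range(period[0], period[1] + 1))

    def test_partial_trailing_block_rejected(self):
        with pytest.raises(ValueError, match="not divisible"):
            year_block_folds((1991, 2011))

    def test_december_attaches_to_following_winter(self):
        folds = year_block_folds((2001, 2004))
        dates = pd.DatetimeIndex(["2002-12-15", "2002-11-15", "2004-12-15"])
        idx = fold_index(dates, folds, december_policy="season")
        assert idx[0] == 1  # Dec 2002 -> winter 2003 -> second block
        assert idx[1] == 0
        assert idx[2] == 1  # final December stays in the last fold
        idx_cal = fold_index(dates, folds, december_policy="calendar")
        assert idx_cal[0] == 0


class TestAucBg:
    def test_perfect_separation_attains_ceiling(self):
        """Presences scored 1, the rest 0: AUC.bg = 1 − p/2 exactly."""
        m, n = 40, 400
        scores_bg = np.zeros(n)
        scores_bg[:m] = 1.0
        auc = auc_bg(scores_bg[:m], scores_bg)
        assert auc == pytest.approx(1.0 - (m / n) / 2.0, abs=1e-12)

    def test_all_ties_give_half(self):
        assert auc_bg(np.ones(5), np.ones(50)) == pytest.approx(0.5)

    def test_matches_brute_force_small(self):
        rng = np.random.default_rng(0)
        bg = rng.integers(0, 6, size=20).astype(float)  # many ties
        pres = bg[rng.choice(20, 5, replace=False)]
        assert auc_bg(pres, bg) == pytest.approx(brute_force_auc(pres, bg), abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(deadline=None, max_examples=25)
    def test_matches_brute_force_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 1000))
        m = int(rng.integers(1, max(2, n // 4)))
        bg = np.round(rng.normal(size=n), 1)  # rounding induces ties
        pres = bg[rng.choice(n, m, replace=False)]
        assert auc_bg(pres, bg) == pytest.approx(brute_force_auc(pres, bg), abs=1e-9)

    def test_empty_presence_raises(self):
        with pytest.raises(ValueError):
            auc_bg([], np.zeros(10))

    def test_roc_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(4)
        bg = rng.normal(size=200)
        curve = roc_bg(bg[:20] + 1.0, bg)
        assert curve.iloc[0].tolist() == [0.0, 0.0]
        assert curve.iloc[-1].tolist() == [1.0, 1.0]
        assert (np.diff(curve["background_fraction"]) >= 0).all()
        assert (np.diff(curve["true_positive_rate"]) >= 0).all()


def _toy_dataset(period=(2001, 2008), p_fire=0.15, signal=0.0, seed=0):
    spec = RegimeSpec("sa", frozenset(range(5, 12)), "any", period)
    bg = assign_regime_days(spec)
    rng = np.random.default_rng(seed)
    x = rng.normal(size=len(bg))
    y = rng.uniform(size=len(bg)) < 1 / (1 + np.exp(-(np.log(p_fire / (1 - p_fire)) + signal * x)))
    frame = pd.DataFrame({"fire_day": y, "x": x, "z": rng.normal(size=len(bg))}, index=bg)
    return RegimeDataset(spec=spec, frame=frame)


class TestCrossValidate:
    def test_constant_model_scores_half_everywhere(self):
        ds = _toy_dataset()
        res = cross_validate(ds, ModelSpec(family="constant", variables=("x",)))
        assert res.fold_aucs == pytest.approx([0.5] * len(res.fold_aucs))
        assert res.mean_auc == 0.5

    def test_fold_count_matches_period(self):
        ds = _toy_dataset(period=(2001, 2008))
        res = cross_validate(ds, ModelSpec(family="constant", variables=("x",)))
        assert len(res.fold_aucs) + len(res.skipped_folds) == 4

    def test_signal_beats_constant(self):
        ds = _toy_dataset(signal=1.2, seed=3)
        spec = ModelSpec(family="maxent", variables=("x",), feature_classes=frozenset({"linear"}))
        res = cross_validate(ds, spec)
        assert res.mean_auc > 0.6

    def test_deterministic(self):
        ds = _toy_dataset(signal=0.8, seed=5)
        spec = ModelSpec(
            family="maxent", variables=("x", "z"), feature_classes=frozenset({"linear", "quadratic"})
        )
        a = cross_validate(ds, spec)
        b = cross_validate(ds, spec)
        assert a.fold_aucs == b.fold_aucs

    def test_folds_without_presences_are_skipped_with_warning(self):
        ds = _toy_dataset(period=(2001, 2004), p_fire=0.02, seed=1)
        # empty one fold's presences by hand
        frame = ds.frame.copy()
        frame.loc[frame.index.year <= 2002, "fire_day"] = False
        ds2 = RegimeDataset(spec=ds.spec, frame=frame)
        with pytest.warns(UserWarning, match="without test presences"):
            res = cross_validate(ds2, ModelSpec(family="constant", variables=("x",)))
        assert res.skipped_folds == [0]


class TestWilcoxon:
    def test_identical_folds_not_significant(self):
        a = _toy_dataset(signal=0.5)
        res = cross_validate(a, ModelSpec(family="constant", variables=("x",)))
        out = compare(res, res)
        assert out["significance"] == "ns"
        assert out["p_value"] == 1.0

    def test_matches_exhaustive_enumeration_11_folds(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            diffs = np.round(rng.normal(0.01, 0.03, size=11), 3)
            _, p = wilcoxon_signed_rank(diffs)
            assert p == pytest.approx(brute_force_wilcoxon_p(diffs), abs=1e-12)

    def test_enumeration_with_zero_differences(self):
        diffs = np.array([0.0, 0.02, -0.01, 0.03, 0.0, 0.05, 0.01, -0.02, 0.04, 0.02, 0.01])
        _, p = wilcoxon_signed_rank(diffs)
        assert p == pytest.approx(brute_force_wilcoxon_p(diffs), abs=1e-12)

    def test_agrees_with_scipy_when_zero_free(self):
        rng = np.random.default_rng(23)
        diffs = rng.normal(0.02, 0.05, size=12)  # continuous: no zeros/ties
        w, p = wilcoxon_signed_rank(diffs)
        ref = scipy_wilcoxon(diffs, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_significance_classes(self):
        assert significance_class(0.0005) == "***"
        assert significance_class(0.005) == "**"
        assert significance_class(0.03) == "*"
        assert significance_class(0.2) == "ns"

    def test_symmetric_under_swap(self):
        a = _toy_dataset(signal=1.0, seed=2)
        res_m = cross_validate(
            a, ModelSpec(family="maxent", variables=("x",), feature_classes=frozenset({"linear"}))
        )
        res_c = cross_validate(a, ModelSpec(family="constant", variables=("x",)))
        assert compare(res_m, res_c)["p_value"] == pytest.approx(
            compare(res_c, res_m)["p_value"], abs=1e-12
        )


class TestBestModelSearch:
    def test_single_variable_pool(self):
        ds = _toy_dataset(signal=1.0, seed=9)
        out = best_model_search(
            ds,
            {"solo": ["x"]},
            families=("maxent",),
            size_range=(1, 1),
            feature_classes=frozenset({"linear"}),
        )
        assert out["results"][0].spec.variables == ("x",)

    def test_ranking_invariant_to_pool_order(self):
        ds = _toy_dataset(signal=0.9, seed=13)
        kwargs = dict(
            families=("maxent",), size_range=(1, 2), feature_classes=frozenset({"linear"})
        )
        out1 = best_model_search(ds, {"p": ["x", "z"]}, **kwargs)
        out2 = best_model_search(ds, {"p": ["z", "x"]}, **kwargs)
        labels1 = [r.spec.variables for r in out1["results"]]
        labels2 = [r.spec.variables for r in out2["results"]]
        assert [tuple(sorted(v)) for v in labels1] == [tuple(sorted(v)) for v in labels2]

    def test_signal_variable_selected(self):
        ds = _toy_dataset(signal=1.5, seed=29)
        out = best_model_search(
            ds,
            {"p": ["x", "z"]},
            families=("maxent", "logistic"),
            size_range=(1, 2),
            feature_classes=frozenset({"linear"}),
        )
        assert "x" in out["results"][0].spec.variables
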