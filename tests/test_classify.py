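"""Welch tests, the cut-point sweep estimator, marker table, normality check."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from ei_hrv import (
    CohortSpec,
    CutpointSweep,
    SplitTest,
    check_normality,
    generate_cohort,
    marker_table,
    sweep_splits,
    welch_ttest,
)
from ei_hrv.classify import SweepError

INJECTED = ["HF", "lnHF", "RSA", "LFp", "LF_HF"]
NOISE = [
    "BPM", "SDNN", "RMSSD", "pNN50", "VLF", "LF", "lnVLF", "lnLF", "VLFp", "HFp",
    "VLF_HF", "tPow", "dPow", "tHz", "dHz", "CohRatio",
]


def make_cohort(seed, d=1.5):
    spec = CohortSpec(
        n_low=22, n_high=26, score_cut=820,
        effect_map={f: d for f in INJECTED}, seed=seed,
    )
    return generate_cohort(spec, features=INJECTED + NOISE)


class TestWelchTtest:
    def test_hand_computed_example(self):
        res = welch_ttest([1, 2, 3], [4, 5, 6])
        assert abs(res.t_stat) == pytest.approx(3.674, abs=1e-3)
        assert res.p_value == pytest.approx(0.021, abs=0.002)
        assert (res.n_low, res.n_high) == (3, 3)

    def test_identical_groups(self):
        res = welch_ttest([1, 2, 3], [1, 2, 3])
        assert res.t_stat == 0.0 and res.p_value == pytest.approx(1.0)

    def test_zero_variance_equal_means_convention(self):
        res = welch_ttest([5, 5, 5], [5, 5])
        assert (res.t_stat, res.p_value) == (0.0, 1.0)

    def test_symmetry_under_group_exchange(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 9)
        fwd, rev = welch_ttest(a, b), welch_ttest(b, a)
        assert fwd.t_stat == pytest.approx(-rev.t_stat)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_agrees_with_exhaustive_permutation(self, rng):
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(1.2, 1.0, 6)
        obs = welch_ttest(a, b)
        pooled = np.concatenate([a, b])
        stats = []
        for idx in combinations(range(12), 6):
            mask = np.zeros(12, dtype=bool)
            mask[list(idx)] = True
            stats.append(welch_ttest(pooled[mask], pooled[~mask]).t_stat)
        perm_p = np.mean(np.abs(stats) >= abs(obs.t_stat) - 1e-12)
        assert obs.p_value == pytest.approx(perm_p, abs=0.02)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(SweepError):
            welch_ttest([1.0], [2.0, 3.0])


class TestCutpointSweep:
    def test_recovers_injected_markers(self):
        feats, scores, _ = make_cohort(seed=0)
        est = CutpointSweep().fit(feats, scores)
        found = set(est.marker_table_["feature"]) & set(INJECTED)
        assert len(found) >= 4
        assert est.best_significant_count_ >= 5

    def test_sklearn_interface(self):
        feats, scores, labels = make_cohort(seed=1)
        est = CutpointSweep(min_group=6)
        assert est.get_params()["min_group"] == 6
        est.set_params(min_group=5).fit(feats, scores)
        for attr in ("cut_score_", "n_low_", "n_high_", "sweep_table_", "marker_table_"):
            assert hasattr(est, attr)
        pred = est.predict(scores)
        # the fitted cut reproduces its own grouping exactly
        assert np.array_equal(pred == "high", scores >= est.cut_score_)
        assert est.n_low_ + est.n_high_ == 48

    def test_cut_score_is_lowest_high_score(self):
        feats, scores, _ = make_cohort(seed=2)
        est = CutpointSweep().fit(feats, scores)
        s = np.sort(scores)
        assert est.cut_score_ == s[est.n_low_]
        assert s[est.n_low_ - 1] < est.cut_score_

    def test_single_candidate_split(self, rng):
        X = rng.normal(size=(10, 3))
        scores = np.arange(10.0)
        res = sweep_splits(scores, X, min_group=5)
        assert len(res.splits) == 1
        assert (res.n_low, res.n_high) == (5, 5)

    def test_tied_scores_never_split(self, rng):
        X = rng.normal(size=(12, 3))
        scores = np.array([0, 0, 0, 0, 0, 0, 10, 10, 10, 10, 10, 10], dtype=float)
        res = sweep_splits(scores, X, min_group=2)
        assert len(res.splits) == 1
        assert (res.n_low, res.n_high) == (6, 6)

    def test_all_scores_identical_rejected(self, rng):
        X = rng.normal(size=(12, 3))
        with pytest.raises(SweepError, match="no valid split|identical"):
            sweep_splits(np.full(12, 5.0), X, min_group=2)

    def test_monotone_score_transform_invariance(self):
        feats, scores, _ = make_cohort(seed=3)
        a = CutpointSweep().fit(feats, scores)
        b = CutpointSweep().fit(feats, scores**3 + 7)
        pd.testing.assert_frame_equal(
            a.sweep_table_.drop(columns="cut_score"),
            b.sweep_table_.drop(columns="cut_score"),
        )
        assert (a.n_low_, a.n_high_) == (b.n_low_, b.n_high_)

    def test_feature_order_invariance(self):
        feats, scores, _ = make_cohort(seed=4)
        a = CutpointSweep().fit(feats, scores)
        b = CutpointSweep().fit(feats[list(reversed(feats.columns))], scores)
        pd.testing.assert_frame_equal(a.sweep_table_, b.sweep_table_)

    def test_null_count_near_alpha_level(self):
        # fixed split, no effects: mean significant count ~ 0.05 * n_features
        counts = []
        for seed in range(100):
            spec = CohortSpec(n_low=22, n_high=26, effect_map={}, seed=seed)
            feats, _, labels = generate_cohort(spec, features=INJECTED + NOISE)
            from scipy import stats as sst

            p = sst.ttest_ind(
                feats[labels == 0], feats[labels == 1], equal_var=False, axis=0
            ).pvalue
            counts.append((p < 0.05).sum())
        assert 0.5 <= np.mean(counts) <= 1.6

    def test_selection_effect_on_null(self):
        # the best-split count dominates any fixed split's count on null data
        best, fixed = [], []
        for seed in range(30):
            spec = CohortSpec(n_low=24, n_high=24, effect_map={}, seed=seed)
            feats, scores, labels = generate_cohort(spec, features=INJECTED + NOISE)
            est = CutpointSweep().fit(feats, scores)
            best.append(est.best_significant_count_)
            true_row = est.sweep_table_[est.sweep_table_["n_low"] == 24]
            fixed.append(int(true_row["significant_count_05"].iloc[0]))
        assert np.mean(best) > np.mean(fixed)


class TestMarkerTable:
    def _test(self, p, feature="HF"):
        return SplitTest(feature=feature, t_stat=2.0, p_value=p, low_mean=0, low_sd=1,
                         high_mean=1, high_sd=1, n_low=22, n_high=26)

    def test_star_tiers(self):
        table = marker_table([self._test(0.008, "RSA"), self._test(0.03, "HF")])
        stars = dict(zip(table["feature"], table["stars"]))
        assert stars == {"RSA": "**", "HF": "*"}

    def test_boundary_p_excluded(self):
        table = marker_table([self._test(0.05)])
        assert table.empty

    def test_grouped_by_source(self):
        table = marker_table(
            [self._test(0.03, "instability_lnHF"), self._test(0.01, "HF"),
             self._test(0.02, "variability_LF_HF")]
        )
        assert list(table["source"]) == ["HRV", "variability", "instability"]


class TestCheckNormality:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(11)
        p, qq = check_normality(rng.normal(size=500))
        assert p > 0.05
        assert {"theoretical", "sample"} <= set(qq.columns)

    def test_exponential_sample_fails(self):
        rng = np.random.default_rng(11)
        p, _ = check_normality(rng.exponential(size=500))
        assert p < 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(SweepError):
            check_normality(np.full(20, 3.0))

    def test_small_sample_rejected(self):
        with pytest.raises(SweepError):
            check_normality(np.arange(5.0))
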