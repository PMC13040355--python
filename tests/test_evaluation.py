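"""Statistics suite vs independent oracles (direct formulas, scipy, sklearn)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from scalpguard.errors import ScalpGuardError
from scalpguard.evaluation import (auc_rank, bootstrap_ci, chi_square_test,
                                   cohens_d, confusion_metrics, cross_validate,
                                   equal_opportunity_gap, its_fit, risk_ratio,
                                   trend_test)
from scalpguard.features import DesignMatrix


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        r = chi_square_test([[10, 10], [10, 10]])
        assert r.statistic == 0.0 and r.effect_size == 0.0

    def test_proportional_rows_give_zero(self):
        r = chi_square_test([[20, 40, 60], [10, 20, 30]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation_and_scipy(self):
        rng = np.random.default_rng(0)
        obs = rng.integers(5, 40, size=(3, 4)).astype(float)
        r = chi_square_test(obs)
        # direct cell-by-cell oracle
        n = obs.sum()
        exp = np.outer(obs.sum(1), obs.sum(0)) / n
        direct = ((obs - exp) ** 2 / exp).sum()
        assert r.statistic == pytest.approx(direct, abs=1e-9)
        chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
        assert r.statistic == pytest.approx(chi2, abs=1e-9)
        assert r.p_value == pytest.approx(p, abs=1e-12)
        assert r.df == df
        assert r.effect_size == pytest.approx(np.sqrt(chi2 / (n * 2)), abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ScalpGuardError, match="margin"):
            chi_square_test([[0, 0], [5, 5]])


class TestTrend:
    def test_equal_proportions_z_zero(self):
        r = trend_test([10, 20, 30], [20, 40, 60])
        assert abs(r.statistic) < 1e-9

    def test_rising_proportions_positive_z(self):
        r = trend_test([100, 200, 300], [1000, 1000, 1000])
        assert r.statistic > 5

    def test_two_groups_z_squared_equals_chi_square(self):
        x, n = [30, 50], [100, 100]
        z = trend_test(x, n).statistic
        chi2 = chi_square_test([[30, 70], [50, 50]]).statistic
        assert z ** 2 == pytest.approx(chi2, abs=1e-9)

    def test_single_group_errors(self):
        with pytest.raises(ScalpGuardError):
            trend_test([5], [10])


class TestRiskRatio:
    def test_completion_rates_round_to_reported_rr(self):
        # 64.6% of 61,624 vs 78.0% of 96,052
        e1, n1 = round(0.646 * 61624), 61624
        e2, n2 = round(0.780 * 96052), 96052
        r = risk_ratio(e1, n1, e2, n2)
        assert round(r.rr, 2) == 1.21
        assert r.ci_low < r.rr < r.ci_high

    def test_identical_rates_rr_one_ci_covers_one(self):
        r = risk_ratio(50, 100, 100, 200)
        assert r.rr == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_larger_n_narrows_ci(self):
        a = risk_ratio(50, 100, 60, 100)
        b = risk_ratio(100, 200, 120, 200)
        assert (b.ci_high - b.ci_low) < (a.ci_high - a.ci_low)

    def test_zero_cell_suggests_correction(self):
        with pytest.raises(ScalpGuardError, match="continuity"):
            risk_ratio(0, 100, 10, 100)


class TestCohensD:
    def test_identical_samples_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert cohens_d(x, x) == 0.0

    def test_shift_by_one_sd_gives_d_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        x = y + y.std(ddof=1)
        assert cohens_d(x, y) == pytest.approx(1.0)

    def test_hand_computed_five_point_lists(self):
        x, y = [2.0, 4.0, 4.0, 4.0, 6.0], [1.0, 2.0, 3.0, 2.0, 2.0]
        # pooled variance = ((4)*2.0 + (4)*0.5)/8 = 1.25; d = 2/sqrt(1.25)
        assert cohens_d(x, y) == pytest.approx(2.0 / np.sqrt(1.25), abs=1e-12)

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ScalpGuardError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestBootstrap:
    def test_constant_records_zero_width(self):
        r = bootstrap_ci(np.full(30, 7.0), np.mean, B=100, seed=0)
        assert r.ci_low == r.ci_high == 7.0

    def test_seeded_determinism(self):
        x = np.random.default_rng(1).normal(size=50)
        a = bootstrap_ci(x, np.mean, B=200, seed=5)
        b = bootstrap_ci(x, np.mean, B=200, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_dataframe_records_resampled_rowwise(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [10.0, 20.0]})
        r = bootstrap_ci(df, lambda d: (d["b"] / d["a"]).mean(), B=50, seed=2)
        assert r.ci_low == r.ci_high == 10.0  # ratio constant row-wise

    def test_invalid_b_errors(self):
        with pytest.raises(ScalpGuardError):
            bootstrap_ci(np.arange(10.0), np.mean, B=0)


class TestITS:
    def test_flat_noiseless_series_all_zero_changes(self):
        y = np.full(12, 0.7)
        r = its_fit(y, intervention_time=6)
        assert r.level_change == pytest.approx(0.0, abs=1e-10)
        assert r.slope_change == pytest.approx(0.0, abs=1e-10)

    def test_recovers_injected_level_jump(self):
        rng = np.random.default_rng(7)
        t = np.arange(24, dtype=float)
        y = 0.6 + 0.0 * t + 0.10 * (t >= 12) + rng.normal(0, 0.005, 24)
        r = its_fit(y, t=t, intervention_time=12)
        assert r.level_change == pytest.approx(0.10, abs=0.02)
        assert abs(r.slope_change) < 0.005

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        t = np.arange(10, dtype=float)
        y = rng.normal(size=10)
        r = its_fit(y, t=t, intervention_time=5)
        post = (t >= 5).astype(float)
        X = np.column_stack([np.ones(10), t, post, (t - 5) * post])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(r.params, beta, atol=1e-9)

    def test_too_few_points_errors(self):
        with pytest.raises(ScalpGuardError):
            its_fit(np.ones(5), intervention_time=4)


class TestConfusionAndAuc:
    def test_perfect_predictions(self):
        m = confusion_metrics([0, 1, 0, 1], [0, 1, 0, 1], scores=[0.1, 0.9, 0.2, 0.8])
        assert m.accuracy == m.sensitivity == m.specificity == m.precision == m.f1 == 1.0
        assert m.auc == 1.0

    def test_f1_harmonic_identity_on_random_predictions(self):
        rng = np.random.default_rng(3)
        y, p = rng.integers(0, 2, 200), rng.integers(0, 2, 200)
        m = confusion_metrics(y, p)
        assert m.f1 == pytest.approx(2 * m.precision * m.sensitivity
                                     / (m.precision + m.sensitivity))

    def test_auc_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 40)
        s = rng.choice([0.1, 0.3, 0.5, 0.7], size=40)  # ties on purpose
        pos, neg = s[y == 1], s[y == 0]
        pairs = [(1.0 if a > b else 0.5 if a == b else 0.0)
                 for a in pos for b in neg]
        assert auc_rank(y, s) == pytest.approx(np.mean(pairs), abs=1e-12)
        assert auc_rank(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 2000)
        s = rng.permutation(y).astype(float)
        assert abs(auc_rank(y, s) - 0.5) < 0.05

    def test_single_class_auc_undefined_other_metrics_returned(self):
        with pytest.raises(ScalpGuardError):
            auc_rank([1, 1, 1], [0.1, 0.2, 0.3])
        with pytest.warns(UserWarning):
            m = confusion_metrics([1, 1, 1], [1, 0, 1], scores=[0.9, 0.1, 0.8])
        assert m.auc is None and m.sensitivity == pytest.approx(2 / 3)


class TestFairness:
    def test_constructed_gap_half(self):
        y = [1, 1, 1, 1]
        pred = [1, 1, 1, 0]
        groups = ["A", "A", "B", "B"]
        r = equal_opportunity_gap(y, pred, groups)
        assert r.tpr_by_group == {"A": 1.0, "B": 0.5}
        assert r.gap == 0.5

    def test_identical_structure_zero_gap(self):
        y = [1, 0, 1, 0]
        pred = [1, 0, 1, 0]
        assert equal_opportunity_gap(y, pred, ["A", "A", "B", "B"]).gap == 0.0

    def test_relabeling_preserves_tpr_multiset(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 100)
        pred = rng.integers(0, 2, 100)
        g = rng.choice(["A", "B", "C"], 100)
        swap = {"A": "B", "B": "C", "C": "A"}
        a = equal_opportunity_gap(y, pred, g)
        b = equal_opportunity_gap(y, pred, [swap[x] for x in g])
        assert sorted(a.tpr_by_group.values()) == pytest.approx(
            sorted(b.tpr_by_group.values()))

    def test_group_without_positives_excluded_with_warning(self):
        r = equal_opportunity_gap([1, 1, 0], [1, 0, 1], ["A", "A", "B"])
        assert r.groups_used == ("A",)
        assert any("B" in w for w in r.warnings)


class TestCrossValidate:
    def _toy_dm(self, n=40):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(0, 0.3, (n // 2, 2)),
                       rng.normal(4, 0.3, (n // 2, 2))])
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        df = pd.DataFrame(X, columns=["a", "b"])
        return DesignMatrix(X=df, y=y, log_columns=(), feature_names=("a", "b"))

    def test_fold_sizes_and_determinism(self):
        dm = self._toy_dm()
        f1, a1 = cross_validate(dm, k=5, seed=3)
        f2, a2 = cross_validate(dm, k=5, seed=3)
        assert len(f1) == 5
        assert a1 == a2

    def test_separable_toy_set_perfect_accuracy(self):
        _, agg = cross_validate(self._toy_dm(), k=5, seed=1)
        assert agg["accuracy"] == 1.0
        assert agg["auc"] == 1.0

    def test_repeated_split_protocol(self):
        _, agg = cross_validate(self._toy_dm(), protocol="repeated_split",
                                repeats=5, seed=2)
        assert agg["accuracy"] == 1.0

    def test_tiny_class_rejected(self):
        dm = self._toy_dm()
        dm2 = DesignMatrix(X=dm.X, y=np.r_[np.zeros(39), np.ones(1)],
                           log_columns=(), feature_names=dm.feature_names)
        with pytest.raises(ScalpGuardError):
            cross_validate(dm2, k=5, seed=0)
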