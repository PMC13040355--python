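"""Gaussian Bayes model: fitting, posteriors, dynamic prior, updating, BN."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import multivariate_normal, norm

import scalpguard as sg
from scalpguard.errors import FittingError, ScalpGuardError
from scalpguard.features import DesignMatrix
from scalpguard.model import (BayesModelParams, GaussianScalperModel,
                              dynamic_prior, expit, logit, results_from_params)


def _dm_from_arrays(X, y, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    return DesignMatrix(X=df, y=np.asarray(y), log_columns=(),
                        feature_names=tuple(names),
                        mean_=pd.Series(0.0, index=names),
                        sd_=pd.Series(1.0, index=names))


def _params_1d(mu_s, mu_l, prior=0.05, threshold=0.75):
    return BayesModelParams(
        prior_scalper=prior, threshold=threshold, shrinkage=0.0,
        mean_scalper=np.array([mu_s]), mean_legit=np.array([mu_l]),
        cov_scalper=np.eye(1), cov_legit=np.eye(1),
        n_scalper=10, n_legit=10, feature_names=("f0",))


class TestFit:
    def test_recovers_separated_cluster_means(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (500, 2)), rng.normal(5, 1, (500, 2))])
        y = np.r_[np.zeros(500), np.ones(500)]
        res = GaussianScalperModel(_dm_from_arrays(X, y), shrinkage=0.0).fit()
        assert np.allclose(res.params.mean_scalper, [5, 5], atol=0.2)
        assert np.allclose(res.params.mean_legit, [0, 0], atol=0.2)

    def test_full_shrinkage_gives_diagonal_covariance(self):
        rng = np.random.default_rng(1)
        X = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=200)
        y = np.r_[np.zeros(100), np.ones(100)]
        res = GaussianScalperModel(_dm_from_arrays(X, y), shrinkage=1.0).fit()
        off = res.params.cov_scalper[0, 1]
        assert off == 0.0

    def test_refit_is_deterministic(self, sm_dm):
        a = GaussianScalperModel(sm_dm).fit().params
        b = GaussianScalperModel(sm_dm).fit().params
        assert np.array_equal(a.mean_scalper, b.mean_scalper)
        assert np.array_equal(a.cov_legit, b.cov_legit)

    def test_missing_class_errors(self):
        X = np.random.default_rng(2).normal(size=(50, 2))
        with pytest.raises(FittingError, match="scalper"):
            GaussianScalperModel(_dm_from_arrays(X, np.zeros(50))).fit()

    def test_error_halves_when_n_quadruples(self):
        """Parameter recovery rate ~ 1/sqrt(n)."""
        def err(n, seed):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(3, 1, (n, 2))])
            y = np.r_[np.zeros(n), np.ones(n)]
            res = GaussianScalperModel(_dm_from_arrays(X, y), shrinkage=0.0).fit()
            return np.linalg.norm(res.params.mean_scalper - 3)
        e_small = np.mean([err(400, s) for s in range(5)])
        e_big = np.mean([err(1600, s + 10) for s in range(5)])
        assert e_big < 0.8 * e_small


class TestPosterior:
    def test_equal_likelihoods_collapse_to_prior(self):
        res = results_from_params(_params_1d(2.0, 0.0))
        assert res.posterior(np.array([[1.0]]))[0] == pytest.approx(0.05, abs=1e-12)

    def test_likelihood_ratio_57_hits_threshold_exactly(self):
        # solve pi L / (pi L + 1 - pi) = tau at pi=0.05, tau=0.75 -> L = 57
        m = 2.0
        x = (np.log(57.0) + m ** 2 / 2) / m
        res = results_from_params(_params_1d(m, 0.0))
        assert res.posterior(np.array([[x]]))[0] == pytest.approx(0.75, abs=1e-12)
        assert res.classify(np.array([[x]]))["decision"].iloc[0] == "flag"

    def test_log_space_matches_naive_density_ratio(self):
        rng = np.random.default_rng(3)
        mu_s, mu_l = rng.normal(size=3), rng.normal(size=3)
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + np.eye(3)
        p = BayesModelParams(0.05, 0.75, 0.0, mu_s, mu_l, cov, np.eye(3),
                             10, 10, ("a", "b", "c"))
        res = results_from_params(p)
        X = rng.normal(size=(20, 3))
        gs = multivariate_normal(mu_s, cov).pdf(X)
        gl = multivariate_normal(mu_l, np.eye(3)).pdf(X)
        naive = 0.05 * gs / (0.05 * gs + 0.95 * gl)
        assert np.allclose(res.posterior(X), naive, atol=1e-9)

    def test_dimension_mismatch_errors(self):
        res = results_from_params(_params_1d(1, 0))
        with pytest.raises(ScalpGuardError, match="dimension"):
            res.posterior(np.ones((2, 3)))

    @given(st.floats(0.01, 0.99), st.floats(0.02, 0.98))
    def test_posterior_increasing_in_prior(self, p1, p2):
        res = results_from_params(_params_1d(2.0, 0.0))
        x = np.array([[1.5]])
        lo, hi = sorted([p1, p2])
        assert res.posterior(x, prior=lo)[0] <= res.posterior(x, prior=hi)[0]


class TestClassify:
    def test_threshold_boundary_inclusive(self):
        res = results_from_params(_params_1d(2.0, 0.0))
        m = 2.0
        x_at = (np.log(57.0) + m ** 2 / 2) / m        # posterior exactly 0.75
        x_below = x_at - 0.01
        out = res.classify(np.array([[x_at], [x_below]]))
        assert list(out["decision"]) == ["flag", "pass"]

    def test_congestion_never_lowers_posterior(self):
        res = results_from_params(_params_1d(2.0, 0.0))
        x = np.array([[1.0]])
        posts = [res.classify(x, congestion=c)["posterior"].iloc[0]
                 for c in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(a <= b + 1e-15 for a, b in zip(posts, posts[1:]))


class TestDynamicPrior:
    def test_neutral_congestion_returns_base(self):
        assert dynamic_prior(0.05, 0.5, gain=2.0) == pytest.approx(0.05)

    def test_zero_gain_disables_modulation(self):
        for c in (0.0, 0.3, 1.0):
            assert dynamic_prior(0.05, c, gain=0.0) == pytest.approx(0.05)

    def test_hand_logit_arithmetic(self):
        expected = expit(logit(0.05) + 2.0 * 0.5)  # = logistic(logit(.05)+1)
        assert dynamic_prior(0.05, 1.0, gain=2.0) == pytest.approx(float(expected), abs=1e-12)

    def test_out_of_range_congestion_errors(self):
        with pytest.raises(ScalpGuardError):
            dynamic_prior(0.05, 1.5, gain=1.0)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_strictly_increasing_in_congestion(self, c1, c2):
        lo, hi = sorted([c1, c2])
        p_lo = dynamic_prior(0.05, lo, gain=2.0)
        p_hi = dynamic_prior(0.05, hi, gain=2.0)
        assert p_lo <= p_hi
        if hi - lo > 1e-6:
            assert p_hi > p_lo


class TestSequentialUpdate:
    def test_window_refit_on_same_data_is_noop(self, sm_dm):
        res = GaussianScalperModel(sm_dm).fit()
        upd = res.sequential_update(sm_dm, mode="window", window=1)
        assert np.allclose(upd.params.mean_scalper, res.params.mean_scalper)

    def test_infinite_pseudocount_freezes_parameters(self, sm_dm):
        res = GaussianScalperModel(sm_dm).fit()
        upd = res.sequential_update(sm_dm, mode="conjugate", pseudo_count=np.inf)
        assert np.array_equal(upd.params.mean_scalper, res.params.mean_scalper)
        assert np.array_equal(upd.params.cov_legit, res.params.cov_legit)

    def test_unknown_mode_errors(self, sm_dm):
        res = GaussianScalperModel(sm_dm).fit()
        with pytest.raises(ScalpGuardError, match="mode"):
            res.sequential_update(sm_dm, mode="bogus")

    def test_update_recovers_drifted_scalpers(self):
        """Evasive drift: frozen model misses drifted scalpers, an updated
        one recovers >=90% of them (1-D stream, fixed seed)."""
        rng = np.random.default_rng(42)

        def batch(mu_s, n=1000, frac=0.05):
            n_s = int(n * frac)
            X = np.r_[rng.normal(0, 1, n - n_s), rng.normal(mu_s, 1, n_s)]
            y = np.r_[np.zeros(n - n_s), np.ones(n_s)]
            return _dm_from_arrays(X[:, None], y)

        train = batch(mu_s=8.0)
        drifted = batch(mu_s=5.0)
        frozen = GaussianScalperModel(train).fit()
        updated = frozen.sequential_update(drifted, mode="window", window=1)

        Xd = drifted.X.to_numpy()
        yd = drifted.y
        rec_frozen = (frozen.posterior(Xd) >= 0.75)[yd == 1].mean()
        rec_updated = (updated.posterior(Xd) >= 0.75)[yd == 1].mean()
        assert rec_updated >= 0.90
        assert rec_frozen < 0.90

    def test_conjugate_pulls_mean_toward_batch(self, sm_dm):
        res = GaussianScalperModel(sm_dm).fit()
        shifted = DesignMatrix(X=sm_dm.X, y=sm_dm.y, mean_=sm_dm.mean_,
                               sd_=sm_dm.sd_, log_columns=sm_dm.log_columns,
                               feature_names=sm_dm.feature_names)
        upd = res.sequential_update(shifted, mode="conjugate", pseudo_count=10.0)
        # same data: posterior mean stays within the convex hull
        assert np.all(np.isfinite(upd.params.mean_scalper))


class TestCalibration:
    def test_sensitivity_specificity_sweep(self, sm_dm):
        res = GaussianScalperModel(sm_dm).fit()
        sweep = res.calibrate_threshold(sm_dm.Xs.to_numpy(), sm_dm.y)
        assert (np.diff(sweep["flag_rate"]) <= 1e-12).all()  # monotone in tau
        assert sweep["sensitivity"].iloc[0] >= sweep["sensitivity"].iloc[-1]


class TestSummary:
    def test_summary_mentions_operating_point(self, sm_dm):
        res = GaussianScalperModel(sm_dm).fit()
        text = res.summary()
        assert "0.0500" in text and "0.7500" in text
        assert "x5_min_op_s" in text
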