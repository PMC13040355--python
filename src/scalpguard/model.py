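"""Gaussian class-conditional Bayes model of scalper risk.

The recognition engine is a two-class Bayes classifier: the behavioral
feature vector ``x`` of an account is modeled as multivariate Gaussian
within each latent class (scalper / legitimate), and the posterior scalper
probability is

    P(scalper | x) = pi * g_s(x) / (pi * g_s(x) + (1 - pi) * g_l(x))

with the prior ``pi`` fixed at its audited baseline (default 5%) rather
than estimated from training prevalence, and a decision threshold ``tau``
(default 0.75, chosen from a sensitivity–specificity trade-off) at which an
account is flagged.  Posteriors are computed in log-space.  Class
covariances are regularized by shrinkage toward their diagonal,
``(1 - lam) * S + lam * diag(S)``, since the scalper class is small.

The queue-driven *dynamic prior* raises vigilance under congestion:

    logit(pi') = logit(pi) + gamma * (congestion - 1/2)

so congestion 0.5 is neutral and the posterior is strictly increasing in
congestion for gamma > 0.

Usage follows the Model/Results convention::

    model = GaussianScalperModel(dm)          # or .from_dataframe(df, "label")
    res = model.fit()
    res.summary()
    scores = res.classify(dm_new, congestion=0.8)
    res2 = res.sequential_update(X_new, y_new, mode="window")
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import FittingError, ScalpGuardError
from .features import DesignMatrix


def logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


from scipy.special import expit  # numerically safe logistic


def dynamic_prior(base_prior: float, congestion: float, gain: float = 2.0) -> float:
    """Congestion-modulated prior on the logit scale (0.5 is neutral)."""
    if not 0.0 <= congestion <= 1.0:
        raise ScalpGuardError(f"congestion must be in [0, 1], got {congestion}")
    if not 0.0 < base_prior < 1.0:
        raise ScalpGuardError(f"base_prior must be in (0, 1), got {base_prior}")
    return float(expit(logit(base_prior) + gain * (congestion - 0.5)))


#: ridge floor added to covariance diagonals (standardized scale); keeps the
#: fit well-posed when a feature is constant within one class (e.g. every
#: scalper books online, so the online-share column has zero class variance)
RIDGE_EPS = 1e-6


def _shrink(S: np.ndarray, lam: float) -> np.ndarray:
    S = np.atleast_2d(S)
    return (1.0 - lam) * S + lam * np.diag(np.diag(S)) + RIDGE_EPS * np.eye(len(S))


class _GaussianClass:
    """Frozen Gaussian with a cached Cholesky factor for log-density."""

    def __init__(self, mean: np.ndarray, cov: np.ndarray):
        self.mean = np.asarray(mean, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        try:
            self._chol = linalg.cholesky(self.cov, lower=True)
        except linalg.LinAlgError as e:
            raise FittingError(f"covariance not positive-definite: {e}") from e
        self._logdet = 2.0 * np.sum(np.log(np.diag(self._chol)))

    def logpdf(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = X.shape[1]
        if d != len(self.mean):
            raise ScalpGuardError(f"dimension mismatch: {d} vs {len(self.mean)}")
        z = linalg.solve_triangular(self._chol, (X - self.mean).T, lower=True)
        return -0.5 * (d * np.log(2 * np.pi) + self._logdet + np.sum(z * z, axis=0))


@dataclass
class BayesModelParams:
    """Fitted parameters of the class-conditional Gaussian model."""

    prior_scalper: float
    threshold: float
    shrinkage: float
    mean_scalper: np.ndarray
    mean_legit: np.ndarray
    cov_scalper: np.ndarray
    cov_legit: np.ndarray
    n_scalper: int
    n_legit: int
    feature_names: tuple = ()

    def __post_init__(self):
        if not 0.0 < self.prior_scalper < 1.0:
            raise FittingError(f"prior must be in (0, 1), got {self.prior_scalper}")
        if not 0.0 < self.threshold < 1.0:
            raise FittingError(f"threshold must be in (0, 1), got {self.threshold}")


class GaussianScalperModel:
    """Class-conditional Gaussian Bayes model bound to a design matrix.

    Parameters
    ----------
    data : DesignMatrix or (X, y)
        Standardized features are taken from ``DesignMatrix.Xs``; the
        standardizer travels with the results for scoring-time reuse.
    prior : float
        Fixed scalper prior; *not* estimated from training labels.
    threshold : float
        Posterior at or above which an account is flagged.
    shrinkage : float
        Diagonal covariance shrinkage weight in [0, 1].
    """

    def __init__(self, data: DesignMatrix, prior: float = 0.05,
                 threshold: float = 0.75, shrinkage: float = 0.1):
        if not isinstance(data, DesignMatrix):
            raise ScalpGuardError("data must be a DesignMatrix")
        self.data = data
        self.prior = float(prior)
        self.threshold = float(threshold)
        self.shrinkage = float(shrinkage)
        if not 0.0 <= self.shrinkage <= 1.0:
            raise FittingError(f"shrinkage must be in [0, 1], got {shrinkage}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       group_cols: tuple = (), **kwargs) -> "GaussianScalperModel":
        """Build from a flat frame of feature columns plus a label column.

        Labels may be {0,1} or {"normal","abnormal"}; remaining non-group
        columns are used as features verbatim (no log transform is applied
        to frames built this way).
        """
        y_raw = df[label_col]
        y = (y_raw.astype(str).isin({"1", "abnormal", "True", "scalper"})).astype(int) \
            if y_raw.dtype == object else y_raw.astype(int)
        feat = df.drop(columns=[label_col, *group_cols])
        groups = df[list(group_cols)] if group_cols else None
        dm = DesignMatrix(X=feat, y=y.to_numpy(), groups=groups,
                          log_columns=(), feature_names=tuple(feat.columns))
        return cls(dm, **kwargs)

    def fit(self) -> "GaussianScalperResults":
        """Estimate per-class means and shrunk covariances.

        Requires both classes present with at least d+2 rows each; raises
        :class:`FittingError` otherwise, or if a covariance stays singular
        after shrinkage.
        """
        Xs = self.data.Xs.to_numpy(dtype=float)
        y = np.asarray(self.data.y, dtype=int)
        d = Xs.shape[1]
        stats = {}
        for cls_val, name in ((1, "scalper"), (0, "legit")):
            sub = Xs[y == cls_val]
            if len(sub) < d + 2:
                raise FittingError(
                    f"class {name!r} has {len(sub)} rows; need >= {d + 2} for a "
                    f"{d}-dimensional Gaussian fit")
            mu = sub.mean(axis=0)
            S = np.cov(sub, rowvar=False, ddof=1)
            stats[name] = (mu, _shrink(S, self.shrinkage), len(sub))
        params = BayesModelParams(
            prior_scalper=self.prior, threshold=self.threshold,
            shrinkage=self.shrinkage,
            mean_scalper=stats["scalper"][0], mean_legit=stats["legit"][0],
            cov_scalper=stats["scalper"][1], cov_legit=stats["legit"][1],
            n_scalper=stats["scalper"][2], n_legit=stats["legit"][2],
            feature_names=tuple(self.data.Xs.columns),
        )
        return GaussianScalperResults(self, params)


def results_from_params(params: BayesModelParams) -> "GaussianScalperResults":
    """Wrap externally specified parameters (no training data attached);
    scoring then requires pre-standardized inputs."""
    return GaussianScalperResults(None, params)


class GaussianScalperResults:
    """Fitted model: posteriors, decisions, updating, and diagnostics."""

    def __init__(self, model: GaussianScalperModel | None, params: BayesModelParams):
        self.model = model
        self.params = params
        self._g_s = _GaussianClass(params.mean_scalper, params.cov_scalper)
        self._g_l = _GaussianClass(params.mean_legit, params.cov_legit)

    # -- uncertainty of the class means (SE = sd/sqrt(n)) --------------------
    @property
    def bse_scalper(self) -> np.ndarray:
        return np.sqrt(np.diag(self.params.cov_scalper) / self.params.n_scalper)

    @property
    def bse_legit(self) -> np.ndarray:
        return np.sqrt(np.diag(self.params.cov_legit) / self.params.n_legit)

    # -- scoring --------------------------------------------------------------

    def _standardize(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return self.model.data.transform(X).to_numpy(dtype=float)
        return np.atleast_2d(np.asarray(X, dtype=float))

    def posterior(self, X, prior: float | None = None,
                  standardized: bool = True) -> np.ndarray:
        """Posterior scalper probability, computed in log space.

        ``X`` may be an already-standardized array (default assumption) or,
        with ``standardized=False``, a natural-unit feature DataFrame which
        is passed through the stored standardization pipeline.
        """
        Z = self._standardize(X) if not standardized else np.atleast_2d(
            np.asarray(X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float))
        pi = self.params.prior_scalper if prior is None else float(prior)
        log_odds = (logit(pi) + self._g_s.logpdf(Z) - self._g_l.logpdf(Z))
        return expit(log_odds)

    def classify(self, X, congestion: float | None = None,
                 gain: float = 2.0, account_ids=None,
                 standardized: bool = True) -> pd.DataFrame:
        """Risk scores: posterior, flag/pass decision, effective prior used.

        When ``congestion`` is supplied the prior is modulated through
        :func:`dynamic_prior`; flagging is inclusive (posterior >= tau).
        """
        pi = self.params.prior_scalper
        if congestion is not None:
            pi = dynamic_prior(pi, congestion, gain)
        post = self.posterior(X, prior=pi, standardized=standardized)
        out = pd.DataFrame({
            "posterior": post,
            "decision": np.where(post >= self.params.threshold, "flag", "pass"),
            "effective_prior": pi,
        })
        if account_ids is not None:
            out.insert(0, "account_id", np.asarray(account_ids))
        elif isinstance(X, pd.DataFrame):
            out.insert(0, "account_id", X.index.to_numpy())
        return out

    # -- closed-loop updating -------------------------------------------------

    def sequential_update(self, new_data: DesignMatrix, mode: str = "window",
                          history: list[DesignMatrix] | None = None,
                          window: int = 4,
                          pseudo_count: float = 200.0) -> "GaussianScalperResults":
        """Iterative updating of the class parameters on a new labeled batch.

        mode="window"
            Refit on the concatenation of the last ``window`` batches
            (``history`` + the new batch); an empty history reduces to a
            plain refit on the original plus new data.
        mode="conjugate"
            Normal–inverse-Wishart step per class with prior strength
            ``pseudo_count`` (kappa0 = n0, nu0 = n0 + d + 1 so the prior
            covariance expectation equals the current estimate);
            ``pseudo_count=inf`` leaves parameters unchanged.

        The prior pi and threshold tau stay fixed in both modes.
        """
        if mode == "window":
            batches = list(history or [self.model.data]) + [new_data]
            batches = batches[-window:]
            X = pd.concat([b.X for b in batches])
            y = np.concatenate([b.y for b in batches])
            base = self.model.data
            dm = DesignMatrix(X=X, y=y, mean_=base.mean_, sd_=base.sd_,
                              log_columns=base.log_columns,
                              feature_names=base.feature_names)
            m = GaussianScalperModel(dm, prior=self.params.prior_scalper,
                                     threshold=self.params.threshold,
                                     shrinkage=self.params.shrinkage)
            return m.fit()
        if mode == "conjugate":
            return self._conjugate_update(new_data, pseudo_count)
        raise ScalpGuardError(f"unknown update mode {mode!r}")

    def _conjugate_update(self, new_data: DesignMatrix,
                          n0: float) -> "GaussianScalperResults":
        p = self.params
        d = len(p.mean_scalper)
        Xs = self.model.data.transform(new_data.X).to_numpy(dtype=float)
        y = np.asarray(new_data.y, dtype=int)
        new = {}
        for cls_val, mu0, S0 in ((1, p.mean_scalper, p.cov_scalper),
                                 (0, p.mean_legit, p.cov_legit)):
            sub = Xs[y == cls_val]
            n = len(sub)
            if n == 0 or not np.isfinite(n0):
                new[cls_val] = (mu0.copy(), S0.copy())
                continue
            xbar = sub.mean(axis=0)
            mu_n = (n0 * mu0 + n * xbar) / (n0 + n)
            scatter = (sub - xbar).T @ (sub - xbar)
            lam0 = n0 * S0  # nu0 = n0 + d + 1 => E[cov prior] = S0
            dm0 = (xbar - mu0)[:, None]
            lam_n = lam0 + scatter + (n0 * n / (n0 + n)) * (dm0 @ dm0.T)
            nu_n = (n0 + d + 1) + n
            new[cls_val] = (mu_n, lam_n / (nu_n - d - 1))
        params = dataclasses.replace(
            p, mean_scalper=new[1][0], cov_scalper=new[1][1],
            mean_legit=new[0][0], cov_legit=new[0][1],
            n_scalper=p.n_scalper + int((y == 1).sum()),
            n_legit=p.n_legit + int((y == 0).sum()))
        return GaussianScalperResults(self.model, params)

    # -- threshold calibration -------------------------------------------------

    def calibrate_threshold(self, X_val, y_val, grid=None,
                            standardized: bool = True) -> pd.DataFrame:
        """Sensitivity/specificity per candidate threshold on held-out data."""
        grid = np.round(np.arange(0.05, 1.0, 0.05), 2) if grid is None else np.asarray(grid)
        post = self.posterior(X_val, standardized=standardized)
        y = np.asarray(y_val, dtype=int)
        rows = []
        for tau in grid:
            pred = (post >= tau).astype(int)
            tp = int(((pred == 1) & (y == 1)).sum())
            fn = int(((pred == 0) & (y == 1)).sum())
            tn = int(((pred == 0) & (y == 0)).sum())
            fp = int(((pred == 1) & (y == 0)).sum())
            rows.append({
                "threshold": float(tau),
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
                "flag_rate": (tp + fp) / len(y),
            })
        return pd.DataFrame(rows)

    # -- reporting -------------------------------------------------------------

    def summary(self) -> str:
        p = self.params
        lines = [
            "Gaussian class-conditional Bayes scalper model",
            "=" * 54,
            f"prior P(scalper)          {p.prior_scalper:10.4f}  (fixed, not estimated)",
            f"decision threshold tau    {p.threshold:10.4f}  (flag at posterior >= tau)",
            f"covariance shrinkage      {p.shrinkage:10.4f}",
            f"n (scalper / legit)       {p.n_scalper:6d} / {p.n_legit}",
            "",
            f"{'feature':<22}{'mu_scalper':>12}{'se':>9}{'mu_legit':>12}{'se':>9}",
            "-" * 64,
        ]
        ses, sel = self.bse_scalper, self.bse_legit
        for i, name in enumerate(p.feature_names):
            lines.append(
                f"{name:<22}{p.mean_scalper[i]:>12.4f}{ses[i]:>9.4f}"
                f"{p.mean_legit[i]:>12.4f}{sel[i]:>9.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        p = self.params
        return (f"<GaussianScalperResults d={len(p.mean_scalper)} "
                f"n_scalper={p.n_scalper} n_legit={p.n_legit} "
                f"pi={p.prior_scalper} tau={p.threshold}>")
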