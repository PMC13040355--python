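"""Pre/post evaluation statistics: contingency tests, effect sizes, trend
test, risk ratio, bootstrap CIs, interrupted time series, confusion/ROC
metrics, Equal Opportunity fairness, and cross-validation.

Conventions: Pearson chi-square without continuity correction; Cochran–
Armitage trend test with equally spaced default scores; Katz log-Wald CI
for the risk ratio; pooled-variance (n−1) Cohen's d; record-level
percentile bootstrap; segmented OLS for the interrupted time series; AUC by
the Mann–Whitney rank statistic with ties counted half.  Tests are
two-sided and p-values are reported raw (no multiplicity adjustment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .errors import ScalpGuardError
from .features import DesignMatrix


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    effect_size: float | None = None
    effect_size_name: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ScalpGuardError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class RiskRatioResult:
    rr: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "katz-log-wald"

    def __post_init__(self):
        if not (0 < self.ci_low <= self.rr <= self.ci_high):
            raise ScalpGuardError(
                f"inconsistent RR CI: {self.ci_low} <= {self.rr} <= {self.ci_high} fails")


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    resample_mean: float
    ci_low: float
    ci_high: float
    level: float
    B: int
    seed: int | None


@dataclass(frozen=True)
class ITSResult:
    """Segmented-regression coefficients.

    beta0 baseline level; beta1 baseline slope per time unit; beta2 level
    change at the intervention; beta3 slope change after it.
    """
    params: np.ndarray            # (beta0..beta3)
    bse: np.ndarray
    p_values: np.ndarray
    durbin_watson: float
    nobs: int

    @property
    def level_change(self) -> float:
        return float(self.params[2])

    @property
    def slope_change(self) -> float:
        return float(self.params[3])


@dataclass(frozen=True)
class ConfusionMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float | None = None

    def __post_init__(self):
        for name in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ScalpGuardError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class FairnessReport:
    tpr_by_group: dict
    gap: float
    groups_used: tuple
    warnings: tuple = ()


# ---------------------------------------------------------------------------
# contingency statistics
# ---------------------------------------------------------------------------

def chi_square_test(table) -> TestResult:
    """Pearson chi-square (no continuity correction) with Cramer's V.

    ``table`` is an r x k count array/DataFrame; a zero row or column margin
    is degenerate and raises; expected cells below 5 draw a warning.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.min() < 0 or obs.sum() <= 0:
        raise ScalpGuardError("table must be a nonnegative 2-D count array with total > 0")
    row, col = obs.sum(axis=1), obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ScalpGuardError("degenerate table: a zero row/column margin")
    n = obs.sum()
    expected = np.outer(row, col) / n
    if (expected < 5).any():
        warnings.warn("expected cell count below 5; chi-square approximation is weak")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    r, k = obs.shape
    df = (r - 1) * (k - 1)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    v = float(np.sqrt(chi2 / (n * (min(r, k) - 1)))) if min(r, k) > 1 else 0.0
    return TestResult(chi2, df, p, effect_size=v, effect_size_name="cramers_v")


def trend_test(successes, totals, scores=None) -> TestResult:
    """Cochran–Armitage linear-by-linear trend Z (positive = rising rate)."""
    x = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if len(x) != len(n) or len(x) < 2:
        raise ScalpGuardError("need >= 2 equal-length groups")
    if (x > n).any() or (x < 0).any():
        raise ScalpGuardError("successes must satisfy 0 <= successes <= totals")
    s = np.arange(len(x), dtype=float) if scores is None else np.asarray(scores, dtype=float)
    N, pbar = n.sum(), x.sum() / n.sum()
    num = float(np.sum(s * (x - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n * s ** 2) - np.sum(n * s) ** 2 / N)
    if var <= 0:
        return TestResult(0.0, None, 1.0)
    z = num / np.sqrt(var)
    return TestResult(float(z), None, float(2 * sps.norm.sf(abs(z))))


def risk_ratio(events1: int, n1: int, events2: int, n2: int,
               level: float = 0.95) -> RiskRatioResult:
    """RR of group 2 vs group 1 with the Katz log-Wald CI."""
    if min(events1, events2) <= 0 or min(n1, n2) <= 0:
        raise ScalpGuardError(
            "all counts must be positive for the Katz CI; consider adding a "
            "0.5 continuity correction to zero cells")
    p1, p2 = events1 / n1, events2 / n2
    rr = p2 / p1
    se = np.sqrt((1 - p1) / (n1 * p1) + (1 - p2) / (n2 * p2))
    z = sps.norm.ppf(0.5 + level / 2)
    return RiskRatioResult(rr, float(rr * np.exp(-z * se)), float(rr * np.exp(z * se)),
                           level=level)


def cohens_d(x, y) -> float:
    """Two-sample Cohen's d with the pooled-variance (n−1) convention."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ScalpGuardError("each sample needs length >= 2")
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 <= 0:
        raise ScalpGuardError("pooled SD is zero")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


# ---------------------------------------------------------------------------
# resampling and time series
# ---------------------------------------------------------------------------

def bootstrap_ci(records, statistic, B: int = 1000, level: float = 0.95,
                 seed: int | None = None) -> BootstrapResult:
    """Record-level percentile bootstrap of ``statistic(records)``.

    ``records`` may be an array or DataFrame; resampling draws rows with
    replacement.  Deterministic for a given seed.
    """
    if B < 1:
        raise ScalpGuardError("B must be >= 1")
    is_frame = isinstance(records, pd.DataFrame)
    n = len(records)
    if n < 2:
        raise ScalpGuardError("need >= 2 records")
    rng = np.random.default_rng(seed)
    arr = records if is_frame else np.asarray(records)
    est = float(statistic(arr))
    reps = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        reps[b] = statistic(arr.iloc[idx] if is_frame else arr[idx])
    alpha = 1.0 - level
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return BootstrapResult(est, float(reps.mean()), float(lo), float(hi),
                           level, B, seed)


def its_fit(y, t=None, intervention_time=None) -> ITSResult:
    """Interrupted time series via segmented OLS.

    Model: ``y_t = b0 + b1 t + b2 post_t + b3 (t - t0) post_t + e`` with
    ``post_t = 1[t >= t0]``.  ``y`` may be a Series (index as time) or an
    array with explicit ``t``.  Requires at least 3 points on each side.
    """
    if isinstance(y, pd.Series):
        t = np.asarray(y.index, dtype=float) if t is None else np.asarray(t, dtype=float)
        y = y.to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
        t = np.arange(len(y), dtype=float) if t is None else np.asarray(t, dtype=float)
    if intervention_time is None:
        raise ScalpGuardError("intervention_time is required")
    t0 = float(intervention_time)
    post = (t >= t0).astype(float)
    if post.sum() < 3 or (1 - post).sum() < 3:
        raise ScalpGuardError("need >= 3 points on each side of the intervention")
    X = sm.add_constant(np.column_stack([t, post, (t - t0) * post]))
    fit = sm.OLS(y, X).fit()
    return ITSResult(params=np.asarray(fit.params), bse=np.asarray(fit.bse),
                     p_values=np.asarray(fit.pvalues),
                     durbin_watson=float(durbin_watson(fit.resid)), nobs=len(y))


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

def auc_rank(labels, scores) -> float:
    """AUC as the Mann–Whitney rank statistic (ties counted half)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ScalpGuardError("AUC undefined: labels contain a single class")
    ranks = sps.rankdata(s)  # average ranks handle ties
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def confusion_metrics(labels, predictions, scores=None) -> ConfusionMetrics:
    """Standard confusion metrics; AUC only when scores are supplied.

    With single-class labels the AUC is undefined: it is reported as None
    with a warning while the other metrics are still returned.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if len(y) != len(p):
        raise ScalpGuardError("labels and predictions differ in length")
    tp = int(((p == 1) & (y == 1)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    n = len(y)
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) and not np.isnan(prec + sens) \
        else (np.nan if np.isnan(prec + sens) else 0.0)
    auc = None
    if scores is not None:
        try:
            auc = auc_rank(y, scores)
        except ScalpGuardError as e:
            warnings.warn(str(e))
    return ConfusionMetrics(accuracy=(tp + tn) / n, sensitivity=sens,
                            specificity=spec, precision=prec, f1=f1, auc=auc)


def equal_opportunity_gap(labels, predictions, groups) -> FairnessReport:
    """True-positive-rate parity across protected groups.

    TPR is computed among true positives per group; groups without a
    positive label are excluded and listed in the report's warnings.  The
    gap is max TPR − min TPR over included groups.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    g = np.asarray(groups)
    tprs, warns = {}, []
    for grp in pd.unique(g):
        mask = (g == grp) & (y == 1)
        if mask.sum() == 0:
            warns.append(f"group {grp!r} has no positive labels; excluded")
            continue
        tprs[grp] = float(p[mask].mean())
    if not tprs:
        raise ScalpGuardError("no group has a positive label")
    vals = np.array(list(tprs.values()))
    return FairnessReport(tpr_by_group=tprs, gap=float(vals.max() - vals.min()),
                          groups_used=tuple(tprs), warnings=tuple(warns))


# ---------------------------------------------------------------------------
# cross-validation of the risk model
# ---------------------------------------------------------------------------

def cross_validate(dm: DesignMatrix, protocol: str = "stratified_kfold",
                   k: int = 10, test_size: float = 0.3, repeats: int = 10,
                   seed: int | None = None, model_kwargs: dict | None = None):
    """Cross-validated confusion metrics of the Gaussian risk model.

    Two protocols are offered: stratified k-fold (default k=10) and
    repeated stratified 70/30 splits.  Returns ``(per_fold, aggregate)``
    where ``per_fold`` is a list of :class:`ConfusionMetrics` and
    ``aggregate`` a dict of means across folds.
    """
    from .model import GaussianScalperModel  # local import avoids a cycle

    y = np.asarray(dm.y, dtype=int)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ScalpGuardError("a class is too small to stratify")
    if protocol == "stratified_kfold":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(dm.X, y)
    elif protocol == "repeated_split":
        splitter = StratifiedShuffleSplit(n_splits=repeats, test_size=test_size,
                                          random_state=seed)
        splits = splitter.split(dm.X, y)
    else:
        raise ScalpGuardError(f"unknown protocol {protocol!r}")

    kwargs = model_kwargs or {}
    per_fold = []
    for train_idx, test_idx in splits:
        dtrain = DesignMatrix(X=dm.X.iloc[train_idx], y=y[train_idx],
                              log_columns=dm.log_columns,
                              feature_names=dm.feature_names)
        res = GaussianScalperModel(dtrain, **kwargs).fit()
        Z = dtrain.transform(dm.X.iloc[test_idx])
        post = res.posterior(Z)
        pred = (post >= res.params.threshold).astype(int)
        per_fold.append(confusion_metrics(y[test_idx], pred, scores=post))
    agg = {
        name: float(np.nanmean([getattr(m, name) for m in per_fold
                                if getattr(m, name) is not None]))
        for name in ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc")
    }
    return per_fold, agg
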