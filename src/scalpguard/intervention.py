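"""Closed-loop intervention layer and the end-to-end pre/post experiment.

Flagged accounts receive graduated interventions: posteriors in the
``verify`` band trigger an SMS-style challenge-response (legitimate users
almost always pass and continue unhindered — the false-positive rescue),
posteriors in the ``restrict`` band trigger a temporary booking
restriction.  The full experiment generates a pre/post registration
stream, trains the risk model on the audited pre period, deploys it over
the post period in review cycles with queue-congestion-driven dynamic
priors, applies the policy, materializes outcome tables, and runs the
evaluation suite.  Everything is a pure function of (configs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import LabelingConfig, SimulationConfig
from .errors import ConfigurationError, ScalpGuardError
from .evaluation import (
    BootstrapResult, ConfusionMetrics, FairnessReport, ITSResult,
    RiskRatioResult, TestResult, chi_square_test, cohens_d, cross_validate,
    equal_opportunity_gap, its_fit, risk_ratio, trend_test,
)
from .features import build_design_matrix, compute_feature_frame
from .labeling import label_accounts
from .model import GaussianScalperModel, GaussianScalperResults
from .queuing import congestion_index
from .simulate import cohort_frame, simulate


# ---------------------------------------------------------------------------
# policy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterventionPolicy:
    """Graduated intervention bands over the posterior scale.

    ``verify_band`` and ``restrict_band`` are half-open [lo, hi) intervals
    (the restrict band is closed at 1); they must be disjoint, ordered and
    lie within [tau, 1].  ``none()`` builds an empty policy (no actions),
    useful for null experiments.
    """

    verify_band: tuple[float, float] | None = (0.75, 0.90)
    restrict_band: tuple[float, float] | None = (0.90, 1.0)
    challenge_pass_prob_legit: float = 0.98
    challenge_pass_prob_scalper: float = 0.05
    restriction_duration_h: float = 1080.0

    def __post_init__(self):
        for name in ("challenge_pass_prob_legit", "challenge_pass_prob_scalper"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(name, f"must be in [0, 1], got {v}")
        if self.restriction_duration_h <= 0:
            raise ConfigurationError("restriction_duration_h", "must be > 0")
        bands = [b for b in (self.verify_band, self.restrict_band) if b is not None]
        for lo, hi in bands:
            if not 0.0 <= lo < hi <= 1.0:
                raise ConfigurationError("bands", f"band ({lo}, {hi}) is not ordered within [0, 1]")
        if self.verify_band and self.restrict_band:
            vlo, vhi = self.verify_band
            rlo, rhi = self.restrict_band
            if vhi > rlo:
                raise ConfigurationError(
                    "bands", f"verify {self.verify_band} overlaps restrict {self.restrict_band}")

    @classmethod
    def none(cls) -> "InterventionPolicy":
        return cls(verify_band=None, restrict_band=None)

    @property
    def is_empty(self) -> bool:
        return self.verify_band is None and self.restrict_band is None


def apply_policy(scores: pd.DataFrame, policy: InterventionPolicy) -> pd.DataFrame:
    """Map risk scores to actions {none, verify, restrict} by band lookup."""
    post = scores["posterior"].to_numpy(dtype=float)
    action = np.full(len(scores), "none", dtype=object)
    if policy.verify_band is not None:
        lo, hi = policy.verify_band
        action[(post >= lo) & (post < hi)] = "verify"
    if policy.restrict_band is not None:
        lo, hi = policy.restrict_band
        in_band = (post >= lo) & ((post < hi) | (hi >= 1.0) & (post <= 1.0))
        action[in_band] = "restrict"
    out = scores.copy()
    out["action"] = action
    return out


def resolve_challenges(action_log: pd.DataFrame, cohort_classes: pd.Series,
                       policy: InterventionPolicy,
                       seed: int | None = None) -> pd.DataFrame:
    """Resolve ``verify`` actions with a class-specific Bernoulli challenge.

    Passing accounts revert to unhindered status (``cleared``); failing or
    restricted accounts end ``blocked``.  ``cohort_classes`` maps
    account_id -> latent class, used only to pick the pass probability (a
    scalper bot cannot answer the SMS challenge; a patient nearly always
    can).  Seeded and deterministic.
    """
    rng = np.random.default_rng(seed)
    out = action_log.copy()
    is_scalper = out["account_id"].map(cohort_classes).eq("scalper").to_numpy()
    p_pass = np.where(is_scalper, policy.challenge_pass_prob_scalper,
                      policy.challenge_pass_prob_legit)
    u = rng.random(len(out))
    verify = (out["action"] == "verify").to_numpy()
    passed = verify & (u < p_pass)
    out["challenge_passed"] = pd.array(
        np.where(verify, passed, None), dtype="boolean")
    out["final_status"] = np.select(
        [out["action"] == "restrict", verify & ~passed, verify & passed],
        ["blocked", "blocked", "cleared"], default="none")
    return out


# ---------------------------------------------------------------------------
# outcome bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class OutcomeTable:
    """Materialized booking outcomes for one period."""

    period: str
    bookings: int
    completions: int
    cancels: int
    no_shows: int
    flagged_accounts: int = 0
    blocked_bookings: int = 0
    wrongly_flagged_legit: int = 0
    first_time_share: float = float("nan")
    channel_shares: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.completions + self.cancels + self.no_shows != self.bookings:
            raise ScalpGuardError(
                f"{self.period}: completions+cancels+no_shows = "
                f"{self.completions + self.cancels + self.no_shows} != bookings {self.bookings}")

    @property
    def completion_rate(self) -> float:
        """Completed / (completed + no-show), the completed/no-show dichotomy."""
        kept = self.completions + self.no_shows
        return self.completions / kept if kept else float("nan")

    @property
    def no_show_rate(self) -> float:
        kept = self.completions + self.no_shows
        return self.no_shows / kept if kept else float("nan")


def _materialize(books: pd.DataFrame, resolutions: pd.DataFrame, period: str,
                 first_seen: pd.Series, **extra) -> OutcomeTable:
    res = resolutions[resolutions["ref_event_id"].isin(books["event_id"])]
    counts = res["action"].value_counts()
    accounts = books["account_id"]
    if len(books):
        t_min = books["timestamp"].min()
        first = accounts.map(first_seen)
        first_share = float((first >= t_min).mean())
        chan = (books["channel"].value_counts(normalize=True)).to_dict()
    else:
        first_share, chan = float("nan"), {}
    return OutcomeTable(
        period=period, bookings=int(len(books)),
        completions=int(counts.get("complete", 0)),
        cancels=int(counts.get("cancel", 0)),
        no_shows=int(counts.get("no_show", 0)),
        first_time_share=first_share, channel_shares=chan, **extra)


# ---------------------------------------------------------------------------
# evaluation report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """All pre/post statistics computed by the experiment."""

    chi_square: TestResult
    trend: TestResult
    rr_completion: RiskRatioResult
    cohens_d_monthly: float
    its: ITSResult
    bootstrap_completion: BootstrapResult
    cv_aggregate: dict
    cv_per_fold: list
    fairness_age: FairnessReport
    fairness_socio: FairnessReport
    monthly_rates: pd.Series
    completion_change_pp: float
    flagged_booking_drop_pct: float
    legit_flagged_pct: float

    def to_dict(self) -> dict:
        return {
            "chi_square": {"statistic": self.chi_square.statistic,
                           "df": self.chi_square.df, "p": self.chi_square.p_value,
                           "cramers_v": self.chi_square.effect_size},
            "trend_z": self.trend.statistic,
            "rr_completion": {"rr": self.rr_completion.rr,
                              "ci": [self.rr_completion.ci_low, self.rr_completion.ci_high]},
            "cohens_d_monthly": self.cohens_d_monthly,
            "its": {"level_change": self.its.level_change,
                    "slope_change": self.its.slope_change,
                    "durbin_watson": self.its.durbin_watson},
            "bootstrap_completion_pp": {
                "estimate": self.bootstrap_completion.estimate,
                "ci": [self.bootstrap_completion.ci_low, self.bootstrap_completion.ci_high]},
            "cv": self.cv_aggregate,
            "fairness": {"age_gap": self.fairness_age.gap,
                         "socio_gap": self.fairness_socio.gap},
            "completion_change_pp": self.completion_change_pp,
            "flagged_booking_drop_pct": self.flagged_booking_drop_pct,
            "legit_flagged_pct": self.legit_flagged_pct,
        }


@dataclass
class ExperimentResult:
    config: SimulationConfig
    policy: InterventionPolicy
    outcome_pre: OutcomeTable
    outcome_post: OutcomeTable
    report: EvaluationReport
    model_results: GaussianScalperResults
    action_log: pd.DataFrame
    flagged_accounts: tuple
    seed: int

    def summary(self) -> str:
        pre, post = self.outcome_pre, self.outcome_post
        r = self.report
        lines = [
            "Pre/post intervention experiment",
            "=" * 60,
            f"{'':<26}{'pre':>14}{'post':>14}",
            f"{'materialized bookings':<26}{pre.bookings:>14}{post.bookings:>14}",
            f"{'completion rate':<26}{pre.completion_rate:>14.3f}{post.completion_rate:>14.3f}",
            f"{'no-show rate':<26}{pre.no_show_rate:>14.3f}{post.no_show_rate:>14.3f}",
            f"{'blocked bookings':<26}{pre.blocked_bookings:>14}{post.blocked_bookings:>14}",
            "",
            f"completion change         {r.completion_change_pp:+.1f} pp",
            f"chi-square                {r.chi_square.statistic:.2f} (p={r.chi_square.p_value:.2g}, "
            f"V={r.chi_square.effect_size:.3f})",
            f"RR (post vs pre)          {r.rr_completion.rr:.3f} "
            f"[{r.rr_completion.ci_low:.3f}, {r.rr_completion.ci_high:.3f}]",
            f"trend Z                   {r.trend.statistic:.2f}",
            f"ITS level change          {r.its.level_change:+.4f} "
            f"(slope change {r.its.slope_change:+.5f}/month)",
            f"bootstrap completion gain {r.bootstrap_completion.estimate:+.2f} pp "
            f"[{r.bootstrap_completion.ci_low:+.2f}, {r.bootstrap_completion.ci_high:+.2f}]",
            f"CV AUC                    {r.cv_aggregate.get('auc', float('nan')):.3f}",
            f"flagged-account bookings  {r.flagged_booking_drop_pct:.1f}% drop post",
            f"legitimate users flagged  {r.legit_flagged_pct:.2f}%",
            f"equal-opportunity gap     age {r.fairness_age.gap:.3f} / "
            f"socio {r.fairness_socio.gap:.3f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    prior: float = 0.05
    threshold: float = 0.75
    shrinkage: float = 0.10
    dynamic_prior_gain: float = 2.0
    use_dynamic_prior: bool = True
    queue_servers: int = 20
    queue_service_rate: float = 1.0   # per hour per server
    n_review_cycles: int = 4


@dataclass(frozen=True)
class EvalConfig:
    bootstrap_B: int = 1000
    cv_folds: int = 10
    cv_protocol: str = "stratified_kfold"
    level: float = 0.95


# ---------------------------------------------------------------------------
# the experiment
# ---------------------------------------------------------------------------

def run_experiment(sim_config: SimulationConfig,
                   model_config: ModelConfig = ModelConfig(),
                   policy: InterventionPolicy = InterventionPolicy(),
                   eval_config: EvalConfig = EvalConfig(),
                   seed: int | None = None) -> ExperimentResult:
    """Generate, train, deploy, intervene, materialize and evaluate.

    Stages (failures are re-raised with the stage name):

    1. simulate the full-period stream;
    2. label the pre period with the two-of-three rule ("audited" labels);
    3. build the pre design matrix and fit the Gaussian risk model;
    4. deploy over the post period in review cycles: behavioral features
       accumulated within the post period, congestion-modulated prior,
       policy actions, challenge rescue, booking restrictions;
    5. materialize outcome tables (blocked bookings never materialize);
    6. run the evaluation suite.
    """
    seed = sim_config.seed if seed is None else seed
    ss = np.random.SeedSequence((seed, 77))
    child = ss.spawn(4)

    stage = "simulate"
    try:
        cohort, events = simulate(sim_config, seed=seed)
        classes = pd.Series({a.account_id: a.latent_class for a in cohort})
        cf = cohort_frame(cohort).set_index("account_id")
        t_interv = sim_config.intervention_dt
        is_book = events["action"] == "book"
        books = events[is_book]
        resolutions = events[~is_book]
        first_seen = books.groupby("account_id")["timestamp"].min()
        pre_events = events[events["timestamp"] < pd.Timestamp(t_interv)]

        stage = "label"
        labels = label_accounts(pre_events, LabelingConfig(),
                                label_noise=sim_config.label_noise,
                                seed=int(child[0].generate_state(1)[0] % (2**31)))

        stage = "features/fit"
        dm = build_design_matrix(pre_events, labels,
                                 groups=cf[["age_band", "socio_band", "latent_class"]])
        results = GaussianScalperModel(
            dm, prior=model_config.prior, threshold=model_config.threshold,
            shrinkage=model_config.shrinkage).fit()

        stage = "deploy"
        deploy = _deploy_post_period(events, results, dm, sim_config,
                                     model_config, policy, classes,
                                     rng_seed=int(child[1].generate_state(1)[0] % (2**31)))

        stage = "materialize"
        pre_books = books[books["timestamp"] < pd.Timestamp(t_interv)]
        post_books_all = books[books["timestamp"] >= pd.Timestamp(t_interv)]
        post_books = post_books_all[~post_books_all["event_id"].isin(deploy["blocked_book_ids"])]
        legit_accounts_post = set(post_books_all["account_id"]) & set(classes.index[classes == "legitimate"])
        wrong = deploy["flagged"] & set(classes.index[classes == "legitimate"])
        outcome_pre = _materialize(pre_books, resolutions, "pre", first_seen)
        outcome_post = _materialize(
            post_books, resolutions, "post", first_seen,
            flagged_accounts=len(deploy["flagged"]),
            blocked_bookings=int(len(post_books_all) - len(post_books)),
            wrongly_flagged_legit=len(wrong))

        stage = "evaluate"
        report = _evaluate(sim_config, eval_config, dm, results, cf,
                           pre_books, post_books, resolutions,
                           outcome_pre, outcome_post, deploy,
                           pre_books_flagged=pre_books[
                               pre_books["account_id"].isin(deploy["flagged"])],
                           post_books_flagged=post_books[
                               post_books["account_id"].isin(deploy["flagged"])],
                           legit_flagged_pct=(100.0 * len(wrong) / max(len(legit_accounts_post), 1)),
                           seed=int(child[2].generate_state(1)[0] % (2**31)))
    except Exception as e:
        raise ScalpGuardError(f"experiment stage {stage!r} failed: {e}") from e

    return ExperimentResult(
        config=sim_config, policy=policy,
        outcome_pre=outcome_pre, outcome_post=outcome_post,
        report=report, model_results=results,
        action_log=deploy["action_log"],
        flagged_accounts=tuple(sorted(deploy["flagged"])), seed=seed)


def _deploy_post_period(events, results, dm, sim_config, model_config,
                        policy, classes, rng_seed) -> dict:
    """Review-cycle deployment: score, act, restrict; returns bookkeeping."""
    t0 = pd.Timestamp(sim_config.intervention_dt)
    t_end = pd.Timestamp(sim_config.end_dt)
    n_cycles = model_config.n_review_cycles
    bounds = pd.date_range(t0, t_end, periods=n_cycles + 1)
    post = events[events["timestamp"] >= t0]

    blocked_until: dict[str, pd.Timestamp] = {}
    blocked_book_ids: set = set()
    flagged: set = set()
    logs = []
    rng_children = np.random.SeedSequence(rng_seed).spawn(n_cycles)

    empty_log = pd.DataFrame(columns=["cycle", "account_id", "posterior",
                                      "decision", "effective_prior", "action",
                                      "challenge_passed", "final_status"])
    if policy.is_empty:
        return {"blocked_book_ids": blocked_book_ids, "flagged": flagged,
                "action_log": empty_log}

    for i in range(n_cycles):
        lo, hi = bounds[i], bounds[i + 1]
        cyc = post[(post["timestamp"] >= lo) & (post["timestamp"] < hi)]
        # restrictions: bookings by blocked accounts never materialize
        if blocked_until:
            bu = cyc["account_id"].map(blocked_until)
            is_blocked = bu.notna() & (cyc["timestamp"] < bu)
            cyc_books = cyc[(cyc["action"] == "book")]
            blocked_book_ids |= set(cyc_books.loc[is_blocked[cyc_books.index], "event_id"])

        # observable history over a trailing window matching the training
        # window width, so behavioral summaries are stationary between
        # training and deployment (suppressed bookings and their resolutions
        # never happened, so they are excluded)
        win_lo = hi - pd.Timedelta(days=sim_config.pre_days)
        seen = events[(events["timestamp"] >= win_lo) & (events["timestamp"] < hi)]
        seen = seen[~(seen["event_id"].isin(blocked_book_ids)
                      | seen["ref_event_id"].isin(blocked_book_ids))]
        if len(seen) == 0:
            continue
        feats = compute_feature_frame(seen)

        cycle_hours = (hi - lo).total_seconds() / 3600.0
        lam = (seen[(seen["action"] == "book")
                    & (seen["timestamp"] >= lo)].shape[0]) / cycle_hours
        rho = lam / (model_config.queue_servers * model_config.queue_service_rate)
        cong = congestion_index(rho) if model_config.use_dynamic_prior else None

        scores = results.classify(dm.transform(feats),
                                  congestion=cong,
                                  gain=model_config.dynamic_prior_gain,
                                  account_ids=feats.index.to_numpy())
        actions = apply_policy(scores, policy)
        resolved = resolve_challenges(
            actions, classes, policy,
            seed=int(rng_children[i].generate_state(1)[0] % (2**31)))
        resolved.insert(0, "cycle", i)
        logs.append(resolved)

        flagged |= set(resolved.loc[resolved["decision"] == "flag", "account_id"])
        newly_blocked = resolved.loc[resolved["final_status"] == "blocked", "account_id"]
        release = hi + pd.Timedelta(hours=policy.restriction_duration_h)
        for acct in newly_blocked:
            cur = blocked_until.get(acct)
            blocked_until[acct] = max(cur, release) if cur is not None else release

    action_log = pd.concat(logs, ignore_index=True) if logs else empty_log
    return {"blocked_book_ids": blocked_book_ids, "flagged": flagged,
            "action_log": action_log}


def _monthly_completion(books, resolutions, start) -> tuple[pd.Series, pd.Series, pd.Series]:
    res = resolutions[resolutions["ref_event_id"].isin(books["event_id"])]
    res = res[res["action"].isin(["complete", "no_show"])]
    book_time = books.set_index("event_id")["timestamp"]
    secs = (book_time.loc[res["ref_event_id"]] - pd.Timestamp(start)).dt.total_seconds()
    month = (secs.to_numpy() / (30 * 86400.0)).astype(int)
    ok = (res["action"] == "complete").to_numpy()
    g = pd.DataFrame({"month": month, "ok": ok}).groupby("month")["ok"]
    return g.mean(), g.sum(), g.size()


def _evaluate(sim_config, eval_config, dm, results, cf, pre_books, post_books,
              resolutions, outcome_pre, outcome_post, deploy,
              pre_books_flagged, post_books_flagged, legit_flagged_pct,
              seed) -> EvaluationReport:
    books = pd.concat([pre_books, post_books])
    rates, succ, tot = _monthly_completion(books, resolutions, sim_config.start_dt)
    months_pre = int(round(sim_config.pre_days / 30.0))
    pre_rates = rates[rates.index < months_pre]
    post_rates = rates[rates.index >= months_pre]

    chi = chi_square_test([[outcome_pre.completions, outcome_pre.no_shows],
                           [outcome_post.completions, outcome_post.no_shows]])
    rr = risk_ratio(outcome_pre.completions,
                    outcome_pre.completions + outcome_pre.no_shows,
                    outcome_post.completions,
                    outcome_post.completions + outcome_post.no_shows,
                    level=eval_config.level)
    trend = trend_test(succ.to_numpy(), tot.to_numpy())
    d = cohens_d(post_rates.to_numpy(), pre_rates.to_numpy())
    its = its_fit(rates, intervention_time=months_pre)

    # record-level bootstrap of the completion-rate difference (pp)
    kept = resolutions[resolutions["action"].isin(["complete", "no_show"])]
    kept = kept[kept["ref_event_id"].isin(books["event_id"])]
    post_ids = set(post_books["event_id"])
    rec = np.column_stack([
        kept["ref_event_id"].isin(post_ids).to_numpy(dtype=float),
        (kept["action"] == "complete").to_numpy(dtype=float)])

    def _diff_pp(a):
        is_post, ok = a[:, 0].astype(bool), a[:, 1]
        return 100.0 * (ok[is_post].mean() - ok[~is_post].mean())

    from .evaluation import bootstrap_ci
    boot = bootstrap_ci(rec, _diff_pp, B=eval_config.bootstrap_B,
                        level=eval_config.level, seed=seed)

    per_fold, agg = cross_validate(dm, protocol=eval_config.cv_protocol,
                                   k=eval_config.cv_folds, seed=seed,
                                   model_kwargs={
                                       "prior": results.params.prior_scalper,
                                       "threshold": results.params.threshold,
                                       "shrinkage": results.params.shrinkage})

    # fairness: TPR parity of the deployed model on the training cohort
    post_hat = results.posterior(dm.Xs.to_numpy())
    pred = (post_hat >= results.params.threshold).astype(int)
    grp = dm.groups.reindex(dm.account_ids)
    fair_age = equal_opportunity_gap(dm.y, pred, grp["age_band"].to_numpy())
    fair_socio = equal_opportunity_gap(dm.y, pred, grp["socio_band"].to_numpy())

    pre_rate_f = len(pre_books_flagged) / max(sim_config.pre_days, 1e-9)
    post_rate_f = len(post_books_flagged) / max(sim_config.post_days, 1e-9)
    drop = (100.0 * (1.0 - post_rate_f / pre_rate_f)) if pre_rate_f > 0 else float("nan")

    return EvaluationReport(
        chi_square=chi, trend=trend, rr_completion=rr, cohens_d_monthly=d,
        its=its, bootstrap_completion=boot, cv_aggregate=agg, cv_per_fold=per_fold,
        fairness_age=fair_age, fairness_socio=fair_socio, monthly_rates=rates,
        completion_change_pp=100.0 * (outcome_post.completion_rate
                                      - outcome_pre.completion_rate),
        flagged_booking_drop_pct=drop, legit_flagged_pct=legit_flagged_pct)
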