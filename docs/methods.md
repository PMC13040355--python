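# Methods

## The detection model

An account's behavior over an observation window is summarized by a feature
vector `x` (12 named variables, 13 matrix columns once the circular booking
hour is expanded to sin/cos).  Conditional on the latent class
(scalper / legitimate), `x` is modeled as multivariate Gaussian; the
posterior scalper probability is

    P(scalper | x) = π g_s(x) / (π g_s(x) + (1 − π) g_l(x)),

computed in log space via Cholesky factors.  Decisions flag an account at
posterior ≥ τ (inclusive at the boundary).

Key parameters, defaults, and rationale:

| parameter | default | meaning |
|---|---|---|
| π (prior) | 0.05 | audited baseline scalper prevalence; **fixed**, never re-estimated from training prevalence, so flagging is calibrated to the historical base rate rather than the sample |
| τ (threshold) | 0.75 | posterior cut; at π = 0.05 this corresponds to a likelihood ratio of exactly 57, a precision-first operating point; a `calibrate_threshold` sweep reports sensitivity/specificity per candidate τ |
| λ_reg (shrinkage) | 0.10 | covariance shrunk toward its diagonal, (1−λ)Σ + λ diag Σ; the scalper class is small (~5% of accounts), so the full MLE covariance is unstable |
| ridge floor | 1e-6·I | keeps the fit well-posed when a feature is constant within one class (every scalper books online, so the online-share column has zero scalper-class variance) |
| γ (dynamic-prior gain) | 2.0 | logit(π′) = logit(π) + γ(congestion − ½): congestion 0.5 is neutral, full congestion roughly e^1-folds the prior odds |

Duration-like features (inter-operation interval, minimum operation time,
session duration) are log1p-transformed before standardization because
they are strongly right-skewed; standardization parameters are frozen on
training data and reused verbatim at scoring time.

Degenerate inputs: a single-operation account receives the configured
inter-operation cap (86,400 s) instead of an undefined interval, and a
one-event session's duration is its operation time, keeping the Gaussian
model total-data.

## Ground-truth labeling

An account is *abnormal* when ≥ 2 of 3 criteria hold.  Interpretation
choices, each config-exposed:

* **"Faster than the 99th percentile of manual operation times"** is read
  as the *fast tail*: a cut below which only the fastest 1% of reference
  operations fall, with the fixed 2 s threshold as the documented default.
  (The literal 99th percentile of a right-skewed duration distribution is a
  slow value; only the fast-tail reading makes "< 2 s" an example of the
  rule.)
* **48 h windows are sliding intervals** (closed left, open right), not
  calendar buckets, and are duration-based so time zones and DST are
  irrelevant (all timestamps are UTC).
* **Strict inequalities**: 4+ cancels, 6+ cards.
* **Device→account attribution**: a fan-out flag on a device marks every
  account that used it, since the criterion is per device but labels are
  per account.
* An optional label-noise flip (default 0) emulates audit error in the
  manually verified training labels.

## What the generator emulates — and what it does not

The generator reproduces the statistical structure the analysis assumes:
Bernoulli(0.05) scalper assignment; cohort-wide Poisson booking arrivals
(uniform given the count) attributed to accounts with a 6× activity weight
on scalpers; scalper bookings re-clustered into automated runs of 8 inside
2 h anchored at the 07:00 slot release; sub-second lognormal operation
times (median 0.8 s, σ 0.5) against a 25 s legitimate median, so the 2 s
rule and the fast-1%-tail rule roughly coincide; one scalper device cycling
deterministically through 6 + Poisson(1.5) cards; outcome mixes of
cancel .55 / complete .02 / no-show .43 (scalper) vs .08 / .80 / .12
(legitimate); and demographic attributes drawn identically for both
classes.  The default problem size — 5,000 accounts, 400 bookings/day over
360 days with the intervention at day 180 — is the package's scaled-down
stand-in for a multi-year, hundreds-of-thousands-of-records registration
window.

Deliberate simplifications, which bound what green tests prove about real
data:

* **Signatures are planted by construction**, and three of the features
  (minimum operation time, cancel bursts, card fan-out) directly encode
  the labeling criteria, so the synthetic classes are nearly separable and
  cross-validated AUC approaches 1.0.  The AUC gate (> 0.85) is therefore a
  property check of the pipeline, not a reproduction of a real-data
  operating point, where behavioral overlap would be substantial.
* Accounts are active over the whole horizon, so the post-period
  "first-time patient share" is structurally near zero here; it is
  reported but never asserted.
* Legitimate-behavior distributions (cancel rates, operation times) are
  stand-ins chosen for plausibility; no public source specifies them.
* No adversarial adaptation: scalpers do not change tactics when blocked
  (concept drift is exercised separately by the sequential-update tests).

A generator-level `intervention_effect` block (post-period scalper activity
multiplier, completion shift) exists for producing exogenous pre/post
shifts; its defaults are neutral, so in the standard experiment *all*
pre/post differences are produced by the intervention policy itself, and a
null experiment (empty policy) shows no effect.

## The closed loop

Deployment proceeds in review cycles (default 4) over the post period.
Each cycle: features are recomputed over a **trailing window equal to the
training-window width**, so behavioral summaries remain stationary between
training and deployment (a growing window would push history-length and
count features outside the fitted class distributions); congestion — the
clamped utilization λ/(c·μ) implied by the cycle's booking rate against the
configured service capacity (default 20 servers × 1/h) — modulates the
prior; flagged posteriors in [0.75, 0.90) trigger verification, [0.90, 1]
temporary restriction (45 days by default).  Verification is resolved by a
challenge-response with pass probabilities 0.98 (legitimate) / 0.05
(scalper) — stand-ins for an SMS challenge a patient answers and a bot
cannot.  Suppressed bookings and their resolutions never materialize, so
outcome tables always satisfy completions + cancels + no-shows = bookings.
Completion and no-show rates use the completed/no-show dichotomy
(cancels excluded from the denominator), matching how such rates are
conventionally tabulated.

## Statistics

All implemented from their standard formulas and cross-checked in the test
suite against independent oracles (direct summation, brute-force rank
counting, closed-form queues, normal-equation solves, scipy/sklearn):

* Pearson χ² without continuity correction; Cramér's V = √(χ²/(n(min(r,k)−1))).
* Cochran–Armitage linear-by-linear trend Z with equally spaced default
  scores; on two groups Z² equals the 2×2 χ² exactly.
* Risk ratio with the Katz log-Wald CI (the method is labeled in the
  result, as CI conventions differ).
* Cohen's d with the pooled-variance (n−1) convention.
* Percentile bootstrap resampling **individual records**; empirical
  coverage of the nominal 95% interval is verified by simulation
  (percentile intervals undercover slightly at n = 200, ~94%).
* Interrupted time series: Y_t = β0 + β1·t + β2·post + β3·(t−t0)·post by
  OLS, Durbin–Watson reported; monthly (30-day) completion rates enter the
  experiment's ITS.
* AUC as the Mann–Whitney rank statistic with ties counted half.
* Equal Opportunity: per-group TPR among true positives; groups without
  positives are excluded and listed in the report's warnings.
* Cross-validation: stratified k-fold (default 10) or repeated stratified
  70/30 splits — both offered because either protocol is defensible and
  published descriptions of "10-fold (70:30)" validation are ambiguous.
* Two-sided tests, raw p-values, no multiplicity adjustment.

Published χ² statistics for the annual summary tables are not reproducible
from the printed totals and rates under any standard Pearson variant, so
the package recomputes only quantities that are derivable from the tables
(rates, risk ratio, rate differences, F1 from precision/recall) and keeps
its χ² implementation formula-faithful.

## Bayesian-network path

The deployed dependency structure among X₁–X₁₂ is not published, so the
default `BayesNetSpec` is naive (class → each feature) over quartile-binned
features with Laplace-smoothed CPTs; arbitrary user DAGs are accepted and
validated (acyclicity, CPT row normalization).  Quartile binning blunts
likelihood ratios relative to the Gaussian path; the BN is a secondary,
fully transparent scoring route, not the default classifier.

## Sequential updating

Two modes, both leaving π and τ fixed: a windowed refit over the last W
labeled batches, and a conjugate normal–inverse-Wishart step per class with
prior strength n₀ (κ₀ = n₀, ν₀ = n₀ + d + 1, so the prior covariance
expectation equals the current estimate and n₀ → ∞ freezes the model).
A drift simulation in the tests shows the operational point: when the
scalper mean migrates toward legitimate behavior, the frozen model's recall
collapses while a windowed refit restores it above 90%.

## Numerical conventions

Posteriors in log space (agreement with the naive density-ratio form to
1e-9 on non-extreme inputs); covariance Cholesky factors cached; queue
time-averages exclude a 10% burn-in; all randomness flows from a single
integer seed through `numpy.random.SeedSequence` spawning, making every
pipeline product — event logs, fitted parameters, evaluation reports — a
pure function of (config, seed).
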