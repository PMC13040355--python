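# scalpguard

Bayesian behavioral-risk modelling of **appointment scalping** in hospital
outpatient registration systems.

Scalpers use automated tools to book sought-after appointment slots
speculatively and resell them, crowding out genuine patients: bookings are
placed in sub-second bursts at slot release, canceled en masse when resale
fails, and routed through one device fanning out to many medical-card IDs.
`scalpguard` implements, end to end and fully tested, an analysis pipeline
for evaluating a Bayesian anti-scalping intervention:

1. **Synthetic registration streams** — a seeded generator of account
   cohorts and event logs (book/cancel/complete/no-show) with configurable
   scalper prevalence (default 5%), behavioral signatures, Poisson arrivals
   and a pre/post intervention period structure, standing in for raw
   hospital registration data that is not publicly deposited.
2. **Ground-truth labeling** — an account is *abnormal* when at least two of
   three criteria hold: more than three cancelations inside a sliding 48 h
   window; a device associated with more than five distinct card IDs; any
   operation faster than the manual-speed floor (2 s by default, optionally
   the fast 1% tail of reference operation times).
3. **Behavioral features** — a 12-variable vector per account (X₁–X₁₂):
   circular booking hour, department entropy, booking rate, inter-operation
   interval, minimum operation time, cancel burst size, cancel ratio, card
   fan-out, distinct IPs, session duration, history length, online share.
4. **The risk model** — a class-conditional Gaussian Bayes classifier:

       P(scalper | x) = π·g_s(x) / (π·g_s(x) + (1−π)·g_l(x))

   with the prior π fixed at its audited baseline (0.05), covariances
   shrunk toward their diagonal, decisions at a posterior threshold
   τ = 0.75, and a **dynamic prior** driven by queue congestion:
   logit(π′) = logit(π) + γ·(congestion − ½).  A discrete Bayesian-network
   scoring path over quartile-binned features (naive structure by default,
   arbitrary DAGs accepted) and closed-loop sequential updating (windowed
   refit or conjugate normal–inverse-Wishart) complete the engine.
5. **Queueing model** — an M/M/c discrete-event simulation with Erlang-C
   analytic cross-checks produces the congestion index that modulates the
   prior.
6. **Intervention loop** — graduated actions on flagged accounts (extra
   verification with an SMS-style challenge-response that rescues false
   positives, or temporary booking restriction) applied over review cycles,
   with materialized pre/post outcome tables.
7. **Evaluation statistics** — Pearson χ² with Cramér's V, Cochran–Armitage
   trend test, Katz risk-ratio CIs, Cohen's d, record-level percentile
   bootstrap, interrupted time series (segmented OLS + Durbin–Watson),
   confusion/ROC metrics with a rank-statistic AUC, Equal-Opportunity TPR
   gaps, and stratified cross-validation.

The model layer follows the statsmodels convention: build a
`GaussianScalperModel` from a design matrix, `fit()` returns a
`GaussianScalperResults` carrying estimates, standard errors, a `summary()`
table, scoring, calibration and updating methods.

## Worked example

```python
import scalpguard as sg
from scalpguard.intervention import run_experiment, EvalConfig

cfg = sg.SimulationConfig(n_accounts=800, arrival_rate_per_day=80, seed=5)
res = run_experiment(cfg, eval_config=EvalConfig(bootstrap_B=500))
print(res.summary())
```

prints

```
Pre/post intervention experiment
============================================================
                                     pre          post
materialized bookings              14527         11350
completion rate                    0.724         0.816
no-show rate                       0.276         0.184
blocked bookings                       0          3067

completion change         +9.2 pp
chi-square                249.57 (p=3.2e-56, V=0.109)
RR (post vs pre)          1.127 [1.111, 1.144]
trend Z                   19.37
ITS level change          -0.0042 (slope change +0.02634/month)
bootstrap completion gain +9.21 pp [+8.12, +10.31]
CV AUC                    1.000
flagged-account bookings  70.6% drop post
legitimate users flagged  0.00%
equal-opportunity gap     age 0.000 / socio 0.000
```

Reading: training on the 180-day pre period flags the scalper accounts;
deploying the policy over four post-period review cycles suppresses 3,067
speculative bookings, so the completion rate among materialized bookings
(completed / (completed + no-show)) climbs from 72.4% to 81.6%, a +9.2
percentage-point gain whose bootstrap CI excludes zero.  Bookings by
flagged accounts drop 70.6% while no legitimate account is flagged, and
true-positive rates are identical across age and socio-economic bands.
`res.model_results.summary()` shows the fitted class means: scalpers sit
3+ SDs from legitimate patients on operation speed, cancel bursts and card
fan-out — the three signatures the generator plants and the labeler keys on.

A CLI mirrors the stages: `scalpguard simulate|label|features|fit|evaluate|run-all`,
each with `--config` (YAML), `--seed`, `--out`.

## Layout

```
src/scalpguard/
  config.py           simulation + labeling configuration
  simulate.py         cohort and event-log generator
  labeling.py         two-of-three ground-truth rule
  features.py         X1–X12 extraction, DesignMatrix
  model.py            GaussianScalperModel / GaussianScalperResults
  bayesnet.py         discrete BN scoring path
  queuing.py          M/M/c simulation + Erlang-C
  intervention.py     policy, challenges, run_experiment
  evaluation.py       the statistics suite
  hospital_tables.py  packaged published summary tables
  io.py, cli.py, runconfig.py
docs/methods.md       modelling assumptions and design choices
```
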