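# Methods

This document records the statistical models implemented in `ltctransfer`,
the design of the synthetic cohort generator, and the numerical choices
behind both. The scientific question throughout: what is the causal effect
of hospital/emergency-department transfer on permanent physical impairment,
permanent cognitive impairment, and death among long-term-care residents,
when sicker residents are transferred more often (confounding by
indication)?

## 1. Data model

All analysis operates on a quarterly assessment grid of 92-day windows.
One *assessment row* holds, for one resident and one window:

- identifiers (`home_id`, `resident_id`, `period_index`),
- baseline covariates fixed at admission (age, sex, comorbidity burden),
- time-varying scales: ADL self-performance hierarchy (0–6), Cognitive
  Performance Scale, CPS (0–6), health-instability scale CHESS (0–5),
  recent-fall and weight-change flags,
- the exposure (`transfer`: any hospital/ED transfer in the window),
- terminal flags (`died_in_period`, `discharged_in_period`).

### Outcomes and permanence

- **Physical impairment**: ADL = 6 at an assessment *and at every later
  assessment* (a later value below 6 cancels the earlier crossing).
- **Cognitive impairment**: CPS ≥ 5, with the same permanence rule.
- **Mortality**: all-cause death.

`detect_permanent_impairment` implements the permanence rule as a single
reverse scan; a property-based test checks it against a naive
quadratic-time suffix scan.

### Eligibility and person-periods

Residents enter at admission if aged ≥ 65; for each impairment outcome,
residents already past the threshold at admission are excluded (they are
not at risk). `build_person_periods` converts assessment rows to
counting-process rows `(start_day, stop_day, exposed, event)`, one per
92-day window, with cause-specific handling: for impairment outcomes,
death acts as a censoring event at its occurrence (cause-specific hazard),
discharge censors, and the administrative horizon censors last. The
exposure in window *k* affects events recorded at the *next* assessment,
so event rows close the window preceding the onset assessment; a
day-scanner oracle test enforces these boundary conventions.

## 2. Estimators

Four estimators are run for each outcome, sharing one Cox engine.

### Cox engine (`cox.py`)

Counting-process Cox partial likelihood with Efron (default) or Breslow
tie handling, case weights, Newton–Raphson with step-halving, model-based
and cluster-robust (home-level sandwich from score residuals) variances.
Written against two oracles: a brute-force risk-set-loop likelihood on
tiny datasets (agreement to 1e−6) and an independent library implementation
on larger data. A fit whose coefficient passes |β| > 10 raises a
separation warning rather than silently returning a diverging estimate.

### Crude and extended Cox

The crude model regresses the outcome hazard on the time-varying exposure
alone. The extended Cox adds baseline and current time-varying covariates.
Both are biased for the causal effect when time-varying confounders (CHESS
here) are themselves affected by past exposure — the classic failure that
motivates the MSM.

### Marginal structural model (`msm.py`)

Pooled logistic models estimate, per person-period, the probability of the
observed exposure (numerator: baseline covariates, exposure history and
period terms; denominator: the same plus time-varying confounders) and of
remaining uncensored by discharge. The stabilized weight is the cumulative
product over a resident's windows of the numerator/denominator ratios.
The outcome model is the weighted Cox of event on exposure plus baseline
covariates with home-clustered robust variance. Under correct
specification the mean stabilized weight is ≈ 1 per period (checked).

**Truncation.** Weights are truncated at the 1st/99th percentiles by
default. This is a bias–variance trade: truncation stabilizes variance on
messy data but introduces a small systematic bias (measured at roughly
+0.03 on the log-HR scale in the recovery simulations, versus ≈ 0 without
truncation). The recovery test therefore runs untruncated; applied runs
keep the default for robustness, and the truncated fraction is reported in
the weight diagnostics.

### Instrumental variable (`iv.py`)

The instrument is the home's prior-year transfer proportion — provider
practice variation ("preference") — recomputed each follow-up year; year 0
uses a burn-in history block shipped with the cohort. Estimation is
two-stage residual inclusion (2SRI): a logistic first stage of exposure on
instrument + baseline covariates, whose residual enters the Cox outcome
model as a control function absorbing unmeasured confounding. The exposure
coefficient is a complier-type causal log hazard ratio. Confidence
intervals come from the home-clustered sandwich by default, or a cluster
bootstrap over homes. Diagnostics cover relevance (first-stage Wald z,
with a `WeakInstrumentWarning` below |z| = 2), an exogeneity proxy
(baseline balance across instrument quintiles) and outcome incidence by
quintile.

### Incidence and balance (`incidence.py`)

Descriptive rates per 100 person-years with log-normal CIs (exact Poisson
below 5 events), ever/never-transferred rate ratios, and standardized mean
differences for the baseline table. The ever/never classification is
descriptive only and carries the usual immortal-time caveat: residents who
survive long enough to be transferred accumulate person-time in the "ever"
group.

## 3. Synthetic cohort generator (`simulate.py`)

The generator is first-class, tested code: its defaults define the study
conditions the estimators are validated against.

Structure per resident-window, all on the 92-day grid:

1. **Homes** carry a transfer propensity θ on an even grid across
   `theta_range`; θ is the instrument's source of exogenous variation.
2. **Frailty** is a latent per-resident normal (`frailty_sd`) loading on
   acute illness, transfer and events — the unmeasured confounder.
3. **Acute illness** strikes with probability `p_illness` (frailty-
   shifted); an ill resident is transferred with a logit shifted by
   `gamma_illness_transfer`, and their next-window event hazards are
   shifted by `gamma_illness`. Chronic frailty also loads directly on
   events through `gamma_frailty`.
4. **Transfers** causally shift next-window event hazards by
   `beta_transfer` (the planted truths the estimators must recover).
5. CHESS evolves with optional feedback from past transfer/illness,
   making it a genuine time-varying confounder/mediator when enabled.
6. The burn-in instrument history draws prior-year transfer counts from
   the illness-gated *marginal* per-period transfer probability
   (Gauss–Hermite quadrature over the frailty distribution), so that the
   year-0 instrument measures the same quantity as later years.

A truth table records every planted parameter and each home's θ.

### Named conditions

- **`paper_like()`** — the documented headline regime: rare
  (`p_illness = 0.05`) but strongly lethal acute illness, almost always
  captured by transfer (`gamma_illness_transfer = 7`), high frailty
  variance concentrating illness and death in a short-stay frail subset,
  and wide practice variation (θ ∈ [0.002, 0.08]) at 400 homes × 150
  residents. This produces the qualitative signature of severe
  confounding by indication: a crude mortality rate ratio far above 1 and
  an MSM mortality HR above 1 (both still confounded by latent frailty),
  while the IV recovers the planted protective mortality effect
  (HR < 1) and returns impairment intervals covering the null. The large
  home count is needed because the impairment IV is weakly identified
  (few impairment events per home): below roughly 400 homes its
  control-function interval estimates are fat-tailed.
- **`measured_confounding()`** — confounding only through observed CHESS
  (no latent pathway, no exposure→CHESS feedback, so CHESS is a pure
  time-varying confounder): the MSM is consistent here, the crude model
  is not. Used by the MSM recovery suite.
- **`latent_confounding()`** — confounding through unobserved acute
  illness with a planted protective mortality effect (log-HR −0.5): the
  IV is consistent here, crude and extended Cox are biased upward. Used
  by the IV recovery suite.
- **`null_effects()`** — no effects, no confounding: falsification runs.

### Numerical and reproducibility choices

- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; per-home/per-resident streams are derived
  deterministically, so results are independent of iteration order.
- Output files are plain UTF-8 CSV with `#` provenance headers
  (configuration hash + seed) and a fixed float format, making pipeline
  runs byte-for-byte reproducible — asserted by tests.
- Cumulative-weight products and quantile computations use stable sorts
  (mergesort) so equal keys cannot reorder across platforms.

## 4. Validation strategy

- **Unit oracles**: brute-force partial likelihood; day-scanner
  person-period oracle; hand-computed weight arithmetic; exact Poisson CI
  formulas; independent library cross-check for the Cox engine.
- **Property-based tests** (derandomized): permanence rule vs naive scan,
  rate-ratio CI containment, θ-grid invariants.
- **Recovery suites**: 200-replicate Monte-Carlo runs of
  `measured_confounding` (MSM within 3 MC SEs of truth, crude biased,
  mean weight ≈ 1 per period, ~95% coverage) and `latent_confounding`
  (IV within 3 MC SEs of the planted −0.5, crude/extended biased upward,
  weak-instrument warning under a degenerate θ range).
- **Determinism**: the full pipeline run twice at one seed must produce
  byte-identical outputs.

## 5. Limitations

- The generator's discrete 92-day grid collapses within-window timing;
  hazards are per-window probabilities, not continuous-time rates.
- The IV estimand is complier-type and its impairment analyses are weakly
  identified at small home counts; interval estimates there should be
  read qualitatively.
- The MSM weight models assume correct specification of the treatment and
  censoring models; diagnostics (mean weight, truncated fraction) flag
  but do not fix misspecification.
- Synthetic validation demonstrates internal consistency of the
  estimators under the generator's assumptions, not external validity for
  any particular real cohort.
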