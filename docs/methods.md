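# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind the `lookaway` pipeline.

## The ideal observer

Events come from a finite alphabet of size K (2 for the single-box
experiment, 3 for the three-box experiment).  The observer holds a
symmetric Dirichlet(α) prior over the multinomial event probabilities; the
latent parameter vector is never sampled or stored — all queries integrate
it out analytically.  Posterior-predictive probability of symbol *i* is
(nᵢ + α)/(N + Kα); surprisal is its negative log (base 2 by default, so
units are bits; any base via `log_base`).  Because α > 0 the predictive
never vanishes and surprisal is always finite and positive.

Scoring is strictly sequential and *predict-then-update*: event *t* is
scored against the posterior built from events 1…t−1 only, and the count is
incremented afterwards.  Model uncertainty is summarised by the
differential entropy of the Dirichlet posterior,
ln B(a) + (a₀ − K)ψ(a₀) − Σ(aⱼ − 1)ψ(aⱼ) with a = n + α, reported in nats
(it enters the regression standardized, so the unit is immaterial).  The
closed form is cross-checked in the tests against Monte-Carlo estimates.

Two variants:

* **marginal** — events are exchangeable; one posterior for the whole
  sequence.
* **transitional** — first-order Markov: one independent posterior row per
  conditioning symbol, all sharing the same α.  The first event has no
  predecessor and is scored by the marginal prior, so traces stay
  full-length; conditioning starts at event 2.  A `conditioning_blind`
  option collapses all rows onto one shared state, which provably reduces
  to the marginal observer on the transition targets (tested).

α defaults to 1 (uniform prior expectation).  The headline U-shape is
insensitive to this choice; α is a plain argument everywhere, so
sensitivity sweeps are one-line loops.

## Stimulus designs

* **Single-box sessions**: 42 trials; the 21 probabilities-of-appearance
  0.00, 0.05, …, 1.00 each occur twice; trial order is shuffled per
  session; the first reveal always shows the object; remaining events are
  independent Bernoulli(p) draws.
* **Three-box sessions**: 32 trials, one per probability triple, sequences
  drawn i.i.d. from the triple.  The original 32 triples were never
  published; the default grid is a documented stand-in spanning
  deterministic (1,0,0)-type, skewed and uniform triples (all distinct
  permutations of seven shapes plus two fillers, exactly 32).  Any
  32-triple grid can be supplied via config.

Events last 2 s (1 s reveal + 1 s conceal) and trials time out at 60 s, so
sequences are pre-generated to a 30-event cap.  Within a simulated cohort
all infants see the same pre-generated sequences in independently shuffled
orders, as in the original three-box design.  Box/object identity is
modelled only as opaque symbol labels; visual appearance, screen layout and
the attention-getter are out of scope.

## The look-away generator

At each event, in order: (1) a *false stop* with probability
`false_stop_prob` (eye-tracker dropout; exogenous, independent of the
stimulus, hence non-informative censoring — the whole trial is later
discarded, mirroring the protocol); (2) otherwise a look-away with
probability given by the U-shaped hazard

    h_t = link( b + γ(s_t − s*)² + λ(s_t − s*) + δ·trial_number )

where s_t is the event's surprisal in bits.  Surviving all 30 events is a
timeout.  The 1-second look-away criterion is absorbed into the per-event
Bernoulli decision; within-event gaze dynamics are not modelled, and the
look-away is attributed to the event during which it occurs.  No
infant-level random effects are generated (none are fitted either).

The default link is logistic — look-aways are decisions made at discrete
events — with defaults frozen after a single calibration pass against the
published study conditions: `baseline_logodds = −3.0`, `curvature γ = 1.5
/bit²`, `optimum s* = 1.25` bits, `linear λ = 0`, `trial_slope δ = 0.027`
(fatigue), `false_stop_prob = 0.03`.  Under these, a 30-infant three-box
cohort shows ≈19–21% false stops, ≈0.5–1% timeouts, and a fitted
standardized squared-complexity coefficient of ≈0.30 — the order of the
reported effects.  A `cloglog` link (h = 1 − exp(−e^η)) is also provided:
it is the exact event-grouped form of a continuous-time proportional-
hazards process, so its coefficients are true log hazard ratios; the
recovery harness uses it.

What the generator deliberately does not emulate: subject heterogeneity
(infant-specific baselines or preferences), drift of attention within an
event, dependence of tracker failures on behaviour, or any learning across
trials beyond the fatigue trend.  Passing tests therefore demonstrate that
the *analysis machinery* recovers known structure under the design's noise
and censoring processes — not that real infants satisfy the model.

## Event table

Exclusions mirror the protocol: timeouts and false stops are discarded, as
are trials with fewer than four observed events (`min_events = 4`;
four events is the retention boundary).  A `keep_timeouts` flag retains
timeouts as right-censored rows for sensitivity analyses.

Retained trials expand to one row per at-risk event with interval
(position−1, position] on the discrete event axis (events are isochronous;
seconds are a multiplication away).  The look-away indicator is 1 only on
the final row of look-away trials.  Covariates: object present and
same-as-previous-reveal (single-box); first appearance, number of objects
not yet appeared (counted through the current event) and same-object-as-
previous (three-box); presentation order (`trial_number`); surprisal and
posterior entropy from the trace.  Same-as-previous at event 1 is defined
as 0 — any constant convention is absorbed by the baseline hazard.  The
first event's row is included even though its surprisal is prior-determined.

Complexity is standardized to mean 0, SD 1 (population SD; the n vs n−1
difference is negligible at these sizes) pooled over all retained rows of
the experiment, and squared *after* standardization — the two orders differ
on skewed data, which the tests demonstrate by counterexample.

## Survival regression

`lifelines.CoxTimeVaryingFitter` fits the counting-process rows with the
Efron tie approximation (the discrete axis produces heavy ties; Efron is
the accurate standard choice) and a non-parametric baseline.  The fit is
verified against R's `survival::coxph` (coefficients, standard errors and
log-likelihoods agree to ≤1e−5 on a shared fixture).  Subject effects are
not modelled; a cluster-robust-variance flag is available as an extension.

Stepwise selection is forward-only by AIC: starting from the empty model,
the candidate that most lowers AIC is added until no addition lowers it.
The empty model's Efron partial log-likelihood has the closed form
−Σ_times Σ_{l<d} log(n_risk − l), implemented directly and checked against
R's null log-likelihood.  Because acceptance is by AIC (penalty 2 per
parameter), non-significant covariates can be retained — expected
behaviour, not a defect.  Linear complexity is a stepwise candidate in both
experiments.

The transitional-vs-marginal comparison enters both squared-complexity
covariates (plus the significant controls) into one joint fit and reports
the Pearson correlation of the two raw complexity columns; perfectly
collinear columns raise rather than silently splitting the effect.

## U-shape summary

Raw look-away probabilities are binned along complexity (default 5
equal-width bins over the observed range; equal-count optional since the
original binning rule is unknown), with binomial standard errors; empty
bins are reported, never dropped.  The smooth view is a binomial-link GAM
(`statsmodels GLMGam`, cubic B-splines, 10 basis functions for complexity
and 5 for position).  The smoothing penalty is selected on a coarse
logarithmic grid (0.1…1000) by AIC — a full GCV optimisation is orders of
magnitude slower for indistinguishable curves at these sizes.  The reported
curve fixes position at its mean; `include_position=False` gives the
marginal curve, which is the one comparable to raw bins.

The Goldilocks value is the argmin of the fitted curve.  It is flagged
`interior` only if it is off the grid edges *and* the curve rises by more
than one pointwise SE on both flanks — a boundary minimum or a monotone
drift does not support a U-shape claim.  GAM standard errors ignore subject
effects; inference rests on the Cox fits.

## Recovery harnesses and their honest limits

`recover_goldilocks` simulates cohorts under the behavioural default hazard
and refits the smooth: at 42 infants the interior minimum lands within
0.25 bits of the generating 1.25 bits in ≥80% of replicates (typically
~100%), essentially unbiased.

`recover_quadratic` validates the coefficient path.  Its generator uses the
cloglog link on *z-scored* surprisal so the generating quadratic
coefficient is a genuine log hazard ratio on the scale the regression
estimates; because that scale (complexity standardized over retained rows)
is only observable after simulating, a two-iteration pilot pass matches the
generator's z-moments to it.  With no complexity effect the Wald test of z²
is well calibrated (5% rejections at the 5% level over 500 cohorts) once
the generator's fatigue trend is included among the fitted covariates —
omitting a real nuisance effect makes the test conservative.

Magnitude recovery of large effects is intrinsically attenuated, and the
corresponding acceptance test fails by design rather than being weakened.
The mechanism, established by simulation during development: the Cox-Efron
estimator is nearly unbiased (−4…−8%) on grouped proportional-hazards data
with i.i.d. covariates of moderate range, but the study design departs from
that regime in two compounding ways.  First, all infants share the same 32
covariate paths, so deaths arrive in large tie groups at identical
covariate values.  Second, surprisal is heavy-tailed (up to ~5 bits, z up
to ~3.8): a quadratic log hazard ratio of 0.356 per z² implies relative
risks of e^5 at the tail, which a per-event probability bounded by 1 cannot
carry — those events become near-certain terminations whose ordering
information the tied partial likelihood cannot use.  At the published
effect size the fitted coefficient recovers ≈0.62–0.65 of the generating
value; sign and significance recover essentially always.  No generator
choice within the stated design (shared sequences, discrete 2 s events,
30-event cap) removes this; it is a property of fitting a continuous-time
model class to heavily tied discrete data.

## Numerical and degenerate-input conventions

Zero-probability events cannot arise (α > 0).  Zero-variance complexity,
empty sequences, unknown symbols, constant covariates, no-event tables and
sub-50-row smooths raise informative errors rather than degrading.  All
randomness flows from `numpy.random.SeedSequence` lineages: one master seed
per run/experiment spawns per-stage and per-replicate children, so any
stage can be re-run in isolation bit-identically; pipeline manifests embed
a config hash and an output hash, and identical configs produce identical
artifacts.

## Problem sizes

Default analysis sizes follow the study conditions (42 infants × 42 trials
single-box, 30 infants × 32 trials three-box).  The statistical test suite
runs the null calibration at 500 replicates of 30 × 32, coefficient
recovery at 100 replicates of 100 × 32, minimum recovery at 50 replicates
of 42 × 42, and model discrimination over 9 cohorts of 30 × 32 — sizes at
which each check's sampling noise is small relative to its acceptance band.
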