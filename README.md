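# lookaway

Ideal-observer analysis of infant looking-time experiments, as a reusable,
fully simulated pipeline.

## The problem

In looking-time experiments an infant watches a sequence of discrete visual
events (an occluder lifts to reveal an object or an empty box; one of three
objects pops out of its box) until they look away for more than a second or
the 60 s trial times out.  The scientific question is *when* they disengage:
the hypothesis is that the probability of looking away at a given event is a
U-shaped function of that event's information content — infants disengage
from streams that are too predictable (nothing left to learn) and from
streams that are too surprising (nothing learnable), and attend longest at
an intermediate "Goldilocks" level of complexity.

Because the original gaze recordings are not public, everything here runs on
synthetic cohorts whose generator is itself part of the package, so every
stage of the analysis is testable end to end.

## The model

A Dirichlet-multinomial ideal observer watches each sequence.  With a
symmetric Dirichlet(α) prior over the multinomial event probabilities and
counts *n₁…n_K* observed so far, the posterior-predictive probability of
event *i* is

    P(i) = (nᵢ + α) / (N + Kα),      N = Σ nᵢ

and the *complexity* (surprisal) of observing event *i* is −log₂ P(i) bits.
α = 1 encodes a uniform prior expectation (50–50 over two outcomes, 33–33–33
over three).  A *transitional* variant keeps one posterior per preceding
event, scoring each event against the row of its predecessor.

The linking model is survival analysis: each retained trial becomes
counting-process rows (one per at-risk event) and a Cox regression with
time-varying covariates — standardized complexity z, its square z², and
controls (object present, item repeat, first appearance, objects not yet
seen, trial number, posterior entropy) — measures the log-linear influence
of each on look-away hazard over a non-parametric baseline.  Covariates are
chosen by forward stepwise AIC.  A positive z² coefficient is the U-shape's
signature; a binomial-link GAM on complexity and sequence position locates
its minimum, the Goldilocks value.

The synthetic cohort generator emulates the published study conditions:
42-trial single-box sessions (probabilities of appearance 0–1 in 0.05
steps, each twice) and 32-trial three-box sessions, a per-event look-away
hazard that is U-shaped in surprisal with its minimum at 1.25 bits, a
per-event eye-tracker failure process ("false stops", ~20% of trials), 60 s
timeouts, and the protocol's exclusion rules (timeouts, false stops and
trials with fewer than four observed events are discarded).

## Worked example

Simulate a 30-infant three-box cohort and fit the survival regression:

```python
import lookaway as lk

cfg = lk.RunConfig(experiment=2, seed=42, mode="marginal", n_infants=30)
rows, inter = lk.simulate_and_build(cfg)
fit = lk.stepwise_aic(rows, lk.survival.DEFAULT_CANDIDATES_EXP2)
print(fit.summary.round(4))
```

prints (from `python examples/04_survival_fit.py`):

```
                      coef  exp(coef)  se(coef)       z       p
covariate
z_complexity_sq     0.1116     1.1181    0.0303  3.6893  0.0002
first_appearance    1.0749     2.9298    0.2301  4.6726  0.0000
trial_number        0.0090     1.0090    0.0052  1.7114  0.0870
n_not_yet_appeared  0.2922     1.3394    0.0957  3.0528  0.0023
z_complexity        0.1992     1.2205    0.0750  2.6570  0.0079
```

Squared complexity enters with a positive coefficient: each additional
squared standard deviation of surprisal multiplies the look-away hazard by
exp(0.11) ≈ 1.12, confirming the U-shape after the controls.  The
descriptive view (`python examples/05_ushape_goldilocks.py`, a 42-infant
single-box cohort) bins raw look-away rates — 0.160 and 0.857 in the
extreme complexity bins versus 0.048 in the middle — and the binomial
smooth places the interior minimum at 1.48 bits, near the generating
optimum of 1.25 bits.

The `examples/` directory has one short script per capability: observer
traces, session design, cohort simulation and exclusions, survival fitting,
U-shape summaries, and the simulate-refit recovery harness.  A thin CLI
(`lookaway generate|complexity|simulate|build-table|fit|report|run|recover`)
wraps the same stages for shell use; `lookaway run --config cfg.yaml` writes
every intermediate artifact plus a manifest with a config hash for exact
reproducibility.

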