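"""Synthetic infant look-away generator.

Look-aways are simulated event by event: at each reveal the infant
terminates attention with a probability given by a U-shaped function of that
event's surprisal.  With the default logistic link the per-event hazard is

    h_t = logistic( b + gamma * (s_t - s*)^2 + lambda * (s_t - s*)
                    + delta * trial_number )

where ``s_t`` is the event's surprisal in bits, ``s*`` the hazard-minimising
("Goldilocks") surprisal, ``gamma >= 0`` the curvature of the U, ``lambda``
an asymmetry term and ``delta`` a per-trial fatigue increment.  A
``cloglog`` link (``h_t = 1 - exp(-exp(...))``) is also provided: it is the
exact event-grouped form of a continuous-time proportional-hazards process,
so its coefficients are true log hazard ratios.  The recovery harness uses
it so that generating coefficients live on the scale the Cox regression
estimates.

Independently of surprisal, each event may end the trial as a *false stop*
(emulating eye-tracker dropout, non-informative censoring), and a trial
that survives all 30 events ends as a *timeout*.

Default parameter values emulate the published study conditions: a
Goldilocks optimum of 1.25 bits, curvature and baseline chosen so that the
fitted standardized squared-complexity coefficient, timeout rate (a few
percent) and false-stop rate (about a fifth of trials) land near the
reported ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .observer import ComplexityTrace, sequence_complexity
from .stimuli import (
    MAX_EVENTS,
    TrialDesign,
    generate_exp1_sequence,
    generate_exp2_sequence,
)

__all__ = ["HazardParams", "LookAwayRecord", "simulate_trial", "simulate_cohort", "records_to_frame"]

Outcome = Literal["lookaway", "timeout", "false_stop"]


@dataclass(frozen=True)
class HazardParams:
    """Parameters of the U-shaped per-event look-away hazard."""

    baseline_logodds: float = -3.0      # look-away log-odds at the optimum
    curvature: float = 1.5              # gain on squared surprisal deviation, per bit^2
    optimum_bits: float = 1.25          # hazard-minimising surprisal s*
    linear_term: float = 0.0            # asymmetry of the U, per bit
    trial_slope: float = 0.027          # fatigue increment per trial
    false_stop_prob: float = 0.03       # tracker-failure probability per event
    timeout_events: int = MAX_EVENTS
    link: Literal["logistic", "cloglog"] = "logistic"

    def __post_init__(self) -> None:
        if not 0 <= self.false_stop_prob < 1:
            raise ValueError("false_stop_prob must lie in [0, 1)")
        if self.timeout_events < 1:
            raise ValueError("timeout_events must be >= 1")
        if self.curvature < 0:
            raise ValueError("curvature must be >= 0")
        if self.link not in ("logistic", "cloglog"):
            raise ValueError("link must be 'logistic' or 'cloglog'")

    @classmethod
    def from_standardized(
        cls,
        quadratic: float,
        linear: float,
        surprisal_mean: float,
        surprisal_sd: float,
        **kwargs,
    ) -> "HazardParams":
        """Build parameters whose quadratic/linear terms act on z-scored
        surprisal, ``z = (s - mean) / sd``.

        ``quadratic * z^2 + linear * z`` is re-expressed in raw bits so the
        generating coefficients are directly comparable to a regression on
        standardized complexity: curvature = quadratic / sd^2, optimum =
        mean, linear_term = linear / sd.
        """
        if surprisal_sd <= 0:
            raise ValueError("surprisal_sd must be > 0")
        return cls(
            curvature=quadratic / surprisal_sd**2,
            optimum_bits=surprisal_mean,
            linear_term=linear / surprisal_sd,
            **kwargs,
        )

    def hazard(self, surprisal_bits: np.ndarray | float, trial_number: int) -> np.ndarray:
        """Per-event look-away probability for the given surprisal values."""
        s = np.asarray(surprisal_bits, dtype=float)
        d = s - self.optimum_bits
        eta = (
            self.baseline_logodds
            + self.curvature * d**2
            + self.linear_term * d
            + self.trial_slope * trial_number
        )
        if self.link == "logistic":
            return 1.0 / (1.0 + np.exp(-eta))
        return -np.expm1(-np.exp(eta))


@dataclass(frozen=True)
class LookAwayRecord:
    """Outcome of one simulated trial."""

    trial_id: int
    infant_id: int
    trial_number: int               # presentation position within the infant's session
    outcome: Outcome
    n_events_observed: int          # events seen before the trial ended
    lookaway_position: int | None   # event index of the look-away, if any

    def __post_init__(self) -> None:
        if self.outcome == "lookaway" and self.lookaway_position != self.n_events_observed:
            raise ValueError("look-away position must equal events observed")
        if self.outcome != "lookaway" and self.lookaway_position is not None:
            raise ValueError("only look-away trials carry a look-away position")


def simulate_trial(
    trace: ComplexityTrace,
    params: HazardParams,
    trial_number: int,
    seed: int | np.random.Generator,
    trial_id: int = 0,
    infant_id: int = 0,
) -> LookAwayRecord:
    """Simulate one trial from its complexity trace.

    Events are scanned in order.  At each event a false stop is drawn first
    (tracker failure precedes the behavioural decision); otherwise a
    look-away is drawn from the U-shaped hazard.  Surviving every event up
    to the timeout cap yields a timeout.
    """
    if len(trace) == 0:
        raise ValueError("trace must be non-empty")
    rng = np.random.default_rng(seed)
    n_events = min(len(trace), params.timeout_events)
    h = params.hazard(trace.surprisal_bits[:n_events], trial_number)
    u_fs = rng.random(n_events)
    u_la = rng.random(n_events)
    for t in range(n_events):
        if u_fs[t] < params.false_stop_prob:
            return LookAwayRecord(trial_id, infant_id, trial_number, "false_stop", t + 1, None)
        if u_la[t] < h[t]:
            return LookAwayRecord(trial_id, infant_id, trial_number, "lookaway", t + 1, t + 1)
    return LookAwayRecord(trial_id, infant_id, trial_number, "timeout", n_events, None)


def simulate_cohort(
    designs: Sequence[TrialDesign],
    n_infants: int,
    params: HazardParams,
    seed: int,
    alpha: float = 1.0,
    mode: Literal["marginal", "transitional"] = "marginal",
    per_infant_sequences: bool = False,
) -> tuple[list[LookAwayRecord], dict[int, ComplexityTrace]]:
    """Simulate a cohort watching a session of trials.

    By default every infant sees the same pre-generated sequences (as in the
    original three-box study) in an independently shuffled order;
    ``trial_number`` records each infant's presentation position.  With
    ``per_infant_sequences=True`` each infant's sequences are re-drawn from
    the trials' generating distributions instead (it is unknown whether the
    original single-box realizations were shared).  Returns the look-away
    records and the per-trial complexity traces that drove the hazard.
    Note: with per-infant sequences the returned traces are the shared-
    session ones and must not be paired with the records in a downstream
    event table; the flag exists for sensitivity analyses at the record
    level (look-away distributions, exclusion rates).
    """
    if n_infants < 1:
        raise ValueError("n_infants must be >= 1")
    traces = {
        d.trial_id: sequence_complexity(d.sequence, d.alphabet, alpha=alpha, mode=mode)
        for d in designs
    }
    ss = np.random.SeedSequence(seed)
    infant_seeds = ss.spawn(n_infants)
    records: list[LookAwayRecord] = []
    for infant_id, child in enumerate(infant_seeds, start=1):
        rng = np.random.default_rng(child)
        order = rng.permutation(len(designs))
        for trial_number, k in enumerate(order, start=1):
            d = designs[k]
            if per_infant_sequences:
                if d.experiment == 1:
                    seq = generate_exp1_sequence(d.generating_p, len(d.sequence), rng)
                else:
                    seq = generate_exp2_sequence(
                        d.generating_distribution, len(d.sequence), rng
                    )
                trace = sequence_complexity(seq, d.alphabet, alpha=alpha, mode=mode)
            else:
                trace = traces[d.trial_id]
            records.append(
                simulate_trial(
                    trace, params, trial_number, rng,
                    trial_id=d.trial_id, infant_id=infant_id,
                )
            )
    return records, traces


def records_to_frame(records: Sequence[LookAwayRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "infant_id": [r.infant_id for r in records],
            "trial_id": [r.trial_id for r in records],
            "trial_number": [r.trial_number for r in records],
            "outcome": [r.outcome for r in records],
            "n_events_observed": [r.n_events_observed for r in records],
            "lookaway_position": [
                r.lookaway_position if r.lookaway_position is not None else pd.NA
                for r in records
            ],
        }
    )
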