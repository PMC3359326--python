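"""Dirichlet-multinomial ideal observer over categorical event streams.

The observer watches a sequence of events drawn from a finite alphabet and
maintains a conjugate posterior over the underlying multinomial event
distribution.  With a symmetric Dirichlet prior of strength ``alpha`` and
observed counts ``n``, the posterior-predictive probability of symbol *i* is

    P(i) = (n_i + alpha) / (N + K * alpha)

where ``N`` is the total count and ``K`` the alphabet size.  The *surprisal*
(information content, in bits) of observing symbol *i* is ``-log2 P(i)``;
because ``alpha > 0`` the predictive never assigns zero probability, so
surprisal is always finite.

Two variants are provided: a *marginal* model that treats successive events
as exchangeable, and a *transitional* (first-order Markov) model that keeps
one independent posterior per conditioning symbol and scores each event
against the posterior row of the immediately preceding symbol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, psi

__all__ = [
    "EventAlphabet",
    "PosteriorState",
    "TransitionPosterior",
    "ComplexityTrace",
    "posterior_predictive",
    "surprisal",
    "update",
    "posterior_entropy",
    "sequence_complexity",
    "EXP1_ALPHABET",
    "EXP2_ALPHABET",
]

Mode = Literal["marginal", "transitional"]


@dataclass(frozen=True)
class EventAlphabet:
    """A finite, ordered set of event symbols."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least two symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise KeyError(f"symbol {symbol!r} not in alphabet {self.symbols}") from None


#: Experiment-1 style binary alphabet: object present vs. empty box.
EXP1_ALPHABET = EventAlphabet(("present", "absent"))
#: Experiment-2 style three-symbol alphabet: one symbol per object/box pair.
EXP2_ALPHABET = EventAlphabet(("A", "B", "C"))


@dataclass(frozen=True)
class PosteriorState:
    """Event counts plus symmetric Dirichlet prior strength.

    The latent multinomial parameter vector is never stored; all queries
    integrate it out analytically (conjugacy).
    """

    alphabet: EventAlphabet
    counts: tuple[int, ...] = ()
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("prior strength alpha must be > 0")
        if not self.counts:
            object.__setattr__(self, "counts", (0,) * self.alphabet.size)
        if len(self.counts) != self.alphabet.size:
            raise ValueError("counts length must equal alphabet size")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def n_observations(self) -> int:
        return int(sum(self.counts))

    # convenience method forms of the module-level operations
    def predictive(self) -> np.ndarray:
        return posterior_predictive(self)

    def surprisal(self, symbol: str, log_base: float = 2.0) -> float:
        return surprisal(self, symbol, log_base=log_base)

    def updated(self, symbol: str) -> "PosteriorState":
        return update(self, symbol)

    def entropy(self) -> float:
        return posterior_entropy(self)


def posterior_predictive(state: PosteriorState) -> np.ndarray:
    """Posterior-predictive probability of each symbol, ``(n_i+a)/(N+Ka)``."""
    n = np.asarray(state.counts, dtype=float)
    return (n + state.alpha) / (n.sum() + state.alphabet.size * state.alpha)


def surprisal(state: PosteriorState, symbol: str, log_base: float = 2.0) -> float:
    """Information content of observing ``symbol`` next, ``-log P(symbol)``.

    Base 2 (bits) by default; pass ``log_base=math.e`` for nats.
    """
    i = state.alphabet.index(symbol)
    p = posterior_predictive(state)[i]
    return float(-math.log(p, log_base))


def update(state: PosteriorState, symbol: str) -> PosteriorState:
    """Return a new state with ``symbol``'s count incremented by one."""
    i = state.alphabet.index(symbol)
    counts = list(state.counts)
    counts[i] += 1
    return replace(state, counts=tuple(counts))


def posterior_entropy(state: PosteriorState) -> float:
    """Differential entropy (nats) of the Dirichlet posterior on the
    multinomial parameters, a measure of the observer's remaining model
    uncertainty.  May be negative (differential entropy convention)."""
    a = np.asarray(state.counts, dtype=float) + state.alpha
    a0 = a.sum()
    k = a.size
    log_beta = float(gammaln(a).sum() - gammaln(a0))
    return float(log_beta + (a0 - k) * psi(a0) - ((a - 1) * psi(a)).sum())


@dataclass
class TransitionPosterior:
    """First-order Markov observer: one posterior row per conditioning symbol.

    Each row is an independent :class:`PosteriorState` sharing the same
    symmetric prior strength.  ``previous_event`` tracks the conditioning
    context while scanning a sequence.  With ``conditioning_blind=True`` a
    single row is shared by every conditioning symbol, which collapses the
    model back onto the marginal (order-free) observer.
    """

    alphabet: EventAlphabet
    alpha: float = 1.0
    conditioning_blind: bool = False
    rows: dict[str, PosteriorState] = field(default_factory=dict)
    previous_event: str | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            if self.conditioning_blind:
                shared = PosteriorState(self.alphabet, alpha=self.alpha)
                self.rows = {s: shared for s in self.alphabet.symbols}
            else:
                self.rows = {
                    s: PosteriorState(self.alphabet, alpha=self.alpha)
                    for s in self.alphabet.symbols
                }

    def row(self, conditioning_symbol: str) -> PosteriorState:
        if conditioning_symbol not in self.rows:
            raise KeyError(f"unknown conditioning symbol {conditioning_symbol!r}")
        return self.rows[conditioning_symbol]

    def observe(self, symbol: str) -> None:
        """Record a transition ``previous_event -> symbol`` (if a previous
        event exists) and advance the conditioning context."""
        self.alphabet.index(symbol)
        if self.previous_event is not None:
            updated = update(self.rows[self.previous_event], symbol)
            if self.conditioning_blind:
                self.rows = {s: updated for s in self.alphabet.symbols}
            else:
                self.rows[self.previous_event] = updated
        self.previous_event = symbol


@dataclass(frozen=True)
class ComplexityTrace:
    """Per-event surprisal and posterior uncertainty aligned to a sequence.

    ``surprisal_bits[t] == -log2(predictive_prob[t])`` exactly; positions are
    1-based.  ``posterior_entropy`` is the differential entropy (nats) of the
    posterior used to score each event, i.e. the belief state *before* the
    event was incorporated.
    """

    symbols: tuple[str, ...]
    predictive_prob: np.ndarray
    surprisal_bits: np.ndarray
    posterior_entropy: np.ndarray
    mode: Mode
    alpha: float

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, len(self.symbols) + 1)

    def to_frame(self, trial_id: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position": self.positions,
                "symbol": list(self.symbols),
                "predictive_prob": self.predictive_prob,
                "surprisal_bits": self.surprisal_bits,
                "posterior_entropy": self.posterior_entropy,
                "mode": self.mode,
            }
        )
        if trial_id is not None:
            df.insert(0, "trial_id", trial_id)
        return df


def sequence_complexity(
    sequence: Sequence[str] | Iterable[str],
    alphabet: EventAlphabet,
    alpha: float = 1.0,
    mode: Mode = "marginal",
    log_base: float = 2.0,
) -> ComplexityTrace:
    """Score every event of a sequence under the sequential ideal observer.

    Each event is scored against the posterior built from the events before
    it (predict-then-update); the first event is therefore scored by the
    prior alone.  In ``transitional`` mode events from position 2 onward are
    scored against the posterior row conditioned on the immediately preceding
    symbol; the first event, which has no predecessor, is scored by the
    marginal prior so the trace stays full-length.

    Parameters
    ----------
    sequence : ordered event symbols (non-empty)
    alphabet : the event alphabet
    alpha : symmetric Dirichlet prior strength (> 0)
    mode : ``"marginal"`` (exchangeable events) or ``"transitional"``
        (first-order Markov conditioning)
    log_base : base of the surprisal logarithm (2 = bits)
    """
    events = tuple(sequence)
    if not events:
        raise ValueError("sequence must be non-empty")
    if mode not in ("marginal", "transitional"):
        raise ValueError(f"unknown mode {mode!r}")

    probs = np.empty(len(events))
    ent = np.empty(len(events))

    if mode == "marginal":
        state = PosteriorState(alphabet, alpha=alpha)
        for t, sym in enumerate(events):
            i = alphabet.index(sym)
            probs[t] = posterior_predictive(state)[i]
            ent[t] = posterior_entropy(state)
            state = update(state, sym)
    else:
        prior_state = PosteriorState(alphabet, alpha=alpha)
        tp = TransitionPosterior(alphabet, alpha=alpha)
        for t, sym in enumerate(events):
            i = alphabet.index(sym)
            if tp.previous_event is None:
                scoring_state = prior_state
            else:
                scoring_state = tp.row(tp.previous_event)
            probs[t] = posterior_predictive(scoring_state)[i]
            ent[t] = posterior_entropy(scoring_state)
            tp.observe(sym)

    surp = -np.log(probs) / math.log(log_base)
    return ComplexityTrace(
        symbols=events,
        predictive_prob=probs,
        surprisal_bits=surp,
        posterior_entropy=ent,
        mode=mode,
        alpha=alpha,
    )
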