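"""Stimulus-design generators for the two looking-time experiments.

Experiment 1: single box, binary events (object present / box empty).  A
session holds 42 trials; each of the 21 probabilities-of-appearance
(0.00, 0.05, ..., 1.00) occurs twice, in an order shuffled per session.  The
first reveal of every sequence always shows the object.

Experiment 2: three box/object pairs, three-symbol events.  A session holds
32 trials, one per probability triple; event sequences are i.i.d. draws from
the trial's triple.  The original study's 32 triples were never published,
so :data:`DEFAULT_EXP2_GRID` is a documented stand-in spanning degenerate,
skewed and uniform distributions.

Events last 2 s (1 s reveal + 1 s conceal) and trials time out at 60 s, so
sequences are pre-generated to a 30-event cap.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .observer import EXP1_ALPHABET, EXP2_ALPHABET, EventAlphabet

__all__ = [
    "TrialDesign",
    "EXP1_P_GRID",
    "DEFAULT_EXP2_GRID",
    "MAX_EVENTS",
    "EVENT_DURATION_S",
    "TIMEOUT_S",
    "generate_exp1_sequence",
    "generate_exp2_sequence",
    "generate_exp1_session",
    "generate_exp2_session",
    "designs_to_frame",
    "session_manifest",
    "write_session",
    "read_designs",
]

EVENT_DURATION_S: float = 2.0
TIMEOUT_S: float = 60.0
#: events per trial implied by the 60 s timeout at 2 s per event
MAX_EVENTS: int = int(TIMEOUT_S // EVENT_DURATION_S)

#: the 21 probabilities-of-appearance, 0 to 1 in steps of 0.05
EXP1_P_GRID: tuple[float, ...] = tuple(np.round(np.arange(0, 21) * 0.05, 2))


def _permutations(triple: tuple[float, float, float]) -> list[tuple[float, float, float]]:
    return sorted(set(itertools.permutations(triple)))


# Stand-in grid for the 32 unpublished probability triples: all distinct
# permutations of a few shapes from degenerate through skewed to uniform.
DEFAULT_EXP2_GRID: tuple[tuple[float, float, float], ...] = tuple(
    p
    for shape in [
        (1.0, 0.0, 0.0),
        (0.8, 0.2, 0.0),
        (0.8, 0.1, 0.1),
        (0.6, 0.2, 0.2),
        (0.6, 0.3, 0.1),
        (0.5, 0.5, 0.0),
        (0.5, 0.3, 0.2),
    ]
    for p in _permutations(shape)
) + ((0.4, 0.4, 0.2), (1 / 3, 1 / 3, 1 / 3))

assert len(DEFAULT_EXP2_GRID) == 32


@dataclass(frozen=True)
class TrialDesign:
    """One trial: its generating distribution and pre-generated sequence."""

    trial_id: int
    experiment: int
    generating_distribution: tuple[float, ...]
    sequence: tuple[str, ...]
    event_duration_s: float = EVENT_DURATION_S
    alphabet: EventAlphabet = field(default=EXP1_ALPHABET)

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if any(not (0 <= q <= 1) for q in self.generating_distribution):
            raise ValueError("distribution entries must lie in [0, 1]")
        if abs(sum(self.generating_distribution) - 1.0) > 1e-9:
            raise ValueError("generating distribution must sum to 1")
        if not self.sequence:
            raise ValueError("sequence must be non-empty")

    @property
    def generating_p(self) -> float:
        """Experiment-1 probability-of-appearance (first distribution entry)."""
        return self.generating_distribution[0]


def generate_exp1_sequence(
    p: float, length: int, seed: int | np.random.Generator
) -> tuple[str, ...]:
    """Draw a single-box event sequence with probability-of-appearance ``p``.

    The first reveal always shows the object; events 2..length are
    independent Bernoulli(p) draws.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"probability-of-appearance must lie in [0, 1], got {p}")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    present, absent = EXP1_ALPHABET.symbols
    draws = rng.random(length - 1) < p
    return (present,) + tuple(present if d else absent for d in draws)


def generate_exp2_sequence(
    triple: Sequence[float], length: int, seed: int | np.random.Generator
) -> tuple[str, ...]:
    """Draw a three-box event sequence i.i.d. from a probability triple."""
    triple = tuple(float(q) for q in triple)
    if len(triple) != 3 or any(not (0 <= q <= 1) for q in triple):
        raise ValueError(f"need a probability triple in [0,1]^3, got {triple}")
    if abs(sum(triple) - 1.0) > 1e-9:
        raise ValueError(f"triple must sum to 1, got {triple}")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(3, size=length, p=np.asarray(triple) / sum(triple))
    return tuple(EXP2_ALPHABET.symbols[i] for i in idx)


def generate_exp1_session(seed: int) -> list[TrialDesign]:
    """Generate one Experiment-1 session: 42 trials, each p twice, shuffled."""
    ss = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    ps = list(EXP1_P_GRID) * 2
    order = order_rng.permutation(len(ps))
    child_seeds = ss.spawn(len(ps) + 1)[1:]
    designs = []
    for trial_id, k in enumerate(order, start=1):
        p = ps[k]
        seq = generate_exp1_sequence(p, MAX_EVENTS, np.random.default_rng(child_seeds[k]))
        designs.append(
            TrialDesign(
                trial_id=trial_id,
                experiment=1,
                generating_distribution=(p, round(1 - p, 10)),
                sequence=seq,
                alphabet=EXP1_ALPHABET,
            )
        )
    return designs


def generate_exp2_session(
    seed: int,
    distribution_grid: Sequence[Sequence[float]] | None = None,
) -> list[TrialDesign]:
    """Generate one Experiment-2 session: 32 trials, one per triple, shuffled.

    ``distribution_grid`` defaults to :data:`DEFAULT_EXP2_GRID` and must hold
    exactly 32 valid probability triples.
    """
    grid = DEFAULT_EXP2_GRID if distribution_grid is None else tuple(
        tuple(float(q) for q in t) for t in distribution_grid
    )
    if len(grid) != 32:
        raise ValueError(f"distribution grid must have 32 entries, got {len(grid)}")
    ss = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    order = order_rng.permutation(len(grid))
    child_seeds = ss.spawn(len(grid) + 1)[1:]
    designs = []
    for trial_id, k in enumerate(order, start=1):
        seq = generate_exp2_sequence(grid[k], MAX_EVENTS, np.random.default_rng(child_seeds[k]))
        designs.append(
            TrialDesign(
                trial_id=trial_id,
                experiment=2,
                generating_distribution=grid[k],
                sequence=seq,
                alphabet=EXP2_ALPHABET,
            )
        )
    return designs


def designs_to_frame(designs: Sequence[TrialDesign]) -> pd.DataFrame:
    """Long-format design table: one row per (trial, event)."""
    rows = []
    for d in designs:
        for t, sym in enumerate(d.sequence, start=1):
            rows.append(
                {
                    "trial_id": d.trial_id,
                    "experiment": d.experiment,
                    "event_index": t,
                    "symbol": sym,
                    "generating_p": d.generating_distribution[0]
                    if d.experiment == 1
                    else np.nan,
                    "generating_distribution": "/".join(
                        repr(float(q)) for q in d.generating_distribution
                    ),
                }
            )
    return pd.DataFrame(rows)


def session_manifest(designs: Sequence[TrialDesign], seed: int) -> dict:
    return {
        "seed": seed,
        "experiment": designs[0].experiment,
        "n_trials": len(designs),
        "event_duration_s": designs[0].event_duration_s,
        "max_events": MAX_EVENTS,
        "trial_order": [d.trial_id for d in designs],
        "distributions": [list(d.generating_distribution) for d in designs],
    }


def write_session(designs: Sequence[TrialDesign], seed: int, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    designs_to_frame(designs).to_csv(outdir / "designs.csv", index=False)
    (outdir / "session_manifest.json").write_text(
        json.dumps(session_manifest(designs, seed), indent=2)
    )


def read_designs(path: str | Path) -> list[TrialDesign]:
    """Rebuild :class:`TrialDesign` objects from a designs CSV."""
    df = pd.read_csv(path)
    designs = []
    for trial_id, g in df.groupby("trial_id", sort=True):
        g = g.sort_values("event_index")
        experiment = int(g["experiment"].iloc[0])
        dist = tuple(float(q) for q in str(g["generating_distribution"].iloc[0]).split("/"))
        alphabet = EXP1_ALPHABET if experiment == 1 else EXP2_ALPHABET
        designs.append(
            TrialDesign(
                trial_id=int(trial_id),
                experiment=experiment,
                generating_distribution=dist,
                sequence=tuple(g["symbol"]),
                alphabet=alphabet,
            )
        )
    return designs
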