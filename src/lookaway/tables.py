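"""Analysis dataset construction: exclusions, counting-process rows, covariates.

The survival analysis predicts a binary look-away at every at-risk event, so
each retained trial is expanded into one row per event up to and including
the look-away event (counting-process format: interval ``(position-1,
position]`` on the discrete event axis).  Exclusion rules mirror the study
protocol: timeouts and false stops are discarded, as are trials where the
infant watched fewer than four events.

Complexity is standardized (z-scored with the population standard deviation,
pooled over all retained rows) *before* squaring, so the quadratic
coefficient of the downstream regression is interpretable as the effect per
squared standard deviation of surprisal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .observer import ComplexityTrace
from .simulate import LookAwayRecord
from .stimuli import TrialDesign

__all__ = ["ExclusionReport", "apply_exclusions", "build_rows", "standardize", "MIN_EVENTS"]

#: trials with fewer observed events than this are discarded
MIN_EVENTS: int = 4


@dataclass(frozen=True)
class ExclusionReport:
    n_total: int
    n_timeout: int
    n_false_stop: int
    n_too_short: int
    n_retained: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.n_total == 0:
            return {"timeout": 0.0, "false_stop": 0.0, "too_short": 0.0, "retained": 0.0}
        return {
            "timeout": self.n_timeout / self.n_total,
            "false_stop": self.n_false_stop / self.n_total,
            "too_short": self.n_too_short / self.n_total,
            "retained": self.n_retained / self.n_total,
        }

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_timeout": self.n_timeout,
            "n_false_stop": self.n_false_stop,
            "n_too_short": self.n_too_short,
            "n_retained": self.n_retained,
            "fractions": self.fractions,
        }


def apply_exclusions(
    records: Sequence[LookAwayRecord],
    min_events: int = MIN_EVENTS,
    keep_timeouts: bool = False,
) -> tuple[list[LookAwayRecord], ExclusionReport]:
    """Apply the protocol's trial filters.

    Removes timeouts, false stops and trials with fewer than ``min_events``
    observed events.  ``keep_timeouts=True`` retains timeout trials as
    right-censored observations (for sensitivity analyses); they still count
    as timeouts in the report.
    """
    n_timeout = sum(r.outcome == "timeout" for r in records)
    n_false_stop = sum(r.outcome == "false_stop" for r in records)
    candidates = [
        r
        for r in records
        if r.outcome == "lookaway" or (keep_timeouts and r.outcome == "timeout")
    ]
    retained = [r for r in candidates if r.n_events_observed >= min_events]
    n_too_short = len(candidates) - len(retained)
    report = ExclusionReport(
        n_total=len(records),
        n_timeout=n_timeout,
        n_false_stop=n_false_stop,
        n_too_short=n_too_short,
        n_retained=len(retained),
    )
    return retained, report


def _exp1_covariates(sequence: tuple[str, ...], n: int) -> dict[str, np.ndarray]:
    present = np.array([s == "present" for s in sequence[:n]], dtype=int)
    # same_as_previous is 0 at event 1 by convention (no previous reveal)
    same = np.zeros(n, dtype=int)
    if n > 1:
        same[1:] = (present[1:] == present[:-1]).astype(int)
    return {"object_present": present, "same_as_previous": same}


def _exp2_covariates(sequence: tuple[str, ...], n: int, k: int) -> dict[str, np.ndarray]:
    first = np.zeros(n, dtype=int)
    not_yet = np.zeros(n, dtype=int)
    same = np.zeros(n, dtype=int)  # same object as the previous event (item repeat)
    seen: set[str] = set()
    for t, sym in enumerate(sequence[:n]):
        first[t] = int(sym not in seen)
        seen.add(sym)
        not_yet[t] = k - len(seen)  # objects not yet appeared through event t
        if t > 0:
            same[t] = int(sym == sequence[t - 1])
    return {
        "first_appearance": first,
        "n_not_yet_appeared": not_yet,
        "same_as_previous": same,
    }


def build_rows(
    records: Sequence[LookAwayRecord],
    traces: Mapping[int, ComplexityTrace],
    designs: Sequence[TrialDesign],
    extra_traces: Mapping[str, Mapping[int, ComplexityTrace]] | None = None,
) -> pd.DataFrame:
    """Expand retained trials into one row per at-risk event.

    ``extra_traces`` attaches additional complexity columns (e.g. the
    transitional trace alongside the marginal one) named
    ``complexity_bits_<key>`` / ``posterior_entropy_<key>``.

    The look-away indicator is 1 only on the final row of look-away trials;
    censored (timeout) trials, if present, carry all-zero indicators.
    """
    design_by_id = {d.trial_id: d for d in designs}
    frames = []
    for r in records:
        if r.trial_id not in traces:
            raise KeyError(f"no complexity trace for trial {r.trial_id}")
        trace = traces[r.trial_id]
        d = design_by_id[r.trial_id]
        n = r.n_events_observed
        if n > len(trace):
            raise ValueError(f"trial {r.trial_id}: record longer than its trace")
        indicator = np.zeros(n, dtype=int)
        if r.outcome == "lookaway":
            indicator[-1] = 1
        cols = {
            "infant_id": r.infant_id,
            "trial_id": r.trial_id,
            "position": np.arange(1, n + 1),
            "start": np.arange(0, n),
            "stop": np.arange(1, n + 1),
            "lookaway_indicator": indicator,
            "censored": int(r.outcome != "lookaway"),
            "trial_number": r.trial_number,
            "complexity_bits": trace.surprisal_bits[:n],
            "posterior_entropy": trace.posterior_entropy[:n],
        }
        if d.experiment == 1:
            cols.update(_exp1_covariates(d.sequence, n))
        else:
            cols.update(_exp2_covariates(d.sequence, n, d.alphabet.size))
        if extra_traces:
            for name, tr_map in extra_traces.items():
                tr = tr_map[r.trial_id]
                cols[f"complexity_bits_{name}"] = tr.surprisal_bits[:n]
                cols[f"posterior_entropy_{name}"] = tr.posterior_entropy[:n]
        frames.append(pd.DataFrame(cols))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def standardize(
    rows: pd.DataFrame, columns: Sequence[str] = ("complexity_bits",)
) -> pd.DataFrame:
    """Add z-scored and squared-z columns for each complexity column.

    Standardization pools every retained row (population SD).  The square is
    taken *after* standardization.  Column ``complexity_bits`` yields
    ``z_complexity`` / ``z_complexity_sq``; a column
    ``complexity_bits_<name>`` yields ``z_complexity_<name>`` and its square.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 rows to standardize")
    out = rows.copy()
    for col in columns:
        x = rows[col].to_numpy(dtype=float)
        sd = x.std()  # population sd
        if sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        z = (x - x.mean()) / sd
        zname = col.replace("complexity_bits", "z_complexity")
        out[zname] = z
        out[zname + "_sq"] = z**2
    return out
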