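"""Cox proportional-hazards regression on the event table.

Look-away data are counting-process rows on a discrete event axis, so the
fit uses a time-varying-covariate Cox model (lifelines
``CoxTimeVaryingFitter``) with the Efron approximation for the heavy ties
the discrete axis produces, and a non-parametric baseline hazard.  Stepwise
model selection is forward-only by AIC: starting from the empty model,
candidates are added greedily while the addition lowers the AIC.  The empty
model's partial log-likelihood has a closed form under Efron weighting
(all relative risks equal 1), which anchors the stepwise path.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter

__all__ = [
    "CoxFit",
    "fit_cox",
    "stepwise_aic",
    "compare_complexity_models",
    "null_log_likelihood",
    "DEFAULT_CANDIDATES_EXP1",
    "DEFAULT_CANDIDATES_EXP2",
]

#: stepwise candidate orders used in the two experiments
DEFAULT_CANDIDATES_EXP1: tuple[str, ...] = (
    "z_complexity",
    "z_complexity_sq",
    "object_present",
    "same_as_previous",
    "trial_number",
    "posterior_entropy",
)
DEFAULT_CANDIDATES_EXP2: tuple[str, ...] = (
    "z_complexity",
    "z_complexity_sq",
    "same_as_previous",
    "trial_number",
    "posterior_entropy",
    "first_appearance",
    "n_not_yet_appeared",
)


@dataclass(frozen=True)
class CoxFit:
    """A fitted Cox regression: per-covariate table plus model summaries."""

    covariates: tuple[str, ...]
    summary: pd.DataFrame            # coef, exp(coef), se(coef), z, p per covariate
    log_likelihood: float
    aic: float
    n_rows: int
    n_events: int
    selection_order: tuple[str, ...] = ()
    aic_trace: tuple[float, ...] = field(default_factory=tuple)

    def coef(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "coef"])

    def se(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "se(coef)"])

    def p_value(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "aic": self.aic,
            "log_likelihood": self.log_likelihood,
            "n_rows": self.n_rows,
            "n_events": self.n_events,
            "selection_order": list(self.selection_order),
            "aic_trace": list(self.aic_trace),
            "table": {
                cov: {
                    k: float(self.summary.loc[cov, k])
                    for k in ("coef", "exp(coef)", "se(coef)", "z", "p")
                }
                for cov in self.covariates
            },
        }


def _prepare(rows: pd.DataFrame) -> pd.DataFrame:
    df = rows.copy()
    if "row_id" not in df.columns:
        df["row_id"] = (
            df["infant_id"].astype(str) + ":" + df["trial_id"].astype(str)
        )
    return df


def null_log_likelihood(rows: pd.DataFrame) -> float:
    """Efron partial log-likelihood of the empty (no-covariate) model.

    With all relative risks equal to 1, a time with ``d`` tied events and
    risk-set size ``n`` contributes ``-sum_{l=0}^{d-1} log(n - l)``.
    """
    stop = rows["stop"].to_numpy(dtype=float)
    start = rows["start"].to_numpy(dtype=float)
    event = rows["lookaway_indicator"].to_numpy(dtype=int)
    ll = 0.0
    for t in np.unique(stop[event == 1]):
        at_risk = int(np.sum((start < t) & (t <= stop)))
        d = int(np.sum((stop == t) & (event == 1)))
        ll -= sum(math.log(at_risk - l) for l in range(d))
    return ll


def fit_cox(
    rows: pd.DataFrame,
    covariates: Sequence[str],
    robust: bool = False,
) -> CoxFit:
    """Fit a Cox regression with time-varying covariates (Efron ties).

    ``rows`` must carry ``start``/``stop``/``lookaway_indicator`` plus the
    requested covariate columns.  ``robust=True`` requests cluster-robust
    standard errors (an extension; the headline analysis uses model-based
    ones and no subject effects).
    """
    covariates = tuple(covariates)
    n_events = int(rows["lookaway_indicator"].sum())
    if n_events == 0:
        raise ValueError("no look-away events: nothing to fit")
    df = _prepare(rows)
    if not covariates:
        ll0 = null_log_likelihood(df)
        return CoxFit(
            covariates=(),
            summary=pd.DataFrame(columns=["coef", "exp(coef)", "se(coef)", "z", "p"]),
            log_likelihood=ll0,
            aic=-2.0 * ll0,
            n_rows=len(df),
            n_events=n_events,
        )
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise KeyError(f"covariates not in rows: {missing}")
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant; degenerate design")
    keep = ["row_id", "start", "stop", "lookaway_indicator", *covariates]
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(
            df[keep],
            id_col="row_id",
            event_col="lookaway_indicator",
            start_col="start",
            stop_col="stop",
            robust=robust,
        )
    summary = ctv.summary.loc[list(covariates), ["coef", "exp(coef)", "se(coef)", "z", "p"]]
    ll = float(ctv.log_likelihood_)
    return CoxFit(
        covariates=covariates,
        summary=summary,
        log_likelihood=ll,
        aic=2.0 * len(covariates) - 2.0 * ll,
        n_rows=len(df),
        n_events=n_events,
    )


def stepwise_aic(rows: pd.DataFrame, candidates: Sequence[str]) -> CoxFit:
    """Forward stepwise selection by AIC over the candidate covariates.

    Starting from the empty model, repeatedly add the candidate that most
    lowers the AIC; stop when no addition lowers it.  Candidates that fail
    to fit (constant or collinear columns) are skipped.  Non-significant
    covariates can end up retained: an addition needs only to beat the 2-per-
    parameter AIC penalty, not a significance threshold.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    df = _prepare(rows)
    current = fit_cox(df, ())
    aic_trace = [current.aic]
    order: list[str] = []
    remaining = list(candidates)
    while remaining:
        trial_fits = []
        for cand in remaining:
            try:
                trial_fits.append(fit_cox(df, tuple(order) + (cand,)))
            except KeyError:
                raise
            except Exception:  # constant/collinear candidate or non-convergence
                continue
        if not trial_fits:
            break
        best = min(trial_fits, key=lambda f: f.aic)
        if best.aic >= current.aic:
            break
        current = best
        order.append(best.covariates[-1])
        aic_trace.append(best.aic)
        remaining.remove(best.covariates[-1])
    return CoxFit(
        covariates=current.covariates,
        summary=current.summary,
        log_likelihood=current.log_likelihood,
        aic=current.aic,
        n_rows=current.n_rows,
        n_events=current.n_events,
        selection_order=tuple(order),
        aic_trace=tuple(aic_trace),
    )


def compare_complexity_models(
    rows: pd.DataFrame,
    base_covariates: Sequence[str] = ("trial_number",),
    marginal_col: str = "z_complexity_sq",
    transitional_col: str = "z_complexity_transitional_sq",
) -> tuple[CoxFit, float]:
    """Joint Cox fit with both complexity variants, plus their correlation.

    Enters the marginal and transitional squared-complexity covariates into
    one regression together with ``base_covariates`` and returns the fit and
    the Pearson correlation between the two underlying complexity columns.
    Identical (perfectly collinear) complexity columns raise rather than
    silently splitting the effect.
    """
    for c in (marginal_col, transitional_col):
        if c not in rows.columns:
            raise KeyError(f"column {c!r} missing; build rows with both traces")
    raw_m = rows[marginal_col.replace("z_complexity", "complexity_bits").replace("_sq", "")]
    raw_t = rows[
        transitional_col.replace("z_complexity", "complexity_bits").replace("_sq", "")
    ]
    corr = float(np.corrcoef(raw_m, raw_t)[0, 1])
    if abs(np.corrcoef(rows[marginal_col], rows[transitional_col])[0, 1]) > 1 - 1e-10:
        raise ValueError(
            "marginal and transitional complexity are perfectly collinear; "
            "a joint fit cannot attribute the effect"
        )
    fit = fit_cox(rows, (transitional_col, marginal_col, *base_covariates))
    return fit, corr
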