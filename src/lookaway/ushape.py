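"""Descriptive U-shape analysis of look-away probability vs. complexity.

Two complementary views of the same relationship:

* raw look-away probabilities in discrete complexity bins (default 5,
  equal-width over the observed range; equal-count available), with
  binomial standard errors, and
* a generalized additive model with a binomial link, smoothing the
  per-event look-away indicator on complexity and sequence position
  (statsmodels ``GLMGam`` with B-spline bases).  The hazard-minimising
  complexity — the "Goldilocks" value — is read off as the interior
  argmin of the fitted complexity curve with position held at its mean.
  A minimum on the boundary of the observed range is flagged: it does not
  support a U-shape claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

__all__ = ["BinSummary", "SmoothFit", "bin_lookaway", "fit_smooth", "plot_ushape"]


@dataclass(frozen=True)
class BinSummary:
    """Raw binned look-away probabilities."""

    edges: np.ndarray            # len n_bins + 1
    n_events: np.ndarray
    n_lookaways: np.ndarray
    probability: np.ndarray      # NaN for empty bins
    binomial_se: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.edges[:-1],
                "bin_right": self.edges[1:],
                "n_events": self.n_events,
                "n_lookaways": self.n_lookaways,
                "probability": self.probability,
                "binomial_se": self.binomial_se,
            }
        )


@dataclass(frozen=True)
class SmoothFit:
    """Binomial-link smooth of look-away on complexity (+ position)."""

    grid: np.ndarray             # complexity grid, bits
    probability: np.ndarray      # fitted look-away probability at the grid
    se: np.ndarray               # pointwise SE on the probability scale
    minimum_bits: float          # argmin of the fitted curve
    interior: bool               # False if the argmin sits on the range boundary
    edf: float                   # effective degrees of freedom of the smooth terms
    penalty: float               # selected smoothing penalty

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"complexity_bits": self.grid, "probability": self.probability, "se": self.se}
        )


def bin_lookaway(
    rows: pd.DataFrame,
    n_bins: int = 5,
    method: Literal["width", "count"] = "width",
    complexity_col: str = "complexity_bits",
) -> BinSummary:
    """Bin per-event look-away indicators along the complexity axis.

    Bins are equal-width over the observed complexity range by default, or
    equal-count (quantile edges) with ``method="count"``.  Empty bins are
    reported with ``n_events=0`` and NaN probability, never dropped.
    """
    if rows.empty:
        raise ValueError("rows must be non-empty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    x = rows[complexity_col].to_numpy(dtype=float)
    y = rows["lookaway_indicator"].to_numpy(dtype=int)
    if method == "width":
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
    elif method == "count":
        edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    else:
        raise ValueError(f"unknown binning method {method!r}")
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    k = len(edges) - 1
    n_events = np.bincount(idx, minlength=k)
    n_look = np.bincount(idx, weights=y, minlength=k).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_events > 0, n_look / np.maximum(n_events, 1), np.nan)
        se = np.sqrt(p * (1 - p) / np.maximum(n_events, 1))
    return BinSummary(edges=edges, n_events=n_events, n_lookaways=n_look,
                      probability=p, binomial_se=se)


_PENALTY_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)


def fit_smooth(
    rows: pd.DataFrame,
    complexity_col: str = "complexity_bits",
    n_grid: int = 200,
    spline_df: tuple[int, int] = (10, 5),
    penalty_grid: Sequence[float] = _PENALTY_GRID,
    include_position: bool = True,
) -> SmoothFit:
    """Fit the binomial-link additive smooth and locate the Goldilocks point.

    The look-away indicator is smoothed on complexity and sequence position
    with penalized B-splines; the smoothing penalty is chosen on a coarse
    logarithmic grid by AIC.  The returned curve is the fitted look-away
    probability over an even complexity grid with position fixed at its
    mean; ``minimum_bits`` is its argmin.  ``include_position=False`` drops
    the position smooth, giving the marginal complexity curve (comparable to
    raw binned rates, which also pool over positions).
    """
    if len(rows) < 50:
        raise ValueError("need at least 50 rows for a stable smooth")
    x = rows[complexity_col].to_numpy(dtype=float)
    pos = rows["position"].to_numpy(dtype=float)
    y = rows["lookaway_indicator"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("complexity has zero range; nothing to smooth")
    if include_position:
        X = np.column_stack([x, pos])
        smoother = BSplines(X, df=list(spline_df), degree=[3, 3])
    else:
        X = x[:, None]
        smoother = BSplines(X, df=[spline_df[0]], degree=[3])
    intercept = np.ones((len(y), 1))
    best = None
    last_err: Exception | None = None
    for alpha in penalty_grid:
        try:
            res = GLMGam(
                y, exog=intercept, smoother=smoother,
                alpha=[alpha] * smoother.k_variables, family=sm.families.Binomial(),
            ).fit()
        except Exception as err:  # noqa: BLE001 - collected into the diagnostic below
            last_err = err
            continue
        if not np.isfinite(res.aic):
            continue
        if best is None or res.aic < best[1]:
            best = (res, res.aic, alpha)
    if best is None:
        raise RuntimeError(
            f"smooth fit failed to converge for any penalty in {tuple(penalty_grid)}"
        ) from last_err
    res, _, alpha = best
    grid = np.linspace(x.min(), x.max(), n_grid)
    if include_position:
        Xp = np.column_stack([grid, np.full(n_grid, pos.mean())])
    else:
        Xp = grid[:, None]
    prob = np.asarray(res.predict(np.ones((n_grid, 1)), exog_smooth=Xp))
    # delta-method SE on the probability scale
    design = np.column_stack([np.ones(n_grid), smoother.transform(Xp)])
    cov = np.asarray(res.cov_params())
    eta_var = np.einsum("ij,jk,ik->i", design, cov, design)
    se = prob * (1 - prob) * np.sqrt(np.maximum(eta_var, 0))
    argmin = int(np.argmin(prob))
    # a U-shape requires an interior minimum: off the grid edges and with the
    # curve rising by at least one pointwise SE on both flanks
    rise_left = prob[: argmin + 1].max() - prob[argmin]
    rise_right = prob[argmin:].max() - prob[argmin]
    interior = bool(
        0 < argmin < n_grid - 1
        and rise_left > se[argmin]
        and rise_right > se[argmin]
    )
    edf = float(np.sum(res.edf)) if res.edf is not None else float("nan")
    return SmoothFit(
        grid=grid,
        probability=prob,
        se=se,
        minimum_bits=float(grid[argmin]),
        interior=interior,
        edf=edf,
        penalty=float(alpha),
    )


def plot_ushape(
    rows: pd.DataFrame,
    bins: BinSummary | None = None,
    smooth: SmoothFit | None = None,
    complexity_col: str = "complexity_bits",
    path: str | None = None,
):
    """Plot the smooth curve with SE band, binned raw probabilities and a
    data rug; returns the matplotlib figure (saved to ``path`` if given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = bins if bins is not None else bin_lookaway(rows, complexity_col=complexity_col)
    smooth = smooth if smooth is not None else fit_smooth(rows, complexity_col=complexity_col)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(smooth.grid, smooth.probability, "k-", lw=1.5, label="binomial GAM")
    ax.plot(smooth.grid, smooth.probability + smooth.se, "k--", lw=0.8)
    ax.plot(smooth.grid, smooth.probability - smooth.se, "k--", lw=0.8)
    centers = 0.5 * (bins.edges[:-1] + bins.edges[1:])
    ok = bins.n_events > 0
    ax.errorbar(
        centers[ok], bins.probability[ok], yerr=bins.binomial_se[ok],
        fmt="D", color="crimson", ms=5, capsize=2, label="binned raw",
    )
    x = rows[complexity_col].to_numpy(dtype=float)
    ax.plot(x, np.full_like(x, -0.005), "|", color="gray", ms=4, alpha=0.3)
    ax.axvline(smooth.minimum_bits, color="steelblue", ls=":", lw=1,
               label=f"minimum {smooth.minimum_bits:.2f} bits")
    ax.set_xlabel("complexity (bits)")
    ax.set_ylabel("look-away probability")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
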