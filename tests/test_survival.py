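"""Tests for the Cox regression layer, including an R survival oracle."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import lookaway as lk
from lookaway.survival import null_log_likelihood


def simulate_ph_rows(rng, n_trials=800, beta2=0.5, beta1=0.0, cap=20, base=-3.0):
    """Counting-process rows from a grouped proportional-hazards process with
    an i.i.d. truncated-normal covariate drawn fresh at every event (truncation
    keeps per-event hazards well below 1, inside the model class)."""
    frames = []
    for i in range(n_trials):
        z = np.clip(rng.normal(size=cap), -2.5, 2.5)
        h = -np.expm1(-np.exp(base + beta1 * z + beta2 * z**2))
        u = rng.random(cap)
        death = np.where(u < h)[0]
        n = (death[0] + 1) if len(death) else cap
        ev = np.zeros(n, dtype=int)
        if len(death):
            ev[-1] = 1
        frames.append(
            pd.DataFrame(
                {
                    "infant_id": 0,
                    "trial_id": i,
                    "start": np.arange(n),
                    "stop": np.arange(1, n + 1),
                    "lookaway_indicator": ev,
                    "z": z[:n],
                    "z2": z[:n] ** 2,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="module")
def ph_rows():
    return simulate_ph_rows(np.random.default_rng(21))


def test_exp_coef_column_consistency(ph_rows):
    fit = lk.fit_cox(ph_rows, ("z", "z2"))
    np.testing.assert_allclose(
        fit.summary["exp(coef)"], np.exp(fit.summary["coef"]), rtol=1e-9
    )


def test_fit_invariant_to_row_order(ph_rows):
    fit = lk.fit_cox(ph_rows, ("z", "z2"))
    shuffled = ph_rows.sample(frac=1.0, random_state=3).reset_index(drop=True)
    fit2 = lk.fit_cox(shuffled, ("z", "z2"))
    np.testing.assert_allclose(fit.summary["coef"], fit2.summary["coef"], atol=1e-8)


def test_quadratic_effect_recovered_in_clean_regime(ph_rows):
    """An i.i.d.-covariate grouped-PH cohort recovers the generating log
    hazard ratio within a couple of standard errors."""
    fit = lk.fit_cox(ph_rows, ("z", "z2"))
    assert abs(fit.coef("z2") - 0.5) < 2.5 * fit.se("z2")
    assert fit.p_value("z2") < 1e-6


def test_noise_covariate_rarely_significant(rng):
    hits = 0
    n = 20
    for _ in range(n):
        df = simulate_ph_rows(rng, n_trials=150, beta2=0.0)
        df["noise"] = rng.normal(size=len(df))
        fit = lk.fit_cox(df, ("noise",))
        hits += abs(float(fit.summary.loc["noise", "z"])) >= 2
    assert hits <= 3  # ~5% nominal rate


def test_degenerate_designs_raise(ph_rows):
    df = ph_rows.assign(const=1.0)
    with pytest.raises(ValueError, match="constant"):
        lk.fit_cox(df, ("const",))
    with pytest.raises(ValueError, match="look-away"):
        lk.fit_cox(ph_rows.assign(lookaway_indicator=0), ("z",))
    with pytest.raises(KeyError):
        lk.fit_cox(ph_rows, ("missing_covariate",))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_against_r_survival_oracle(ph_rows, tmp_path):
    """Coefficients, standard errors and log-likelihoods match R's coxph
    (Efron ties) on the same counting-process data."""
    csv = tmp_path / "rows.csv"
    ph_rows.to_csv(csv, index=False)
    script = f"""
    d <- read.csv("{csv}")
    suppressMessages(library(survival))
    m <- coxph(Surv(start, stop, lookaway_indicator) ~ z + z2, data = d, ties = "efron")
    cat(sprintf("%.10f", c(coef(m)["z"], coef(m)["z2"], sqrt(diag(vcov(m))),
                           m$loglik[1], m$loglik[2])), sep="\\n")
    """
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    rz, rz2, rse_z, rse_z2, rll0, rll = map(float, out.stdout.strip().split())
    fit = lk.fit_cox(ph_rows, ("z", "z2"))
    assert fit.coef("z") == pytest.approx(rz, abs=1e-5)
    assert fit.coef("z2") == pytest.approx(rz2, abs=1e-5)
    assert fit.se("z") == pytest.approx(rse_z, abs=1e-5)
    assert fit.se("z2") == pytest.approx(rse_z2, abs=1e-5)
    assert fit.log_likelihood == pytest.approx(rll, abs=1e-4)
    assert null_log_likelihood(ph_rows) == pytest.approx(rll0, abs=1e-6)


def test_stepwise_selects_strong_predictor_among_noise(rng):
    df = simulate_ph_rows(rng, n_trials=600, beta2=0.5)
    df["noise1"] = rng.normal(size=len(df))
    df["noise2"] = rng.normal(size=len(df))
    fit = lk.stepwise_aic(df, ("z2", "noise1", "noise2"))
    assert "z2" in fit.covariates
    assert fit.selection_order[0] == "z2"
    assert np.all(np.diff(fit.aic_trace) < 0)


def test_stepwise_all_noise_prefers_empty_model(rng):
    empties = 0
    for _ in range(8):
        df = simulate_ph_rows(rng, n_trials=120, beta2=0.0)
        df["noise1"] = rng.normal(size=len(df))
        df["noise2"] = rng.normal(size=len(df))
        fit = lk.stepwise_aic(df, ("noise1", "noise2"))
        empties += len(fit.covariates) == 0
    assert empties >= 5  # empty model is the modal outcome


def test_stepwise_selects_both_real_effects(rng):
    # quadratic complexity effect plus a fatigue-like trial trend
    frames = []
    for i in range(900):
        trial_number = (i % 30) + 1
        z = np.clip(rng.normal(size=20), -2.5, 2.5)
        h = -np.expm1(-np.exp(-3.5 + 0.5 * z**2 + 0.03 * trial_number))
        u = rng.random(20)
        death = np.where(u < h)[0]
        n = (death[0] + 1) if len(death) else 20
        ev = np.zeros(n, dtype=int)
        if len(death):
            ev[-1] = 1
        frames.append(pd.DataFrame({
            "infant_id": 0, "trial_id": i, "start": np.arange(n),
            "stop": np.arange(1, n + 1), "lookaway_indicator": ev,
            "z2": z[:n] ** 2, "trial_number": trial_number,
        }))
    df = pd.concat(frames, ignore_index=True)
    fit = lk.stepwise_aic(df, ("z2", "trial_number"))
    assert set(fit.covariates) == {"z2", "trial_number"}


def test_empty_candidate_set_rejected(ph_rows):
    with pytest.raises(ValueError):
        lk.stepwise_aic(ph_rows, ())


def test_joint_comparison_rejects_identical_columns(event_rows):
    rows = event_rows.copy()
    rows["complexity_bits_transitional"] = rows["complexity_bits"]
    rows["z_complexity_transitional"] = rows["z_complexity"]
    rows["z_complexity_transitional_sq"] = rows["z_complexity_sq"]
    with pytest.raises(ValueError, match="collinear"):
        lk.compare_complexity_models(rows)


def test_joint_comparison_reports_correlation(exp2_session):
    cfg = lk.RunConfig(experiment=2, seed=3, mode="both", n_infants=15)
    rows, _ = lk.simulate_and_build(cfg)
    fit, corr = lk.compare_complexity_models(
        rows,
        marginal_col="z_complexity_marginal_sq",
        transitional_col="z_complexity_sq",
    )
    assert 0.5 < corr < 1.0
    assert {"z_complexity_sq", "z_complexity_marginal_sq"} <= set(fit.covariates)
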