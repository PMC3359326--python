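"""Simulate-refit recovery: how well does the pipeline recover known truth?

Two quick harness runs (kept small here; the test suite runs them at full
scale): coefficient recovery for a known squared-complexity hazard effect,
and recovery of the 1.25-bit hazard minimum by the binomial smooth.  The
coefficient run also illustrates an honest limitation: on a discrete event
axis with heavy ties, the Cox fit systematically attenuates large
quadratic effects (see docs/methods.md).
"""

import lookaway as lk

cfg = lk.RunConfig(experiment=2, seed=3, mode="transitional", n_infants=40)
df, summary = lk.recover_quadratic(cfg, n_replicates=5, quadratic=0.356)
print("coefficient recovery (generating log hazard ratio 0.356, 5 reps):")
for k in ("mean_coef", "bias", "rmse", "sign_agreement", "rejection_rate"):
    print(f"  {k:>15}: {summary[k]:.3f}")

cfg_min = lk.RunConfig(experiment=1, seed=3, mode="marginal", n_infants=42)
df_min, summary_min = lk.recover_goldilocks(cfg_min, n_replicates=5)
print("\nGoldilocks-minimum recovery (generating optimum 1.25 bits, 5 reps):")
print(f"  fitted minima: {[round(m, 2) for m in df_min['minimum_bits']]}")
print(f"  fraction within 0.25 bits: {summary_min['frac_within_quarter_bit']:.0%}")

print(
    "\nThe sign and significance of the quadratic effect recover reliably; "
    "its magnitude is attenuated by discrete-time ties, while the location "
    "of the hazard minimum recovers essentially unbiased."
)
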