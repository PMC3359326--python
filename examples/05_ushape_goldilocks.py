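"""Locate the Goldilocks complexity with binned rates and a binomial smooth.

Bins raw per-event look-away probabilities along the complexity axis and
fits a binomial-link additive smooth (complexity + sequence position).
The interior minimum of the fitted curve is the Goldilocks value: the
surprisal level at which the simulated infants were least likely to
disengage.  Pass a filename as argv[1] to also save the figure.
"""

import sys

import lookaway as lk

cfg = lk.RunConfig(experiment=1, seed=5, mode="marginal", n_infants=42)
rows, _ = lk.simulate_and_build(cfg)

bins = lk.bin_lookaway(rows, n_bins=5)
print("raw binned look-away probabilities:")
print(bins.to_frame().round(3).to_string(index=False))

smooth = lk.fit_smooth(rows)
print(f"\nsmooth fit: minimum at {smooth.minimum_bits:.2f} bits "
      f"(interior={smooth.interior}, edf={smooth.edf:.1f})")
print(
    "The end bins exceed the middle ones and the fitted minimum sits near "
    "the generating optimum of 1.25 bits: the cohort preferred events that "
    "were neither too predictable nor too surprising."
)

if len(sys.argv) > 1:
    lk.plot_ushape(rows, bins, smooth, path=sys.argv[1])
    print(f"figure written to {sys.argv[1]}")
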