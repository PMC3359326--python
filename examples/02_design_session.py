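"""Generate the two experimental stimulus sessions from a seed.

A single-box session holds 42 trials (each probability-of-appearance from 0
to 1 in 0.05 steps used twice, first reveal always showing the object); a
three-box session holds 32 trials, one per probability triple.  Sequences
are pre-generated to the 30-event cap implied by the 60 s timeout.
"""

import collections

import lookaway as lk

exp1 = lk.generate_exp1_session(seed=7)
print(f"single-box session: {len(exp1)} trials")
counts = collections.Counter(d.generating_p for d in exp1)
print(f"  distinct probabilities-of-appearance: {len(counts)} (each x{counts[0.5]})")
print(f"  first reveal always shows the object: "
      f"{all(d.sequence[0] == 'present' for d in exp1)}")
d = exp1[0]
print(f"  trial 1: p = {d.generating_p:.2f}, first 10 events: "
      + ",".join("1" if s == "present" else "0" for s in d.sequence[:10]))

exp2 = lk.generate_exp2_session(seed=7)
print(f"\nthree-box session: {len(exp2)} trials")
simple = next(x for x in exp2 if x.generating_distribution == (1.0, 0.0, 0.0))
print(f"  a deterministic triple {simple.generating_distribution} gives: "
      + ",".join(simple.sequence[:8]) + ",...")
skewed = next(x for x in exp2 if sorted(x.generating_distribution) == [0.1, 0.1, 0.8])
print(f"  a skewed triple {skewed.generating_distribution} gives:        "
      + ",".join(skewed.sequence[:8]) + ",...")
print("\nEvery infant in a simulated cohort watches these same sequences in "
      "an independently shuffled order, as in the original design.")
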