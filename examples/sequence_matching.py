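"""Stimulus sequences with matched histograms but opposite dynamics.

Generates an i.i.d. reference sequence, then tunes the random-walk and
two-state generators so their histograms match the reference's while their
temporal structure stays completely different — the construction used to
show that the three generative assumptions are distinguishable only through
sequential structure, not through marginal distributions.
"""

import magest as mg
from magest.sequences import lag1_autocorrelation

reference = mg.gen_iid_sequence(1000, mean=1150, sd=300, bounds=(400, 1900),
                                seed=42)
walk, kl_walk = mg.match_histograms(reference, "random_walk", seed=1)
two_state, kl_two = mg.match_histograms(reference, "two_state", seed=1)

print(f"{'sequence':<12} {'KL to reference':>16} {'lag-1 autocorr':>15}")
print(f"{'iid (ref)':<12} {0.0:16.4f} {lag1_autocorrelation(reference.values):15.3f}")
print(f"{'random walk':<12} {kl_walk:16.4f} {lag1_autocorrelation(walk.values):15.3f}")
print(f"{'two-state':<12} {kl_two:16.4f} {lag1_autocorrelation(two_state.values):15.3f}")
print()
print("Small KL: nearly indistinguishable marginals.  The lag-1 "
      "autocorrelation separates the generators: ~0 for i.i.d., ~1 for the "
      "walk, intermediate for the drifting-mean (two-state) process.")
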