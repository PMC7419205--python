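"""Date LTR retrotransposon insertions from 5'/3' LTR divergence.

An element's two terminal repeats are identical at insertion and diverge
neutrally afterwards: lambda (mismatch proportion of their alignment) is
corrected for multiple hits, K = -0.75 ln(1 - 4 lambda / 3), and the
insertion age is T = K / (2r) at r = 1.51e-9 substitutions/site/year.
A cohort inserted around 9.9 Ma shows a K-density mode near 0.03.
"""

import numpy as np

from paleodup import dating, simcore

cohort = simcore.simulate_ltr_cohort(
    500, age_distribution=(9.9, 2.0), r=1.51e-9, ltr_length=1000, seed=6
)
dated = dating.date_ltr_cohort(cohort, r=1.51e-9)
curve, mode_k = dating.ltr_burst_profile(dated)

ages = np.array([p.T_ma for p in dated if p.T_ma is not None])
true_ages = np.array([age for _, _, _, age in cohort.pairs])
print(f"elements dated:    {ages.size}")
print(f"mean inferred age: {ages.mean():.2f} Ma (true mean {true_ages.mean():.2f} Ma)")
print(f"K density mode:    {mode_k:.4f}")
print(f"burst age at mode: {mode_k / (2 * 1.51e-9) / 1e6:.1f} Ma")
# The mode of the per-element Jukes-Cantor distance K is the cohort's burst
# signature; dividing by 2r converts it to the burst age.
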