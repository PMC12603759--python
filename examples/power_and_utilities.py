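"""Small statistics: animal-study group size, 2^-ddCt, proliferation ratio."""

from cytohts.aux_stats import (PhaseCounts, PowerSpec, fold_change_ddct,
                               proliferation_ratio, sample_size_two_sample_t,
                               simulate_rejection_rate)

# Tumor-volume design: detect a 400 mm3 difference with sd 125 mm3,
# two-sided alpha 5%, power 80%.
spec = PowerSpec(delta=400, sd=125, alpha=0.05, power=0.80)
n = sample_size_two_sample_t(spec)
rate = simulate_rejection_rate(n, 400, 125, n_sim=10000, seed=1)
print(f"minimum animals per group: {n} "
      f"(simulated rejection rate at n={n}: {rate:.1%})")

# Relative transcript quantification: a ddCt of +1.52 means the target is
# reduced to 2^-1.52 = 35% of control, i.e. a 65% knockdown.
fc = fold_change_ddct(ct_target_treated=24.52, ct_ref_treated=18.0,
                      ct_target_control=23.0, ct_ref_control=18.0)
print(f"fold change: {fc:.3f} (a {1 - fc:.1%} reduction)")

# Cell-cycle proliferation ratio: proliferating (S+G2) over
# non-proliferating (sub-G1 + G1) events.
ratio = proliferation_ratio(PhaseCounts(sub_g1=0, g1=100, s=10, g2=19))
print(f"proliferation ratio: {ratio:.2f}")
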