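"""Binned A/B comparison: where does cholesterol associate with CVD?

After a Pearson screen for cholesterol-blood-pressure confounding, the
cohort is stratified into diastolic-pressure bins; in each bin the mean
cholesterol of CVD cases (a dot) is compared against a 95%
percentile-bootstrap CI for the whole bin's mean cholesterol (whiskers).
"""

from dietheart import FHSGeneratorConfig, generate_fhs, run_scenario3

cohort = generate_fhs(FHSGeneratorConfig(seed=1))
res = run_scenario3(cohort, n_boot=5000, level=0.95, seed=4)

print(f"cholesterol-DBP Pearson correlation = {res.corr:.3f} "
      f"(screen passed: {res.corr_screen_passed})")
print()
print(f"{'bin':>10} {'n':>5} {'cases':>5} {'pop CI (mg/dL)':>18} {'case mean':>10}  flag")
for b in res.bins:
    if b.insufficient:
        flag = "insufficient"
        ci = "-" if b.n_all == 0 else f"[{b.ci_low:6.1f},{b.ci_high:6.1f}]"
        case = "-" if b.n_cvd == 0 else f"{b.mean_cvd:8.1f}"
    else:
        flag = "ASSOCIATED" if b.associated else "-"
        ci = f"[{b.ci_low:6.1f},{b.ci_high:6.1f}]"
        case = f"{b.mean_cvd:8.1f}"
    print(f"{b.label:>10} {b.n_all:>5} {b.n_cvd:>5} {ci:>18} {case:>10}  {flag}")
print()
print("Case-mean dots escape the population interval in every normal")
print("pressure bin (60-100 mmHg): there, CVD cases carry ~20-25 mg/dL")
print("higher cholesterol. In abnormal pressure ranges the true association")
print("is absent, though the dot-versus-interval rule can still fire there")
print("by chance (the case mean is noisier than the interval is wide; see")
print("docs/methods.md on the rule's calibration).")
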