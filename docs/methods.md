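# Methods

## What the package models

Three questions about the diet–heart hypothesis are examined with
resampling methods chosen for small, non-normal, right-censored samples:

1. whether a low-saturated-fat diet lowers serum total cholesterol
   (two-sample permutation test on percent cholesterol change);
2. whether a change in cholesterol is linked to CVD-caused death
   (bootstrap rank test on cause-specific hazards within each trial arm);
3. whether the cholesterol–CVD association depends on diastolic blood
   pressure (Pearson screen plus a per-pressure-bin comparison of
   CVD-case mean cholesterol against a bootstrap CI for the bin
   population mean).

Because participant-level trial and cohort data of this kind are
restricted, the package ships synthetic generators that reproduce the
*summary* structure those analyses see, and all calibration targets are
expressed against those summaries.

## Synthetic trial cohort (MCE-style)

Per arm, percent cholesterol change is normal:
diet arm mean −14, SD 13; control arm mean −1, SD 16 (percent points).
The SDs and the 13-point mean gap are the anchors the analyses are
calibrated to; the individual means are chosen to sum to that gap with a
realistic diet-arm reduction. Survival is competing exponentials with
administrative censoring at the 4.5-year follow-up horizon: each subject
draws a CVD-death time at a hazard selected by arm and by the sign of the
subject's own cholesterol change (change exactly 0 counts as "increase"),
plus an independent other-cause death time at 0.04/yr. Defaults, per
year:

| arm     | decrease subgroup | increase subgroup |
|---------|-------------------|-------------------|
| control | 0.18              | 0.06              |
| diet    | 0.085             | 0.065             |

The control values put the observed subgroup hazard contrast near
0.12/yr with a clearly significant bootstrap test. The diet values were
calibrated once by simulation and frozen so that the diet-arm contrast is
small and *non-significant*: across seeds the observed difference
averages ≈0.02/yr (inside the 0.04 ± 0.03 target band) and the two-tailed
bootstrap p-value has median ≈0.07. A larger diet-arm gap (e.g.
0.10 vs 0.06) makes the test reject almost always, which is not the
behavior being modeled. One consequence of keeping the arm means at
−14/−1 is a diet increase-subgroup of only ~160 subjects; its bootstrap
null spread is ≈±0.033, somewhat narrower than the ±0.05 spread the
modeled study reports — matching that spread would require CVD hazards
above 0.25/yr or a much smaller increase subgroup, both judged
unrealistic.

Censoring is administrative only (no random dropout) and the event code
is unique per subject. What the generator does **not** emulate: hospital
site clustering, non-exponential hazards, informative censoring,
longitudinal cholesterol trajectories, or LDL/HDL subfractions. Passing
tests therefore demonstrate correctness of the *methods* under a clean
data-generating process, not robustness to those real-data features.

## Synthetic observational cohort (FHS-style)

(cholesterol, diastolic blood pressure) is bivariate normal — means
235 mg/dL and 83 mmHg, SDs 45 and 12, correlation 0.33 — truncated below
at 1 to keep measurements positive (measure-zero effect at these
parameters). CVD is Bernoulli with log-odds
`logit(0.25) + 0.8 · z_chol` for subjects with DBP in [60, 100] mmHg and
`logit(0.25)` outside, so the cholesterol–CVD association exists *only*
inside the normal-pressure window, by construction. The 0.8 log-odds per
cholesterol SD shifts the CVD-case mean cholesterol by ≈25 mg/dL inside
the window — large enough that every sufficiently populated in-window bin
is flagged. Whether the flag is incident or prevalent disease is not
modeled; it is a cross-sectional label.

## Numerical and procedural choices

* **Hazard estimator.** "Rank estimator" is fixed as Nelson–Aalen; ties
  are handled by summing deaths at a time before decrementing the risk
  set, and deaths at a time are processed before censorings at the same
  time. The cumulative hazard is summarized as H(τ)/τ so the statistic is
  a per-year rate; τ defaults to the largest observed time in the arm.
  Other-cause deaths are *recoded* as censored (cause-specific
  convention), never deleted, so they keep contributing to risk sets.
* **Null schemes.** Scenario 1 relabels without replacement per round
  (classic permutation), sampling assignments with replacement across
  rounds; exhaustive enumeration replaces sampling when C(n, n₁) ≤ 10⁴.
  Scenario 2 uses a pooled bootstrap (resampling with replacement, then a
  pseudo-split at the observed subgroup sizes), which imposes the null of
  no subgroup effect; a label-permutation variant is available via
  `method="permutation"`. Resampling within subgroups (which would *not*
  impose the null) is deliberately not offered.
* **Empirical p-values** are plain indicator fractions with no +1
  correction, so p = 0 is attainable and should be read as "below the
  Monte-Carlo resolution" (1/2500 or 1/5000 at the defaults).
* **Bins.** Pressure bins default to 10-mmHg cut-points 40…120 with open
  tails; intervals are left-closed right-open except the last finite bin,
  which is closed, so 60 and 100 mmHg are exact bin edges. Bins with
  fewer than 20 members or zero CVD cases are reported but flagged
  `insufficient` and never `associated`.
* **Correlation screen.** The screen threshold |r| ≥ 0.1 operationalizes
  "any correlation present"; the correlation itself uses n−1 sample SDs
  and is clamped to [−1, 1] against floating-point overshoot. Zero
  variance raises a degenerate-input error rather than returning 0.
* **Bootstrap CI.** Percentile method (not BCa or normal-approximation):
  the simplest interval consistent with the package's nonparametric
  stance. For a fixed seed the resampled means are independent of the
  requested level, so nested levels give nested intervals.
* **Seeds.** Every public operation takes a seed; the pipeline derives
  per-stage seeds (< 2³¹) from one master seed via
  `numpy.random.SeedSequence` in a fixed stage order, so a single seed
  pins the whole run.

## Calibration of the dot-versus-interval rule

The Scenario-3 flag compares the CVD-case mean, a *point*, against the
CI of the *whole-bin* mean (cases included). This mirrors how such
figures are drawn, but it is not a calibrated two-sample test: in a null
bin with case fraction p, the case-mean deviation from the bin mean has
standard deviation s·√(1/m − 1/N) while the CI half-width is ≈1.96·s/√N,
so the flag fires with probability ≈ 2Φ(−1.96·√(p/(1−p))) — about 0.26
at the default 25% prevalence, not 1 − level = 0.05 (it would equal 0.05
only at p = 0.5). Simulation confirms ≈0.27. Users who need a calibrated
per-bin test should compare means with a two-sample procedure instead;
the package keeps the visual rule because reproducing that rule's
behavior is the point. Consequently, gate-recovery accuracy is assessed
over all bins with insufficient bins counted as "no association
evidence"; it averages ≈0.92 at the defaults, with errors concentrated in
sparse out-of-window bins.

## Problem sizes used in the test suite

Decision-level checks run at the full defaults (n = 2355 trial rows,
2500 permutations, 5000 bootstrap iterations). Calibration properties
(type-I error, CI coverage, uniformity of null p-values) run on reduced
problems — groups of 30–150 subjects, 200–600 resampling rounds, 400–1000
replicates — sizes at which the Monte-Carlo error of the property itself,
not the cost, dictates the design. Seed-averaged quantities use 10–50
replicate cohorts as stated per check.

## Known limitations

* The diet-arm hazard calibration is a reconstruction: the modeled study
  prints only the hazard contrasts (≈0.12 and ≈0.04), a p-value (≈0.067),
  and histogram spreads, never event counts or the estimator's time
  horizon, so the generator matches those summaries rather than any
  recovered dataset, and cannot match all of them simultaneously (see
  above on the null spread).
* Per-seed scenario-2 diet-arm p-values are intrinsically dispersed
  (the observed contrast sits at ~1.5 null SDs); single-seed runs reject
  at the 0.05 level in roughly a third of seeds. Seed-averaged p-values
  are the stable summary and are what the reproduction script reports.
* Exhaustive enumeration is O(C(n, n₁)) and guarded at 10⁴ assignments;
  the Monte-Carlo path is the practical route for trial-sized data.
* The A/B stage is associational only; no confounder adjustment or
  causal claim is implemented.
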