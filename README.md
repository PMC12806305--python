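# dietheart

Resampling re-analysis toolkit for the diet–heart question: does replacing
saturated fat lower serum total cholesterol, does lowering cholesterol
change cardiovascular (CVD) mortality, and how does diastolic blood
pressure modulate the cholesterol–CVD association?

The package is aimed at biostatisticians and epidemiology students who
want small-sample-robust, nonparametric versions of the classic diet–heart
analyses (which traditionally use a *t*-test and a Cox model), together
with synthetic cohorts that reproduce the statistical structure of a
Minnesota Coronary Experiment–style randomized trial (two arms of
1179/1176 participants) and a Framingham-style observational cohort
(3840 participants) — so every stage is testable without access to any
restricted participant-level data.

## The three analyses

**Scenario 1 — permutation test.** For diet-arm percent cholesterol
changes $d_i$ and control-arm changes $c_j$, the statistic is

$$t = \left| \tfrac{1}{n_d}\textstyle\sum_i d_i - \tfrac{1}{n_c}\sum_j c_j \right|,$$

with null distribution $\{t_n\}$ from random relabelings of the pooled
sample (2500 rounds by default; exhaustive enumeration when the
assignment space is small) and empirical p-value
$p = \tfrac{1}{N}\sum_n \mathbf{1}\{t_n \ge t\}$.

**Scenario 2 — bootstrap rank test on cause-specific hazards.** Each arm
is split by the sign of the individual cholesterol change. The CVD-death
hazard per subgroup is the time-averaged Nelson–Aalen estimate
$\hat\lambda = H(\tau)/\tau$ with
$H(t) = \sum_{s \le t} dN(s)/Y(s)$ (other-cause deaths and administrative
censoring both treated as censored). The statistic is
$h = \hat\lambda_{\text{decrease}} - \hat\lambda_{\text{increase}}$; its
null $\{h_n\}$ comes from 5000 bootstrap resamples of the pooled arm
split into pseudo-subgroups of the original sizes, and
$p = \tfrac{1}{N}\sum_n \mathbf{1}\{|h_n| \ge |h|\}$ (two-tailed).

**Scenario 3 — binned bootstrap-CI A/B comparison.** After a Pearson
screen for cholesterol–blood-pressure confounding
($r = \tfrac{1}{n-1}\sum_i \tfrac{x_i-\bar x}{s_x}\tfrac{y_i-\bar y}{s_y}$),
the cohort is stratified into 10-mmHg diastolic-pressure bins; in each
bin the mean cholesterol of CVD cases is compared against a 95%
percentile-bootstrap confidence interval for the bin population's mean
cholesterol, flagging the bin *associated* when the case mean falls
outside the interval.

## Worked example

```bash
python examples/scenario2_hazard_rank.py
```

generates the default trial cohort (2355 participants, seed 1) and runs
the subgroup hazard comparison in both arms (5000 bootstrap iterations),
printing

```
control arm: subgroups 610 decrease / 566 increase
  observed hazard difference h = +0.1296 per year
  bootstrap null spread (SD)   = 0.0111
  two-tailed p-value           = 0.0000 -> reject at 0.05
diet arm: subgroups 1048 decrease / 131 increase
  observed hazard difference h = +0.0265 per year
  bootstrap null spread (SD)   = 0.0147
  two-tailed p-value           = 0.0738 -> fail to reject at 0.05
```

Read: in the
control arm, participants whose cholesterol fell die of CVD about 0.13/yr
faster than those whose cholesterol rose — a contrast far outside the
bootstrap null, so cholesterol change and CVD hazard are linked there. In
the diet arm the contrast (~0.03/yr) sits inside its null spread: no link
is demonstrated. The other capabilities are walked through in
`examples/` (cohort generation, the permutation test, the binned A/B
table, and the single-seed full pipeline / JSON report, also available as
the `dietheart` command-line tool).

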