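# omega3cmr

Quantitative cardiac-MR tissue characterization and genotype-stratified
analysis of omega-3 treatment effects on post-infarction remodeling.

## The problem

After an acute myocardial infarction, adverse left-ventricular remodeling —
rising end-systolic volume, diffuse interstitial fibrosis — drives later
heart failure.  High-dose omega-3 fatty acids (O-3FA) can attenuate this
remodeling, but the response varies between patients.  A plausible modifier
is the FADS2 gene (rs1535): its minor G allele reduces delta-6 desaturase
activity (measurable as a lower arachidonic/linoleic, ArA/LA, ratio in red
blood cell membranes), and GG homozygotes may benefit most from
supplemented long-chain omega-3s.

`omega3cmr` implements the full quantitative chain needed to study this
question, for imaging scientists and trial statisticians:

1. **Relaxometry** — per-segment inversion-recovery fitting
   S(TI) = A − B·e^(−TI/T1\*) with the Look-Locker correction
   T1 = T1\*·(B/A − 1).
2. **ECV mapping** — partition coefficient λ as the OLS slope of myocardial
   R1 = 1/T1 on blood-pool R1 across contrast states (pairs with blood
   R1 ≥ 3.5 s⁻¹ excluded for fast-water-exchange validity), then
   ECV = λ·(1 − HCT); non-infarct ECV is averaged over AHA-16 segments
   without late enhancement.
3. **Infarct quantification** — 2-SD thresholding of LGE images against
   remote myocardium; infarct mass (1.05 g/mL) and percent of LV mass.
4. **Lipids & genetics** — omega-3 index (EPA% + DHA%), ArA/LA desaturase
   surrogate, allele frequencies and Hardy-Weinberg chi-square.
5. **Trial statistics** — per-genotype drug-vs-placebo change-score
   contrasts (Welch t), odds ratios of ≥10% LVESVi improvement, Spearman
   correlations of fatty-acid rises with remodeling, ANOVA/chi-square
   baseline comparisons, Bonferroni-adjusted paired Wilcoxon visit tests.
6. **Synthetic data** — imaging phantoms and trial cohorts with embedded
   ground truth, defaulting to the published study summaries, so every
   stage is testable without patient data.
7. **Pipeline + CLI** — end-to-end orchestration with deterministic,
   seed-stamped JSON reports (`omega3cmr report`, `... analyze`,
   `... ingest`, …).

## Worked example

```python
import numpy as np
from omega3cmr.simulate import PhantomConfig, CohortConfig, generate_phantom, generate_cohort
from omega3cmr.pipeline import fit_phantom
from omega3cmr import trialstats as ts

# Imaging: noiseless phantom through relaxometry -> ECV -> infarct
bundle = generate_phantom(PhantomConfig(noise_sd=0.0, seed=0))
out = fit_phantom(bundle)
print(f"lambda = {np.mean(out['lambda_per_segment']):.4f}")
print(f"non-infarct ECV = {out['noninfarct_ecv']:.4f}")

# Cohort: balanced synthetic trial at the published effect sizes
df, truth = generate_cohort(CohortConfig(n_per_genotype_arm=5000, seed=1))
eff = ts.stratified_effect(df, "lvesvi", "GG")
print(f"GG dLVESVi: drug {eff.mean_change_drug:+.2f}, placebo {eff.mean_change_placebo:+.2f}")
for gt in ("AA", "AG", "GG"):
    print(gt, "OR =", ts.responder_odds(df[df['genotype'] == gt]).odds_ratio_1dp)
```

prints

```
lambda = 0.4500
non-infarct ECV = 0.2700
GG dLVESVi: drug -4.44, placebo +1.15
AA OR = 1.4
AG OR = 1.7
GG OR = 9.1
```

The phantom closure is exact: the fitted partition coefficient and ECV equal
the embedded truth (λ = 0.45, ECV = 0.45·(1 − 0.40) = 0.27).  In the
synthetic cohort the GG stratum reproduces its generator means (−4.4 vs
+1.2 mL/m² LVESVi change), and the odds of ≥10% LVESVi improvement are far
higher on drug than placebo only in GG patients — the AA < AG < GG ordering
of odds ratios that motivates genotype-guided treatment.

## Layout

```
src/omega3cmr/
  relaxometry.py   IR fitting, Look-Locker correction
  ecv.py           R1, partition coefficient, ECV, non-infarct aggregation
  infarct.py       2-SD LGE segmentation, masses
  lipids.py        O3I, ArA/LA, genotype tables, Hardy-Weinberg
  trialstats.py    stratified effects, odds, correlations, visit tests
  simulate.py      phantom and cohort generators with ground truth
  pipeline.py      orchestration, ingest, JSON reports
  cli.py           click CLI (simulate / fit-t1 / ecv / infarct / analyze / report / ingest)
docs/methods.md    models, assumptions, generator design, limitations
```
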