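# Methods

This note documents the models implemented in `omega3cmr`, the assumptions
behind them, the synthetic-data generators that stand in for patient data,
and the numerical and design choices that were genuinely open.

## Quantitative CMR tissue characterization

### Inversion-recovery relaxometry (`relaxometry`)

A Look-Locker gradient-echo readout samples the recovering longitudinal
magnetization at a series of inversion times TI.  The segment-averaged
(or blood-pool-averaged) signed signal is modeled as

    S(TI) = A − B·exp(−TI/T1*),

and the apparent relaxation time T1* — shortened by the repeated readout —
is corrected to the true T1 with

    T1 = T1*·(B/A − 1).

The fit is a bounded nonlinear least squares (`scipy.optimize.least_squares`)
over (A, B, T1*) with T1* ∈ (0, 10 s], initialized at A₀ = max signal,
B₀ = max − min, T1*₀ = median TI; this start is robust across physiologic
myocardial and blood T1 at any clinical field strength.  Solver tolerances
are set to 1e−14 so a noiseless curve is recovered to well below 1e−6
relative error; non-convergence is reported via a `converged` flag rather
than an exception, while a fit that collapses onto the T1* lower bound
raises a degenerate-fit error.  The model is fit to *signed* signals;
magnitude data with polarity restoration are out of scope.  Fitting is
per-segment (segment-averaged signal), not per-pixel.  All times are
seconds internally; the blood-pool exclusion rule below (3.5 s⁻¹) fixes
that unit choice.

### Partition coefficient and ECV (`ecv`)

Gadolinium distributes extracellularly, so across contrast states the
myocardial relaxation rate R1 = 1/T1 tracks blood-pool R1 linearly under
fast transcytolemmal water exchange.  The partition coefficient λ is the
OLS slope of R1_myo on R1_blood over the pre-contrast and 5/15/25-minute
post-contrast pairs, with an intercept (the regression is a line fit, not a
forced ratio; λ is the slope only).  Pairs with blood R1 ≥ 3.5 s⁻¹ are
excluded before fitting — at high contrast concentration the fast-exchange
assumption fails and λ (hence ECV) would be biased low.  The boundary value
3.5 itself is excluded (only pairs strictly below the limit are kept, a
literal reading of the "below" rule).  Then

    ECV = λ·(1 − HCT)

with the hematocrit HCT as a fraction in (0, 1).  A result outside [0, 1]
is non-physical; it is flagged with a warning and returned unclipped so the
caller can audit it.  The global non-infarct ECV is the unweighted mean of
ECV over AHA-16 segments without matching late enhancement; it estimates
diffuse interstitial fibrosis away from the scar.  The module fits whatever
pair set it is given (≥ 2 retained pairs); pooling across patients or
segments is the caller's decision.

### 2-SD infarct segmentation (`infarct`)

On LGE images, infarct is defined as myocardial pixels with intensity at or
above mean + 2·SD of an operator-supplied remote-myocardium region
(inclusive ≥; sample SD with n−1 denominator; k is configurable).  No
connectivity or minimum-feature-size filtering is applied.  Masses use
pixel area × slice thickness × 1.05 g/mL, the standard myocardial density.
Infarct percent of LV mass is 100·(infarct mass)/(LV mass from all
myocardial pixels).  A remote region with zero spread has no defined
threshold and raises an error.  A remote mask is required per slice.

## Fatty acids and FADS2 genetics (`lipids`)

The omega-3 index is O3I = EPA% + DHA% of total RBC membrane fatty acids.
Delta-6 desaturase (FADS2) activity is proxied by the product/precursor
ratio ArA/LA; rs1535 G-allele carriers desaturate less, giving an
AA > AG > GG gradient in the ratio.  Fatty-acid columns are used as
delivered by the assay (percent of total identified fatty acids); no
re-normalization is applied.

Hardy-Weinberg equilibrium is tested with the standard asymptotic
chi-square: expected counts n·p², 2npq, n·q² from the observed allele
frequencies, one degree of freedom after estimating p.  On the genotype
counts 156/122/34 this gives χ² ≈ 1.84, p ≈ 0.17.  An exact test could give
a different p-value; since the choice of test is an open question for this
cohort, no specific published p-value is asserted.  Monomorphic samples fit
HWE trivially (statistic 0); an expected cell below 1 flags a warning
because the asymptotic approximation degrades.

## Trial statistics (`trialstats`)

The cohort is a pandas DataFrame (one row per patient) with the column
dictionary in `trialstats.COLUMN_DICT`.  All analyses are complete-case
with exclusion counts logged; no imputation.

- **Change scores** are absolute 6-month changes (followup − baseline);
  negative is improvement for volumes, ECV and biomarkers.  Natural-log
  transformation is available for skewed biomarkers; non-positive values
  are excluded with logging.
- **Stratified effects** compare arms within a genotype stratum with a
  two-sample t-test.  Welch (unequal variances) is the default for
  robustness; the pooled-variance Student flavor is exposed as an option.
- **Responder odds**: a responder improves LVESVi by ≥ 10% of baseline
  (relative definition, configurable to absolute).  Per-arm odds are
  responders/non-responders; the odds ratio is drug/placebo.  A zero cell
  yields an infinite, flagged odds ratio; an optional Haldane-Anscombe
  +0.5 correction is off by default.  Ratios are reported to one decimal;
  full precision is retained internally.
- **Rank correlations** between fatty-acid changes and the LVESVi change
  use Spearman's rho (midranks for ties).
- **Baseline comparisons** across genotypes use chi-square (categorical)
  or one-way ANOVA (continuous).
- **Paired visit tests** use the paired Wilcoxon signed-rank test with
  Bonferroni adjustment (p × number of comparisons, capped at 1).
- **Median splits** label values ≤ median as "low" (ties go low).
- Significance is two-sided p < 0.05; no multiplicity adjustment is
  applied outside the paired-visit context.

## Synthetic data (`simulate`)

### Imaging phantom

`generate_phantom` embeds a known λ, intercept and HCT: blood T1 defaults
(1.90, 0.40, 0.55, 0.70 s for pre/5/15/25 min, approximating a 3 T study
with 0.1 mmol/kg gadolinium) are converted to R1, and myocardial R1 is set
to λ·R1_blood + intercept *exactly* before noise, so the regression stage
has a closed-form truth.  IR curves use A = 1000, B/A = 1.8 (T1* = T1/0.8)
sampled at TI = 0.1–3.0 s in 0.2 s steps, with optional i.i.d. Gaussian
noise.  The LGE slice plants a hyperenhanced block at remote mean + 6 SD
inside a block myocardium.  The remote texture is a deterministic two-level
pattern (mean ± SD on alternating pixels) rather than a random draw: this
gives the noiseless phantom a well-defined remote SD, so the 2-SD threshold
exists and the segmented mask equals the planted region exactly — the
noise-free closure every stage is tested against.  Gaussian noise is added
on top when configured.

### Trial cohort

`generate_cohort` draws, per patient: genotype from Hardy-Weinberg
proportions of the G-allele frequency 190/624 ≈ 0.305 (matching counts
156/122/34 at n = 312); arm as Bernoulli(0.5); race with the cohort's
frequencies (81% Caucasian); hematocrit ≈ 0.395 ± 0.05; ArA/LA ratio
Normal by genotype (2.01 ± 0.36 / 1.76 ± 0.35 / 1.62 ± 0.35) applied to a
linoleic-acid percentage of 8.5 ± 1.0; baseline endpoints at the cohort's
published baseline summaries (normal for volumes/LVEF/ECV, log-normal for
infarct size and biomarkers); and 6-month changes Normal with the
per-(genotype, arm) means/SDs of the published effectiveness table for the
five imaging endpoints, the published GG stratum values for NT-proBNP,
galectin-3 and Lp(a), and arm-similar values consistent with the overall
cohort for the AA/AG biomarker strata, which were reported only as
"similar between arms".  hsCRP changes are arm-similar small values (no
significant differences were reported anywhere).

On-study EPA and DHA rises (drug +2.4 ± 1.3 and +2.0 ± 1.3 percentage
points; placebo 0 ± 0.4/0.5) were chosen once as realistic for 4 g/day
omega-3 therapy, since the published levels are shown only graphically.
Each acid's change shares a latent Gaussian factor with the LVESVi change:
for Spearman target ρ_s the copula uses r = 2·sin(π·ρ_s/6), which is exact
for bivariate normals.  Targets are the published whole-cohort coefficients
(EPA −0.17, DHA −0.31); O3I changes are the sum of the two, so their
coupling is emergent.  The configured target is achieved *within* a
(genotype, arm) stratum; the whole-cohort rank correlation comes out
stronger (≈ −0.3 to −0.4) because the treatment effect itself aligns
fatty-acid rises with LVESVi improvement across arms.  This is verified
empirically in tests, not assumed.

Endpoint changes other than the configured fatty-acid coupling are drawn
independently within a patient; real within-patient correlation between,
say, ΔLVESVi and ΔNT-proBNP is unreported and not emulated.  Other
deliberate non-realism: no measurement error model on top of the endpoint
changes, no dropout/missingness, biomarker followups can go slightly
negative in extreme draws (absolute-change analyses are unaffected;
log-scale analyses exclude them with logging), and no MR artifacts
(motion, partial volume) in the phantom.  Passing tests therefore
demonstrate correctness of the estimators and pipeline plumbing under the
published distributional summaries — not robustness to real-data
pathologies.

### Problem sizes

Parameter-recovery runs use balanced blocks of 5,000 patients per
genotype × arm (30,000 per replicate) and 100 seeded replicates for the
odds-ratio ordering check; distributional checks of the generator itself
use 20,000–100,000 patients.  Phantom Monte-Carlo uses 100 noisy
replicates.  These sizes put Monte-Carlo error well below the 3-standard-
error acceptance bands while keeping a full run to a few seconds.

## Pipeline and ingest (`pipeline`, `cli`)

`run_pipeline` chains simulate → relaxometry → ECV → infarct → cohort →
stratified analysis and writes per-stage text outputs plus a JSON report
carrying the package version, seed and a SHA-256 configuration hash; the
report contains no timestamps, so identical config + seed reruns are
byte-identical.  Every reported number is reproducible by calling the
underlying module on the saved intermediate files (tested).  Cohort
spreadsheets (CSV/XLSX) are ingested through a JSON column map onto the
documented schema; rows with missing/invalid genotype or arm are excluded
with logged counts, and internally inconsistent values (e.g. negative
volumes) are warned about, never corrected.  The CLI subcommands
(`simulate`, `fit-t1`, `ecv`, `infarct`, `analyze`, `report`, `ingest`)
are thin wrappers over the library.

## Known limitations

- Per-segment (not per-pixel) T1 fitting; no MOLLI/ShMOLLI variants, no
  inversion-efficiency or B1 correction, no polarity restoration.
- Bolus-equilibrium ECV only; the fast-exchange breakdown is handled by
  exclusion, not by two-space kinetic modeling.
- 2-SD thresholding only (no FWHM family); no microvascular-obstruction
  handling; remote ROIs are inputs, never inferred.
- Stratum-wise contrasts only: no mixed models, covariate adjustment or
  formal genotype × treatment interaction tests.
- The HWE test is asymptotic; small-cell exactness is flagged, not solved.
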