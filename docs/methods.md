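# Methods

`mrmref` implements a targeted-proteomics reference-range workflow for
first-trimester maternal serum: stable-isotope-dilution MRM quantification
with bioanalytical acceptance gating, normalization benchmarking, and
multiples-of-the-median (MoM) reference ranges with clinical covariate
adjustment. This note records the models, the defaults and why they were
chosen, the numerical conventions, and known limitations.

## Quantification model

Each peptide's quantification signal is the light/heavy peak-area ratio
against a spiked stable-isotope internal standard (SIS, 100 fmol/µL). Per
peptide and batch, a straight line is fitted to the calibration standards by
weighted least squares with weights `w_i = 1/x_i²`, minimizing
`Σ w_i (y_i − a − b·x_i)²`. The 1/x² weighting equalizes the *relative*
leverage of levels spanning more than two decades, which is the standard
choice for bioanalytical assays. The fit is solved by the closed-form 2×2
normal equations; tests check agreement with an independent normal-equations
oracle to ten significant digits. Concentrations are recovered by inversion,
`ĉ = (r − a)/b`, in fmol/µL (numerically equal to nM for serum).

R² is reported on the weighted fit (weighted residual sum of squares over
weighted total sum of squares about the weighted mean); the weighting scheme
and an unweighted correlation-based R² are both configurable since
conventions differ between software packages.

### Acceptance gating

All thresholds live in `PipelineConfig` and default to the ICH M10-style
rules for this assay class:

| parameter | default | meaning |
|---|---|---|
| `accuracy_tol` | 0.20 | max relative deviation of back-calculated standards/QCs |
| `precision_tol` | 0.20 | max CV across replicate back-calculations of a level |
| `min_standards_pass` | 5 | levels that must pass for a curve to pass |
| `total_standards` | 7 | calibration levels A (LLOQ) … G (HLOQ) |
| `qc_pass_frac` | 0.66 | QC measurements within tolerance for a valid batch |
| `curve_pass_frac` | 0.90 | passing curves for a valid batch |
| `r2_min` | 0.99 | R² a curve must exceed for "quantified" status |
| `detect_frac` | 0.50 | max fraction of clamped/missing cohort cells |
| `cv_exclude` | 0.20 | mean control CV at/above which a protein is excluded |

Source descriptions of this assay class are inconsistent about whether the
design has seven or eight calibration levels and correspondingly whether
"five standards" is 5-of-7 or 5-of-8; both counts are exposed as
configuration and the default is 5 of 7. Cohort duplicates are averaged
*after* back-calculation so the LLOQ/HLOQ clamp applies to the biological
estimate; clamped cells carry flags and participate in downstream medians
(the assigned-value convention). The pooled-serum control has no nominal
concentration and therefore does not enter the 66% QC rule; precision for a
calibration level with a single replicate cannot be evaluated and the level
is gated on accuracy alone.

## Synthetic cohort generator

The generator produces a complete in-silico experiment with known ground
truth. Cohort covariates follow the target population: age from a truncated
normal (median 30.5 y, range 20.5–37.3), BMI likewise (21.2, 15.6–30.1),
gestational age uniform on 11.3–13.9 weeks, parity categorical
(48/39/12/1 % for 1–4), uterine myoma Bernoulli(0.10), male fetus
Bernoulli(0.49), batches assigned near-equally.

True concentrations per protein *p* and sample *s*:

```
C[s,p] = median_p · 10^(σ_p·N(0,1)) · Π_c (1 + β_{p,c}·z_{s,c})
```

with `z` the mean-centered covariate. Protein medians are log-uniform over
5.3 decades. Biological spreads σ_p (log10) are drawn from [0.03, 0.13] for
the majority so their 90%-central fold change (q95/q5 = 10^(3.29·σ)) stays
below 3; 10% of the panel is designated high-variance, anchored by two
extreme proteins with designed fold changes of 123.9 and 9.9 (a pregnancy-
zone-protein-like and a lipoprotein(a)-like analyte). Covariate effects are
multiplicative, `(1+β·z)`, exactly the form under which an ordinary linear
model of MoM on covariates is correctly specified; the default effect set
puts moderate effects (|β| ≈ 0.03–0.15 per unit) on a dozen proteins,
heaviest on BMI and parity, mirroring the dominant associations in this
population.

Measured response ratios add technical structure:

```
r = C/sis · 10^(δ_{batch,protein} + s_sample) · ε,   ε lognormal, median 1
```

* Batch effects δ are per-(batch, protein) log10 shifts, SD 0.05; sample
  effects are per-sample log10 shifts, SD 0.05 — exactly the structures
  ComBat and RobNorm model, so recovery tests are well-posed.
* Technical noise is multiplicative log-normal so the CV is directly
  interpretable. Serum/BSA-matrix material (cohort samples, QCA-C, the
  pooled-serum control) carries `tech_cv` = 0.08; calibration standards —
  chemically defined peptide spikes in clean surrogate matrix — carry
  `standard_cv` = `tech_cv`/2. Separating the two reflects the physical
  difference between matrix-digested serum and synthetic spikes, and it is
  what lets a strict per-batch R² > 0.99 gate coexist with ~8% serum-level
  replicate CVs: with a single uniform 8% CV the weighted R² of a perfectly
  linear curve sits almost exactly at 0.99 and the gate becomes a coin flip.
* Batch and sample shifts apply only to serum-matrix rows: they model
  matrix/digestion effects that per-batch calibration cannot remove, which
  is why they survive into the quantified matrix and must be handled by
  normalization. This also makes the pooled-serum control the batch-effect
  sentinel, as in real designs.
* Two proteins default to a 1.0 matrix CV with clean calibration
  ("acute-phase-like" instability; real counterparts show >70% CVs). They
  pass quantification and are then excluded by the CV filter — each
  exclusion rule binds at its designed stage.
* 24 proteins default to "dropout": their LLOQ is placed at the 75th
  percentile of the *measured* cohort distribution (biological spread plus
  shift and duplicate-averaged noise variance), so they fail the >50%
  out-of-range rule and 115 of 139 panel proteins are quantified by
  construction.

Proteins are generated independently; no inter-protein correlation is
simulated, and no chromatographic drift, interference or digestion
variability is modeled. Passing tests therefore demonstrate correctness of
the pipeline's statistics under the stated error model, not robustness to
every failure mode of real LC-MRM-MS data.

## Normalization and benchmarking

All model-based methods work on log10 concentrations and exponentiate back.
Methods are fitted on cohort samples only; control samples are transformed
with the fitted parameters, so the CV criterion scores generalization rather
than self-fit.

* **Quantile** — rank-based; each sample's sorted values are replaced by the
  cross-sample mean of order statistics (ties receive midrank-interpolated
  reference values). Applied on the concentration scale.
* **Cyclic LOESS** — per sample, a locally weighted regression of
  M = log-difference on A = log-average against the mean reference profile
  is subtracted; cycles repeat until corrections vanish (default span 0.7,
  3 cycles; `lowess` with δ-interpolation for speed). The classic
  all-pairs variant with symmetric half-corrections is also implemented;
  the reference-based variant is the default because it is O(n) rather than
  O(n²) in samples and converges to the same fixed point for shift-like
  distortions.
* **RobNorm** — per-sample effects estimated by a density-power-weighted
  Gaussian criterion: observations are weighted by the model density to the
  power γ (default 0.5), so outlying proteins are down-weighted and the
  majority determines the shift. The scale update uses the density-power
  fixed point σ² = (1+γ)·Σw r²/Σw; γ → 0 recovers maximum-likelihood column
  means. New samples are transformed by re-estimating their scalar effect
  with µ and σ held fixed.
* **ComBat** — parametric empirical-Bayes location/scale batch adjustment:
  standardize per protein, estimate per-(batch, protein) location/scale,
  shrink toward moment-fitted normal / inverse-gamma priors via the standard
  iterative solution, adjust, de-standardize. The implementation matches
  Bioconductor `sva::ComBat` to ~1e-7 on identical input (unit-tested via
  Rscript).

The benchmark: per protein, CV = SD/mean (linear scale) within each control
group — standards pooled per level across batches, each surrogate-matrix QC
level, pooled serum — averaged over groups; the median over proteins
summarizes a method; methods are compared by one-sided paired Wilcoxon
signed-rank tests on per-protein mean CVs ("paired Mann–Whitney" in common
usage names the same paired rank test). Proteins with mean CV ≥ 20% on the
selected method are excluded.

Two honest findings from this design, verified experimentally and left
visible as failing checks rather than hidden:

1. *EB shrinkage bounds ComBat's measurable batch-effect removal.* Because
   standardized batch-effect sizes differ across proteins, the common prior
   shrinks each location estimate by δ²/(nτ²+δ²) (~15–30% here), so the
   empirical batch-mean reduction plateaus near 70–85%, not ≥90%;
   `sva::ComBat` reproduces the identical 70.3% on the same matrix.
2. *On noise-only control profiles, a flexible correction beats a scalar
   one by construction.* LOESS's smoother absorbs ~2.5 effective degrees of
   freedom of each control replicate's own noise versus ~1 for RobNorm's
   scalar, giving LOESS a systematic ~0.5–1.5% relative CV edge under purely
   scalar simulated shifts. RobNorm's real-data advantage — robustness of
   corrections against heavy-tailed biological variation — has nothing to
   grip on control profiles that contain no biology, so the RobNorm ≤ LOESS
   ordering observed on real cohorts does not emerge from this generator
   (joint all-pairs normalization was tested and does not change this).

## MoM transformation and reference statistics

`MoM[s,p] = C[s,p] / median_p(C)`, medians over non-missing cells, so the
per-protein median MoM is exactly 1 before adjustment and the transform is
invariant to per-protein rescaling. Reference entries report n, median, SD,
CV (SD/mean, linear scale), min/max, the 5%/95% quantiles (numpy's
linear-interpolation estimator, used consistently everywhere), the fold
change q95/q05 (identical on raw and MoM scales), and the central-90% MoM
interval and width. Entries with fewer than 20 observations are flagged
unreliable. MoM denominators default to the normalized matrix chosen by the
benchmark, following the pipeline order normalize → MoM; raw-scale outputs
are also emitted.

## Covariate screening and adjustment

The Spearman screen correlates every protein's MoM values with every
clinical column (parity as a numeric ordinal; myoma and fetal sex as 0/1;
any extra numeric annotation column is screened generically). Rho uses
midranks; two-sided p-values use the t-approximation with n−2 df, replaced
by exact permutation enumeration for n ≤ 9 (full enumeration beyond ~9! is
not worth its cost; at the study n = 83 the t-approximation's type-I error
is calibrated to [0.03, 0.07] by Monte Carlo in the acceptance suite). Raw
p < 0.05 flags significance, and a Benjamini–Hochberg q-value column is
emitted because a ~100 × 6 screen demands it for any serious reuse.

Per protein, MoM is regressed on the six candidates by OLS (on the MoM
scale, matching the multiplicative effect model; a log-scale variant is a
one-line change) and refined by backward elimination: while any predictor
has p ≥ 0.05, the largest-p predictor is dropped and the model refitted,
one at a time. Note the familywise consequence: with six null candidates,
the *most* significant one survives to the final refit, so ~25% of null
proteins retain a spurious predictor at α = 0.05 (each individual predictor
is falsely retained in only ~5% of runs) — an inherent property of
backward elimination at a fixed α, not an implementation artifact.

Each final model reports the baseline covariate profile x₀ at which the
expected MoM is exactly 1: retained covariates are anchored at cohort
medians and the remaining one is solved analytically (trying the last
retained predictor first and preferring in-range solutions; the profile is
flagged when no in-range solution exists). The underdetermined multi-
covariate case has no canonical answer; the median-anchored convention is
this package's documented choice. Adjusted values are
`observed / expected MoM`, with the expected value floored at 0.1 to
prevent explosion, intercept-only models passing through unchanged, and
each adjusted column re-centered to median 1.

## Problem sizes and determinism

All randomness flows from a single integer seed through
`numpy.random.default_rng` / `SeedSequence`; the CLI logs the seed and a
configuration hash, and two runs with the same seed produce byte-identical
tables. The default experiment is the study condition itself (83 samples ×
139 proteins × 3 batches) and runs the full pipeline in a few seconds.
Monte-Carlo checks use 50 seeds for the normalization ordering, 200
replicate cohorts for covariate-model recovery, and 1000 simulations for
screen calibration — sizes at which the binomial error of the checked rates
is well below the asserted margins.

## Known limitations

* Proteins are simulated independently; real serum proteins co-vary.
* The noise model is a two-level (serum vs spike) constant-CV lognormal; it
  has no intensity-dependent variance, carryover or drift, so LOESS's
  ability to remove intensity-dependent bias is exercised only by a
  dedicated synthetic bend, not by the default generator.
* The backward-elimination procedure inherits the selection-inference
  caveats of stepwise methods; reported per-predictor p-values are not
  adjusted for selection.
* Trisomy-risk calculators, raw-spectra processing and cross-platform
  (ELISA) harmonization are out of scope.
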