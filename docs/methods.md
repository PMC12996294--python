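# Methods

This note documents the models behind `cfmulti`, the defaults that matter,
what the synthetic-cohort generator does and does not emulate, and the
numerical choices a maintainer should know about.

## Synthetic cohorts

The generator (`cfmulti.simulate`) produces complete studies — sample
sheet, fragment-length histograms, copy-number bin counts, methylation
window matrices, PSA and staging labels — as deterministic functions of
`(GeneratorConfig, seed)`, together with the ground truth (per-sample
tumor fraction, planted copy-number segments, planted marker windows)
needed for recovery tests.

### Fragment-length densities

Plasma cfDNA is modeled as a two-population mixture on the integer
30–700 bp grid: a fraction `tfx` of fragments is tumor-derived, the rest
healthy. Each population is a mixture of

* a mono-nucleosomal Gaussian at 167 bp (σ = 10) and a di-nucleosomal
  Gaussian at 334 bp (σ = 20), shared by both populations;
* a sub-150 bp component (truncated Gaussian; healthy: μ = 118, σ = 28,
  weight 0.15; tumor: μ = 134, σ = 22, weight 0.45) carrying a
  multiplicative 10 bp-periodic modulation
  `1 + A·cos(2π·l/10)`, clipped at 0 (healthy A = 0.25, tumor A = 0.06).

This yields the qualitative structure the pipeline must resolve: the
density mode at 167 bp, the secondary maximum at 334 bp, local extrema at
exact 10 bp spacing below 150 bp, short-fragment (90–150 bp) mass
non-decreasing and oscillation contrast non-increasing in `tfx`. Cohort
ordering of the oscillation score (controls > localized > advanced) is an
emergent consequence of the per-cohort tumor-fraction distributions, not a
hard-coded label effect.

Urinary cfDNA is a broad truncated Gaussian (μ = 170, σ = 85; ≥ 99% of
mass within 30–400 bp) plus a nucleosomal peak at 166 bp whose weight is
drawn per sample (Beta around 0.12, concentration 40) to reproduce the
high intersample variability of urine, with the modulation extended to
30–300 bp (healthy A = 0.12). The tumor population has a heavier 166 bp
peak (weight 0.38, σ = 4), so P163–169 grows with `tfx`.

Histograms are multinomial draws (default 10⁶ fragments per sample,
matching the scale at which the oscillation score is stable).

### Copy-number counts and size selection

The genome model is 2500 bins of 1000 kb spread over 22 autosome labels
(about the bin count of a human genome at this bin size). Each bin carries
a GC fraction (0.30–0.60) and mappability (~0.96, 2% of bins low). Counts
are negative-binomial with mean

    depth · (tfx·c + 2·(1−tfx))/2 · exp(b₁·(gc−0.45) + b₂·(gc−0.45)²) · mappability

with depth 18,000 reads/bin (≈ 2.8× coverage at 100 bp reads, the depth
regime of the emulated assay) and dispersion size 2000 (~2% extra-Poisson
noise). Planted segments cover ~30% of the genome (18% single-copy loss,
10% three-copy gain, 2% four-copy amplification; mean segment length 80
bins). Controls are flat diploid.

In-silico size selection cannot be re-applied to bin counts (they carry no
fragment lengths), so the generator emits a paired size-selected track per
plasma sample: the effective tumor fraction after restricting to the
90–150 bp band is computed from the component densities,
`tfx' = tfx·ρ_t / (tfx·ρ_t + (1−tfx)·ρ_n)` with ρ the band mass of the
tumor/normal component, and the depth is scaled by the retained mass.
With the defaults, ρ_t ≈ 0.36 vs ρ_n ≈ 0.15, so selection roughly doubles
small tumor fractions at ~5× fewer reads — the sensitivity/noise trade-off
the real procedure exhibits.

### Methylation

Window-level β-values are generated directly: marker windows mix a
background β (Beta(1.6, 8) per window, shared across samples) with a tumor
level (0.85) in proportion `tfx`, plus truncated Gaussian noise
(σ = 0.05); non-marker windows keep the background. The nrpkm signal is
the saturating inverse of the β transform (`s = m·β/(1−β)`, CpG-scaled),
so β is a monotone transform of signal within each sample, as the analysis
side assumes. 67 marker windows are planted among 5000 genome-wide 300 bp
windows by default. A separate tissue-experiment generator produces 8
matched tumor/buffy pairs plus an emulated external top-100 DMR list
(500 bp windows over every planted window, decoys elsewhere) for the
marker-derivation pipeline.

### What the generator does not emulate

No read-level data (alignment, duplicates, mappability artifacts beyond a
scalar), no sequence content, no sex chromosomes, no enrichment-efficiency
biases of immunoprecipitation, no subclonal copy-number structure, no
correlation between a patient's plasma and urine tumor fractions beyond a
shared log-normal scaling. Passing tests therefore demonstrate that the
*analysis logic* is correct and well calibrated under realistic noise —
not that the thresholds or effect sizes transfer to real cohorts.

## Analysis stack

### Copy number, tumor fraction, CIA

Bin counts are masked below mappability 0.75, converted to
log2(count/mappability), GC-corrected by lowess of log-depth on GC
(span 0.3), and median-centered. The panel of normals stores per-bin
mean/SD of these profiles over controls; controls are always scored
against a leave-one-out panel. Segmentation is a 5-state sticky HMM
(self-transition 1−10⁻⁶) with Gaussian emissions around
μ_c(t) = log2((t·c + 2(1−t))/2) — state 2 is ratio-neutral at every t —
and a shared SD estimated robustly from first differences
(1.4826·MAD/√2, floor 0.02). The c = 0 ratio is floored at 0.05 to avoid
−∞. TFx is the Viterbi-likelihood argmax over t ∈ {0, 0.01, …, 0.95},
preferring smaller t on ties (strict-improvement scan), and is forced to 0
when fewer than 1% of bins leave the diploid state: flat genomes must not
hallucinate tumor fraction, which also means control TFx estimates are an
atom at 0 rather than a continuous distribution (relevant when
percentile-calibrating TFx thresholds; the calibration guarantee is a
continuous-feature property). The Viterbi recursion is vectorized across
the whole candidate grid, which keeps a 2500-bin, 96-candidate decode
around a quarter second.

The CIA score standardizes each bin against the panel
(z = (log2 − mean)/SD) and averages the thresholded excess
Σ_{|z|>3}(|z|−3)/n_bins; it is permutation-invariant and zero when no bin
deviates beyond the cutoff. The threshold z = 3 and the normalization are
exposed as parameters.

### Methylation analysis

nrpkm = count / (window kb × library millions). The β transform
CpG-adjusts the signal (s_w = nrpkm_w/cpg_w × median cpg) and maps it
through s/(s+m) with m the sample's median adjusted signal — bounded,
monotone, and anchored at β = 0.5 for the typical window. Since scores are
only compared through control-calibrated thresholds, any shared monotone
transform preserves the pipeline's logic; this one is declared rather than
copied from the upstream enrichment tool, whose calibration is not public.

DMR calling is per-window on β with Benjamini–Hochberg correction across
tested windows; logFC is log2 of the pseudocounted (0.1 nrpkm) mean signal
ratio, positive = hypermethylated. The test is selectable:
rank-sum/signed-rank (default for biofluid comparisons at p < 0.05;
distribution-free at small n) or Welch/paired t. Marker derivation
defaults to the t-test because the tissue filter demands adjusted
p < 0.01 at n = 8 vs 8 over thousands of windows, which no rank test can
reach — the exact rank-sum two-sided floor at that size is
2/C(16,8) ≈ 1.6·10⁻⁴, and BH across ~5000 windows lifts even the floor
above 0.01. Marker selection intersects the filtered hypermethylated DMRs
(adjusted p < 0.01, logFC > 2) with the external list at ≥ 1 bp overlap in
half-open coordinates (abutting intervals do not overlap). The
methylation score is the per-sample median β over marker windows.

Region annotation resolves gene-model overlaps by the priority
promoter > 5'UTR > 3'UTR > exon > intron > downstream, with
distal-intergenic as fallback, and labels the CpG landscape island /
shore (≤ 2 kb) / shelf (2–4 kb) / open sea by gap distance to the nearest
island. The promoter extent is whatever the supplied gene-model BED
declares; a TSS −2000/+500 bp convention is used when deriving one.

### Detection and integration

Thresholds are percentiles of the control feature distribution — 95th, or
5th for the plasma oscillation score — using linear interpolation between
order statistics (numpy's default, R type-7), with strict comparison
("beyond" the threshold), so a control equal to its own calibration
threshold is never positive. Fluids are integrated complementarily: a
feature family (TFx, CIA, methylation, fragmentation) is positive for a
patient if positive in plasma or urine, negative if at least one fluid
was evaluable, not-available otherwise; the per-patient count is 0–4.
Missing urine samples are representable and propagate as not-available.
Cross-fluid max-z features standardize each (feature, fluid) against
control mean/SD and take the per-patient maximum; a feature with a
degenerate control distribution (TFx, see above) is centered but not
scaled, and flagged. PSA strata are half-open: [0, 4), [4, 10),
[10, ∞) ng/mL.

### Statistics

Kruskal–Wallis uses scipy's tie-corrected statistic; Dunn's post-hoc z is
computed from pooled mean ranks with the tie term Σ(t³−t)/(12(N−1)), BH
over the pairwise family. The logistic GLM is damped IRLS on z-scored
predictors: full Newton steps halved until the deviance does not increase
(the per-iteration deviance path is exposed and is non-increasing by
construction), convergence at max update < 10⁻⁸, coefficients projected
onto [−15, 15] with a separation flag — small cohorts separate routinely
and must yield a usable, monotone-deviance fit rather than an error. The
fit agrees with statsmodels' GLM to 10⁻⁶ on regular problems (tested).
AUC is pair counting with ties at 0.5 (computed via the rank-sum
identity); DeLong's test uses the midrank placement-value covariance
estimator, returning a flagged p = 1 when the variance of the difference
degenerates; the bootstrap is stratified (class counts preserved), 500
iterations by default, percentile 2.5/97.5 interval. The likelihood-ratio
test is the deviance difference of nested fits on identical observations
with df = added parameters.

One caution: the BH *adjustment map* is not idempotent (re-adjusting
adjusted p-values can change them); the property the implementation
guarantees, and the one tested, is step-up consistency — adjusted
p ≤ α exactly reproduces the step-up rejection set at level α.

## Problem sizes used in the checks

The cohort-level acceptance tests run at: threshold calibration — 20 null
cohorts × (100 + 100) controls, 800 bins / 1200 windows / 150k fragments;
TFx recovery — 2500 bins, default depth, 20 replicates per tumor-fraction
level; size-selection gain — 1200 bins, 20 replicates; CIA coupling — 60
samples at 800 bins; marker recovery — 5000 windows, 8 tissue pairs;
oscillation contracts — 50 and 30 samples per arm at 10⁶ fragments; model
nesting — 50 replicate cohorts (12/18/12 patients) at 400 bins / 1000
windows / 120k fragments with a 0.02 TFx grid. These sizes are the
package's validation conditions; the estimators themselves default to the
full-resolution settings.

## Known limitations

* TFx is identifiable only through the planted emission model; ploidy and
  subclonality are out of scope, and solutions with near-equal likelihood
  (e.g. halved tumor fraction at doubled copy change) are resolved only by
  the smaller-t tie preference.
* The CIA normalization and z-cut follow a declared formula; published
  instability scores differ in detail, so absolute values are not
  comparable across tools — only the coupling to tumor fraction is.
* Percentile thresholds calibrated on ≲ 36 controls have high variance;
  the nominal 5% false-positive rate is a property of the procedure in
  expectation, not of any single calibration.
* The β transform is a stand-in with the right shape and invariances, not
  a reimplementation of the enrichment tool's calibration; β values are
  comparable within this pipeline only.
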