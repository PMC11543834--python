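# Methods

This note documents the models behind each pipeline stage, the defaults and
why they are set where they are, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was open.

## Spot histology classification

A Visium spot is a 55 µm disk; annotation masks are binary rasters exported
per class. The spot's class fraction is the number of raster pixel centers
inside the disk that are set in that class, divided by all pixel centers
inside the disk. No partial-pixel weighting is applied: binary mask exports
carry no sub-pixel information, and the pixel-center rule is exactly
reproducible by brute-force enumeration, which the tests exploit. A spot
whose disk covers no pixel center is an error (the raster is too coarse for
the geometry). Pixels covered by no class form an implicit "outside tissue"
class, so fractions over classes plus outside sum to 1 exactly.

The rule engine applies, in order: exclusion (outside > 0.50, tissue fold >
0.50, lumen > 0.80, uncertain > 0.50 — all strict inequalities, read
literally from the protocol's ">"), then the stroma call (stroma > 0.55),
then the dominating class among lymphocytes, non-cancer epithelium and
cancer GG1–5, with GG1–2 → low grade and GG3–5 → high grade. The rules are
order-invariant given the fractions; the first firing exclusion rule is
reported (a flag reports all). Dominant-class ties are broken by a fixed
priority — cancer (higher grade first) over lymphocytes over non-cancer
epithelium — because the protocol is silent and determinism is required; the
fired rule is logged per spot. A spot that survives exclusion but has only
stroma ≤ 55% and special classes is reported unclassifiable rather than
silently forced into a class. Stroma subclassification (normal / LG cancer /
HG cancer stroma) is derived from the sample's own non-stroma spot calls; a
pathologist-supplied sample-level grade can override it.

## Filtering and cell-count normalization

Genes are kept when total reads ≥ 10 **and** the gene is detected (nonzero)
in ≥ 10 spots. The protocol sentence admits more than one reading; this
conjunction is the documented interpretation and both parameters are
configurable. Normalized counts are round(count / n_cells × target) with
target = the median cell count over the included spots (the reference
cohort's value, 21, can be fixed in config). Rounding is half-away-from-zero
— "nearest integer" does not pin the half case, so the rule is fixed and
covered by a boundary test (5/2 × 21 = 52.5 → 53). Spots with zero cell
count cannot be put on a per-cell basis and are dropped with a warning.
After normalization, spots need ≥ 40 detected genes and a normalized total
≥ 100.

## NB quasi-likelihood differential expression

Counts for gene g in spot s are modelled NB(μ, φ) with log μ = xₛ'β +
offset, var = μ + φμ². Spots are the replicates; the default design is
intercept + group indicator, and the default offset is the centered log of
the normalized spot total (standard GLM practice for residual depth
differences; disablable). The fit per gene:

1. **Dispersion.** φ maximizes the Cox–Reid adjusted profile likelihood
   (penalty −½ log det X'WX), which removes most of the downward bias of the
   plain MLE. The genewise estimate is shrunk on the log scale toward the
   all-gene mean log dispersion, with weight = residual df against a prior
   weight of 20 (configurable); this stabilizes genes with little signal
   without flattening genuine dispersion differences.
2. **Coefficients.** IRLS at the shrunk φ; group means for a saturated
   two-group design reproduce the (offset-adjusted) arithmetic means, which
   is the closed-form check in the tests.
3. **Quasi-dispersion.** s² = residual deviance / df absorbs what the NB
   variance misses; it is moderated toward the 20%-trimmed mean of all
   genewise s² with a prior df of 10, and the covariance of β is scaled by
   the moderated s². The t reference distribution gets df = residual df +
   prior df.

The threshold (TREAT-style) test declares a gene significant only when
|log₂FC| credibly exceeds τ = 0.5: with contrast estimate b and standard
error s (both on the log₂ scale), p = P(T > (|b|−τ)/s) + P(T > (|b|+τ)/s).
At τ = 0 this is exactly the two-sided t-test; for |b| ≤ τ it is ≥ 0.5 by
construction. p-values are BH-adjusted across genes and compared to α =
0.01. The protocol text says "higher than 0.01 was considered significant";
that contradicts the construction of the test and is treated as a typo —
significance here means p_adj < 0.01.

Calibration measured by the suite: at τ = 0 the type-I error over 2000
simulated null genes (100 spots/group) sits inside the 95% binomial band
around 0.05, and at τ = 0.5 null genes essentially never pass; a planted
log₂FC of 2.0 at 400 spots/group is recovered with mean bias below 0.05
over 20 replicates.

## Stain deconvolution and collagen quantification

Optical density is OD = −log₁₀((I+1)/256) per channel; the +1 offsets keep
OD finite at I = 0 and bias it by < 0.002. The published blue and pink stain
vectors are completed by their normalized cross product into an invertible
basis; concentrations are the per-pixel solve, negatives clamped to zero
(flaggable). Quantification resamples the image to the working resolution of
0.55 µm/pixel (bilinear for intensities, nearest for the stroma mask, so
masks stay binary), Gaussian-filters the **pink concentration** channel
(σ = 1 px; the upstream tool does not state whether it smooths concentration
or OD — concentration was chosen because the threshold is defined on it),
and classifies stroma pixels as pink above the threshold. The default
threshold 0.20 sits mid-range of the validated 0.15–0.30 band; per-section
overrides mirror intensity-matched thresholds and values outside the band
warn but run. pink + blue = 1 exactly by construction, and raising the
threshold can only lower the pink fraction.

## Methylation

Promoter = {TSS1500, TSS200, 5′UTR, 1stExon}, gene body = {3′UTR, Body}.
Region means are arithmetic means of beta values per sample. Associations
with expression are Spearman per site and for the region means,
BH-adjusted across sites at α = 0.05. Differential methylation fits the
random-intercept model below to each site's betas (the linear model on
betas is the same moderated-linear-model idea used for arrays, here with
the patient intercept made explicit), BH across sites.

## Random-intercept mixed model

y = Xβ + u + ε with u ~ N(0, σ_u²) per patient. The REML criterion is
profiled down to the single variance ratio λ = σ_u²/σ_e²; block structure
makes V⁻¹ and log det V closed-form (Woodbury per patient), and λ is found
by 1-D bounded minimization over log λ ∈ [−12, 10]. If the interior optimum
is no better than λ → 0, the model reduces to OLS and σ_u² = 0 is reported
with a warning. Fixed effects are GLS at the optimum. Contrast df is
containment-style, n − rank(X) − (n_patients − 1), floored at 1, except at
the boundary where the random effect has dropped out and the OLS df
n − rank(X) applies — this makes the one-sample-per-patient case agree
exactly with the two-sample t-test. Satterthwaite df would also be
defensible; containment was chosen for transparency and is configurable in
effect through the reported df. Covariates are treatment-coded with the
first category (stroma ≤35%, age 51–58) as reference; covariate levels
absent from a comparison subset are dropped from the design. A fit against
an independent general-purpose mixed-model implementation agrees to four
decimals on estimate, standard error and σ_u².

## Survival

Kaplan–Meier uses the product-limit estimator (steps at event times only);
the two-group log-rank test uses the hypergeometric variance and a χ²₁
reference. One sample represents each patient: the one with the highest
biomarker expression (ties broken by sample id, logged). The optimal cutoff
is an exhaustive scan over midpoints of consecutive sorted unique expression
values leaving at least max(3, 10% of patients) per side, choosing the
minimum log-rank p. That minimized p is reported **unadjusted** together
with an explicit overfitting warning in the output — cutoff optimization is
known to be optimistic, and the number is a selection statistic, not a
confirmatory p-value.

## Synthetic data generator

The generator emulates the *structure* the pipeline assumes, with every
generative parameter recorded in a truth object:

- **Geometry.** Hexagonal spot lattice (row pitch spacing·√3/2, odd rows
  offset by spacing/2) with 55 µm spots at 200 µm spacing by default.
- **Tissue masks.** One Gaussian-smoothed noise field rank-transformed to
  uniform and cut at the cumulative class proportions: a partition by
  construction, blob-like regions, exact areas.
- **Counts.** Cell count per spot is shifted Poisson (≥ 1) with mean 21,
  matching the reference cohort's median; composition π ~ Dirichlet(α of the
  spot's dominant class); gene mean = n_cells · Σ_t π_t · signature; counts
  are gamma-Poisson NB with per-gene dispersions in [0.1, 0.5]. The planted
  fibroblast marker and its two ECM partner genes carry a cell-level log₂
  enrichment of 4 which, diluted through the default class compositions,
  puts the spot-level stroma-vs-gland log₂FC near 2 — the scale at which
  strongly stroma-enriched transcripts are reported in prostate tissue. A
  per-sample latent factor scales the marker/partner genes and drives the
  collagen fraction, giving the cross-sample correlations their planted
  structure.
- **Trichrome.** Two concentration fields from a thresholded smooth random
  field, rendered through Beer–Lambert with the published stain vectors and
  8-bit quantization. The muscle concentration is placed symmetrically about
  the classification threshold so boundary smoothing at quantification time
  is unbiased; the true collagen fraction is exact by construction.
- **Methylation.** Promoter betas logistic(a − slope·z + ε) against
  standardized log expression (slope 1 by default), body betas independent.
- **Bulk.** 37 patients × 5 samples, σ_u² = σ_e² = 0.5, cancer effect 1.5,
  grade and relapse effects 0.5 and 0.8, small stroma-category effects. The
  truth records both the raw betas and the *marginal* contrast a model
  adjusting only for stroma and age estimates (grade mixes into the cancer
  effect at its sampling rate) — recovery tests compare against the marginal
  value, which is what the estimator is consistent for.
- **Survival.** Exponential relapse times with rate ∝ exp(γ·z), γ = 1,
  censored at a 10-(arbitrary-unit) horizon.

The generator does **not** emulate: H&E/trichrome texture, spatial
autocorrelation of expression beyond the blob masks, segmentation error in
cell counting, batch or section effects, array normalization artifacts, or
non-proportional hazards. Passing tests therefore demonstrate correctness of
the statistical machinery and rule logic under the stated models, not
robustness to the full messiness of scanner output.

## Problem sizes and determinism

Default desk-scale study: 6–8 samples of ~100–250 spots each, 150–300 genes,
5 cell types, 512² trichrome rasters (256² inside the study object), 64
methylation samples, 37 patients. Every stochastic path takes a seed, and a
full study is a pure function of (config, seed); the CLI writes a JSON log
line per stage with the config hash and seed.

## Known limitations

- The NB QL moderation uses fixed prior weights (20 for dispersion, 10 for
  the quasi-dispersion) rather than estimating prior df empirically; at
  spot-level sample sizes (hundreds of replicates) the choice is nearly
  immaterial, at very small n it is conservative.
- The cutoff scan reproduces the behaviour of interactive cutoff-finder
  tools, including their optimism; no minimum-p correction is applied.
- Cross-compartment and stain-expression correlations operate on per-sample
  means, so they inherit the small-n behaviour of Spearman at cohort sizes
  below ~10 samples.
- `spot_class_fractions` assumes masks share shape and pixel size; no
  registration is performed.
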