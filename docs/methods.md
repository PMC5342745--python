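# Methods

This note documents the statistical models behind `tamsig`, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerical choices a maintainer should know about.

## Expression preprocessing

Counts are converted to TPM with annotated gene lengths and no
effective-length correction (inputs are gene-level counts):
TPM_gs = 10⁶ (c_gs/l_g) / Σ_j (c_js/l_j). All correlation, PCA and
clustering work happens on log2(TPM+1) — a standard variance
stabilization; the scale choice is a package decision, made once and
used consistently.

The purity filter keeps genes with **median TAM TPM ≥ 3** and median
ratios TAM/TAT > 0.1 and TAM/TU > 0.1. The minimum-TPM rule is applied
to the TAM group median (the aggregation matching the neighbouring
median-ratio rules). A zero reference median passes the ratio: absence
of the gene from the contaminating type is evidence the signal is not
contamination.

## In-silico purification

TAM samples from ascites carry tumor cells and T cells. A linear
two-component mixture is assumed,
`observed = (1−f_tu−f_tat)·pure + f_tu·TU + f_tat·TAT`,
with fractions estimated as the median of `observed[m]/ref[m]` over
marker genes m expressed in the contaminating type and silent in
macrophages; the profile is then un-mixed, clipped at zero, and
renormalized. Fractions are clipped at 0.5 — a "TAM" sample that is
majority foreign is a QC failure, not an adjustment case. Marker lists
are configuration, not code. This is the simplest identifiable model
for the task; no claim is made that it reproduces any particular
published deconvolution procedure, and it does not handle more than the
two named contaminant types.

## Batch adjustment

After dropping genes with log-scale sample variance < 1, a parametric
empirical-Bayes location/scale adjustment is applied: per-gene
standardization, per-(gene,batch) location γ̂ and scale δ̂² estimates,
shrinkage toward a normal prior on γ and an inverse-gamma prior on δ²
(hyperparameters by method of moments per batch), fixed-point iteration
to tolerance 10⁻⁴ (max 100 iterations), back-transformation. No
covariate design is modelled; batches must not be confounded with cell
type. A test cross-checks the implementation against scanpy's
parametric ComBat (agreement to ~10⁻³, the scale of the iteration
tolerances).

Two properties worth knowing:

* **Idempotence is approximate, not exact.** The scale posterior is
  roughly half-shrunk toward its prior at any sample size (posterior
  weights n/2 versus a_prior−1 ≈ n/2), so re-adjusting corrected data
  re-scales residuals by a few percent. The location part is idempotent
  up to shrinkage residue. The tests assert the attainable property: a
  second pass is a small (mean |Δ| < 0.1 on unit-variance data),
  non-growing perturbation.
* **Downstream medians use corrected data.** Once batch effects are
  removed, every later median and fold change is computed on the
  corrected matrix back-transformed to TPM (2^x − 1). Computing medians
  on uncorrected TPM interacts badly with unequal group sizes: with 17
  TAM (odd, split 9/8 across batches) vs 4 pMPH (2/2), a large per-gene
  batch shift puts the two group medians on opposite sides of the batch
  levels and can fake a >3-fold change. Genes removed by the variance
  filter keep their adjusted-TPM medians, so seed genes are never lost
  silently.

## Seed selection: exact NB test

Libraries are equalized to the geometric-mean depth (scale and round) —
a deliberate simplification of TMM-style normalization that is adequate
when library sizes are within a small factor, as here. A common
dispersion φ (variance μ + φμ²) is estimated by pooled method of
moments **within cell-type × batch cells** (so per-gene batch shifts do
not masquerade as dispersion), taking the **median across genes** so
that a handful of strongly co-regulated genes cannot dominate; the
estimate is floored at 10⁻⁸. The naive μ²-weighted pooling was observed
to inflate φ̂ more than tenfold on cohorts with a planted co-expression
module, collapsing test power — the robust pooling recovers the true
value.

The test conditions on the per-gene total: with equalized depths, group
sums are sufficient, and the sum of n NB(μ, 1/φ) variables is
NB(nμ, n/φ). The two-sided p-value is the conditional probability of
all splits of the total at most as probable as the observed split
(ties at relative tolerance 10⁻¹⁰ are included); below φ = 10⁻¹⁰ the
Poisson limit is used. The implementation is verified against an
independent per-sample pmf-convolution oracle and the conditional
binomial (Poisson-limit) test. Seeds are genes with BH-FDR q ≤ 0.2
(boundary inclusive). The median-of-genes dispersion estimator is
slightly biased low in small samples (the χ² median effect), which
makes the plug-in test marginally liberal; the test itself is
calibrated at the true φ, and the downstream extension rules — not the
seed — perform the final selection.

## Signature extension

For each comparison (TAM vs pMPH, TAM vs MDM; each with its own seed), a
gene enters the up-set iff it is a seed gene with median fold change > 3,
or it satisfies all of:

* max Pearson r > 0.9 against **any individual seed gene** across TAM
  samples (the most permissive reading of "correlated with the seed
  set"; centroid-based correlation would be stricter and is a
  configuration alternative),
* quartile non-overlap: TAM lower quartile above reference upper
  quartile (mirrored for down-genes), with linear-interpolation
  (type-7) quantiles — documented because quartiles of 4 reference
  samples are sensitive to the rule,
* median fold change > 3 (strict; a 2-fold variant is available via
  `fc_threshold=2`) and median TPM > 1.5 in the higher group.

Zero reference medians with nonzero TAM medians classify as up.
Candidates are drawn from the purity-filtered, variance-filtered,
batch-corrected matrix; seed genes failing the fold-change rule are
reported with a reason, never dropped silently. Raising any threshold
can only shrink the sets (tested).

## Modules, similarity, enrichment

Co-regulated modules are read off a WPGMA dendrogram over the recovered
up-genes with correlation distance d = 1 − r across TAM samples, cut at
d = 0.5 (pairwise r ≈ 0.5). The cut height is a package default — the
module boundary is not prescribed by any rule stronger than "tightly
co-expressed" — and module reports always state the height used.
Sample-level similarity is reported as Pearson correlation heatmaps over
all samples and median-profile correlations per cell-type pair; PCA is a
gene-centered SVD with the sign convention that each component's
largest-magnitude loading is positive. Enrichment is a one-sided
hypergeometric over-representation test against GMT collections, with
the purity-filtered gene list as the universe (conditioning on the
expression filter is the standard guard against filter bias) and BH
correction across sets.

## The synthetic cohort

Defaults describe the validation conditions: 2000 genes plus 30 marker
genes; 17 TAM / 4 pMPH / 3 MDM / 3 TAT / 3 TU samples; baseline log2
mean TPM uniform on (2, 9); NB dispersion φ = 0.05; 30 planted up-genes
at 8-fold vs pMPH (20 of them also 8-fold vs MDM; the other 10 equally
elevated in MDM), 4 planted down-genes; a 19-gene module among the
up-genes with target pairwise r = 0.95; two balanced batches with
per-gene×batch shifts (sd 0.5 log2) and scale factors (sd 0.1 log2);
per-gene-and-sample biological noise of 0.15 log2; library sizes
1.5–2.5 M reads; three TAM samples contaminated at 5–15% tumor/T-cell
fractions. Planted set sizes deliberately mirror the signature sizes the
analysis is designed to resolve, so end-to-end recovery is a meaningful
check; dispersion, noise and library sizes are desk-scale choices made
once for testability — no empirical estimates of these quantities were
available to match.

Construction notes:

* Counts are drawn NB around expected counts
  `lib_s · (TPM·length / Σ TPM·length)`, so `compute_tpm` approximately
  inverts the generator.
* Down-planted genes draw their baseline from the upper expression range
  so the TAM side (baseline/8) still clears the TPM ≥ 3 purity filter;
  TU/TAT means for planted genes are pinned (at baseline for up-genes,
  at the TAM level for down-genes) so planted genes pass the purity
  ratio filter *by construction*, while null genes get independent
  TU/TAT profiles and genuinely exercise it.
* Module loadings are solved from the target pairwise correlation
  against the per-gene residual log2 variance (biological +
  NB-sampling), then inflated by a fixed-point correction for
  compositional attenuation: because TPM columns are renormalized, a
  high latent factor inflates the module's share of the library and
  deflates every TPM, damping the realized correlation by roughly the
  factor-weighted module share. Calibration is verified by simulation
  with batch effects and contamination off; with them on, the raw-data
  correlation is lower (by design — the pipeline measures correlation
  after adjustment and correction).

What the generator does **not** emulate: read-level artifacts, splice
isoforms, per-gene dispersion trends, length biases, correlated null
genes beyond the one planted module, or realistic cell-type-specific
transcriptome geometry (TAT/TU profiles are independent redraws, giving
TAM-tumor correlations ≈ 0.3 rather than a biologically structured
divergence). Passing recovery tests therefore demonstrates that the
pipeline's rules interlock correctly under its own model assumptions —
not that the thresholds are optimal for any real cohort.

## Determinism and problem sizes

All randomness flows from a single integer seed through
`numpy.random.default_rng`; two runs with the same configuration produce
bit-identical artifacts (content-hash manifest). The default end-to-end
run (2000 genes, two comparisons, exact tests on ~1500 purity-filtered
genes) completes in well under two minutes on one CPU; Monte-Carlo
property tests use 800-gene cohorts and 2000-gene null panels, sizes
chosen to keep the whole suite under a minute of simulation time while
leaving binomial confidence intervals tight enough to be informative.

## Known limitations

* The exact test ignores batch structure at the count level; the seed is
  therefore permissive under strong batch effects and relies on the
  extension rules for specificity (observed seed sizes of a few hundred
  genes shrink to the planted 30/4).
* The contamination model is linear with two components and assumes
  marker genes that are strictly macrophage-silent.
* Depth equalization by global scaling (no TMM) assumes library sizes
  within a small factor and roughly balanced composition.
* With 4 reference samples, quartile non-overlap and median fold change
  are sensitive to single samples; the defaults follow the published
  thresholds rather than any optimality argument.
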