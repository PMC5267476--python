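# Methods

## Model

For a CpG *m* with cis-SNP dosages s₁…s_w (the *w* nearest same-chromosome
SNPs by base-pair distance; positions are 1-based, distances are absolute bp
differences, and SNPs on other chromosomes are treated as infinitely far):

  m = β₀ + Σᵢ βᵢ sᵢ + ε

with ε independent across samples. Methylation enters on the beta scale
(proportions in [0, 1]); the model treats it linearly, which is adequate for
the mid-range values where genetically driven probes live.

The coefficient vector is estimated by LASSO. Because *w* is large relative
to typical reference-cohort sizes, the active set is additionally capped at
*p* predictors.

### Penalty selection

The LASSO penalty is not chosen by inner cross-validation. Instead the
regularization path is computed from the fully penalized end (100
log-spaced penalties down to 10⁻³ of the null penalty, via scikit-learn's
coordinate-descent path) and the fit at the **smallest penalty whose active
set still has ≤ p nonzero coefficients** is used. This is deterministic,
honours the predictor cap exactly, and is cheap enough to run across an
entire array. Predictions use the shrunk LASSO coefficients as-is; an OLS
refit on the selected support is available (`BuilderParams(refit_ols=True)`)
but off by default. Since the downstream score is a squared *correlation*,
coefficient shrinkage costs almost nothing: correlations are scale-invariant.

### Cross-validated score

Samples are shuffled once per cohort with a seeded permutation and split into
*k* folds (default 10). For each fold, the model is trained on the
complement — predictor standardization statistics are computed on the
training fold only, so no information leaks — and predicts the held-out fold.
The per-fold statistic is the squared Pearson correlation between predicted
and observed values; a degenerate fold (constant prediction or observation)
contributes 0 by convention. The CpG's score is the **median** over folds
(numpy's convention: the mean of the two central order statistics for even
*k*). One fold partition is shared by all CpGs of a cohort, which keeps
scores comparable across CpGs and the whole build reproducible from a single
`fold_seed`.

The reference list contains the CpGs with score **strictly greater** than the
threshold (default 0.5), sorted by descending score with ties broken by id.
CpGs with an empty cis window are skipped (reported, not scored 0).
Polymorphic probes are *not* excluded during building — their signal is
genuinely genetic and helps the inference — but can be excluded at inference
time via an exclusion list for sensitivity analyses.

## Inference

`epistructure(meth, ref, covariates, n_pcs, exclusions)` runs, in this fixed
order: intersect the data's CpGs with the reference list (absent reference
CpGs are dropped silently but counted), apply the optional exclusion list,
regress out the optional covariates, then PCA.

- **Covariate adjustment** replaces each CpG by its OLS residual on an
  intercept plus the covariates (typically six cell-composition surrogate
  variables; simulated cell proportions stand in during tests). Rank-deficient
  designs are rejected with the collinear columns named.
- **PCA** standardizes columns to mean 0 and unit population (1/n) SD —
  zero-variance columns become zero vectors — then takes the thin SVD.
  Scores are U·s, loadings are the right singular vectors, and explained
  variance ratios are squared singular values over total variance. Each
  component's sign is fixed so its largest-magnitude loading is positive
  (signs are otherwise arbitrary; all downstream R² statistics are
  sign-invariant). Requests beyond the matrix rank are truncated with a
  warning. Whether to standardize reference CpGs before PCA is a genuinely
  open choice; standardization is adopted so that high- and low-variance
  probes contribute equally, and the population-SD convention is documented
  so an implementer can flip to 1/(n−1) — every R² reported downstream is
  insensitive to that divisor.
- `explained_variance_profile` reports in-sample OLS R² of an external target
  (genotype PC, admixture fraction) on the first j components, j = 1…max_j;
  the profile is monotone because the models are nested. In-sample rather
  than cross-validated R² is deliberate: it is the quantity the method's
  evaluations use.
- `genotype_pcs` applies the same PCA to dosages after 5%-missingness
  filtering and mean imputation (`impute_genotypes`), matching standard
  genotype-PCA practice.

## Synthetic cohorts

`simulate_genotypes` draws ancestral allele frequencies Uniform(0.1, 0.9),
per-ancestry frequencies from the Balding–Nichols Beta(p(1−F)/F,
(1−p)(1−F)/F) at divergence F (default 0.1, a typical continental-scale
value), per-sample admixture from Dirichlet(α) (default α = 0.25 per
ancestry, giving the bimodal two-cluster structure of strongly admixed
two-way cohorts), and dosages Binomial(2, q·p). SNPs sit on two chromosomes
at 1 kb spacing so cross-chromosome cis-window logic is exercised. The
Hudson Fst estimator over SNPs recovers the nominal F within ±20% at 2000
SNPs.

`simulate_methylation` plants four CpG kinds:

- **genetic** (default 25%): 1–3 causal SNPs drawn from the CpG's own cis
  window, random normal effects, noise scaled so the in-sample genetic
  variance fraction equals `rho2_genetic` (default 0.8, the regime of
  reference-grade CpGs) exactly before squashing;
- **cellular** (default 50%): linear in six Dirichlet-distributed leukocyte
  proportions (granulocyte-dominated concentrations) with signal-to-noise
  `cell_var_scale` = 3, i.e. a 0.9 variance fraction — cell composition
  dominates the raw methylation PCs, as in real whole blood;
- **polymorphic** (optional): a direct copy of the nearest SNP's standardized
  dosage, emulating probe-binding artifacts;
- **noise**: the remainder, pure Gaussian.

Raw signals (unit variance) are mapped to the beta scale by the affine clamp
0.35–0.65 + 0.06·z clipped to [0.02, 0.98]. The clamp is mild on purpose: the
linear model stays essentially exact (clipping is a > 5 SD event), so planted
variance fractions survive to the beta scale within ±0.05. What the generator
does **not** emulate: linkage disequilibrium (SNPs are independent given
ancestry), array chemistry and batch noise, age/sex/smoking effects, and the
bimodal genome-wide beta distribution of real arrays. Passing tests therefore
demonstrate the statistical machinery — score calibration, confound
separation, structure recovery — not robustness to those real-data artifacts.

Covariate matrices emitted by `simulate_cohort` contain the first five of the
six cell proportions: proportions sum to one, so the full set would be
collinear with the intercept.

## Test and validation problem sizes

Correctness of the LASSO fit is checked against an independent cyclic
coordinate-descent solver (objective agreement ≤ 10⁻⁶ on 100 random
instances of ≤ 10 SNPs × ≤ 50 samples); PCA against an eigendecomposition
oracle (≤ 10⁻⁸ on fixtures up to 50×50). Statistical properties run at
deliberately scaled cohort sizes chosen to keep the full suite in the
minutes range while leaving comfortable statistical margins: score
calibration on 10 CpGs per planted cis-R² level at n = 1000 (grid 0–0.9,
tolerance ±0.05) plus 100 null CpGs; reference-list recovery on 100-CpG
cohorts (50 planted at ρ² = 0.8, 50 null) at n = 500 over 20 seeds; and the
confounded-cohort experiment on a 500-sample reference cohort plus a
300-sample methylation-only target with 2000 SNPs and 1000 CpGs (250
genetic, 500 cellular, 50 polymorphic). On that cohort the supervised PC1
reaches R² ≈ 0.92 with the true admixture fraction while the full-matrix PC1
stays below 0.01, cell-adjusted full-matrix PCs recover R² ≈ 0.92, and
excluding the planted polymorphic probes from the reference costs < 0.02 —
the same qualitative pattern expected on real admixed cohorts, at desk
scale. A 5000-CpG × 4000-SNP profile (`make_fixture("fullscale", ...)`)
is provided for larger experiments.

## Numerical choices and edge cases

- Ties in cis-SNP selection (equidistant SNPs) go to the lower position, then
  lexicographic id — arbitrary but reproducible.
- `standardize` uses the population (1/n) SD; constant columns become zero
  vectors rather than raising.
- Genotype columns that are entirely missing are always dropped; observed
  dosages are never altered by imputation.
- A constant response or all-constant design yields the null model (intercept
  only) rather than an error from the path solver.
- Median fold r² uses `numpy.median`; squared correlations are clamped to
  [0, 1].
- The CLI derives per-stage seeds from the global seed by SHA-256, so stages
  are individually reproducible and all derived seeds stay below 2³¹.

## Limitations

- The reference list transfers across cohorts only insofar as cis-meQTL
  architecture is shared; a reference built on one ancestry group may be
  suboptimal for others.
- Cell-composition surrogates are *inputs*: the package does not estimate
  cell proportions (reference-free or reference-based deconvolution is out of
  scope), and reference building deliberately ignores tissue heterogeneity.
- No binary genotype formats (PLINK .bed) or array-manifest parsing; inputs
  are delimited text. Array normalization, batch correction and QC are
  assumed done upstream.
- trans-SNP effects are ignored by design; only cis windows are modelled.
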