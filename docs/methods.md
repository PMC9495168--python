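# Methods

This note documents the statistical models behind `gsfs`, the choices
made where the methodology is genuinely open, and what the synthetic
data generator does and does not emulate.

## Synthetic breeding population

The simulator (`gsfs.simdata`) produces the statistical structure the
downstream analysis assumes, not a biological forward simulation.

* **Genotypes.** Each chromosome is a first-order Gaussian Markov chain
  per gamete: latent z₁ ~ N(0,1), z_k = ρ·z_{k−1} + √(1−ρ²)·ε, and the
  allele at marker k is 1 when z_k < Φ⁻¹(p_k). Two independent gametes
  sum to the additive code 0/1/2. The single parameter `ld_rho` (default
  0.6) gives adjacent-marker LD that decays geometrically with map
  distance — a one-parameter, reproducible stand-in for real haplotype
  structure. Allele frequencies are uniform on `maf_range`
  (default 0.05–0.5).
* **Genetic values.** `n_qtl` markers (default 100) receive i.i.d.
  normal effects, rescaled so the empirical variance of the true
  breeding values (TBV) equals h². Phenotypic variance is normalized to
  1, so σ²_a = h² with no free scale.
* **DRPs.** A de-regressed proof is TBV plus noise with per-individual
  variance σ²_a(1−r²)/r², the variance implied by a DRP of reliability
  r². Reliabilities are uniform on `reliability_range` (default
  0.3–0.95, deliberately straddling the 0.40 validation filter); birth
  years are uniform on 2008–2015 around the default 2013
  reference/validation cutoff.
* **Defaults** (1,500 individuals, 5 chromosomes × 1,000 SNPs, 100 QTL,
  h² = 0.3) are the desk-scale study conditions used by the acceptance
  checks and `scripts/acceptance.py`.

What it does **not** emulate: pedigree structure and family
stratification, selection over generations, a realistic cattle MAF
spectrum or LD decay calibrated to Holsteins, imputation error, or the
de-regression procedure itself (DRPs are generated directly from their
defining variance model). Passing tests therefore demonstrate internal
correctness and calibration of the methods, not real-data accuracy
levels: in this unstructured population, panels of selected SNPs
out-predict a sparse random chip by a much wider margin than chip and
sequence panels differ in real cattle, where pervasive relatedness and
long-range LD let a 50K chip capture most of the signal.

## Quality control

Filters mirror standard array QC: individual call rate, SNP call rate,
MAF, and Hardy–Weinberg equilibrium, applied in one pass in that order
(individuals first, then SNPs, each SNP removed for the first criterion
it fails). Retention is *strictly greater than* the threshold; defaults
are 0.95 / 0.95 / 0.01 / 1e−6. Non-autosomal SNPs (non-integer
chromosome labels) are dropped unconditionally. The HWE test is the
conditional exact test (probabilities of heterozygote counts given
allele counts, two-sided by summing configurations no more probable
than the observed one); a chi-square variant is available via
`QcThresholds(hwe_method="chisq")` since QC tools differ here. The
exact test is the default because the chi-square approximation
misbehaves exactly where the filter matters, at low MAF.

## Relationship matrices

* `vanraden1`: G = ZZ′/(2Σp(1−p)), Z column-centered at 2p. A true Gram
  matrix — symmetric and PSD by construction.
* `gcta_eq2`: off-diagonals are per-SNP standardized cross-products
  averaged over markers; the diagonal uses the distinct estimator
  1 + mean[(x² − (1+2p)x + 2p²)/(2p(1−p))].

Both are invariant to which allele is counted (the centered factors
flip sign together), so the minor/major coding ambiguity of chip
exports is immaterial. Missing calls are mean-imputed at 2p;
monomorphic markers are excluded from numerator and scaling.

**A PSD caveat for the standardized form.** With sample frequencies the
standardized matrix W has zero column sums, so 1′(WW′/N)1 = 0, while
the distinct diagonal differs from the Gram diagonal by terms that sum
to zero but do not vanish individually; hence G·1 ≠ 0 and the matrix
has a strictly negative eigenvalue of order 1/N whenever those terms
are nonzero (they vanish identically only when every sample frequency
is exactly 0.5). This is a property of the estimator, not a bug; the
REML consumer clips small negative eigenvalues to zero and rejects a
matrix only when its negative eigenvalue mass exceeds 5% of the
positive mass.

## Mixed-model GWAS

The null model y = 1μ + g + e is fit by REML once per chromosome on
the corresponding leave-one-chromosome-out `gcta_eq2` matrix: after an
eigendecomposition the restricted likelihood is a 1-D function of the
variance ratio δ = σ²_e/σ²_g, optimized on log δ ∈ [−12, 12] by bounded
Brent search (xatol 1e−8). A ratio at the upper bound flags a
zero-heritability boundary fit.

The scan holds each chromosome's variance *ratio* fixed (the EMMAX
device) but re-estimates the overall scale per SNP from the weighted
residual sum of squares with n−2 degrees of freedom. This keeps the
per-SNP cost at one rotation and a 2×2 solve, and makes the scan reduce
*exactly* to ordinary least-squares Wald tests when σ²_g is forced to
zero. The squared effect/SE ratio is referred to a 1-df chi-square,
matching large-n scan-tool convention. An exact variant that
re-optimizes the ratio per SNP (`wald_scan_exact`) exists for small
data; on test problems the fixed-ratio approximation moves −log₁₀ p by
less than 0.3. SNPs whose (weighted, centered) dosage is numerically
collinear with the intercept are flagged untestable, never silently
dropped. Pre-selection keeps SNPs with p strictly below 0.05 — nominal,
uncorrected, because the stage is a screen, not an inference.

The GWAS residual is homoscedastic (Iσ²_e) even though GBLUP weights
residuals by reliability; the two stages are implemented as their
models are written.

## Penalized selection

The elastic net uses the conventional objective
(1/2n)·RSS + λ[(1−α)/2‖b‖² + α‖b‖₁] (coordinate descent via
scikit-learn). The unnormalized-RSS form seen in some texts has the
same solution path under λ → λ/(2n) reparameterization, so selected
sets are identical; printed λ values are only comparable within one
parameterization. Columns are standardized to unit variance inside
each training fold (penalty fairness across allele frequencies) and
coefficients reported on the genotype scale. Per α the λ path is 100
log-spaced values from λ_max = max|x′(y−ȳ)|/(nα) down to 10⁻³λ_max;
10-fold CV (seeded, equal-size, unstratified folds) gives mean and
standard error of validation MSE; the 1SE rule takes the largest λ
within one SE of the minimum, and the α grid 0.05–0.95 (step 0.1)
is searched by smallest 1SE-rule CV error. Fitted solutions are
verified in tests against the orthonormal-design soft-threshold closed
form and a KKT subgradient check at 1e−6.

The rank-based comparators take the n smallest scan p-values, with n
matched to the paired LASSO/EN panel size; ties break by larger
|effect|, then map order, so selection is deterministic.

## GBLUP and AI-REML

For K relationship matrices, V = Σ_k σ²_k G_k + σ²_e D with fixed
diagonal weights d_jj = (1−r²_j)/r²_j floored at 1e−6 (a reliability of
exactly 1 would give a zero residual weight). One σ²_e scales the whole
weighted residual — the standard DRP-weighted formulation. Updates are
average-information Newton steps on (σ²_1…σ²_K, σ²_e); whenever an AI
step proposes a component below the 1e−10 floor (or the AI matrix is
singular) the iteration takes the monotone EM update instead.
Convergence is a relative parameter-change norm below 1e−8, capped at
1,000 iterations; hitting the cap sets `converged=False` and is
reported, never raised — confounded two-matrix models (e.g. two panels
in strong LD) are an expected outcome, not an error. GEBVs are the
conditional means σ²_k G_k V⁻¹(y−1μ̂), verified in tests against the
mixed-model-equation solution and, for VanRaden-1 matrices, against
ridge-regression SNP-BLUP with penalty σ²_e·2Σp(1−p)/σ²_a.

Validation animals enter the relationship matrices but not the REML:
components and μ̂ come from the reference block, and validation GEBVs
are projected through the cross-block, GEBV_val = Σ_k σ²_k
G[val,ref] V_ref⁻¹(y_ref − 1μ̂) — the conditional mean given reference
data at the estimated components.

In the merged chip+selected scenarios, overlapping SNPs are removed
from the chip set, so |union| = |chip| + |selected| − |overlap| holds
exactly and the two-matrix model never fits a SNP twice.

## Evaluation

Accuracy divides the validation Pearson correlation of DRP and GEBV by
√(mean r²); the mean is taken over the validation set (the averaging
population is configurable, as conventions differ), and the
correlation is plain Pearson on DRPs, unweighted. The reliability
filter (≥ 0.40) applies to validation only. Bias is the OLS slope of
DRP on GEBV. The synthetic "50K chip" is a fixed seeded subsample of
1,000 simulated SNPs — it emulates the chip-within-sequence nesting
without an array manifest.

## Known limitations

* The scan's fixed-ratio approximation slightly mis-states p-values
  for SNPs with large effects (where the null components are wrong);
  the exact per-SNP variant is impractical beyond toy scale.
* AI-REML forms dense V⁻¹ per iteration (O(n³)); the implementation is
  intended for populations up to a few thousand individuals.
* The 1SE rule with unstratified folds can return an empty panel on
  weak-signal data; the pipeline reports this rather than backing off
  to the CV-minimum λ.
* Simulated LD is short-range only; strategies whose real-data
  behaviour depends on long-range LD or family structure (notably how
  much a sparse chip recovers) will look different here than on cattle
  data.
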