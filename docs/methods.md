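# Methods

## Model and procedure

The package tests whether a genomic region — a gene, or an intergenic gap
between genes — is associated with a quantitative trait, treating the
region's variants jointly.

**Adjustment.** Trait and genotypes are adjusted for covariates by two
linear models: `y_i = α₀ + Σ_p α_p z_ip + ε_i` and, per variant,
`x_im = α₀m + Σ_p α_pm z_ip + τ_im`. All testing operates on the OLS
residuals `ỹ_i`, `x̃_im`. Residualization uses a QR decomposition of the
intercept-augmented design (not the normal equations), so residuals are
orthogonal to every covariate at machine precision; a rank-deficient design
raises an error naming the collinear columns. Dosage is treated as numeric
additive coding. Missing dosages are mean-imputed per variant before
residualization — the smallest-impact choice, since mean imputation leaves
the centered column unchanged for observed samples. Samples missing any
phenotype or covariate are dropped before analysis.

**TOW.** Variant `m` receives the weight `w_m`, the slope of the simple
regression of `ỹ` on `x̃_m`; the statistic is the covariance score of `ỹ`
with the `w`-weighted dosage combination, which algebraically equals
`Σ_m (Σ_i ỹc_i x̃c_im)² / Σ_i x̃c_im²` (centered quantities), a sum of
per-variant score-test-like terms. It is non-negative, and opposite-signed
effects contribute additively — the property that distinguishes it from an
unweighted burden sum. Variants whose residual dosage has zero variance get
weight 0 and are excluded from the statistic; if no variant varies the
statistic is 0 with a warning.

**Permutation p-values.** The trait-residual vector is permuted across
samples, genotype residuals stay fixed, and the statistic — including the
weights, which are a function of `ỹ` — is recomputed per permutation:
`p = (b + 1)/(B + 1)` with `b = #{T_perm ≥ T_obs}`, so `p ≥ 1/(B+1)` and
never zero. Permuting residuals (rather than re-fitting the covariate model
on permuted raw traits) is the standard reading of permutation after
adjustment and is the cheap one; it is a documented design choice, not a
claim about what any particular prior analysis did. One permutation-index
matrix can be shared across all regions of a scan (the default in the
pipeline), which also makes rare/common/combined p-values comparable under
identical permutations; per-region streams are available by passing a seed
instead.

**VW-TOW.** With `T_r`, `T_c` the TOW statistics of the rare (MAF < 0.01)
and common subsets, the combination `T_λ = λ·T_r/var(T_r) +
(1−λ)·T_c/var(T_c)` is scanned over `λ_k = k/K`, `K = 10` by default (the λ
dependence is smooth, so a coarse grid suffices). `var(T_r)`, `var(T_c)`
are the sample variances of the permuted statistics — the permutation
distribution is already computed and the estimator needs no extra
assumptions. The test statistic is the minimum over the grid of the
per-λ permutation p-values. Because this minimum is selected
data-dependently, the naive minimum is anti-conservative; the final p-value
recalibrates it by computing, for each permutation, its own min-p against
the pooled permutation set (every value, observed included, is ranked
within the same pooled set, making observed and permuted minima
exchangeable) and reporting `(#{min-p_perm ≤ min-p_obs} + 1)/(B + 1)`. The
exact calibration scheme used by earlier implementations of this statistic
is not restated in the literature we follow; this pooled-rank scheme is our
choice and is validated empirically by the type-I-error study. Degenerate
cases collapse to plain TOW on the non-empty (or non-degenerate) subset and
are flagged in the result.

**Region definitions.** Gene spans come from a UCSC refGene-layout table:
per gene symbol and chromosome, the union span min(txStart)..max(txEnd),
converted from 0-based half-open to 1-based inclusive coordinates. A
variant inside two overlapping gene spans is assigned to *each* such gene —
the test asks a per-gene question — so the partition invariant holds at the
gene-versus-intergenic layer. Intergenic regions are the maximal gaps
between consecutive *merged* gene spans (plus the two flanks); gaps holding
no variant produce no region, and chromosomes absent from the annotation
yield one whole-chromosome intergenic region. Monomorphic variants are
removed before mapping. "Rare" means MAF strictly below the threshold
(default 0.01; a variant exactly at the threshold is common — the boundary
rule is declared here and tested). MAFs are always computed on the analyzed
samples, after incomplete-sample removal, and folded above 0.5.

**Pipeline.** The end-to-end scan tests every region on its rare-only,
common-only and combined subsets (VW-TOW on a single-kind subset collapses
to TOW by construction), filters regions with `p < threshold` (strict;
default 0.001) under **both** TOW and VW-TOW, and runs Lasso and sparse PLS
on the survivors. The fixed threshold follows the original design;
Bonferroni and Benjamini–Hochberg columns are emitted alongside as a
clearly-labelled extension and play no role in the filter. The pipeline
warns when `1/(B+1) ≥ threshold` (no region can pass). Outputs are a pure
function of config + seed: reruns are byte-identical, and results are
independent of the `--threads` setting because the permutation matrix is
generated once up front.

**Composite trait.** Mean arterial pressure is `MAP = (2/3)·DBP +
(1/3)·SBP` (mmHg), computed after incomplete-sample removal.

**Selection.** Lasso goes through scikit-learn (`LassoCV` with
deterministic unshuffled folds, or a walk along `lasso_path` picking the
penalty whose active set is closest to a target count, preferring the
sparser fit on ties). Sparse PLS is implemented here as a NIPALS-style
algorithm in the spirit of the sparse-PLS literature: per component the
direction vector is the soft-thresholded covariance `X'y` (threshold
`η · max|X'y|`), scores are deflated from `X` and `y`, and a variant is
selected if it loads on any component; final coefficients are the
least-squares fit on the selected set, reported on the original dosage
scale after column standardization. `η` is tuned by unshuffled K-fold
prediction error over a fixed grid (0.05..0.95), or count-targeted. At
maximal sparsity the soft threshold keeps only the argmax covariance, so
the selection floor is a singleton. Everything is deterministic given the
data.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `maf_threshold` | 0.01 | rare/common split (strict `<` for rare) |
| `n_permutations` (B) | 10,000 (pipeline); 499–999 in simulation | permutation count; p-value floor is 1/(B+1) |
| `K` | 10 | λ grid resolution, λ_k = k/K |
| `significance_threshold` | 0.001 | strict region filter applied to both tests |
| `alpha` | 0.05 | nominal level in power studies (reject when p ≤ α; exact size when α(B+1) is an integer) |
| `n_components` | 2 | sparse-PLS latent components |

## Synthetic data

The generator emulates the data regime the analysis targets: a few hundred
unrelated samples; Hardy–Weinberg genotypes `Binomial(2, MAF)` independent
across variants; a mixed MAF spectrum (rare variants uniform on
0.002–0.01, common on 0.05–0.4); a trait that is linear in covariates and
in a causal variant subset with signed effects, plus Gaussian noise.
Blood-pressure scenarios emit SBP and DBP sharing the genetic score through
per-trait loadings (baselines 120/80 mmHg) with independent noise, so the
composite MAP can be studied. Options: random dosage masking (the trait is
always built from complete dosages), and a block-correlation stress mode
via a Gaussian copula with a common factor per block. RNG discipline: one
seed per scenario, with named sub-streams per operation and per variant
column, so adding variants never perturbs earlier columns and identical
scenarios are bit-reproducible.

What the generator does **not** emulate: realistic linkage disequilibrium
maps, pedigree structure, genotyping error, imputation uncertainty, or
non-Gaussian trait tails. Passing tests therefore demonstrate correctness
and calibration under the stated generating model, not performance on any
particular real cohort.

## Standard operating points (`towgene.studies`)

Simulation sizes were chosen once as desk-scale defaults that still give
informative Monte-Carlo precision (binomial SE ≈ 0.01 at 500 replicates,
≈ 0.035 at 200):

* **Type-I error**: 500 null replicates, n = 200, 20 variants
  (5 rare + 15 common), one covariate, B = 499, α = 0.05.
* **Effect ladder**: three causal common variants with β ∈ {0, 0.08, 0.2}
  trait-SD per allele, n = 500, 200 replicates. The small/large values were
  calibrated by pilot simulation to sit in the low-power and high-power
  regimes respectively; only the *ordering* of the ladder is asserted.
* **Mixed directions**: two common causal variants with effects (+0.35,
  −0.35), n = 300, 200 replicates; TOW is compared against the unweighted
  burden collapse, where such effects cancel by construction.
* **Selection**: one strong causal variant (β = 0.5, MAF 0.3) among 20
  null variants, n = 500, 100 replicates with CV tuning; count-targeted
  tuning is checked at target 5 over 50 replicates.

## Numerical choices and degenerate inputs

* OLS via QR; collinearity detected from the R diagonal and reported by
  covariate name.
* Permutation comparisons use `≥` on raw float statistics; the observed
  value always counts itself in pooled ranks, so ties are conservative.
* Zero-variance variants: weight 0, excluded; all-zero regions: statistic
  0 with a warning; empty subsets: error (tests refuse empty regions).
* VW-TOW with an empty or zero-variance subset collapses to TOW on the
  other subset, flagged in the result.
* MAFs above 0.5 are folded; all-missing variant columns count as
  monomorphic and are removed.
* Per-replicate seeds in power studies derive from the master seed through
  `SeedSequence((master, scenario, replicate))`, so every scenario is
  independently reproducible.

## Known limitations

* Permutation of residuals assumes exchangeability after covariate
  adjustment; strong heteroscedasticity or population structure would
  violate it (a principal-component covariate adjustment is a possible
  user-level mitigation, not built in).
* No family/pedigree support; samples must be unrelated.
* No adaptive early stopping for permutations; B is paid in full per scan
  (mitigated by the shared permutation matrix and vectorized statistics).
* The sparse-PLS implementation targets variable selection; it is not a
  general-purpose PLS regression library.
* Asymptotic (non-permutation) p-values are out of scope.
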