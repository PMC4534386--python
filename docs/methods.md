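# Methods

## Model and procedure

The package targets quantitative traits y with environmental covariates z
and SNP genotypes coded as minor-allele counts s ∈ {0,1,2}.  All scoring
starts from the covariates-only null model

    l(μᵢ) = α + zᵢᵀγ,

fitted by OLS (identity link, normal errors) or by a gamma GLM with log
link for strictly positive right-skewed traits.  Genotypes never enter
the null model, so residual scores are computed once per dataset, not per
candidate combination or per cross-validation fold.

Residual scores:

* **ordinary** — the raw response-scale residuals yᵢ − μ̂ᵢ;
* **trimmed (L-estimator)** — the internally studentized residual
  rᵢ = (yᵢ − μ̂ᵢ) / (sdᵢ √(1 − hᵢᵢ)), set to 0 with the sample excluded
  whenever |rᵢ| > T (the boundary |rᵢ| = T is kept);
* **winsorized (M-estimator)** — rᵢ clamped to [−T, +T].

Here hᵢᵢ is the hat-matrix leverage and sdᵢ the estimated residual SD:
σ̂ for the normal family, √φ̂·μ̂ᵢ for the gamma family (φ̂ the Pearson
dispersion, so sdᵢ is the model SD of yᵢ at its fitted mean).  The
studentization is *internal*; an external (leave-one-out) reading would
be equally defensible, and a `leverage_adjust=False` switch divides by
sdᵢ alone.  Scores are derived from the maximum-likelihood null fit; an
optional `refit=True` one-step variant (fit → trim at T → refit on the
retained samples → re-score everyone with plain studentization → trim
again) honours the least-trimmed-squares motivation of the trimmed score
at the cost of one extra fit.  Full LTS or Tukey-biweight IRLS regression
is deliberately not implemented: the contribution is the score transform,
not a robust fitter.

The MDR engine enumerates all C(p, k) SNP combinations (k = 2 by
default).  Each combination's samples are binned into 3ᵏ cells by
mixed-radix (base-3) encoding of the genotype calls; a cell is HIGH when
its score sum is strictly positive, LOW otherwise (so empty and
exactly-zero cells are LOW).  For case/control data a binary mode labels
a cell HIGH when cases/controls strictly exceeds a ratio threshold
(default 1; cases with no controls → HIGH, empty → LOW).  Balanced
accuracy cross-classifies the per-sample outcome (score sign, or case
status) against the cell label; a fold lacking an outcome class
contributes 0.5 for the undefined term.  Samples with score exactly 0 —
in particular trimmed ones — are excluded from both training and testing;
samples missing a genotype at a combination are excluded for that
combination only.

Cross-validation assigns folds by a seeded uniform permutation (sizes
differ by ≤ 1, no stratification).  Per fold, every combination is
trained on the other folds and tested on the held-out fold; CVC counts
the folds where a combination has the best training BA.  Every
tie is broken deterministically: per-fold winners by lexicographically
smallest combo, the final ranking by (CVC desc, mean test BA desc, combo
lexicographic).  Combinations are generated over lexicographically sorted
SNP ids, making results invariant to genotype column order.

## Screening and network post-analysis

For larger panels the search is preceded by: (1) one additive-coding
regression per SNP with all covariates (Wald p for the SNP term;
monomorphic SNPs get p = 1 and a flag); (2) greedy LD pruning in
ascending-p order, keeping a SNP iff its squared Pearson correlation of
allele counts (composite LD — phase is unavailable from dosages) with
every kept SNP is below r² = 0.8; (3) truncation at floor(n / ln n), the
sure-independence-screening heuristic (base configurable, cutoff
overridable).  Pruning is global greedy rather than windowed: at the
hundreds-of-SNPs scale this tool targets, determinism matters more than
the O(p·kept) cost.

The post-analysis graphs the top pairs by mean test BA (top 100 by
convention), one edge per pair, optionally mapping SNPs to gene labels
(parallel edges collapse, keeping multiplicity; self-loops drop), and
reports hub nodes with at least `min_degree` (default 4) edges.

## Synthetic data

The generator reproduces the two-family contamination designs used to
study the scores:

* **Normal**: y = envir1 + β₁s₁ + β₂s₂ + β₁ₓ₂s₁s₂ + ε with envir1,
  ε ~ N(0,1) and all SNPs ~ Bin(2, MAF).  Each sample is independently an
  outlier with probability equal to the mixed proportion, in which case
  y ~ N(0, 400) (SD 20) while genotypes and the recorded envir1 covariate
  are untouched.
* **Gamma**: y ~ Gamma(shape = m²/2, scale = 2) with
  m = envir1 + β₁s₁ + β₂s₂ + β₃s₁s₂, giving conditional mean m²,
  variance 2m² and skewness 2√2/|m|; outliers receive a +0.1 location
  shift.  The two Gamma parameters admit more than one reading; the
  scale-2 parameterization was adopted because it lets the genetic signal
  shift the trait mean, and a rate reading (scale = m²) is available via
  a flag.  m = 0 (a measure-zero event) triggers resampling of envir1;
  draws from near-zero shapes that underflow to 0.0 are floored at 1e-12
  to stay inside the open Gamma support.

Seven named designs per family encode the studied effect-size /
contamination grid (e.g. Normal design1 = β = (0.2, 0.2, 0.18), 6.7%
outliers; design7 = same effects, no outliers).  Exact narrow-sense
heritability for the Normal family enumerates the 9 genotype classes:
h² = Var(g) / (σ²_env + Var(g) + σ²_err) with
g = β₁s₁ + β₂s₂ + β₁ₓ₂s₁s₂.

What the generator does **not** emulate: linkage disequilibrium between
noise SNPs (they are independent), Hardy–Weinberg departures, missing
genotypes, covariate–genotype confounding, and population structure.
Passing power results therefore show robustness to trait outliers under
idealized genetics, not performance on structured cohorts.

## Power and false-detection experiments

Power = fraction of simulated datasets whose top-ranked pair is the
causal one (simulate → null fit with envir1 as covariate → score →
exhaustive k = 2 search → best by CVC).  A master `SeedSequence` spawns
one stream per iteration (split again for data and fold assignment), so
estimates are reproducible and methods are compared on *paired* datasets.
FDER permutes the trait of one simulated dataset per replicate, reruns
the pipeline, and counts how often the designated target pair wins; with
exchangeable pairs the expected rate is 1/C(p,2).

Problem sizes in the shipped tests are the package's own scaled choices:
power ordering uses n = 1000, p = 20 SNPs, 100 paired iterations with a
one-sided sign test at α = 0.05 (the positive claims must be significant;
the no-outlier claim requires that trimming is *not* significantly
better than ordinary); null calibration uses n = 300, p = 10, 2000
iterations against a 99% binomial interval around 1/45.  The full
published-scale grids (1000 iterations × 1000 SNPs, 500,000 permutation
replicates) are supported by the same drivers but are cluster-sized runs.

## Numerical choices and edge cases

* Genotypes are validated to {0, 1, 2, NA}; the PLINK `.raw` reader
  assumes A1 = minor allele (export accordingly).
* A null-model residual scale at float-roundoff level (perfect fit)
  raises a degeneracy error instead of producing huge studentized values.
* Rank-deficient covariate matrices are rejected with the collinear
  columns named.
* Float cell sums accumulate in sample order; training sums are formed
  as total − fold, which is fast and exactly reproducible.
* SIS with n = 8,577 gives 947 (natural log) — published analyses have
  used other cutoffs (585 appears in the literature for this n without a
  stated base), which is why the cutoff is user-overridable.
* The engine caps 3ᵏ cells (default k ≤ 8) and the number of candidate
  combinations (default 200,000), pointing users to the screening step.

## Known limitations

* Only the score-based quantitative path is cross-validated against a
  brute-force reference; the binary MDR mode is tested functionally.
* The gamma-family residual definition (response-scale, SD at the fitted
  mean) is one of several defensible choices; deviance or Anscombe
  residuals would change scores but not the engine.
* No multiple-testing correction is applied in the screening scan — it is
  a ranking device, not an inference procedure.
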