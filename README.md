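# robust-gmdr

Gene–gene interaction (epistasis) detection for quantitative traits that
contain outlying observations.

Generalized multifactor dimensionality reduction (GMDR) finds interacting
SNP pairs by collapsing the 3×3 genotype table of each candidate pair into
"high risk" / "low risk" cells: a covariates-only null model
`l(μᵢ) = α + zᵢᵀγ` is fitted, and a cell is high-risk when the sum of its
samples' residuals is positive.  Model fit is scored by balanced accuracy
BA = (sensitivity + specificity)/2 under 10-fold cross-validation, and the
pair selected most often across folds (largest cross-validation
consistency, CVC) wins.  Because the classification depends on *sums* of
residuals, a handful of outlying trait values can flip cell labels and
wreck power.  This package implements two robust residual scores that fix
that:

* **L-estimator (trimmed)** — the internally studentized residual
  rᵢ = (yᵢ − μ̂ᵢ)/(σ̂√(1−hᵢᵢ)), set to 0 (sample excluded) when |rᵢ| > T;
* **M-estimator (winsorized)** — rᵢ clamped to ±T, so extreme residuals
  keep their sign but lose leverage,

with threshold T = 1.5 by default (1.75 and 2 are common alternatives).
Around the core engine the package provides normal- and gamma-family null
models, a single-SNP screening scan with LD pruning and an n/log(n)
sure-independence-screening cutoff, simulation designs with controlled
outlier contamination, exact two-locus heritability, power and
false-detection-rate experiments, and an interaction-network/hub
post-analysis.

## Worked example

```python
from robust_gmdr import (fit_null_model, compute_scores, exhaustive_search,
                         get_design, simulate)

design = get_design("design1", "normal", maf=0.3, n_samples=1000, n_snps=10)
data = simulate(design, seed=7)          # 6.7% of traits replaced by N(0, 400)
fit = fit_null_model(data.pheno)         # trait ~ envir1 (OLS)
for method in ("ordinary", "trimmed", "winsorized"):
    best = exhaustive_search(data.geno, compute_scores(fit, method, T=1.5),
                             k=2, folds=10, seed=1)[0]
    print(method, best.combo, best.cvc, round(best.mean_test_ba, 4))
```

prints

```
ordinary ('SNP01', 'SNP02') 4 0.5483
trimmed ('SNP01', 'SNP02') 10 0.5832
winsorized ('SNP01', 'SNP02') 10 0.5787
```

The causal pair is SNP01×SNP02.  With 6.7% contamination the ordinary
residual score backs the true pair in only 4 of 10 folds, while both
robust scores select it in all 10 and achieve higher held-out balanced
accuracy (0.58 vs 0.55; 0.5 is chance).  The `examples/` directory has one
short script per capability (heritability table, outlier-robust search,
power comparison, screening pipeline, network hubs); run them with
`python examples/<name>.py`.

A thin CLI mirrors the library for shell use:

```
rgmdr simulate --design design1 --n 1000 --p 20 --seed 1 --out data/
rgmdr search --geno data/genotypes.tsv --pheno data/phenotypes.tsv \
      --method winsorized --T 1.5 --seed 1 --out run/
rgmdr network --results run/results.tsv --top-k 100 --out net/
```

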