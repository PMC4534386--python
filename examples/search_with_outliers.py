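"""Effect of trait outliers on the interaction search, and the robust fix.

Simulates 1,000 samples with a planted SNP1 x SNP2 interaction where 6.7%
of traits are replaced by N(0, 400) noise, then runs the exhaustive pair
search with ordinary, trimmed (L-estimator) and winsorized (M-estimator)
residual scores.
"""

from robust_gmdr import (
    compute_scores,
    exhaustive_search,
    fit_null_model,
    get_design,
    simulate,
)

design = get_design("design1", "normal", maf=0.3, n_samples=1000, n_snps=10)
data = simulate(design, seed=7)
print(f"simulated {design.n_samples} samples, {design.n_snps} SNPs, "
      f"{int(data.is_outlier.sum())} outliers; causal pair = {data.causal_ids}")

fit = fit_null_model(data.pheno)  # trait ~ envir1, OLS
for method in ("ordinary", "trimmed", "winsorized"):
    scores = compute_scores(fit, method, T=1.5)
    ranked = exhaustive_search(data.geno, scores, k=2, folds=10, seed=1)
    best = ranked[0]
    hit = "HIT " if set(best.combo) == set(data.causal_ids) else "miss"
    print(f"{method:10s} best={','.join(best.combo):15s} CVC={best.cvc:2d} "
          f"mean test BA={best.mean_test_ba:.4f}  [{hit}]")

print(
    "\nCVC counts the folds (of 10) in which the pair had the best training "
    "BA;\nmean test BA above 0.5 indicates out-of-fold predictive signal. "
    "With heavy\ncontamination the ordinary residual score often misses the "
    "causal pair that\nthe trimmed/winsorized scores recover."
)
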