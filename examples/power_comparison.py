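"""Scaled-down power comparison of the three GMDR score methods.

Estimates, over paired simulated datasets, how often each method selects
the true causal pair: once under 6.7% N(0,400) contamination and once on
clean data.  (40 iterations at p = 15 SNPs keeps this quick; the ordering
is the quantity of interest, not the absolute power.)
"""

from robust_gmdr import AnalysisConfig, get_design, power_matrix

configs = {m: AnalysisConfig(score_method=m, threshold_T=1.5)
           for m in ("ordinary", "trimmed", "winsorized")}

for label, name in (("with outliers (6.7%)", "design1"),
                    ("no outliers", "design7")):
    design = get_design(name, "normal", maf=0.3, n_samples=1000, n_snps=15)
    hits = power_matrix(configs, design, n_iter=40, seed=11)
    powers = "  ".join(f"{m}={h.mean():.2f}" for m, h in hits.items())
    print(f"{label:22s} {powers}")

print(
    "\nPower = fraction of datasets whose best-ranked pair is the causal "
    "one.\nUnder contamination the trimmed/winsorized scores dominate; on "
    "clean data\ntrimming discards information and the ordinary score is "
    "competitive or better."
)
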