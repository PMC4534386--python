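"""Synthetic trait/genotype generator, heritability, and power/FDER drivers.

Two generative families are provided, each with an outlier-contamination
mechanism controlled by a mixed proportion:

* Normal: y = envir1 + b1*SNP1 + b2*SNP2 + b12*SNP1*SNP2 + eps with
  envir1, eps ~ N(0,1) and SNPs ~ Bin(2, MAF); an outlying sample instead
  draws y ~ N(0, outlier_sd^2) (default SD 20, variance 400) with its
  genotypes untouched.
* Gamma: y ~ Gamma(shape = m^2/2, scale = 2) with linear predictor
  m = envir1 + b1*SNP1 + b2*SNP2 + b12*SNP1*SNP2, so conditionally
  E[y] = m^2, Var[y] = 2 m^2 and skewness = 2*sqrt(2)/|m|; an outlying
  sample adds a +0.1 location shift.  The printed source for the two Gamma
  parameters is ambiguous, so the alternative rate reading
  (scale = m^2) is available via ``parameterization="rate"``.

Narrow-sense heritability for the Normal family is computed exactly by
enumerating the 9 two-locus genotype classes.  The power driver runs the
full pipeline (simulate -> null model -> scores -> exhaustive pair search
-> best pair) and reports the fraction of iterations selecting the causal
pair; the FDER driver does the same on permuted (null) traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnalysisConfig, GenotypeMatrix, PhenotypeTable, ValidationError
from .engine import exhaustive_search
from .scoring import compute_scores, fit_null_model


@dataclass
class SimulationDesign:
    """One row of the simulation design grid."""

    beta1: float
    beta2: float
    beta12: float
    maf: float = 0.3
    mixed_proportion: float = 0.0
    family: str = "normal"
    n_samples: int = 1000
    n_snps: int = 100
    outlier_sd: float = 20.0
    gamma_shift: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValidationError("maf must be in (0, 0.5]")
        if not 0 <= self.mixed_proportion < 1:
            raise ValidationError("mixed_proportion must be in [0, 1)")
        if self.family not in ("normal", "gamma"):
            raise ValidationError("family must be 'normal' or 'gamma'")
        if self.n_snps < 2:
            raise ValidationError("need at least the two causal SNPs")
        if not self.outlier_sd > 0:
            raise ValidationError("outlier_sd must be positive")


#: Effect-size / contamination grids of the two design tables
#: (beta1, beta2, interaction, mixed proportion).
NORMAL_DESIGNS: dict[str, tuple[float, float, float, float]] = {
    "design1": (0.2, 0.2, 0.18, 0.067),
    "design2": (0.2, 0.2, 0.18, 0.033),
    "design3": (0.4, 0.4, -0.3, 0.067),
    "design4": (0.4, 0.4, -0.3, 0.033),
    "design5": (0.25, 0.25, 0.15, 0.067),
    "design6": (0.25, 0.25, 0.15, 0.033),
    "design7": (0.2, 0.2, 0.18, 0.0),
}

GAMMA_DESIGNS: dict[str, tuple[float, float, float, float]] = {
    "design1": (0.6, 0.6, 0.3, 0.067),
    "design2": (0.6, 0.6, 0.3, 0.033),
    "design3": (1.2, 0.4, 0.3, 0.067),
    "design4": (1.2, 0.4, 0.3, 0.033),
    "design5": (0.8, -0.4, -0.2, 0.067),
    "design6": (0.8, -0.4, -0.2, 0.033),
    "design7": (0.6, 0.6, 0.3, 0.0),
}


def get_design(name: str, family: str = "normal", **overrides) -> SimulationDesign:
    """Look up a named design row (e.g. ``design1``) for a family; keyword
    overrides adjust maf, sample size, SNP count, etc."""
    table = NORMAL_DESIGNS if family == "normal" else GAMMA_DESIGNS
    if name not in table:
        raise ValidationError(f"unknown design {name!r}; choose from {sorted(table)}")
    b1, b2, b12, mix = table[name]
    return replace(
        SimulationDesign(b1, b2, b12, family=family, mixed_proportion=mix),
        **overrides,
    )


def write_design_registry(path) -> None:
    """Write the built-in design grids as a plain-text registry TSV."""
    rows = []
    for family, table in (("normal", NORMAL_DESIGNS), ("gamma", GAMMA_DESIGNS)):
        for name, (b1, b2, b12, mix) in table.items():
            rows.append({"design": name, "family": family, "beta1": b1,
                         "beta2": b2, "beta12": b12, "mixed_proportion": mix})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_design_registry(path) -> dict[tuple[str, str], tuple[float, float, float, float]]:
    df = pd.read_csv(path, sep="\t")
    return {
        (r.family, r.design): (r.beta1, r.beta2, r.beta12, r.mixed_proportion)
        for r in df.itertuples()
    }


@dataclass
class SimulatedDataset:
    """Genotypes, phenotype (trait + envir1 covariate) and truth labels."""

    geno: GenotypeMatrix
    pheno: PhenotypeTable
    is_outlier: np.ndarray
    causal_pair: tuple[int, int] = (0, 1)

    @property
    def causal_ids(self) -> tuple[str, str]:
        return (self.geno.snp_ids[self.causal_pair[0]],
                self.geno.snp_ids[self.causal_pair[1]])


def _ids(n: int, p: int) -> tuple[list[str], list[str]]:
    sw, pw = len(str(n)), len(str(p))
    return ([f"S{i + 1:0{sw}d}" for i in range(n)],
            [f"SNP{j + 1:0{pw}d}" for j in range(p)])


def _package(design, calls, trait, envir, outlier) -> SimulatedDataset:
    sample_ids, snp_ids = _ids(design.n_samples, design.n_snps)
    geno = GenotypeMatrix(sample_ids, snp_ids, calls)
    pheno = PhenotypeTable(sample_ids, trait, envir[:, None], ["envir1"])
    return SimulatedDataset(geno, pheno, outlier)


def simulate_normal(design: SimulationDesign, seed) -> SimulatedDataset:
    """Normal-family dataset with N(0, outlier_sd^2) contamination.

    Outlier status is an independent Bernoulli(mixed_proportion) draw per
    sample; outliers keep their genotypes and recorded envir1 but their
    trait ignores both.
    """
    if design.family != "normal":
        raise ValidationError("design family is not 'normal'")
    rng = np.random.default_rng(seed)
    n, p = design.n_samples, design.n_snps
    calls = rng.binomial(2, design.maf, size=(n, p)).astype(np.int8)
    envir = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    s1, s2 = calls[:, 0].astype(float), calls[:, 1].astype(float)
    pure = (envir + design.beta1 * s1 + design.beta2 * s2
            + design.beta12 * s1 * s2 + eps)
    outlier = rng.random(n) < design.mixed_proportion
    y_out = rng.normal(0.0, design.outlier_sd, size=n)
    trait = np.where(outlier, y_out, pure)
    return _package(design, calls, trait, envir, outlier)


def simulate_gamma(design: SimulationDesign, seed,
                   parameterization: str = "scale2") -> SimulatedDataset:
    """Gamma-family dataset; outliers gain a +gamma_shift location shift.

    ``parameterization``: ``scale2`` (default; shape m^2/2, scale 2) or
    ``rate`` (shape m^2/2, scale m^2).
    """
    if design.family != "gamma":
        raise ValidationError("design family is not 'gamma'")
    if parameterization not in ("scale2", "rate"):
        raise ValidationError("parameterization must be 'scale2' or 'rate'")
    rng = np.random.default_rng(seed)
    n, p = design.n_samples, design.n_snps
    calls = rng.binomial(2, design.maf, size=(n, p)).astype(np.int8)
    s1, s2 = calls[:, 0].astype(float), calls[:, 1].astype(float)
    genetic = (design.beta1 * s1 + design.beta2 * s2
               + design.beta12 * s1 * s2)
    envir = rng.standard_normal(n)
    m = envir + genetic
    # shape must be positive: redraw envir1 on the (measure-zero) event m == 0
    while np.any(m == 0.0):
        bad = m == 0.0
        envir[bad] = rng.standard_normal(int(bad.sum()))
        m[bad] = envir[bad] + genetic[bad]
    shape = 0.5 * m ** 2
    scale = 2.0 if parameterization == "scale2" else m ** 2
    trait = rng.gamma(shape, scale)
    # tiny shapes (|m| near 0) concentrate mass so close to 0 that draws
    # underflow to exactly 0.0; floor them to stay in the open support
    trait = np.maximum(trait, 1e-12)
    outlier = rng.random(n) < design.mixed_proportion
    trait = np.where(outlier, trait + design.gamma_shift, trait)
    return _package(design, calls, trait, envir, outlier)


def simulate(design: SimulationDesign, seed, **kwargs) -> SimulatedDataset:
    fn = simulate_normal if design.family == "normal" else simulate_gamma
    return fn(design, seed, **kwargs)


def heritability_normal(beta1: float, beta2: float, beta12: float, maf: float,
                        env_var: float = 1.0, err_var: float = 1.0) -> float:
    """Narrow-sense heritability of the Normal model, exactly.

    Enumerates the 9 (SNP1, SNP2) genotype classes with Binomial(2, maf)
    probabilities, takes the variance of the genetic value
    g = b1*s1 + b2*s2 + b12*s1*s2, and returns
    h^2 = var_g / (env_var + var_g + err_var).
    """
    if not 0 < maf <= 0.5:
        raise ValidationError("maf must be in (0, 0.5]")
    s = np.arange(3)
    pr = stats.binom.pmf(s, 2, maf)
    s1, s2 = np.meshgrid(s, s, indexing="ij")
    w = np.outer(pr, pr)
    g = beta1 * s1 + beta2 * s2 + beta12 * s1 * s2
    mean = float((w * g).sum())
    var_g = float((w * (g - mean) ** 2).sum())
    return var_g / (env_var + var_g + err_var)


def _run_pipeline(data: SimulatedDataset, config: AnalysisConfig, cv_seed) -> bool:
    """Score the dataset, search all pairs, report whether the causal
    (unordered) pair wins."""
    family = "gamma_log" if config.family == "gamma_log" else "normal_identity"
    fit = fit_null_model(data.pheno, family)
    scores = compute_scores(fit, config.score_method, config.threshold_T)
    ranked = exhaustive_search(data.geno, scores, k=2,
                               folds=config.cv_folds, seed=cv_seed)
    return set(ranked[0].combo) == set(data.causal_ids)


def power_matrix(configs: dict[str, AnalysisConfig], design: SimulationDesign,
                 n_iter: int, seed: int) -> dict[str, np.ndarray]:
    """Per-iteration success indicators for several methods on *shared*
    datasets (paired design), keyed by config name.

    A master seed spawns one stream per iteration (dataset + fold split),
    so estimates are reproducible and methods see identical data.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be at least 1")
    out = {name: np.zeros(n_iter, dtype=bool) for name in configs}
    master = np.random.SeedSequence(seed)
    for i, child in enumerate(master.spawn(n_iter)):
        data_ss, cv_ss = child.spawn(2)
        data = simulate(design, data_ss)
        for name, cfg in configs.items():
            out[name][i] = _run_pipeline(data, cfg, cv_ss)
    return out


def estimate_power(method_config: AnalysisConfig, design: SimulationDesign,
                   n_iter: int, seed: int) -> float:
    """Fraction of iterations in which the causal pair is selected best."""
    hits = power_matrix({"m": method_config}, design, n_iter, seed)["m"]
    return float(hits.mean())


def estimate_fder(method_config: AnalysisConfig, design: SimulationDesign,
                  n_datasets: int, seed: int) -> tuple[int, float]:
    """False detection rate: how often a designated (causal-slot) pair is
    selected best when traits are permuted, i.e. under the null.

    One dataset is simulated; each replicate permutes its trait, refits
    the null model, rescores and reruns the pair search.
    Returns (selected_count, selected_count / n_datasets).
    """
    if n_datasets < 1:
        raise ValidationError("n_datasets must be at least 1")
    master = np.random.SeedSequence(seed)
    data_ss, perm_ss, cv_root = master.spawn(3)
    data = simulate(design, data_ss)
    rng = np.random.default_rng(perm_ss)
    count = 0
    for cv_ss in cv_root.spawn(n_datasets):
        perm = rng.permutation(data.pheno.n_samples)
        pheno_null = PhenotypeTable(
            data.pheno.sample_ids, data.pheno.trait[perm],
            data.pheno.covariates, list(data.pheno.covariate_names),
        )
        null_data = SimulatedDataset(data.geno, pheno_null,
                                     data.is_outlier, data.causal_pair)
        count += _run_pipeline(null_data, method_config, cv_ss)
    return count, count / n_datasets
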