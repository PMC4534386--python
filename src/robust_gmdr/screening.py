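"""Pre-filtering for genome-scale inputs: per-SNP scan, LD pruning, SIS cutoff.

The exhaustive pairwise search is quadratic in the number of SNPs, so the
real-data workflow first ranks SNPs by a covariate-adjusted single-SNP
regression, prunes pairs in strong linkage disequilibrium (r^2 above a
threshold, best-ranked SNP kept), and truncates the list at roughly
n / log(n) SNPs (the sure independence screening heuristic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .datamodel import GenotypeMatrix, PhenotypeTable, ValidationError


@dataclass
class ScanResult:
    """Single-SNP association result."""

    snp_id: str
    effect_estimate: float
    p_value: float
    rank: int = 0
    monomorphic: bool = False


def single_snp_scan(geno: GenotypeMatrix, pheno: PhenotypeTable,
                    family: str = "normal_identity") -> list[ScanResult]:
    """One additive-coding regression per SNP, adjusting for all covariates.

    Returns Wald p-values for the SNP coefficient, ranked ascending
    (rank 1 = smallest p).  Samples with a missing call are dropped per
    SNP; a monomorphic SNP gets p = 1 and a warning flag.
    """
    if geno.sample_ids != pheno.sample_ids:
        raise ValidationError("genotypes and phenotypes are not aligned")
    n = geno.n_samples
    base = np.column_stack([np.ones(n), pheno.covariates])
    y = pheno.trait
    results = []
    for j, snp in enumerate(geno.snp_ids):
        g = geno.calls[:, j].astype(float)
        ok = g >= 0
        gj, Xj, yj = g[ok], base[ok], y[ok]
        if gj.size == 0 or np.all(gj == gj[0]):
            results.append(ScanResult(snp, 0.0, 1.0, monomorphic=True))
            continue
        X = np.column_stack([Xj, gj])
        if family == "normal_identity":
            q = X.shape[1]
            beta, _, rank, _ = np.linalg.lstsq(X, yj, rcond=None)
            resid = yj - X @ beta
            df = len(yj) - q
            if df <= 0 or rank < q:
                results.append(ScanResult(snp, float(beta[-1]), 1.0, monomorphic=True))
                continue
            sigma2 = resid @ resid / df
            xtx_inv = np.linalg.inv(X.T @ X)
            se = math.sqrt(max(sigma2 * xtx_inv[-1, -1], 0.0))
            if se == 0.0:
                p = 0.0 if beta[-1] != 0 else 1.0
            else:
                t = beta[-1] / se
                p = 2.0 * stats.t.sf(abs(t), df)
            results.append(ScanResult(snp, float(beta[-1]), float(p)))
        elif family == "gamma_log":
            res = sm.GLM(yj, X, family=sm.families.Gamma(sm.families.links.Log())).fit()
            results.append(ScanResult(snp, float(res.params[-1]),
                                      float(res.pvalues[-1])))
        else:
            raise ValidationError(f"unknown family {family!r}")
    order = np.argsort([r.p_value for r in results], kind="stable")
    for rank, i in enumerate(order, start=1):
        results[i].rank = rank
    return results


def genotype_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of allele counts (composite LD), over
    samples non-missing in both SNPs."""
    ok = (a >= 0) & (b >= 0)
    x, y = a[ok].astype(float), b[ok].astype(float)
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(geno: GenotypeMatrix, r2_threshold: float = 0.8,
             priority: list[str] | None = None) -> list[str]:
    """Greedy LD pruning: walk SNPs in priority order (best association
    first) and keep a SNP iff its r^2 with every kept SNP is below the
    threshold.  Exactly one SNP survives from any perfectly correlated set.
    """
    if not 0 < r2_threshold <= 1:
        raise ValidationError("r2_threshold must be in (0, 1]")
    order = priority if priority is not None else list(geno.snp_ids)
    kept: list[str] = []
    kept_cols: list[np.ndarray] = []
    for snp in order:
        col = geno.column(snp)
        if all(genotype_r2(col, kc) < r2_threshold for kc in kept_cols):
            kept.append(snp)
            kept_cols.append(col)
    return kept


def sis_select(n_samples: int, log_base: float | None = None) -> int:
    """Sure-independence-screening cutoff: floor(n / log(n)).

    Natural log by default; ``log_base`` switches the base.
    """
    if n_samples < 3:
        raise ValidationError("need at least 3 samples for the SIS cutoff")
    denom = math.log(n_samples) if log_base is None else math.log(n_samples, log_base)
    return int(n_samples / denom)


def screen(geno: GenotypeMatrix, pheno: PhenotypeTable,
           family: str = "normal_identity", r2_threshold: float = 0.8,
           n_keep: int | None = None) -> tuple[list[ScanResult], list[str]]:
    """Full screening pipeline: scan, rank, LD-prune, truncate at the SIS
    cutoff (or ``n_keep``).  Returns the scan results and the kept SNP ids."""
    scan = single_snp_scan(geno, pheno, family)
    by_rank = sorted(scan, key=lambda r: r.rank)
    kept = ld_prune(geno, r2_threshold, priority=[r.snp_id for r in by_rank])
    cut = sis_select(geno.n_samples) if n_keep is None else n_keep
    return scan, kept[:cut]
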