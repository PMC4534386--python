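"""Shared data model: genotype matrix, phenotype table, analysis configuration.

Genotypes are coded as minor-allele counts 0/1/2 (the additive coding under
which simulated SNPs are Binomial(2, MAF) draws).  Missing calls are stored
as :data:`MISSING` (-1) internally; text formats use the token ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Sentinel for a missing genotype call in the integer calls matrix.
MISSING: int = -1

#: Missing-value token used by the text formats.
MISSING_TOKEN: str = "NA"

VALID_SCORE_METHODS = ("ordinary", "trimmed", "winsorized", "binary_mdr")
VALID_FAMILIES = ("normal_identity", "gamma_log")


class ValidationError(ValueError):
    """Input data violates a domain invariant (bad call value, dup ids...)."""


class ParseError(ValueError):
    """A file could not be parsed (malformed row, unknown token...)."""


class DegenerateInputError(RuntimeError):
    """Computation cannot proceed (perfect fit, empty intersection...)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs matrix of minor-allele counts.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``calls``.
    snp_ids : list of str
        Unique SNP identifiers, one per column of ``calls``.
    calls : ndarray of int8, shape (n_samples, n_snps)
        Minor-allele counts in {0, 1, 2}; :data:`MISSING` (-1) marks a
        missing call.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValidationError("calls must be a 2-D matrix")
        n, p = self.calls.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != p:
            raise ValidationError(
                f"dimension mismatch: calls {self.calls.shape}, "
                f"{len(self.sample_ids)} sample ids, {len(self.snp_ids)} snp ids"
            )
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.snp_ids, "snp ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype call {self.calls[i, j]} at sample "
                f"{self.sample_ids[i]!r}, snp {self.snp_ids[j]!r} is not in "
                "{0, 1, 2, NA}"
            )

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown snp id {snp_id!r}") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.calls[:, self.snp_index(snp_id)]

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx], list(self.snp_ids), self.calls[idx]
        )


@dataclass
class PhenotypeTable:
    """Quantitative trait plus covariates, aligned to genotype samples.

    ``trait`` holds the (possibly transformed) phenotype y_i; ``covariates``
    the environmental factors z_i entering the null model.  Rows with a
    missing trait are dropped at load time, so ``trait`` is complete.
    """

    sample_ids: list[str]
    trait: np.ndarray
    covariates: np.ndarray = field(default=None)  # type: ignore[assignment]
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.trait = np.asarray(self.trait, dtype=float)
        n = len(self.sample_ids)
        if self.trait.shape != (n,):
            raise ValidationError("trait length must match sample_ids")
        if np.isnan(self.trait).any():
            raise ValidationError("trait contains missing values after filtering")
        if self.covariates is None:
            self.covariates = np.empty((n, 0))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        if self.covariates.shape[0] != n:
            raise ValidationError("covariate rows must match sample_ids")
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise ValidationError("covariate_names must match covariate columns")
        _check_unique(self.sample_ids, "sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def take_samples(self, idx: np.ndarray) -> "PhenotypeTable":
        return PhenotypeTable(
            [self.sample_ids[i] for i in idx],
            self.trait[idx],
            self.covariates[idx],
            list(self.covariate_names),
        )


@dataclass
class AnalysisConfig:
    """Configuration of one GMDR analysis run.

    ``threshold_T`` is the trimming/winsorizing threshold applied to
    studentized residuals (default 1.5, the recommended practical choice);
    ``ratio_threshold`` is the case/control ratio cutoff of binary MDR,
    conventionally 1.
    """

    score_method: str = "ordinary"
    threshold_T: float = 1.5
    family: str = "normal_identity"
    interaction_order_k: int = 2
    cv_folds: int = 10
    seed: int = 0
    ratio_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.score_method not in VALID_SCORE_METHODS:
            raise ValidationError(
                f"score_method {self.score_method!r} not in {VALID_SCORE_METHODS}"
            )
        if self.family not in VALID_FAMILIES:
            raise ValidationError(f"family {self.family!r} not in {VALID_FAMILIES}")
        if not self.threshold_T > 0:
            raise ValidationError("threshold_T must be positive")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be at least 2")
        if self.interaction_order_k < 1:
            raise ValidationError("interaction_order_k must be at least 1")
        if not self.ratio_threshold > 0:
            raise ValidationError("ratio_threshold must be positive")
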