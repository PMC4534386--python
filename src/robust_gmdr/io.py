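"""Readers/writers for the plain-text genotype, phenotype and result formats.

Two genotype dialects are supported:

* ``tsv`` — header ``sample_id<TAB>snp1<TAB>...``, one sample per row,
  calls in {0,1,2} with ``NA`` for missing.
* ``plink_raw`` — the whitespace-delimited PLINK ``--recode A`` dialect:
  columns ``FID IID PAT MAT SEX PHENOTYPE`` followed by one column per SNP
  counting the A1 allele.  The user must export with A1 = minor allele for
  the 0/1/2 coding to mean minor-allele count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    MISSING_TOKEN,
    GenotypeMatrix,
    ParseError,
    PhenotypeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

_PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _calls_from_frame(df: pd.DataFrame, path) -> np.ndarray:
    raw = df.to_numpy()
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    mask = pd.notna(raw)
    vals = pd.to_numeric(pd.Series(raw[mask].ravel()), errors="coerce")
    if vals.isna().any():
        bad = raw[mask].ravel()[vals.isna().to_numpy()][0]
        raise ValidationError(f"{path}: unknown genotype token {bad!r}")
    v = vals.to_numpy(dtype=float)
    if not np.all((v == np.floor(v)) & np.isin(v, (0.0, 1.0, 2.0))):
        bad = v[~np.isin(v, (0.0, 1.0, 2.0))][0]
        raise ValidationError(f"{path}: genotype call {bad!r} not in {{0,1,2,NA}}")
    calls[mask] = v.astype(np.int8)
    return calls


def _check_row_lengths(path: Path, sep: str | None) -> None:
    with open(path) as fh:
        header = fh.readline().split(sep)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            if len(line.rstrip("\n").split(sep)) != len(header):
                raise ParseError(
                    f"{path}: line {lineno} has "
                    f"{len(line.rstrip(chr(10)).split(sep))} fields, "
                    f"expected {len(header)}"
                )


def read_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    """Load a genotype matrix from ``tsv`` or ``plink_raw`` text.

    Raises :class:`ParseError` on malformed rows (the pandas tokenizer error
    names the offending line) and :class:`ValidationError` for calls outside
    {0, 1, 2, NA}.
    """
    path = Path(path)
    try:
        if format == "tsv":
            _check_row_lengths(path, "\t")
            df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING_TOKEN],
                             keep_default_na=False)
        elif format == "plink_raw":
            _check_row_lengths(path, None)
            df = pd.read_csv(path, sep=r"\s+", dtype=str, na_values=[MISSING_TOKEN],
                             keep_default_na=False)
        else:
            raise ValueError(f"unknown genotype format {format!r}")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if format == "tsv":
        sample_ids = df.iloc[:, 0].tolist()
        snp_ids = list(df.columns[1:])
        body = df.iloc[:, 1:]
    else:
        missing_meta = [c for c in _PLINK_META_COLS if c not in df.columns]
        if missing_meta:
            raise ParseError(f"{path}: not PLINK .raw, missing columns {missing_meta}")
        sample_ids = df["IID"].tolist()
        snp_ids = list(df.columns[len(_PLINK_META_COLS):])
        body = df.iloc[:, len(_PLINK_META_COLS):]
    return GenotypeMatrix(sample_ids, snp_ids, _calls_from_frame(body, path))


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    """Write the ``tsv`` dialect; missing calls become ``NA``."""
    df = pd.DataFrame(geno.calls.astype(object), columns=geno.snp_ids)
    df = df.mask(df == MISSING, MISSING_TOKEN)
    df.insert(0, "sample_id", geno.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path, trait_col: str = "trait") -> PhenotypeTable:
    """Load sample id + trait + numeric covariates from tab-delimited text.

    Rows with a missing trait are dropped (the count is logged); all
    remaining columns are parsed as numeric covariates.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN])
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if trait_col not in df.columns:
        raise ValidationError(f"{path}: trait column {trait_col!r} not found")
    id_col = df.columns[0]
    n_before = len(df)
    df = df[df[trait_col].notna()]
    dropped = n_before - len(df)
    if dropped:
        logger.info("%s: dropped %d rows with missing trait", path, dropped)
    cov_names = [c for c in df.columns if c not in (id_col, trait_col)]
    try:
        covs = df[cov_names].astype(float).to_numpy()
        trait = df[trait_col].astype(float).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric value: {exc}") from exc
    return PhenotypeTable(df[id_col].astype(str).tolist(), trait, covs, cov_names)


def write_phenotypes(pheno: PhenotypeTable, path, trait_col: str = "trait") -> None:
    df = pd.DataFrame({"sample_id": pheno.sample_ids, trait_col: pheno.trait})
    for j, name in enumerate(pheno.covariate_names):
        df[name] = pheno.covariates[:, j]
    df.to_csv(path, sep="\t", index=False)


def align(geno: GenotypeMatrix, pheno: PhenotypeTable):
    """Restrict both inputs to their shared samples, in genotype order.

    Idempotent; raises :class:`ValidationError` when no sample is shared.
    """
    shared = set(geno.sample_ids) & set(pheno.sample_ids)
    if not shared:
        raise ValidationError("no shared sample ids between genotypes and phenotypes")
    order = [s for s in geno.sample_ids if s in shared]
    gidx = np.array([geno.sample_ids.index(s) for s in order])
    pmap = {s: i for i, s in enumerate(pheno.sample_ids)}
    pidx = np.array([pmap[s] for s in order])
    return geno.take_samples(gidx), pheno.take_samples(pidx)


def write_results(results, path) -> None:
    """Write ranked search results as TSV: combo, CVC, mean train/test BA."""
    rows = [
        {
            "combo": ",".join(r.combo),
            "cvc": r.cvc,
            "mean_train_ba": r.mean_train_ba,
            "mean_test_ba": r.mean_test_ba,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    """Read a ranked-results TSV back; combo becomes a tuple of SNP ids."""
    df = pd.read_csv(path, sep="\t")
    df["combo"] = df["combo"].map(lambda s: tuple(s.split(",")))
    return df
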