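"""Exhaustive k-order MDR search engine.

For each candidate SNP combination the samples are cross-classified into
the 3^k genotype cells.  A cell is "high risk" when the sum of its
residual scores is positive (score mode) or when its case/control ratio
exceeds a threshold (binary mode).  Model fit is measured by balanced
accuracy, BA = (sensitivity + specificity) / 2, and combinations are
compared through 10-fold cross-validation: the cross-validation
consistency (CVC) counts the folds in which a combination has the best
training BA.

Conventions (deterministic throughout):

* zero or empty cell score sum -> LOW (the strict "positive sum" rule);
* per-sample outcome for quantitative scores is the score sign; samples
  with score exactly 0 (and trimmed samples) are excluded;
* a fold with an absent outcome class contributes 0.5 for the undefined
  sensitivity/specificity term;
* ties broken by (CVC desc, mean test BA desc, combo lexicographic).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import DegenerateInputError, GenotypeMatrix, ValidationError
from .scoring import ScoreVector

logger = logging.getLogger(__name__)

HIGH, LOW = 1, 0

#: default cap on 3^k cells (k <= 8)
MAX_CELLS = 3 ** 8
#: default cap on the number of candidate combinations
MAX_COMBOS = 200_000


@dataclass
class CellTable:
    """Score sums and counts over the 3^k genotype cells of one combination."""

    combo: tuple[str, ...]
    cell_score_sum: np.ndarray
    cell_count: np.ndarray
    cell_pos_count: np.ndarray
    cell_neg_count: np.ndarray
    cell_case_count: np.ndarray | None = None
    cell_control_count: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.combo)

    @property
    def n_cells(self) -> int:
        return len(self.cell_count)


@dataclass
class RiskModel:
    """High/low label for every cell of a combination."""

    combo: tuple[str, ...]
    cell_label: np.ndarray  # HIGH/LOW per cell


@dataclass
class ConfusionTable:
    """2x2 cross-classification of outcome sign/case-status vs cell label."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class SearchResult:
    """Cross-validated summary for one SNP combination."""

    combo: tuple[str, ...]
    cvc: int
    mean_train_ba: float
    mean_test_ba: float
    per_fold_best: np.ndarray

    def __post_init__(self) -> None:
        self.per_fold_best = np.asarray(self.per_fold_best, dtype=bool)


def encode_cells(geno: GenotypeMatrix, combo: tuple[str, ...],
                 max_cells: int = MAX_CELLS) -> tuple[np.ndarray, np.ndarray]:
    """Mixed-radix (base-3) cell index per sample, plus a validity mask.

    Samples missing a call at any SNP of the combination are invalid for
    this combination only.
    """
    k = len(combo)
    if 3 ** k > max_cells:
        raise ValidationError(
            f"3^{k} cells exceeds the cap of {max_cells}; use a lower "
            "interaction order or raise max_cells"
        )
    cols = np.stack([geno.column(s) for s in combo], axis=1)
    valid = (cols >= 0).all(axis=1)
    weights = 3 ** np.arange(k - 1, -1, -1)
    cell = (np.where(cols < 0, 0, cols) * weights).sum(axis=1)
    return cell.astype(np.int64), valid


def build_cell_table(geno: GenotypeMatrix, combo: tuple[str, ...],
                     scores: ScoreVector | None = None,
                     case: np.ndarray | None = None,
                     sample_mask: np.ndarray | None = None,
                     max_cells: int = MAX_CELLS) -> CellTable:
    """Aggregate scores (or case/control counts) into the 3^k cells.

    Trimmed-out samples (``scores.included`` False) and samples missing a
    genotype at the combination contribute neither to sums nor counts.
    ``sample_mask`` optionally restricts to a training subset.
    """
    if scores is None and case is None:
        raise ValidationError("provide scores or case status")
    cell, valid = encode_cells(geno, combo, max_cells)
    ncells = 3 ** len(combo)
    mask = valid.copy()
    if sample_mask is not None:
        mask &= np.asarray(sample_mask, dtype=bool)
    if scores is not None:
        mask &= scores.included
        m = np.flatnonzero(mask)
        c = cell[m]
        w = scores.scores[m]
        return CellTable(
            combo=tuple(combo),
            cell_score_sum=np.bincount(c, weights=w, minlength=ncells),
            cell_count=np.bincount(c, minlength=ncells),
            cell_pos_count=np.bincount(c[w > 0], minlength=ncells),
            cell_neg_count=np.bincount(c[w < 0], minlength=ncells),
        )
    case = np.asarray(case, dtype=bool)
    m = np.flatnonzero(mask)
    c = cell[m]
    is_case = case[m]
    case_cnt = np.bincount(c[is_case], minlength=ncells)
    ctrl_cnt = np.bincount(c[~is_case], minlength=ncells)
    return CellTable(
        combo=tuple(combo),
        cell_score_sum=np.zeros(ncells),
        cell_count=case_cnt + ctrl_cnt,
        cell_pos_count=case_cnt,
        cell_neg_count=ctrl_cnt,
        cell_case_count=case_cnt,
        cell_control_count=ctrl_cnt,
    )


def classify_cells(ct: CellTable) -> RiskModel:
    """Label each cell HIGH iff its score sum is strictly positive.

    A sum of exactly 0 — including every empty cell — falls in the
    "otherwise" branch and is LOW.
    """
    return RiskModel(ct.combo, np.where(ct.cell_score_sum > 0, HIGH, LOW))


def classify_cells_binary(ct: CellTable, ratio_threshold: float = 1.0) -> RiskModel:
    """Binary MDR rule: HIGH iff case/control ratio strictly exceeds the
    threshold; a cell with cases but no controls is HIGH, an empty cell LOW."""
    if ct.cell_case_count is None:
        raise ValidationError("cell table lacks case/control counts")
    case = ct.cell_case_count.astype(float)
    ctrl = ct.cell_control_count.astype(float)
    label = np.where(case > ratio_threshold * ctrl, HIGH, LOW)
    return RiskModel(ct.combo, label)


def confusion_table(rm: RiskModel, ct_eval: CellTable) -> ConfusionTable:
    """Cross-classify positive/negative outcomes against HIGH/LOW cells."""
    if rm.combo != ct_eval.combo:
        raise ValidationError("risk model and cell table refer to different combos")
    high = rm.cell_label == HIGH
    pos, neg = ct_eval.cell_pos_count, ct_eval.cell_neg_count
    return ConfusionTable(
        tp=int(pos[high].sum()),
        fn=int(pos[~high].sum()),
        fp=int(neg[high].sum()),
        tn=int(neg[~high].sum()),
    )


def balanced_accuracy(rm: RiskModel, ct_eval: CellTable) -> float:
    """BA = (sensitivity + specificity) / 2 over the evaluation cell table.

    An outcome class absent from the evaluation data contributes 0.5 for
    its undefined term; no classifiable samples at all is an error.
    """
    c = confusion_table(rm, ct_eval)
    if c.total == 0:
        raise DegenerateInputError("no classifiable samples (all scores zero or trimmed)")
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.5
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else 0.5
    return 0.5 * (sens + spec)


def make_folds(n_samples: int, folds: int, seed) -> np.ndarray:
    """Seeded unstratified fold assignment; fold sizes differ by at most 1."""
    if folds < 2:
        raise ValidationError("need at least 2 folds")
    if n_samples < folds:
        raise ValidationError("need at least as many samples as folds")
    perm = np.random.default_rng(seed).permutation(n_samples)
    fold_id = np.empty(n_samples, dtype=np.int64)
    fold_id[perm] = np.arange(n_samples) % folds
    return fold_id


def _ba_terms(pos_hi, pos_lo, neg_hi, neg_lo):
    """Vectorized BA over folds, with the 0.5 degenerate-term convention."""
    npos = pos_hi + pos_lo
    nneg = neg_hi + neg_lo
    sens = np.where(npos > 0, pos_hi / np.maximum(npos, 1), 0.5)
    spec = np.where(nneg > 0, neg_lo / np.maximum(nneg, 1), 0.5)
    return 0.5 * (sens + spec)


def cross_validate(geno: GenotypeMatrix, scores: ScoreVector | None,
                   combos: list[tuple[str, ...]], folds: int = 10, seed=0,
                   case: np.ndarray | None = None, ratio_threshold: float = 1.0,
                   max_cells: int = MAX_CELLS) -> list[SearchResult]:
    """Cross-validate every candidate combination on a shared fold split.

    Within each fold a combination is trained (cells classified on the
    other folds) and tested (BA on the held-out fold); ``per_fold_best``
    marks the combination with the best training BA in that fold, ties
    going to the lexicographically smallest combo.
    """
    if not combos:
        raise ValidationError("no candidate combinations")
    n = geno.n_samples
    fold_id = make_folds(n, folds, seed)
    n_combos = len(combos)
    train_ba = np.empty((n_combos, folds))
    test_ba = np.empty((n_combos, folds))
    binary = scores is None
    if binary:
        case = np.asarray(case, dtype=bool)
        base_mask = np.ones(n, dtype=bool)
        w = None
    else:
        base_mask = scores.included
        w = scores.scores
    for ci, combo in enumerate(combos):
        cell, valid = encode_cells(geno, combo, max_cells)
        ncells = 3 ** len(combo)
        mask = valid & base_mask
        m = np.flatnonzero(mask)
        enc = cell[m] + ncells * fold_id[m]
        minl = ncells * folds
        if binary:
            is_case = case[m]
            fold_pos = np.bincount(enc[is_case], minlength=minl).reshape(folds, ncells)
            fold_neg = np.bincount(enc[~is_case], minlength=minl).reshape(folds, ncells)
            tot_pos = fold_pos.sum(axis=0)
            tot_neg = fold_neg.sum(axis=0)
            tr_pos, tr_neg = tot_pos - fold_pos, tot_neg - fold_neg
            labels_hi = tr_pos > ratio_threshold * tr_neg
        else:
            wm = w[m]
            fold_sum = np.bincount(enc, weights=wm, minlength=minl).reshape(folds, ncells)
            fold_pos = np.bincount(enc[wm > 0], minlength=minl).reshape(folds, ncells)
            fold_neg = np.bincount(enc[wm < 0], minlength=minl).reshape(folds, ncells)
            tot_sum = fold_sum.sum(axis=0)
            tot_pos = fold_pos.sum(axis=0)
            tot_neg = fold_neg.sum(axis=0)
            tr_pos, tr_neg = tot_pos - fold_pos, tot_neg - fold_neg
            labels_hi = (tot_sum - fold_sum) > 0
        train_ba[ci] = _ba_terms(
            (tr_pos * labels_hi).sum(1), (tr_pos * ~labels_hi).sum(1),
            (tr_neg * labels_hi).sum(1), (tr_neg * ~labels_hi).sum(1),
        )
        test_ba[ci] = _ba_terms(
            (fold_pos * labels_hi).sum(1), (fold_pos * ~labels_hi).sum(1),
            (fold_neg * labels_hi).sum(1), (fold_neg * ~labels_hi).sum(1),
        )
        if (ci + 1) % 1000 == 0:
            logger.info("cross-validated %d/%d combinations", ci + 1, n_combos)
    # per-fold winner by training BA, ties to the lexicographically smallest combo
    lex = sorted(range(n_combos), key=lambda i: combos[i])
    per_fold_best = np.zeros((n_combos, folds), dtype=bool)
    for f in range(folds):
        winner = lex[int(np.argmax(train_ba[lex, f]))]
        per_fold_best[winner, f] = True
    return [
        SearchResult(
            combo=tuple(combos[ci]),
            cvc=int(per_fold_best[ci].sum()),
            mean_train_ba=float(train_ba[ci].mean()),
            mean_test_ba=float(test_ba[ci].mean()),
            per_fold_best=per_fold_best[ci],
        )
        for ci in range(n_combos)
    ]


def rank_results(results: list[SearchResult]) -> list[SearchResult]:
    """Order by (CVC desc, mean test BA desc, combo lexicographic)."""
    return sorted(results, key=lambda r: (-r.cvc, -r.mean_test_ba, r.combo))


def exhaustive_search(geno: GenotypeMatrix, scores: ScoreVector | None,
                      k: int = 2, folds: int = 10, seed=0,
                      case: np.ndarray | None = None,
                      ratio_threshold: float = 1.0,
                      max_combos: int = MAX_COMBOS,
                      max_cells: int = MAX_CELLS) -> list[SearchResult]:
    """Evaluate all C(p, k) combinations and return them ranked.

    Combinations are generated over lexicographically sorted SNP ids, so
    the result is invariant to the column order of the genotype matrix.
    """
    from math import comb

    p = geno.n_snps
    if comb(p, k) > max_combos:
        raise ValidationError(
            f"C({p},{k}) = {comb(p, k)} combinations exceeds the cap of "
            f"{max_combos}; screen SNPs first or raise max_combos"
        )
    combos = list(itertools.combinations(sorted(geno.snp_ids), k))
    return rank_results(
        cross_validate(geno, scores, combos, folds, seed, case=case,
                       ratio_threshold=ratio_threshold, max_cells=max_cells)
    )


def select_best(results: list[SearchResult]) -> SearchResult:
    """The top-ranked combination (largest CVC, then test BA, then lexical)."""
    if not results:
        raise ValidationError("empty result list")
    return rank_results(list(results))[0]
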