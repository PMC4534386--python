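"""Independent brute-force reference implementations used as test oracles.

The MDR reference below re-implements cell tables, high/low labelling,
balanced accuracy, cross-validation and ranking with plain loops and
dictionaries, independently of the vectorized engine.  Float cell sums are
accumulated per (fold, cell) in ascending sample order and training sums
formed as total minus fold — the same floating-point operation order the
engine uses — so agreement can be checked exactly rather than to a
tolerance.
"""

from __future__ import annotations

import numpy as np


def brute_force_folds(n: int, folds: int, seed) -> np.ndarray:
    perm = np.random.default_rng(seed).permutation(n)
    fid = np.empty(n, dtype=int)
    for j, s in enumerate(perm):
        fid[s] = j % folds
    return fid


def _ba(pos_hi, pos_lo, neg_hi, neg_lo) -> float:
    sens = pos_hi / (pos_hi + pos_lo) if (pos_hi + pos_lo) > 0 else 0.5
    spec = neg_lo / (neg_hi + neg_lo) if (neg_hi + neg_lo) > 0 else 0.5
    return 0.5 * (sens + spec)


def brute_force_cv(calls: np.ndarray, snp_ids: list[str], scores: np.ndarray,
                   included: np.ndarray, combos: list[tuple[str, ...]],
                   folds: int, seed) -> dict[tuple[str, ...], dict]:
    """Reference cross-validation over candidate combinations.

    Returns per combo: cvc, mean train/test BA, per-fold best flags.
    """
    n = calls.shape[0]
    fid = brute_force_folds(n, folds, seed)
    col = {s: j for j, s in enumerate(snp_ids)}
    per_combo = {}
    for combo in combos:
        k = len(combo)
        ncells = 3 ** k
        fold_sum = np.zeros((folds, ncells))
        fold_pos = np.zeros((folds, ncells), dtype=int)
        fold_neg = np.zeros((folds, ncells), dtype=int)
        for i in range(n):
            if not included[i]:
                continue
            g = [calls[i, col[s]] for s in combo]
            if any(v < 0 for v in g):
                continue
            cell = 0
            for v in g:
                cell = cell * 3 + int(v)
            f = fid[i]
            fold_sum[f, cell] += scores[i]
            if scores[i] > 0:
                fold_pos[f, cell] += 1
            elif scores[i] < 0:
                fold_neg[f, cell] += 1
        tot_sum = fold_sum.sum(axis=0)
        tot_pos = fold_pos.sum(axis=0)
        tot_neg = fold_neg.sum(axis=0)
        train_ba, test_ba = [], []
        for f in range(folds):
            high = (tot_sum - fold_sum[f]) > 0
            tr_pos = tot_pos - fold_pos[f]
            tr_neg = tot_neg - fold_neg[f]
            train_ba.append(_ba(tr_pos[high].sum(), tr_pos[~high].sum(),
                                tr_neg[high].sum(), tr_neg[~high].sum()))
            test_ba.append(_ba(fold_pos[f][high].sum(), fold_pos[f][~high].sum(),
                               fold_neg[f][high].sum(), fold_neg[f][~high].sum()))
        per_combo[tuple(combo)] = {
            "train_ba": np.array(train_ba),
            "test_ba": np.array(test_ba),
        }
    # per-fold winner: max training BA, ties to the lexicographically first combo
    lex = sorted(per_combo)
    for combo in per_combo:
        per_combo[combo]["best"] = np.zeros(folds, dtype=bool)
    for f in range(folds):
        winner, best = None, -np.inf
        for combo in lex:
            v = per_combo[combo]["train_ba"][f]
            if v > best:
                winner, best = combo, v
        per_combo[winner]["best"][f] = True
    for combo, d in per_combo.items():
        d["cvc"] = int(d["best"].sum())
        d["mean_train_ba"] = float(np.mean(d["train_ba"]))
        d["mean_test_ba"] = float(np.mean(d["test_ba"]))
    return per_combo


def brute_force_rank(per_combo: dict) -> list[tuple[str, ...]]:
    return sorted(per_combo,
                  key=lambda c: (-per_combo[c]["cvc"],
                                 -per_combo[c]["mean_test_ba"], c))


def hat_matrix(X: np.ndarray) -> np.ndarray:
    """Explicit hat matrix H = X (X'X)^-1 X'."""
    return X @ np.linalg.inv(X.T @ X) @ X.T
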