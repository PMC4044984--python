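"""Independent brute-force oracles used to check the library.

Each oracle re-derives its quantity by a route deliberately different
from the library implementation: AUC by exhaustive pair counting, the
hinge rank loss by a literal penalty trace over explicit partition lists,
the split threshold by enumerating every candidate, and node selection by
enumerating every singleton and every pair containing the best singleton
with a normal-equations fit.
"""
from __future__ import annotations

import numpy as np


def pair_count_auc(scores, labels) -> float:
    """AUC as concordant (pos, neg) pairs / all pairs, ties worth 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == -1]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def hrl_trace(scores, labels, theta) -> tuple[int, int, int]:
    """Literal hinge-rank-loss trace; returns (total, neg_pen, pos_pen)."""
    order = sorted(range(len(scores)), key=lambda i: scores[i])
    d_neg = [labels[i] for i in order if scores[i] <= theta]
    d_pos = [labels[i] for i in order if scores[i] > theta]
    neg_pen = 0
    for i, lab in enumerate(d_neg, start=1):
        if lab == 1:
            neg_pen += len(d_neg) - i + 1
    pos_pen = 0
    for i, lab in enumerate(d_pos, start=1):
        if lab == -1:
            pos_pen += i
    return neg_pen + pos_pen, neg_pen, pos_pen


def best_threshold_bruteforce(labels, derived) -> tuple[float, int]:
    """(theta, hrl) minimizing HRL over every candidate; smallest theta on ties."""
    best = None
    for theta in sorted(set(float(v) for v in derived)):
        total, _, _ = hrl_trace(derived, labels, theta)
        if best is None or total < best[1]:
            best = (theta, total)
    return best


def _normal_eq_fit(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LSE through the normal equations (pinv for the singular case)."""
    return np.linalg.pinv(D.T @ D) @ D.T @ y


def exhaustive_select(matrix, labels, excluded=frozenset()):
    """Best singleton, then best pair containing it, by full enumeration.

    Returns (feature_indices, auc): the pair only when it strictly beats
    the singleton; ties to the lowest index at both stages.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=float)
    candidates = [j for j in range(X.shape[1]) if j not in excluded]
    singles = {j: pair_count_auc(X[:, j], y) for j in candidates}
    alpha = max(candidates, key=lambda j: (singles[j], -j))
    best_pair, best_pair_auc = None, -np.inf
    for i in candidates:
        if i == alpha:
            continue
        D = X[:, [alpha, i]]
        b = _normal_eq_fit(D, y)
        a = pair_count_auc(D @ b, y)
        if a > best_pair_auc:
            best_pair, best_pair_auc = (alpha, i), a
    if best_pair is not None and best_pair_auc > singles[alpha]:
        return best_pair, best_pair_auc
    return (alpha,), singles[alpha]
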