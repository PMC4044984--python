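"""ROC curves and trapezoidal AUC for real-valued scores against {-1,+1} labels.

The AUC is the node-quality criterion of the whole tree: a feature (or a
least-squares combination of two features) is treated as a one-dimensional
classifier whose operating point sweeps over its observed values, and the
area under the resulting sensitivity vs. (1 - specificity) curve measures
its discriminative power.

Conventions
-----------
* +1 is the positive class; a sample is predicted positive when its score
  strictly exceeds the threshold.
* The curve is traced at every distinct score value plus a ``-inf`` sentinel,
  so it always starts at (0, 0) and ends at (1, 1).
* Tied scores are grouped into a single curve step; the trapezoid over that
  diagonal step credits exactly 1/2 per tied positive-negative pair, which
  makes the trapezoidal area identical to the normalized Mann-Whitney U
  statistic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .dataset import validate_labels
from .exceptions import DegenerateLabelsError, InputError

__all__ = ["RocCurve", "roc_curve", "auc"]


@dataclass(frozen=True)
class RocCurve:
    """Operating points of a score vector used as a 1-D classifier.

    ``fpr`` and ``tpr`` are non-decreasing, start at (0, 0) and end at
    (1, 1); ``thresholds[i]`` is the score cut-off producing point ``i``
    (the final sentinel is ``-inf``, where everything is predicted
    positive). ``auc`` is the trapezoidal area under the curve.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1:
        raise InputError(f"scores must be 1-D, got shape {s.shape}")
    y = validate_labels(labels)
    if len(s) != len(y):
        raise InputError(f"{len(s)} scores but {len(y)} labels")
    if len(s) < 2:
        raise InputError("need at least 2 samples for a ROC curve")
    if not np.all(np.isfinite(s)):
        raise InputError("scores contain non-finite values")
    if y.min() == y.max():
        raise DegenerateLabelsError("both classes are required to compute an AUC")
    return s, y


def roc_curve(scores, labels) -> RocCurve:
    """Sweep the decision threshold over the distinct score values.

    Parameters
    ----------
    scores
        Real-valued classifier outputs, one per sample.
    labels
        Class labels over {-1, +1}; +1 is positive.

    Returns
    -------
    RocCurve
        Full set of operating points with the trapezoidal AUC.
    """
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(np.sum(y == 1))
    n_neg = len(y) - n_pos

    order = np.argsort(-s, kind="stable")  # descending scores
    s_sorted = s[order]
    pos_sorted = (y[order] == 1).astype(np.int64)

    # last index of each distinct-score group (ties collapse to one point)
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tp = np.cumsum(pos_sorted)[distinct]
    fp = (distinct + 1) - tp

    # threshold == highest score predicts nothing positive -> (0, 0);
    # the -inf sentinel predicts everything positive -> (1, 1)
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[s_sorted[0], s_sorted[distinct[:-1] + 1], -np.inf]

    area = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=area)


def auc(scores, labels) -> float:
    """Area under the ROC curve of ``scores`` vs. ``labels``.

    Equals the fraction of (positive, negative) sample pairs ranked
    concordantly, counting ties as 1/2. 1 means every positive outranks
    every negative (perfect classification); 0.5 means no discrimination.

    The value is the trapezoidal integral of the curve, but it is
    evaluated through the equivalent rank-sum identity
    ``(R+ - n+(n+ + 1)/2) / (n+ n-)``: mid-ranks are exact multiples of
    1/2, so the result is a single exact division. This keeps AUC
    comparisons (argmax tie-breaking during feature selection)
    deterministic, where the accumulated trapezoid can drift by an ulp.
    """
    s, y = _check_scores_labels(scores, labels)
    ranks = rankdata(s, method="average")
    n_pos = int(np.sum(y == 1))
    n_neg = len(y) - n_pos
    rank_sum = float(np.sum(ranks[y == 1]))
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
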