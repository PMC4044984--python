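"""Recursive induction of the bivariate ROC tree, prediction, serialization.

Each internal node thresholds a least-squares combination of at most two
genes (chosen by AUC, cut by hinge rank loss); samples with derived value
> theta go to the ``left`` (predicted-positive) child, the rest to the
``right`` child — exactly the partition the loss optimized. Growth stops
when a node is pure, when its combination already reaches the stopping AUC
(0.95 by default, to curb overfitting on tiny subsets), or when one of the
safety stops fires (minimum samples, maximum depth, feature exhaustion, or
a degenerate split). Genes used at a node are excluded along the whole
subtree below it, so no root-to-leaf path reuses a gene.

Leaves carry their training class counts; ``predict`` returns the majority
label, ``predict_score`` the leaf's fraction of positive training samples
(usable as a score for ROC analysis of the whole tree).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .dataset import Dataset
from .exceptions import (
    DegenerateSplitError,
    FeatureExhaustionError,
    InputError,
    TreeSchemaError,
)
from .selection import NodeModel, select_genes
from .threshold import calculate_split_threshold

__all__ = ["TreeConfig", "Leaf", "Internal", "Tree", "fit"]

SCHEMA_FORMAT = "bvroctree"
SCHEMA_VERSION = 1
_FLOAT_FMT = ".17g"  # round-trip exact for doubles


@dataclass(frozen=True)
class TreeConfig:
    """Induction parameters.

    stop_auc
        Node AUC at or above which the tree stops growing beneath the node
        (the node is still split once; its children become leaves).
    limit
        Maximum genes combined per node (2 = bivariate).
    max_depth, min_samples_split
        Safety stops for noisy data where AUC/purity alone would not
        terminate quickly.
    stop_mode
        ``"split"``: a node reaching ``stop_auc`` performs its split and
        its children become leaves. ``"leaf"``: the node itself becomes a
        majority leaf without splitting.
    orient_features
        Let the singleton scan flip inverted markers (see selection).
    """

    stop_auc: float = 0.95
    limit: int = 2
    max_depth: int = 25
    min_samples_split: int = 3
    stop_mode: str = "split"
    orient_features: bool = False

    def __post_init__(self) -> None:
        if self.stop_mode not in ("split", "leaf"):
            raise ValueError(f"stop_mode must be 'split' or 'leaf', got {self.stop_mode!r}")


@dataclass
class Leaf:
    label: int  # -1 or +1
    class_counts: tuple[int, int]  # (n_negative, n_positive) training samples
    score: float  # fraction of +1 training samples reaching the leaf


@dataclass
class Internal:
    model: NodeModel
    left: "TreeNode"  # derived > theta (predicted-positive side)
    right: "TreeNode"  # derived <= theta


TreeNode = Union[Leaf, Internal]


def _majority(labels: np.ndarray, fallback: int) -> int:
    n_pos = int(np.sum(labels == 1))
    n_neg = len(labels) - n_pos
    if n_pos > n_neg:
        return 1
    if n_neg > n_pos:
        return -1
    return fallback


def _leaf(labels: np.ndarray, fallback: int) -> Leaf:
    n_pos = int(np.sum(labels == 1))
    n_neg = len(labels) - n_pos
    label = _majority(labels, fallback)
    score = n_pos / len(labels) if len(labels) else (1.0 if label == 1 else 0.0)
    return Leaf(label=label, class_counts=(n_neg, n_pos), score=score)


@dataclass
class Tree:
    """A fitted bivariate ROC tree."""

    root: TreeNode
    config: TreeConfig
    feature_names: list[str]

    # ------------------------------------------------------------------ fit
    @property
    def size(self) -> int:
        """Number of internal (decision) nodes."""
        return tree_size(self)

    # -------------------------------------------------------------- predict
    def _check_matrix(self, X) -> np.ndarray:
        A = np.asarray(X, dtype=float)
        if A.ndim == 1:
            A = A[None, :]
        if A.ndim != 2 or A.shape[1] != len(self.feature_names):
            raise InputError(
                f"expected {len(self.feature_names)} feature values per sample, "
                f"got shape {A.shape}"
            )
        return A

    def _apply(self, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Route all rows of ``A`` to leaves; returns (labels, scores).

        Derived values are recomputed with the same vectorized matrix
        product used during induction, so resubstitution routes training
        samples exactly as the fitted partition did (a per-row dot product
        can differ by 1 ulp at the threshold boundary).
        """
        labels = np.empty(len(A), dtype=np.int8)
        scores = np.empty(len(A), dtype=float)

        def walk(node: TreeNode, rows: np.ndarray) -> None:
            if len(rows) == 0:
                return
            if isinstance(node, Leaf):
                labels[rows] = node.label
                scores[rows] = node.score
                return
            cols = list(node.model.feature_indices)
            vals = A[rows][:, cols]
            if not np.all(np.isfinite(vals)):
                r = rows[np.argwhere(~np.isfinite(vals))[0][0]]
                bad = [self.feature_names[j] for j in cols if not np.isfinite(A[r, j])]
                raise InputError(
                    f"missing/non-finite value for feature(s) {bad} in row {r}"
                )
            derived = vals @ node.model.coefficients
            go_left = derived > node.model.threshold
            walk(node.left, rows[go_left])
            walk(node.right, rows[~go_left])

        walk(self.root, np.arange(len(A)))
        return labels, scores

    def predict(self, X) -> np.ndarray:
        """Majority-label prediction (-1/+1) for each row of ``X``."""
        A = self._check_matrix(X)
        return self._apply(A)[0]

    def predict_score(self, X) -> np.ndarray:
        """Leaf positive-class proportion in [0, 1] for each row of ``X``."""
        A = self._check_matrix(X)
        return self._apply(A)[1]

    # ---------------------------------------------------------- (de)serialize
    def to_dict(self) -> dict:
        def encode(node: TreeNode) -> dict:
            if isinstance(node, Leaf):
                return {
                    "kind": "leaf",
                    "label": int(node.label),
                    "class_counts": [int(c) for c in node.class_counts],
                    "score": format(node.score, _FLOAT_FMT),
                }
            m = node.model
            return {
                "kind": "internal",
                "features": [self.feature_names[j] for j in m.feature_indices],
                "feature_indices": [int(j) for j in m.feature_indices],
                "coefficients": [format(float(c), _FLOAT_FMT) for c in m.coefficients],
                "threshold": format(float(m.threshold), _FLOAT_FMT),
                "auc": format(float(m.auc), _FLOAT_FMT),
                "left": encode(node.left),
                "right": encode(node.right),
            }

        return {
            "format": SCHEMA_FORMAT,
            "version": SCHEMA_VERSION,
            "feature_names": list(self.feature_names),
            "config": {
                "stop_auc": self.config.stop_auc,
                "limit": self.config.limit,
                "max_depth": self.config.max_depth,
                "min_samples_split": self.config.min_samples_split,
                "stop_mode": self.config.stop_mode,
                "orient_features": self.config.orient_features,
            },
            "root": encode(self.root),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Tree":
        if not isinstance(payload, dict) or payload.get("format") != SCHEMA_FORMAT:
            raise TreeSchemaError("not a bvroctree tree document")
        if payload.get("version") != SCHEMA_VERSION:
            raise TreeSchemaError(
                f"unsupported schema version {payload.get('version')!r}; "
                f"expected {SCHEMA_VERSION}"
            )
        try:
            feature_names = list(payload["feature_names"])

            def decode(node: dict) -> TreeNode:
                if node["kind"] == "leaf":
                    return Leaf(
                        label=int(node["label"]),
                        class_counts=tuple(int(c) for c in node["class_counts"]),
                        score=float(node["score"]),
                    )
                if node["kind"] != "internal":
                    raise TreeSchemaError(f"unknown node kind {node['kind']!r}")
                idx = tuple(int(j) for j in node["feature_indices"])
                model = NodeModel(
                    feature_indices=idx,
                    coefficients=np.array([float(c) for c in node["coefficients"]]),
                    derived=np.empty(0),
                    auc=float(node["auc"]),
                    threshold=float(node["threshold"]),
                )
                return Internal(
                    model=model, left=decode(node["left"]), right=decode(node["right"])
                )

            root = decode(payload["root"])
            cfg = TreeConfig(**payload.get("config", {}))
        except (KeyError, TypeError, ValueError) as exc:
            raise TreeSchemaError(f"malformed tree document: {exc}") from exc
        return cls(root=root, config=cfg, feature_names=feature_names)

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "Tree":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise TreeSchemaError(f"invalid JSON: {exc}") from exc
        return cls.from_dict(payload)

    def render_text(self) -> str:
        """Human-readable indented rendering of the decision rules."""
        lines: list[str] = []

        def walk(node: TreeNode, depth: int, prefix: str) -> None:
            pad = "  " * depth
            if isinstance(node, Leaf):
                n_neg, n_pos = node.class_counts
                lines.append(
                    f"{pad}{prefix}leaf label={node.label:+d} "
                    f"(neg={n_neg}, pos={n_pos}, score={node.score:.3f})"
                )
                return
            m = node.model
            rule = " + ".join(
                f"{c:.4g}*{self.feature_names[j]}"
                for c, j in zip(m.coefficients, m.feature_indices)
            )
            lines.append(
                f"{pad}{prefix}node [{rule}] > {m.threshold:.6g} (auc={m.auc:.3f})"
            )
            walk(node.left, depth + 1, "yes: ")
            walk(node.right, depth + 1, "no:  ")

        walk(self.root, 0, "")
        return "\n".join(lines)


def tree_size(tree: Tree) -> int:
    """Number of internal decision nodes (0 for a lone leaf)."""

    def count(node: TreeNode) -> int:
        if isinstance(node, Leaf):
            return 0
        return 1 + count(node.left) + count(node.right)

    return count(tree.root)


def fit(data: Dataset, config: TreeConfig | None = None) -> Tree:
    """Grow a bivariate ROC tree on ``data``.

    Parameters
    ----------
    data
        Training samples; labels over {-1, +1}, at least one sample.
    config
        Induction parameters; defaults to :class:`TreeConfig`.
    """
    cfg = config or TreeConfig()
    if data.n_genes == 0:
        raise InputError("dataset has no features")
    if data.n_samples == 0:
        raise InputError("dataset has no samples")

    def grow(sub: Dataset, excluded: frozenset[int], depth: int, fallback: int) -> TreeNode:
        y = sub.labels
        if len(y) == 0:
            # empty partition: inherit the parent's majority label
            return Leaf(
                label=fallback,
                class_counts=(0, 0),
                score=1.0 if fallback == 1 else 0.0,
            )
        if y.min() == y.max():
            return _leaf(y, fallback)
        if len(y) < cfg.min_samples_split or depth >= cfg.max_depth:
            return _leaf(y, fallback)
        try:
            model = select_genes(
                sub, excluded=excluded, limit=cfg.limit, orient=cfg.orient_features
            )
        except FeatureExhaustionError:
            return _leaf(y, fallback)
        if cfg.stop_mode == "leaf" and model.auc >= cfg.stop_auc:
            return _leaf(y, fallback)
        try:
            split = calculate_split_threshold(y, model.derived)
        except DegenerateSplitError:
            return _leaf(y, fallback)
        model.threshold = split.theta
        go_left = model.derived > split.theta
        if not go_left.any() or go_left.all():
            return _leaf(y, fallback)
        here_majority = _majority(y, fallback)
        left_rows = np.nonzero(go_left)[0]
        right_rows = np.nonzero(~go_left)[0]
        if model.auc >= cfg.stop_auc:
            # discriminative enough: split once more, children become leaves
            left: TreeNode = _leaf(y[left_rows], here_majority)
            right: TreeNode = _leaf(y[right_rows], here_majority)
        else:
            child_excluded = excluded | set(model.feature_indices)
            left = grow(sub.subset(left_rows), frozenset(child_excluded), depth + 1, here_majority)
            right = grow(sub.subset(right_rows), frozenset(child_excluded), depth + 1, here_majority)
        return Internal(model=model, left=left, right=right)

    root = grow(data, frozenset(), 0, fallback=-1)
    return Tree(root=root, config=cfg, feature_names=list(data.feature_names))
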