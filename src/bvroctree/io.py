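"""Delimited-text dataset I/O and tree (de)serialization on disk.

Expression matrices are read from CSV/TSV with a header row and an index
column. Both layouts common in transcriptomics are supported: samples in
rows (one label column) or genes in rows (one label row, the usual
microarray export). Labels are mapped onto {-1, +1} by naming the positive
token; any other single token becomes -1, and more than two distinct
tokens is an error (the tree is strictly binary).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import Dataset
from .exceptions import InputError, TreeSchemaError
from .tree import Tree

__all__ = ["read_dataset", "write_dataset", "read_tree", "write_tree"]


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_dataset(
    path: str | Path,
    label: str = "class",
    positive: str = "1",
    delimiter: str | None = None,
    genes_in_rows: bool = False,
) -> Dataset:
    """Read a labeled expression matrix from delimited text.

    Parameters
    ----------
    path
        CSV/TSV file with a header and an index column (sample or gene
        identifiers).
    label
        Name of the label column (samples-in-rows) or label row
        (genes-in-rows).
    positive
        Label token mapped to +1; the (single) remaining token maps to -1.
        Tokens are compared as stripped strings.
    delimiter
        Field separator; inferred from the extension when omitted
        (``.tsv``/``.tab``/``.txt`` -> tab, else comma).
    genes_in_rows
        Set when rows are genes and columns are samples; the matrix is
        transposed on read.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    try:
        frame = pd.read_csv(p, sep=_sep_for(p, delimiter), index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"could not parse {p}: {exc}") from exc
    if genes_in_rows:
        frame = frame.T
    if label not in frame.columns:
        raise InputError(
            f"label {'row' if genes_in_rows else 'column'} {label!r} not found "
            f"(have: {list(frame.columns)[:8]}...)"
        )
    raw = frame[label]
    expr = frame.drop(columns=[label])

    tokens = raw.astype(str).str.strip()
    distinct = sorted(tokens.unique())
    if len(distinct) > 2:
        raise InputError(
            f"more than two classes are not supported; found labels {distinct}"
        )
    pos_token = str(positive).strip()
    if pos_token not in distinct:
        raise InputError(
            f"positive class token {pos_token!r} not among labels {distinct}"
        )
    labels = np.where(tokens.to_numpy() == pos_token, 1, -1).astype(np.int8)

    if expr.columns.duplicated().any():
        dups = expr.columns[expr.columns.duplicated()].tolist()
        raise InputError(f"duplicate feature names: {dups[:5]}")
    matrix = expr.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(matrix)):
        r, c = np.argwhere(~np.isfinite(matrix))[0]
        raise InputError(
            f"missing or non-numeric expression value for sample "
            f"{expr.index[r]!r}, gene {expr.columns[c]!r}"
        )
    return Dataset(
        matrix=matrix,
        labels=labels,
        feature_names=[str(c) for c in expr.columns],
        sample_ids=[str(i) for i in expr.index],
    )


def write_dataset(data: Dataset, path: str | Path, label: str = "class") -> None:
    """Write a dataset as samples-in-rows CSV/TSV with a label column.

    Labels are written as ``1``/``-1`` tokens, so the file reads back with
    the default ``positive='1'``.
    """
    p = Path(path)
    frame = pd.DataFrame(data.matrix, index=data.sample_ids, columns=data.feature_names)
    frame.insert(0, label, data.labels.astype(int))
    frame.index.name = "sample"
    frame.to_csv(p, sep=_sep_for(p, None), float_format="%.17g")


def write_tree(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(tree.to_json() + "\n")


def read_tree(path: str | Path) -> Tree:
    p = Path(path)
    if not p.exists():
        raise TreeSchemaError(f"no such file: {p}")
    return Tree.from_json(p.read_text())


def write_truth(truth, path: str | Path) -> None:
    """Ground-truth sidecar for simulated data (JSON)."""
    payload = {
        "pairs": [
            {
                "genes": list(p.genes),
                "weights": list(p.weights),
                "margin": p.margin,
                "anchor_fraction": p.anchor_fraction,
                "latent_sd": p.latent_sd,
            }
            for p in truth.pairs
        ],
        "singles": [{"gene": s.gene, "effect": s.effect} for s in truth.singles],
        "n_noise_genes": len(truth.noise_genes),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
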