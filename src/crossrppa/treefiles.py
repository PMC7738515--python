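"""Clustered-data-table (CDT) and tree (GTR/ATR) file writer and reader.

The dialect is the tab-separated format consumed by Java TreeView: the
CDT holds the clustered (reordered) matrix with GID/AID identifier rows
and columns, the GTR lists row-tree merges and the ATR column-tree
merges, one ``NODEkX  childA  childB  score`` line per merge in creation
order.  Leaves are named ``GENE{i}X`` (rows) / ``ARRY{i}X`` (columns)
after their position in the original, unclustered matrix.

Node scores are stored as 1 - merge height for every metric (the
similarity convention of correlation-based trees, applied uniformly so
the files are self-describing without a metric tag); the bundled reader
inverts this.  Floats are written with ``repr`` so matrix values
round-trip exactly and heights to within one unit in the last place.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import Dendrogram
from .exceptions import SchemaError

__all__ = [
    "write_cluster_files",
    "read_tree_file",
    "read_cdt",
    "read_cluster_files",
]


def _fmt(x: float) -> str:
    return repr(float(x))


def _tree_lines(dend: Dendrogram, leaf_prefix: str) -> list[str]:
    lines = []
    n = dend.n_leaves
    for node, left, right, height in dend.merges:
        def name(i: int) -> str:
            return f"{leaf_prefix}{i}X" if i < n else f"NODE{i - n + 1}X"
        lines.append(
            f"NODE{node - n + 1}X\t{name(left)}\t{name(right)}\t{_fmt(1.0 - height)}"
        )
    return lines


def write_cluster_files(
    matrix: pd.DataFrame,
    row_dend: Dendrogram,
    col_dend: Dendrogram,
    base: str | Path,
) -> dict[str, Path]:
    """Write ``base.cdt``, ``base.gtr`` and ``base.atr``.

    ``matrix`` must be the *original-order* matrix whose row labels equal
    ``row_dend.labels`` and column labels equal ``col_dend.labels``; it is
    reordered by the two leaf orders on writing.
    """
    base = Path(base)
    if list(map(str, matrix.index)) != list(row_dend.labels):
        raise SchemaError("matrix rows do not match row dendrogram labels")
    if list(map(str, matrix.columns)) != list(col_dend.labels):
        raise SchemaError("matrix columns do not match column dendrogram labels")

    row_order = [row_dend.labels.index(l) for l in row_dend.leaf_order]
    col_order = [col_dend.labels.index(l) for l in col_dend.leaf_order]
    M = matrix.to_numpy(dtype=float)[np.ix_(row_order, col_order)]

    paths = {
        "cdt": base.with_suffix(".cdt"),
        "gtr": base.with_suffix(".gtr"),
        "atr": base.with_suffix(".atr"),
    }
    paths["gtr"].write_text("\n".join(_tree_lines(row_dend, "GENE")) + "\n")
    paths["atr"].write_text("\n".join(_tree_lines(col_dend, "ARRY")) + "\n")

    header = ["GID", "UNIQID", "NAME"] + [col_dend.labels[j] for j in col_order]
    aid = ["AID", "", ""] + [f"ARRY{j}X" for j in col_order]
    body = []
    for pos, i in enumerate(row_order):
        label = row_dend.labels[i]
        body.append(
            "\t".join([f"GENE{i}X", label, label] + [_fmt(v) for v in M[pos]])
        )
    paths["cdt"].write_text(
        "\t".join(header) + "\n" + "\t".join(aid) + "\n" + "\n".join(body) + "\n"
    )
    return paths


def _parse_node(name: str, n_leaves: int, leaf_prefix: str) -> int:
    if name.startswith("NODE") and name.endswith("X"):
        return n_leaves + int(name[4:-1]) - 1
    if name.startswith(leaf_prefix) and name.endswith("X"):
        return int(name[len(leaf_prefix):-1])
    raise SchemaError(f"unparseable node name {name!r}")


def read_tree_file(path: str | Path, n_leaves: int, leaf_prefix: str
                   ) -> list[tuple[int, int, int, float]]:
    """Parse a GTR/ATR file into merge tuples (node, left, right, height)."""
    merges = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        node_s, left_s, right_s, score_s = line.split("\t")
        merges.append(
            (
                _parse_node(node_s, n_leaves, leaf_prefix),
                _parse_node(left_s, n_leaves, leaf_prefix),
                _parse_node(right_s, n_leaves, leaf_prefix),
                1.0 - float(score_s),
            )
        )
    return merges


def read_cdt(path: str | Path) -> tuple[pd.DataFrame, list[int], list[int]]:
    """Parse a CDT file.

    Returns (matrix in clustered order, row leaf indices in clustered
    order, column leaf indices in clustered order); indices refer to the
    original pre-clustering order encoded in the GENE/ARRY identifiers.
    """
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    aid = lines[1].split("\t")
    if header[0] != "GID" or aid[0] != "AID":
        raise SchemaError(f"{path}: not a CDT file (missing GID/AID rows)")
    col_labels = header[3:]
    col_idx = [int(a[4:-1]) for a in aid[3:]]
    rows, row_idx, row_labels = [], [], []
    for line in lines[2:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        row_idx.append(int(parts[0][4:-1]))
        row_labels.append(parts[1])
        rows.append([float(v) for v in parts[3:]])
    df = pd.DataFrame(rows, index=row_labels, columns=col_labels)
    return df, row_idx, col_idx


def read_cluster_files(base: str | Path) -> tuple[pd.DataFrame, Dendrogram, Dendrogram]:
    """Read back a CDT/GTR/ATR trio written by :func:`write_cluster_files`.

    Returns the clustered-order matrix and the two reconstructed
    dendrograms (original label order recovered from the identifier
    indices).
    """
    base = Path(base)
    df, row_idx, col_idx = read_cdt(base.with_suffix(".cdt"))
    n_rows, n_cols = len(row_idx), len(col_idx)

    row_labels = [None] * n_rows
    for pos, i in enumerate(row_idx):
        row_labels[i] = df.index[pos]
    col_labels = [None] * n_cols
    for pos, j in enumerate(col_idx):
        col_labels[j] = df.columns[pos]

    row_merges = read_tree_file(base.with_suffix(".gtr"), n_rows, "GENE")
    col_merges = read_tree_file(base.with_suffix(".atr"), n_cols, "ARRY")
    row_dend = Dendrogram(labels=list(row_labels), merges=row_merges)
    col_dend = Dendrogram(labels=list(col_labels), merges=col_merges)
    return df, row_dend, col_dend
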