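"""Jaccard-index quantification of motif crosstalk between networks.

Cancer pathway maps and signal transduction networks (STNs) share many
motif genes; the degree of coupling between a cancer network and an STN
is measured on their *motif node sets* -- the genes appearing in at
least one motif instance of each network -- with the Jaccard index

    JI(A, B) = |A n B| / (|A| + |B| - |A n B|).

The full crosstalk matrix tabulates JI for every (STN, cancer network)
pair; the argmax pair names the most strongly coupled combination.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .motifs import MotifInstance


@dataclass(frozen=True)
class MotifNodeSet:
    """The genes of one network that occur in >= 1 motif instance."""

    network_name: str
    genes: frozenset[str]


def motif_node_set(instances: Sequence[MotifInstance],
                   network_name: str = "") -> MotifNodeSet:
    """Union of all role positions of all instances (every motif type
    contributes)."""
    genes: set[str] = set()
    for inst in instances:
        genes |= set(inst.nodes)
    return MotifNodeSet(network_name=network_name, genes=frozenset(genes))


def jaccard(a: MotifNodeSet | frozenset | set,
            b: MotifNodeSet | frozenset | set) -> float:
    """|A n B| / (|A| + |B| - |A n B|); two empty sets give 0 (warned)."""
    sa = a.genes if isinstance(a, MotifNodeSet) else frozenset(a)
    sb = b.genes if isinstance(b, MotifNodeSet) else frozenset(b)
    inter = len(sa & sb)
    denom = len(sa) + len(sb) - inter
    if denom == 0:
        _warnings.warn("Jaccard of two empty sets returned as 0", stacklevel=2)
        return 0.0
    return inter / denom


@dataclass(frozen=True)
class CrosstalkResult:
    """|group2| x |group1| JI matrix, with row/column names and the
    best-coupled (row, column) pair."""

    row_names: tuple[str, ...]     # group 2 (e.g. STNs)
    col_names: tuple[str, ...]     # group 1 (e.g. cancer networks)
    matrix: np.ndarray
    argmax: tuple[str, str]
    max_value: float


def crosstalk_matrix(group1: Sequence[MotifNodeSet],
                     group2: Sequence[MotifNodeSet]) -> CrosstalkResult:
    """Pairwise JI of every group-2 set against every group-1 set.

    Rows are group 2, columns group 1 (STN rows x cancer-network
    columns in the canonical layout).  Ties in the argmax resolve to the
    first row-major occurrence."""
    if not group1 or not group2:
        raise ValueError("both groups must be non-empty")
    mat = np.zeros((len(group2), len(group1)))
    for i, b in enumerate(group2):
        for j, a in enumerate(group1):
            mat[i, j] = jaccard(a, b)
    i, j = np.unravel_index(int(np.argmax(mat)), mat.shape)
    return CrosstalkResult(
        row_names=tuple(s.network_name for s in group2),
        col_names=tuple(s.network_name for s in group1),
        matrix=mat,
        argmax=(group2[i].network_name, group1[j].network_name),
        max_value=float(mat[i, j]),
    )


def write_crosstalk(result: CrosstalkResult, path) -> None:
    """Matrix TSV: one STN per row, one cancer network per column."""
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t" + "\t".join(result.col_names) + "\n")
        for name, row in zip(result.row_names, result.matrix):
            fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
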