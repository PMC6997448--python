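"""Motif-motif similarity, hierarchical clustering and set distances.

The motif distance aligns two IUPAC words at every ungapped offset with at
least ``min_overlap`` aligned columns; each aligned column scores the
Jaccard similarity of its two allowed-base sets, the alignment scores the
summed column similarity divided by the longer motif's length, and the
distance is one minus the best alignment score.  Normalizing by the longer
length penalizes length mismatch, so a motif contained in a longer one is
*not* at distance zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .motif import Motif


@dataclass
class MotifDistanceMatrix:
    labels: list[str]  # e.g. "tissue:consensus"
    values: np.ndarray  # symmetric, zero diagonal, entries in [0,1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _alignment_score(a: Motif, b: Motif, offset: int, min_overlap: int) -> float | None:
    la, lb = len(a), len(b)
    ai0 = max(0, -offset)
    bi0 = max(0, offset)
    ov = min(la - ai0, lb - bi0)
    if ov < min_overlap:
        return None
    total = 0.0
    for j in range(ov):
        sa = a.position_sets[ai0 + j]
        sb = b.position_sets[bi0 + j]
        total += len(sa & sb) / len(sa | sb)
    return total / max(la, lb)


def motif_distance(a: Motif, b: Motif, min_overlap: int = 3, revcomp: bool = False) -> float:
    """Sequence-similarity distance between two IUPAC motifs, in [0, 1].

    Returns 1 when no ungapped offset achieves ``min_overlap`` aligned
    columns.  Symmetric; identical motifs are at distance 0.
    """
    la, lb = len(a), len(b)
    best = 0.0
    variants = [b]
    if revcomp:
        variants.append(b.reverse_complement())
    for bv in variants:
        for offset in range(-(la - min_overlap), lb - min_overlap + 1):
            s = _alignment_score(a, bv, offset, min_overlap)
            if s is not None and s > best:
                best = s
    return 1.0 - min(best, 1.0)


def motif_distance_matrix(
    motifs: list[Motif],
    labels: list[str] | None = None,
    min_overlap: int = 3,
    revcomp: bool = False,
) -> MotifDistanceMatrix:
    n = len(motifs)
    if labels is None:
        labels = [m.consensus for m in motifs]
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = motif_distance(
                motifs[i], motifs[j], min_overlap=min_overlap, revcomp=revcomp
            )
    return MotifDistanceMatrix(labels=list(labels), values=v)


def hierarchical_cluster(
    matrix: MotifDistanceMatrix,
    method: str = "average",
    cut_height: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of a distance matrix.

    Returns (cluster assignment per label, scipy linkage matrix).  Groups
    are the connected components of the tree below ``cut_height``.
    """
    n = len(matrix.labels)
    if n == 1:
        return np.array([1]), np.zeros((0, 4))
    condensed = squareform(matrix.values, checks=False)
    Z = linkage(condensed, method=method)
    assignment = fcluster(Z, t=cut_height, criterion="distance")
    return assignment, Z


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage tree as a Newick string with branch lengths."""
    if len(labels) == 1:
        return f"{labels[0]}:0.0;"
    tree = to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def jaccard_distance(a: set, b: set) -> float:
    """1 - |a ∩ b| / |a ∪ b|; two empty sets are at distance 0 by convention."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def jaccard_distance_matrix(sets: dict[str, set]) -> MotifDistanceMatrix:
    """Pairwise Jaccard distances among named CpG sets (e.g. per-tumor iDMCs)."""
    labels = list(sets)
    n = len(labels)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = jaccard_distance(sets[labels[i]], sets[labels[j]])
    return MotifDistanceMatrix(labels=labels, values=v)
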