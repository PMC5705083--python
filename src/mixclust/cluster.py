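"""Hierarchical clustering, tree cutting and two-class recovery metrics.

Agglomeration runs on a precomputed :class:`DistanceMatrix` via the
Lance-Williams recurrences (scipy).  "Ward" follows the ward.D2
convention: the input entries are treated as Euclidean distances and the
classic minimum-variance criterion is applied to their squares, which is
the textbook Ward criterion for distance-matrix input.

Cluster-vs-truth agreement for two known classes is summarized in a 2x2
:class:`ConfusionTable` with entries a_ij, from which

    MCR = (a_12 + a_21) / (a_11 + a_12 + a_21 + a_22)
    BER = 0.5 * (a_12 / (a_11 + a_12) + a_21 / (a_21 + a_22))

are computed.  Because cluster labels are arbitrary, both metrics are
minimized over the two possible cluster-to-class matchings.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from .mixedio import DistanceMatrix, MixedDataError

__all__ = [
    "LINKAGE_METHODS",
    "LinkageTree",
    "ConfusionTable",
    "hierarchical_cluster",
    "cut_clusters",
    "misclassification_rate",
    "balanced_error_rate",
    "export_newick",
]

LINKAGE_METHODS = ("ward", "complete", "average", "single")


@dataclasses.dataclass
class LinkageTree:
    """Hierarchical merge structure over labeled leaves.

    ``linkage`` is the (n-1) x 4 scipy linkage matrix (children, height,
    size); for a single leaf it is empty.
    """

    linkage: np.ndarray
    labels: list[str]
    method: str = ""

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = len(self.labels)
        expected = max(n - 1, 0)
        if self.linkage.shape[0] != expected:
            raise MixedDataError(
                f"{n} leaves require {expected} merges, got {self.linkage.shape[0]}"
            )

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merges(self) -> np.ndarray:
        return self.linkage[:, :2].astype(int)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[int]:
        """Leaf indices in dendrogram display order."""
        if self.n_leaves == 1:
            return [0]
        return list(sch.leaves_list(self.linkage))


def hierarchical_cluster(D: DistanceMatrix, linkage: str = "ward") -> LinkageTree:
    """Agglomerative clustering of a distance matrix."""
    if linkage not in LINKAGE_METHODS:
        raise MixedDataError(
            f"unknown linkage {linkage!r}; expected one of {LINKAGE_METHODS}"
        )
    if not np.all(np.isfinite(D.values)):
        raise MixedDataError("distance matrix has non-finite entries")
    if len(D.labels) == 1:
        return LinkageTree(np.empty((0, 4)), list(D.labels), method=linkage)
    condensed = squareform(D.values, checks=False)
    z = sch.linkage(condensed, method=linkage)
    return LinkageTree(z, list(D.labels), method=linkage)


def cut_clusters(t: LinkageTree, k: int) -> np.ndarray:
    """Cut the tree into exactly ``k`` clusters (ids 0..k-1 per leaf)."""
    n = t.n_leaves
    if not 1 <= k <= n:
        raise MixedDataError(f"k must be in [1, {n}], got {k}")
    if n == 1:
        return np.zeros(1, dtype=int)
    return sch.cut_tree(t.linkage, n_clusters=k).ravel().astype(int)


@dataclasses.dataclass(frozen=True)
class ConfusionTable:
    """2x2 cluster-vs-truth counts (rows: true class, cols: cluster)."""

    a11: int
    a12: int
    a21: int
    a22: int

    def __post_init__(self) -> None:
        if min(self.a11, self.a12, self.a21, self.a22) < 0:
            raise MixedDataError("confusion counts must be nonnegative")

    @classmethod
    def from_labels(cls, truth, clusters) -> "ConfusionTable":
        truth = np.asarray(truth)
        clusters = np.asarray(clusters)
        if truth.shape != clusters.shape:
            raise MixedDataError("truth and cluster labels differ in length")
        t_classes = sorted(set(truth.tolist()))
        c_classes = sorted(set(clusters.tolist()))
        if len(t_classes) != 2:
            raise MixedDataError("truth must have exactly two classes")
        if len(c_classes) > 2:
            raise MixedDataError("more than two clusters in assignment")
        if len(c_classes) == 1:  # everything in one cluster
            c_classes = c_classes + [None]
        counts = np.zeros((2, 2), dtype=int)
        for i, tc in enumerate(t_classes):
            for j, cc in enumerate(c_classes):
                counts[i, j] = int(np.sum((truth == tc) & (clusters == cc)))
        return cls(*counts.ravel().tolist())

    @property
    def total(self) -> int:
        return self.a11 + self.a12 + self.a21 + self.a22

    def swapped(self) -> "ConfusionTable":
        """Same table with the two cluster labels interchanged."""
        return ConfusionTable(self.a12, self.a11, self.a22, self.a21)


def _mcr_raw(c: ConfusionTable) -> float:
    return (c.a12 + c.a21) / c.total


def misclassification_rate(c: ConfusionTable) -> float:
    """MCR minimized over the two cluster-to-class matchings."""
    if c.total == 0:
        raise MixedDataError("empty confusion table")
    return min(_mcr_raw(c), _mcr_raw(c.swapped()))


def _ber_raw(c: ConfusionTable) -> float:
    return 0.5 * (c.a12 / (c.a11 + c.a12) + c.a21 / (c.a21 + c.a22))


def balanced_error_rate(c: ConfusionTable) -> float:
    """BER minimized over the two cluster-to-class matchings."""
    if c.a11 + c.a12 == 0 or c.a21 + c.a22 == 0:
        raise MixedDataError("a truth class is empty")
    return min(_ber_raw(c), _ber_raw(c.swapped()))


def _sanitize(label: str) -> str:
    out = label
    for ch in "(),:;[] \t'\"":
        out = out.replace(ch, "_")
    return out


def export_newick(t: LinkageTree) -> str:
    """Newick text of the dendrogram.

    Leaves sit at elevation 0 and each internal node at half its merge
    height (the ultrametric dendrogram convention), so two leaves merged
    at height h are rendered ``(A:h/2,B:h/2);``.
    """
    if t.n_leaves == 1:
        return f"{_sanitize(t.labels[0])};"
    root = sch.to_tree(t.linkage)

    def rec(node) -> tuple[str, float]:
        if node.is_leaf():
            return _sanitize(t.labels[node.id]), 0.0
        left, lh = rec(node.left)
        right, rh = rec(node.right)
        h = node.dist / 2.0
        return f"({left}:{h - lh:.10g},{right}:{h - rh:.10g})", h

    text, _ = rec(root)
    return text + ";"
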