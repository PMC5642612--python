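"""Unsupervised hierarchical clustering of samples (or genes) on a signature.

Thin, reproducibility-minded wrapper around scipy's agglomerative
clustering: the linkage tree, the metric/linkage names and the leaf
order are kept together so a heatmap layout can be reassembled exactly.
Defaults (Euclidean metric, average linkage, samples clustered on
row-z-scored log2 data) are the common heatmap conventions; every
choice is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from .preprocess import ExpressionMatrix


class ClusterError(ValueError):
    pass


@dataclass
class LinkageResult:
    """A linkage tree over named items, with full provenance.

    ``merges`` is the scipy linkage matrix: row i joins nodes a and b
    (leaves are 0..n-1, internal nodes n+i) at the given height into a
    cluster of the given size.
    """

    merges: np.ndarray
    items: tuple[str, ...]
    metric: str
    linkage: str
    axis: str

    def __post_init__(self) -> None:
        if self.merges.shape != (len(self.items) - 1, 4):
            raise ClusterError("linkage matrix must have n-1 rows of 4")

    @property
    def leaf_order(self) -> list[str]:
        return [self.items[i] for i in hierarchy.leaves_list(self.merges)]

    def to_newick(self) -> str:
        """Newick text export (branch lengths from merge heights)."""
        tree = hierarchy.to_tree(self.merges)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.items[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(tree, tree.dist) + ";"


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    axis: str = "samples",
    metric: str = "euclidean",
    linkage: str = "average",
) -> LinkageResult:
    """Cluster samples (columns) or genes (rows) of an expression matrix."""
    if axis not in ("samples", "genes"):
        raise ClusterError(f"axis must be 'samples' or 'genes', got {axis!r}")
    X = matrix.values.T if axis == "samples" else matrix.values
    items = tuple(matrix.samples if axis == "samples" else matrix.genes)
    if len(items) < 2:
        raise ClusterError(f"need at least 2 {axis} to cluster")
    if not np.isfinite(X).all():
        raise ClusterError("matrix contains NaN or infinite values")
    Z = hierarchy.linkage(X, method=linkage, metric=metric)
    return LinkageResult(merges=Z, items=items, metric=metric, linkage=linkage, axis=axis)


def cut_to_k(tree: LinkageResult, k: int) -> pd.Series:
    """Cut the tree into exactly k groups (labels 1..k, deterministic)."""
    n = len(tree.items)
    if not 1 <= k <= n:
        raise ClusterError(f"k={k} outside [1, {n}]")
    labels = hierarchy.fcluster(tree.merges, t=k, criterion="maxclust")
    return pd.Series(labels, index=list(tree.items), name="cluster")


def label_agreement(a: pd.Series, b: pd.Series) -> float:
    """Adjusted Rand index between two partitions of the same items."""
    if set(a.index) != set(b.index):
        raise ClusterError("partitions cover different item sets")
    b = b.reindex(a.index)
    return float(adjusted_rand_score(a.to_numpy(), b.to_numpy()))
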