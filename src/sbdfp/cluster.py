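"""Hierarchical clustering of dataset distance matrices and Adjusted Rand
Index evaluation against a ground-truth partition.

The workflow: each inter-dataset similarity matrix is converted to a
distance matrix (1 - similarity), clustered agglomeratively with complete
linkage, cut at a fixed number of clusters (10 in the reference workflow),
and scored with the ARI against the partition obtained the same way from an
independent ground truth (e.g. the distance form of a protein sequence
identity matrix).  ARI = 1 means the representation recovers the known
groups; ARI near 0 means chance-level assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "ClusterLabeling",
    "complete_linkage",
    "cut_tree",
    "adjusted_rand_index",
    "to_newick",
    "identity_to_distance",
    "evaluate_representations",
]


@dataclass
class ClusterLabeling:
    """Flat cluster assignment aligned to a list of item names."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.k:
            raise ValueError("labels must lie in [0, k)")
        if uniq.size != self.k:
            raise ValueError(f"expected {self.k} non-empty clusters, got {uniq.size}")


def _as_square(dist) -> tuple[np.ndarray, list[str]]:
    if isinstance(dist, pd.DataFrame):
        return dist.to_numpy(dtype=float), [str(x) for x in dist.index]
    d = np.asarray(dist, dtype=float)
    return d, [str(i) for i in range(d.shape[0])]


def complete_linkage(dist) -> np.ndarray:
    """Agglomerative complete-linkage merge tree of a square distance matrix.

    Accepts a labelled DataFrame or a plain symmetric array with zero
    diagonal and non-negative entries; returns a SciPy linkage matrix
    (merge pairs with heights, heights non-decreasing).
    """
    d, _ = _as_square(dist)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return hierarchy.linkage(squareform(d, checks=False), method="complete")


def cut_tree(linkage_matrix: np.ndarray, k: int) -> ClusterLabeling:
    """Cut a merge tree into exactly ``k`` flat clusters (labels 0..k-1)."""
    n = linkage_matrix.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    raw = hierarchy.cut_tree(linkage_matrix, n_clusters=k).ravel()
    # relabel to consecutive ints in order of first appearance
    _, labels = np.unique(raw, return_inverse=True)
    return ClusterLabeling(labels=labels, k=int(np.unique(labels).size))


def adjusted_rand_index(a: ClusterLabeling, b: ClusterLabeling) -> float:
    """Permutation-model Adjusted Rand Index between two labelings.

    Symmetric and invariant under relabeling; 1 for identical partitions,
    expectation 0 for independent random partitions.
    """
    if a.labels.shape != b.labels.shape:
        raise ValueError("labelings must cover the same items")
    return float(adjusted_rand_score(a.labels, b.labels))


def to_newick(linkage_matrix: np.ndarray, labels: list[str]) -> str:
    """Render a linkage matrix as a Newick string with merge heights as
    branch lengths (child branch length = parent height - child height)."""
    tree = hierarchy.to_tree(linkage_matrix)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    body = walk(tree, tree.dist)
    # the root carries no branch; strip its trailing length
    return body.rsplit(":", 1)[0] + ";"


def identity_to_distance(identity, percent: str = "auto") -> pd.DataFrame:
    """Convert a sequence-identity matrix to a distance matrix.

    ``percent`` is ``"auto"`` (treat values as percentages when any exceeds
    1.5), ``"yes"`` ((100 - identity)/100) or ``"no"`` (1 - identity).
    """
    m, labels = _as_square(identity)
    if percent == "auto":
        is_pct = float(np.nanmax(m)) > 1.5
    elif percent in ("yes", "no"):
        is_pct = percent == "yes"
    else:
        raise ValueError("percent must be 'auto', 'yes' or 'no'")
    d = (100.0 - m) / 100.0 if is_pct else 1.0 - m
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=labels, columns=labels)


def evaluate_representations(
    distance_matrices: Mapping[str, pd.DataFrame],
    ground_truth_dist: pd.DataFrame,
    k: int = 10,
) -> pd.DataFrame:
    """ARI of each representation's clustering against the ground truth.

    Every distance matrix (and the ground truth) is clustered with complete
    linkage and cut at ``k`` clusters; the returned table has one row per
    representation with its ARI against the ground-truth labeling.
    """
    gt_labels = [str(x) for x in ground_truth_dist.index]
    gt = cut_tree(complete_linkage(ground_truth_dist), k)
    rows = []
    for name, dist in distance_matrices.items():
        labels = [str(x) for x in dist.index]
        if labels != gt_labels:
            raise ValueError(
                f"representation {name!r} labels do not match the ground truth"
            )
        rep = cut_tree(complete_linkage(dist), k)
        rows.append({"representation": name, "ari": adjusted_rand_index(rep, gt)})
    return pd.DataFrame(rows).set_index("representation")
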