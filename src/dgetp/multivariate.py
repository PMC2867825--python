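"""Structure analysis of log10 transcription-ratio matrices.

Two complementary views of the feature x condition ratio matrix:

* PCA with varimax rotation of the leading axes — which conditions drive
  shared transcriptome responses;
* agglomerative hierarchical clustering with Pearson's *uncentered*
  distance (1 - cosine similarity, no mean-centering) and complete
  linkage, with exact optimal leaf ordering — which features co-respond.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from scipy.spatial.distance import squareform
from skbio import TreeNode
from statsmodels.multivariate.factor_rotation import rotate_factors


@dataclass
class PcaResult:
    scores: pd.DataFrame        # features x axes, varimax-rotated
    loadings: pd.DataFrame      # conditions x axes, orthonormal columns
    variance_shares: pd.Series  # per rotated axis, fraction of total variance


def pca_varimax(matrix: pd.DataFrame, n_axes: int = 5) -> PcaResult:
    """PCA of a feature x condition matrix, varimax-rotated.

    Columns (conditions) are mean-centered; no unit scaling by default.
    The rotation is orthogonal, so the loadings keep orthonormal columns
    and the total variance captured by the ``n_axes`` leading axes is
    preserved; only its distribution over axes changes.  Axis signs are
    fixed so each axis' largest-magnitude loading is positive.
    """
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if n_axes > min(X.shape):
        raise ValueError(
            f"n_axes={n_axes} exceeds matrix rank bound {min(X.shape)}"
        )
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps)) if s.size else 0
    if n_axes > rank:
        raise ValueError(f"n_axes={n_axes} exceeds matrix rank {rank}")
    V = vt[:n_axes].T                      # conditions x axes, orthonormal
    scores = X @ V                         # features x axes
    if n_axes > 1:
        V_rot, T = rotate_factors(V, "varimax")
    else:
        V_rot, T = V, np.eye(1)
    scores_rot = scores @ T
    # sign convention: largest-magnitude loading positive per axis
    flip = np.sign(V_rot[np.abs(V_rot).argmax(axis=0), np.arange(n_axes)])
    flip[flip == 0] = 1.0
    V_rot = V_rot * flip
    scores_rot = scores_rot * flip
    total_var = float((X ** 2).sum())
    if total_var == 0:
        raise ValueError("matrix has zero variance")
    shares = (scores_rot ** 2).sum(axis=0) / total_var
    axes = [f"axis{i + 1}" for i in range(n_axes)]
    return PcaResult(
        scores=pd.DataFrame(scores_rot, index=matrix.index, columns=axes),
        loadings=pd.DataFrame(V_rot, index=matrix.columns, columns=axes),
        variance_shares=pd.Series(shares, index=axes),
    )


def uncentered_pearson_distance(u, v) -> float:
    """1 - cosine similarity (Pearson's r about zero, not the mean).

    Ranges over [0, 2]: 0 for proportional profiles, 1 for orthogonal,
    2 for anti-proportional.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("uncentered distance undefined for a zero vector")
    d = 1.0 - float(u @ v) / (nu * nv)
    return min(max(d, 0.0), 2.0)


def uncentered_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Condensed pairwise uncentered-Pearson distances between rows."""
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError("uncentered distance undefined for a zero row")
    C = (X / norms[:, None]) @ (X / norms[:, None]).T
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return squareform(np.clip(D, 0.0, 2.0), checks=False)


@dataclass
class Dendrogram:
    """Complete-linkage tree with optimized leaf order."""

    linkage_matrix: np.ndarray
    labels: list[str]
    leaf_order: list[str]

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.labels)
        return str(tree).strip()

    def flat_clusters(self, height: float) -> pd.Series:
        from scipy.cluster.hierarchy import fcluster

        assignments = fcluster(self.linkage_matrix, t=height, criterion="distance")
        return pd.Series(assignments, index=self.labels, name="cluster")


def hierarchical_cluster(
    matrix: pd.DataFrame, axis: Literal["features", "conditions"] = "features"
) -> Dendrogram:
    """Complete-linkage tree over rows (features) or columns (conditions).

    Distances are uncentered Pearson; leaf order is the exact optimal
    leaf ordering (minimum sum of adjacent-leaf distances).  Items are
    pre-sorted by label so ties in the merge sequence break
    deterministically.
    """
    if axis == "conditions":
        matrix = matrix.T
    matrix = matrix.sort_index()
    if len(matrix) < 2:
        raise ValueError("need at least 2 items to cluster")
    X = matrix.to_numpy(dtype=float)
    d = uncentered_distance_matrix(X)
    Z = linkage(d, method="complete")
    Z = optimal_leaf_ordering(Z, d)
    labels = [str(i) for i in matrix.index]
    order = [labels[i] for i in leaves_list(Z)]
    return Dendrogram(linkage_matrix=Z, labels=labels, leaf_order=order)
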