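"""Unsupervised learning: rank-based distances, average-linkage clustering, PCA.

Distances are Spearman (1 - r_s), Kendall (1 - tau_b) or Euclidean, the
rank metrics computed over pairwise-complete observations with
average-tie ranking.  Hierarchical clustering is binary agglomerative
with unweighted pairwise average linkage (UPGMA-style): at each step the
globally closest pair of clusters is merged, ties broken on the lowest
(left id, right id) pair, and the inter-cluster distance is the mean of
all member pairwise distances.  Average linkage admits height inversions;
they are counted, not hidden.  PCA is a mean-centred SVD with a
deterministic sign convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .exceptions import ConfigError, SchemaError

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "PcaResult",
    "distance_matrix",
    "hierarchical_cluster",
    "two_dimensional_cluster",
    "pca",
]

METRICS = ("spearman", "euclidean", "kendall")


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix over named items."""

    labels: list[str]
    d: np.ndarray
    metric: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def _rank_metric_complete(X: np.ndarray, metric: str) -> np.ndarray:
    """Fast path: no missing data."""
    if metric == "spearman":
        R = np.apply_along_axis(stats.rankdata, 0, X)
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(R.T)
        return 1.0 - C
    # kendall tau_b per pair
    m = X.shape[1]
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            tau = stats.kendalltau(X[:, i], X[:, j]).statistic
            D[i, j] = D[j, i] = 1.0 - tau
    return D


def distance_matrix(
    matrix: pd.DataFrame,
    axis: str = "columns",
    metric: str = "spearman",
    min_complete: int = 3,
) -> DistanceMatrix:
    """Pairwise dissimilarities between rows or columns of a matrix.

    Rank metrics require at least ``min_complete`` pairwise-complete
    observations per pair; pairs below that yield a missing distance
    (clustering on such a matrix raises).  Euclidean distances are
    computed over pairwise-complete entries without rescaling.
    """
    if metric not in METRICS:
        raise ConfigError(f"unknown metric {metric!r}; choose from {METRICS}")
    if axis not in ("rows", "columns"):
        raise ConfigError("axis must be 'rows' or 'columns'")
    df = matrix if axis == "columns" else matrix.T
    labels = [str(c) for c in df.columns]
    if len(labels) < 2:
        raise SchemaError("need at least 2 items to compute distances")
    X = df.to_numpy(dtype=float)

    if not np.isnan(X).any():
        if metric == "euclidean":
            D = squareform(pdist(X.T, metric="euclidean"))
        else:
            D = _rank_metric_complete(X, metric)
    else:
        m = X.shape[1]
        D = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                mask = ~(np.isnan(X[:, i]) | np.isnan(X[:, j]))
                xi, xj = X[mask, i], X[mask, j]
                if metric == "euclidean":
                    d = float(np.sqrt(((xi - xj) ** 2).sum())) if mask.any() else np.nan
                elif mask.sum() < min_complete:
                    d = np.nan
                elif metric == "spearman":
                    d = 1.0 - float(stats.spearmanr(xi, xj).statistic)
                else:
                    d = 1.0 - float(stats.kendalltau(xi, xj).statistic)
                D[i, j] = D[j, i] = d

    np.fill_diagonal(D, 0.0)
    # clamp numerical negatives from correlations of identical items
    with np.errstate(invalid="ignore"):
        D[D < 0] = np.where(D[D < 0] > -1e-9, 0.0, D[D < 0])
    return DistanceMatrix(labels=labels, d=D, metric=metric)


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    Leaves carry ids 0..n-1 in the order of ``labels``; the merge created
    at step k has id n+k.  Each merge is (node_id, left, right, height)
    with the earlier-created child stored on the left, which also defines
    the leaf order (left-to-right traversal from the root).
    """

    labels: list[str]
    merges: list[tuple[int, int, int, float]]
    metric: str = ""
    _members: dict[int, list[int]] = field(default_factory=dict, repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_members(self, node: int) -> list[int]:
        """Leaf indices under a node, in traversal (left-to-right) order."""
        if node < self.n_leaves:
            return [node]
        if node not in self._members:
            _, left, right, _ = self.merges[node - self.n_leaves]
            self._members[node] = self.node_members(left) + self.node_members(right)
        return self._members[node]

    @property
    def leaf_order(self) -> list[str]:
        if not self.merges:
            return list(self.labels)
        root = self.merges[-1][0]
        return [self.labels[i] for i in self.node_members(root)]

    @property
    def n_inversions(self) -> int:
        """Merges lower than one of their internal children (average-linkage quirk)."""
        height = {m[0]: m[3] for m in self.merges}
        count = 0
        for node, left, right, h in self.merges:
            for child in (left, right):
                if child in height and h < height[child] - 1e-12:
                    count += 1
                    break
        return count

    def parent_and_sibling(self) -> dict[int, tuple[int, int]]:
        """node id -> (parent id, sibling id)."""
        out: dict[int, tuple[int, int]] = {}
        for node, left, right, _ in self.merges:
            out[left] = (node, right)
            out[right] = (node, left)
        return out

    def cophenetic_matrix(self) -> np.ndarray:
        """Leaf-by-leaf matrix of merge heights of lowest common ancestors."""
        n = self.n_leaves
        C = np.zeros((n, n))
        for node, left, right, h in self.merges:
            for u in self.node_members(left):
                for v in self.node_members(right):
                    C[u, v] = C[v, u] = h
        return C


def hierarchical_cluster(dm: DistanceMatrix) -> Dendrogram:
    """Binary agglomerative clustering with unweighted average linkage.

    Inter-cluster distances are maintained with the Lance-Williams update
    d(A+B, K) = (|A| d(A,K) + |B| d(B,K)) / (|A|+|B|), which equals the
    unweighted mean over member pairs.  Ties on the minimum distance are
    broken by the lexicographically smallest (left, right) node-id pair;
    distances are considered tied when within a small relative tolerance,
    because rank metrics on few observations produce exact mathematical
    ties whose floating-point images differ in the last bit depending on
    summation order.
    """
    if np.isnan(dm.d).any():
        raise SchemaError("distance matrix contains missing entries; cannot cluster")
    n = len(dm.labels)
    if n == 1:
        return Dendrogram(labels=list(dm.labels), merges=[], metric=dm.metric)
    size = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(dm.d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, int, float]] = []
    for step in range(n - 1):
        bi, bj, bd = -1, -1, np.inf
        for (i, j), d in dist.items():
            tol = 1e-9 * max(1.0, abs(d), abs(bd) if np.isfinite(bd) else 0.0)
            if d < bd - tol or (abs(d - bd) <= tol and bi >= 0 and (i, j) < (bi, bj)):
                bi, bj, bd = i, j, d
        new = n + step
        merges.append((new, bi, bj, bd))
        si, sj = size.pop(bi), size.pop(bj)
        others = list(size)
        for k in others:
            dik = dist.pop((min(bi, k), max(bi, k)))
            djk = dist.pop((min(bj, k), max(bj, k)))
            dist[(k, new)] = (si * dik + sj * djk) / (si + sj)
        del dist[(bi, bj)]
        size[new] = si + sj
    return Dendrogram(labels=list(dm.labels), merges=merges, metric=dm.metric)


def two_dimensional_cluster(
    matrix: pd.DataFrame, metric: str = "spearman", min_complete: int = 3
) -> tuple[Dendrogram, Dendrogram, pd.DataFrame]:
    """Independent row-wise and column-wise clustering plus the reordered matrix."""
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise SchemaError("two-dimensional clustering needs a matrix of at least 2x2")
    row_dend = hierarchical_cluster(
        distance_matrix(matrix, axis="rows", metric=metric, min_complete=min_complete)
    )
    col_dend = hierarchical_cluster(
        distance_matrix(matrix, axis="columns", metric=metric, min_complete=min_complete)
    )
    reordered = matrix.loc[row_dend.leaf_order, col_dend.leaf_order]
    return row_dend, col_dend, reordered


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # columns x components
    variance_fraction: np.ndarray
    imputed: int = 0  # number of missing cells median-imputed before the SVD


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """Column-mean-centred SVD principal component analysis.

    Missing values are imputed by their column median (recorded in the
    result) since the SVD requires complete data.  The sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    X = matrix.to_numpy(dtype=float).copy()
    nmiss = int(np.isnan(X).sum())
    if nmiss:
        med = np.nanmedian(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(med, idx[1])
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
    k = min(matrix.shape) if n_components is None else n_components
    if k > rank:
        warnings.warn(
            f"n_components={k} exceeds rank {rank}; truncating", stacklevel=2
        )
        k = rank
    total = float((S**2).sum())
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    for c in range(k):
        imax = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[imax, c] < 0:
            loadings[:, c] = -loadings[:, c]
            scores[:, c] = -scores[:, c]
    comp = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=comp),
        variance_fraction=(S[:k] ** 2) / total if total > 0 else np.zeros(k),
        imputed=nmiss,
    )
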