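"""Pearson-distance spectral matching and hierarchical clustering.

Identification works by nearest neighbor under the Pearson distance
``d = 1 − r``, where ``r`` is the product-moment correlation between two
processed spectra on the shared wavenumber grid: a query is assigned the
label of the library spectrum it covaries with most strongly.  The same
all-pairs distance matrix feeds agglomerative clustering, whose dendrogram
shows how polymer families group by spectral similarity.

Estimator classes follow the scikit-learn protocol; the module-level
functions operate directly on :class:`~ramanmatch.types.SpectrumLibrary`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .types import MatchResult, ProcessedSpectrum, SpectrumLibrary

__all__ = [
    "pearson_r",
    "pairwise_pearson",
    "DistanceMatrix",
    "distance_matrix",
    "match_query",
    "ClusterTree",
    "hcluster",
    "export_tree",
    "PearsonNearestNeighbor",
    "PearsonHierarchicalClustering",
]

LINKAGE_METHODS = ("complete", "average", "single", "ward")


class DegenerateVectorError(ValueError):
    """A constant vector has no defined correlation."""


class AxisError(ValueError):
    """Query and library are not on the same wavenumber grid."""


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation between two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        raise DegenerateVectorError("constant vector: correlation undefined")
    return float(np.clip(da @ db / (na * nb), -1.0, 1.0))


def pairwise_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Correlations between all rows of X and all rows of Y (vectorized)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    yn = np.linalg.norm(Yc, axis=1)
    if np.any(xn == 0) or np.any(yn == 0):
        raise DegenerateVectorError("constant row: correlation undefined")
    return np.clip((Xc @ Yc.T) / np.outer(xn, yn), -1.0, 1.0)


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs Pearson correlations and distances for a library."""

    ids: list[str]
    r_matrix: np.ndarray
    d_matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        r, d = self.r_matrix, self.d_matrix
        if r.shape != (n, n) or d.shape != (n, n):
            raise ValueError("matrix shape inconsistent with id count")
        if not (np.allclose(r, r.T) and np.allclose(d, d.T)):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0) or not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be r = 1, d = 0")
        if r.min() < -1 - 1e-12 or r.max() > 1 + 1e-12:
            raise ValueError("correlations outside [-1, 1]")

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy's condensed order."""
        d = self.d_matrix.copy()
        np.fill_diagonal(d, 0.0)
        return squareform(d, checks=False)


def distance_matrix(lib: SpectrumLibrary) -> DistanceMatrix:
    """Pearson r and d = 1 − r for every unordered pair of library spectra."""
    if len(lib) < 2:
        raise ValueError("need at least 2 spectra for a distance matrix")
    sds = lib.matrix.std(axis=1)
    flat = [lib.ids[i] for i in np.flatnonzero(sds == 0)]
    if flat:
        raise DegenerateVectorError(f"constant spectra in library: {flat}")
    r = pairwise_pearson(lib.matrix, lib.matrix)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(lib.ids), r_matrix=r, d_matrix=d)


def match_query(
    query: ProcessedSpectrum, lib: SpectrumLibrary, top_k: int = 5
) -> MatchResult:
    """Score a query against every library spectrum; return the top_k.

    Candidates sort by ascending Pearson distance with ties broken by
    ascending specimen id, so results are deterministic.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if query.grid.shape != lib.grid.shape or not np.array_equal(query.grid, lib.grid):
        raise AxisError(
            f"{query.specimen_id}: query grid does not match the library grid"
        )
    q = query.intensities
    if q.std() == 0:
        raise DegenerateVectorError(f"{query.specimen_id}: constant query spectrum")
    r = pairwise_pearson(q[None, :], lib.matrix)[0]
    d = 1.0 - r
    order = sorted(range(len(lib)), key=lambda i: (d[i], lib.ids[i]))
    k = min(top_k, len(lib))
    cands = [(lib.ids[i], float(r[i]), float(d[i])) for i in order[:k]]
    return MatchResult(
        query_id=query.specimen_id,
        candidates=cands,
        metadata_echo=lib.metadata[cands[0][0]],
    )


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge history over library spectra.

    ``linkage`` is the scipy (n−1, 4) linkage matrix: merged cluster
    indices, merge height, merged leaf count.
    """

    leaf_ids: list[str]
    linkage: np.ndarray
    linkage_method: str

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage shape inconsistent with leaf count")
        if self.linkage_method not in LINKAGE_METHODS:
            raise ValueError(f"linkage_method must be one of {LINKAGE_METHODS}")

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels (1..n_clusters) in leaf order."""
        return hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distances between leaves."""
        return hierarchy.cophenet(self.linkage)


def hcluster(dm: DistanceMatrix, linkage_method: str = "complete") -> ClusterTree:
    """Agglomerative clustering of the Pearson distance matrix."""
    if len(dm.ids) < 3:
        raise ValueError("need at least 3 leaves to cluster")
    if linkage_method not in LINKAGE_METHODS:
        raise ValueError(f"linkage_method must be one of {LINKAGE_METHODS}")
    Z = hierarchy.linkage(dm.condensed(), method=linkage_method)
    return ClusterTree(leaf_ids=list(dm.ids), linkage=Z, linkage_method=linkage_method)


def export_tree(tree: ClusterTree) -> str:
    """Serialize the dendrogram as a Newick string with branch lengths.

    Heights are halved so leaf-to-leaf path length through the tree equals
    the cophenetic (merge) distance — the usual ultrametric convention.
    """
    n = len(tree.leaf_ids)
    Z = tree.linkage

    def node_height(k: int) -> float:
        return 0.0 if k < n else Z[k - n, 2] / 2.0

    def render(k: int, parent_h: float) -> str:
        blen = parent_h - node_height(k)
        if k < n:
            return f"{tree.leaf_ids[k]}:{blen:.10g}"
        i, j = int(Z[k - n, 0]), int(Z[k - n, 1])
        h = node_height(k)
        return f"({render(i, h)},{render(j, h)}):{blen:.10g}"

    root = 2 * n - 2
    h = node_height(root)
    i, j = int(Z[-1, 0]), int(Z[-1, 1])
    return f"({render(i, h)},{render(j, h)});"


class PearsonNearestNeighbor(ClassifierMixin, BaseEstimator):
    """Nearest-neighbor classifier under the Pearson distance.

    ``fit(X, y)`` stores the processed library matrix and its labels;
    ``predict(X)`` assigns each row the label of its minimum-distance
    library row.  Pearson's affine invariance means predictions are
    unchanged under per-spectrum gain/offset, so SNV'd and rescaled
    inputs score identically.

    Attributes
    ----------
    X_ : ndarray of shape (n_library, n_nodes)
    classes_ : ndarray of unique labels
    """

    def __init__(self, top_k: int = 1, min_r: float | None = None):
        self.top_k = top_k
        self.min_r = min_r

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if X.shape[0] < 1:
            raise ValueError("empty library")
        if np.any(X.std(axis=1) == 0):
            raise DegenerateVectorError("constant library spectrum")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        return self

    def decision_distances(self, X) -> np.ndarray:
        """Pearson distances from each query row to each library row."""
        check_is_fitted(self, "X_")
        X = np.asarray(X, dtype=float)
        return 1.0 - pairwise_pearson(X, self.X_)

    def predict(self, X):
        d = self.decision_distances(X)
        return self.y_[np.argmin(d, axis=1)]

    def score_r(self, X) -> np.ndarray:
        """Best-match correlation per query (for min_r confidence flags)."""
        return 1.0 - self.decision_distances(X).min(axis=1)


class PearsonHierarchicalClustering(ClusterMixin, BaseEstimator):
    """Agglomerative clustering of spectra under the Pearson distance.

    Attributes after ``fit``: ``linkage_`` (scipy linkage matrix),
    ``labels_`` (flat cut at ``n_clusters``), ``tree_`` (:class:`ClusterTree`).
    """

    def __init__(self, n_clusters: int = 2, linkage: str = "complete"):
        self.n_clusters = n_clusters
        self.linkage = linkage

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 spectra to cluster")
        r = pairwise_pearson(X, X)
        r = (r + r.T) / 2.0
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        ids = [str(i) for i in range(X.shape[0])]
        dm = DistanceMatrix(ids=ids, r_matrix=r, d_matrix=d)
        self.tree_ = hcluster(dm, self.linkage)
        self.linkage_ = self.tree_.linkage
        self.labels_ = self.tree_.cut(self.n_clusters) - 1
        return self
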