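"""k-NN RBF feature-similarity graphs and their Laplacians.

Nodes are features (matrix columns), not samples.  Edge weights are
Gaussian similarities exp(-||x^i - x^j||^2 / sigma^2) kept only where one
endpoint is among the other's k nearest features (union rule), which makes
the matrix symmetric by construction.  Class-specific graphs are built on
the per-class sample partition with per-class bandwidths; the global graph
uses all samples.  In dense mode (k >= d-1) with a single shared bandwidth
the global similarity factorizes into the entrywise product of the class
similarities, which ``verify_product_identity`` checks numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform

from drfs.core_io import DataMatrix, split_by_class


class GraphError(ValueError):
    """Raised when a similarity graph cannot be constructed."""


@dataclass
class FeatureGraph:
    """Symmetric non-negative d x d feature-similarity matrix.

    ``sim`` is stored sparse (CSR) when k < d-1 and dense otherwise; entries
    lie in [0, 1] with a zero diagonal.  ``scope`` is ``"global"`` or
    ``"class <l>"``.
    """

    sim: np.ndarray | sp.csr_array
    sigma2: float
    k: int
    scope: str = "global"

    @property
    def d(self) -> int:
        return self.sim.shape[0]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.sim):
            return self.sim.toarray()
        return np.asarray(self.sim)


@dataclass
class GraphLaplacian:
    """L = Deg - M with Deg the diagonal degree matrix; PSD, zero row sums."""

    lap: np.ndarray | sp.csr_array
    degrees: np.ndarray

    @property
    def d(self) -> int:
        return self.lap.shape[0]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.lap):
            return self.lap.toarray()
        return np.asarray(self.lap)

    def quad(self, w: np.ndarray) -> float:
        """Quadratic form w^T L w (equals half the weighted sum of squared
        weight differences over graph edges)."""
        return float(w @ (self.lap @ w))


def _feature_sqdist(F: np.ndarray) -> np.ndarray:
    """Full d x d matrix of squared Euclidean distances between feature columns."""
    F = np.asarray(F, dtype=float)
    return squareform(pdist(F.T, metric="sqeuclidean"))


def compute_sigma2(F: np.ndarray) -> float:
    """Bandwidth: mean squared distance over unordered feature pairs i < j.

    Self-distances are excluded from the average, otherwise the bandwidth is
    systematically deflated.  Raises if every feature is identical (zero
    bandwidth): drop duplicate features or supply sigma2 manually.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[1] < 2:
        raise GraphError("need at least 2 features to compute a bandwidth")
    s2 = float(pdist(F.T, metric="sqeuclidean").mean())
    if s2 <= 0.0:
        raise GraphError(
            "all features are identical (sigma^2 = 0); drop duplicate "
            "features or supply sigma2 manually"
        )
    return s2


def knn_feature_graph(
    F: np.ndarray, k: int, sigma2: float, scope: str = "global"
) -> FeatureGraph:
    """Build the k-NN RBF feature graph on the columns of F.

    An edge (i, j), i != j, is kept iff i is among the k nearest features of
    j or vice versa; its weight is exp(-||x^i - x^j||^2 / sigma2).  Neighbor
    sets exclude the feature itself and k is capped at d-1 (cap => complete
    off-diagonal graph).  Ties in distance break by ascending feature index.
    """
    if sigma2 <= 0:
        raise GraphError(f"sigma2 must be positive, got {sigma2}")
    if k < 1:
        raise GraphError(f"k must be >= 1, got {k}")
    D2 = _feature_sqdist(F)
    d = D2.shape[0]
    k_eff = min(k, d - 1)

    with np.errstate(under="ignore"):
        W = np.exp(-D2 / sigma2)
    np.fill_diagonal(W, 0.0)

    if k_eff >= d - 1:
        sim: np.ndarray | sp.csr_array = W
    else:
        D2_self = D2.copy()
        np.fill_diagonal(D2_self, np.inf)
        # stable argsort: equal distances resolve to the lower feature index
        nbrs = np.argsort(D2_self, axis=1, kind="stable")[:, :k_eff]
        adj = np.zeros((d, d), dtype=bool)
        rows = np.repeat(np.arange(d), k_eff)
        adj[rows, nbrs.ravel()] = True
        adj |= adj.T
        sim = sp.csr_array(np.where(adj, W, 0.0))
    return FeatureGraph(sim=sim, sigma2=float(sigma2), k=k, scope=scope)


def build_class_graphs(X: DataMatrix, k: int) -> list[FeatureGraph]:
    """One feature graph per class, each with its own bandwidth sigma_l^2."""
    graphs = []
    for l, Xl in enumerate(split_by_class(X), start=1):
        try:
            s2 = compute_sigma2(Xl)
        except GraphError as exc:
            raise GraphError(f"class {l}: {exc}") from exc
        graphs.append(knn_feature_graph(Xl, k=k, sigma2=s2, scope=f"class {l}"))
    return graphs


def build_global_graph(X: DataMatrix, k: int) -> FeatureGraph:
    """Feature graph on all samples with the global bandwidth."""
    s2 = compute_sigma2(X.values)
    return knn_feature_graph(X.values, k=k, sigma2=s2, scope="global")


def laplacian(G: FeatureGraph) -> GraphLaplacian:
    """Graph Laplacian L = Deg - M. Positive semidefinite with zero row sums."""
    if sp.issparse(G.sim):
        deg = np.asarray(G.sim.sum(axis=1)).ravel()
        lap = sp.csr_array(sp.diags(deg) - G.sim)
    else:
        deg = G.sim.sum(axis=1)
        lap = np.diag(deg) - G.sim
    return GraphLaplacian(lap=lap, degrees=deg)


def verify_product_identity(X: DataMatrix, shared_sigma2: float) -> float:
    """Max off-diagonal deviation |M_ij - prod_l M^(l)_ij| in dense mode.

    Holds (< 1e-10) only when all graphs are dense (k capped at d-1) and the
    class and global graphs share one bandwidth; with per-class bandwidths
    or genuine k-NN sparsification the factorization is not exact.
    """
    d = X.n_features
    k_dense = d - 1
    global_g = knn_feature_graph(X.values, k=k_dense, sigma2=shared_sigma2)
    prod = np.ones((d, d))
    for Xl in split_by_class(X):
        prod *= knn_feature_graph(Xl, k=k_dense, sigma2=shared_sigma2).dense()
    dev = np.abs(global_g.dense() - prod)
    np.fill_diagonal(dev, 0.0)
    return float(dev.max())
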