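"""Subject-level connectivity graphs from ROI time series.

A subject's parcellated time series (T timepoints x R regions) is turned into
an undirected weighted graph: node i carries the i-th row of the Pearson
correlation matrix as its feature vector, and the edge between i and j is
weighted by the absolute partial correlation between the two regions.  Partial
correlations are read off the precision matrix of a shrinkage-regularized
covariance estimate, since with typical scan lengths the sample covariance of
a 200-region parcellation is singular.

Indexing convention: ROIs are 0-based; the R(R-1)/2 unordered pairs are
enumerated row-major over the strict upper triangle.  Feature masks and edge
vectors are portable across the package only under this fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.covariance import ledoit_wolf

__all__ = [
    "ConnectivityGraph",
    "edge_index_map",
    "pearson_matrix",
    "partial_correlation_matrix",
    "vectorize_upper",
    "unvectorize_upper",
    "build_graph",
]


@dataclass
class ConnectivityGraph:
    """Weighted undirected graph for one subject.

    ``node_features`` is the (possibly mask-zeroed) Pearson matrix: row i is
    the feature vector of node i.  ``pearson`` keeps the unmasked matrix.
    ``edges`` lists unordered pairs (i < j) and ``edge_weights`` their
    |partial correlation| weights, all in [0, 1].
    """

    n_nodes: int
    node_features: np.ndarray  # R x R
    edges: np.ndarray  # m x 2, each row (i, j) with i < j
    edge_weights: np.ndarray  # m
    pearson: np.ndarray  # R x R, unmasked

    def adjacency(self) -> np.ndarray:
        """Dense symmetric weighted adjacency with zero diagonal."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        i, j = self.edges[:, 0], self.edges[:, 1]
        a[i, j] = self.edge_weights
        a[j, i] = self.edge_weights
        return a


def edge_index_map(n_roi: int) -> np.ndarray:
    """The fixed enumeration of unordered ROI pairs.

    Returns an (R(R-1)/2, 2) array; row k is the pair (i, j), i < j, in
    row-major strict-upper-triangle order.  Bijective by construction.
    """
    iu, ju = np.triu_indices(n_roi, k=1)
    return np.column_stack([iu, ju])


def _check_timeseries(ts: np.ndarray, permissive: bool) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D T x R array")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    constant = np.flatnonzero(ts.std(axis=0) == 0)
    if constant.size and not permissive:
        raise ValueError(f"constant (zero-variance) ROI columns: {constant.tolist()}")
    return ts


def pearson_matrix(ts: np.ndarray, permissive: bool = False) -> np.ndarray:
    """Pearson correlation between all ROI pairs; the node-feature matrix.

    Symmetric with unit diagonal, entries in [-1, 1].  A constant column is an
    error naming the ROI unless ``permissive``, in which case its row/column
    are zero-filled (diagonal kept at 1).
    """
    ts = _check_timeseries(ts, permissive)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    bad = ~np.isfinite(r)
    if bad.any():
        r[bad] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def partial_correlation_matrix(ts: np.ndarray, shrinkage: float | str = "auto") -> np.ndarray:
    """Partial correlations from a shrinkage-regularized precision matrix.

    The covariance estimate is the convex combination
    ``(1 - lam) * S + lam * (tr(S)/R) * I`` of the sample covariance S with a
    scaled identity; ``shrinkage="auto"`` picks the analytic Ledoit-Wolf
    intensity.  With Theta its inverse, the partial correlation is
    ``rho_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj)``.
    """
    ts = _check_timeseries(ts, permissive=False)
    x = ts - ts.mean(axis=0)
    n, r = x.shape
    if shrinkage == "auto":
        cov, _ = ledoit_wolf(x, assume_centered=True)
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must be in [0, 1] or 'auto'")
        s = x.T @ x / n
        cov = (1.0 - lam) * s + lam * (np.trace(s) / r) * np.eye(r)
    eigs = np.linalg.eigvalsh((cov + cov.T) / 2)
    if eigs[0] <= max(eigs[-1], 1.0) * 1e-10:
        raise ValueError(
            "covariance matrix is singular (e.g. fewer timepoints than regions); "
            "use a nonzero (or 'auto') shrinkage"
        )
    theta = np.linalg.inv(cov)
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    rho = (rho + rho.T) / 2.0
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def vectorize_upper(matrix: np.ndarray, index_map: np.ndarray | None = None) -> np.ndarray:
    """Flatten a symmetric R x R matrix to its R(R-1)/2 upper-triangle vector."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("input must be a square matrix")
    if index_map is None:
        index_map = edge_index_map(matrix.shape[0])
    return matrix[index_map[:, 0], index_map[:, 1]]


def unvectorize_upper(vector: np.ndarray, n_roi: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: symmetric matrix with unit diagonal."""
    vector = np.asarray(vector)
    if vector.size != n_roi * (n_roi - 1) // 2:
        raise ValueError("vector length inconsistent with n_roi")
    m = np.eye(n_roi)
    iu, ju = np.triu_indices(n_roi, k=1)
    m[iu, ju] = vector
    m[ju, iu] = vector
    return m


def build_graph(
    pearson: np.ndarray,
    partial: np.ndarray,
    mask=None,
    edge_rule: str = "complete",
    top_k: int = 10,
) -> ConnectivityGraph:
    """Assemble the subject graph from its Pearson and partial matrices.

    Edge weights are |partial correlation|.  By default the graph is complete
    (every ROI pair, no self-loops); ``edge_rule="top_k"`` keeps, for each
    node, its ``top_k`` strongest incident edges.  When a feature mask is
    given, Pearson entries whose edge was not retained are zeroed in both
    triangles (diagonal kept at 1), so the node-feature dimension stays R.
    """
    pearson = np.asarray(pearson, dtype=float)
    partial = np.asarray(partial, dtype=float)
    if pearson.shape != partial.shape or pearson.shape[0] != pearson.shape[1]:
        raise ValueError("pearson and partial must be square matrices of equal size")
    r = pearson.shape[0]

    weights_full = np.clip(np.abs(partial), 0.0, 1.0)
    np.fill_diagonal(weights_full, 0.0)

    if edge_rule == "complete":
        keep = np.ones((r, r), dtype=bool)
    elif edge_rule == "top_k":
        keep = np.zeros((r, r), dtype=bool)
        k = min(top_k, r - 1)
        order = np.argsort(-weights_full, axis=1)[:, :k]
        rows = np.repeat(np.arange(r), k)
        keep[rows, order.ravel()] = True
        keep |= keep.T  # an edge survives if either endpoint keeps it
    else:
        raise ValueError(f"unknown edge_rule: {edge_rule!r}")
    np.fill_diagonal(keep, False)

    iu, ju = np.triu_indices(r, k=1)
    sel = keep[iu, ju]
    edges = np.column_stack([iu[sel], ju[sel]])
    edge_weights = weights_full[iu[sel], ju[sel]]

    node_features = pearson.copy()
    if mask is not None:
        if mask.n_original != r * (r - 1) // 2:
            raise ValueError("feature mask was built for a different number of ROIs")
        node_features = mask.apply_matrix(node_features)

    return ConnectivityGraph(
        n_nodes=r,
        node_features=node_features,
        edges=edges,
        edge_weights=edge_weights,
        pearson=pearson,
    )
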