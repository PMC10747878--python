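"""SVM-driven recursive feature elimination over vectorized connectomes.

Each subject's connectome is flattened to its R(R-1)/2 upper-triangle vector;
a linear support-vector machine is fitted repeatedly and the lowest-weighted
features are discarded until a predetermined number remains.  The retained
edge set, together with the full elimination-order ranking, forms a
:class:`FeatureMask` that downstream stages apply to node features.

The default per-feature importance is |w_j| / ||w||_2 — the classical SVM-RFE
criterion (the squared-weight ordering is identical).  An alternative
``importance="unit_point"`` scores feature j by the distance of the unit
feature point e_j to the separating hyperplane, |w_j + b| / ||w||_2; it is
provided for comparison but is sensitive to the bias term and not recommended.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.svm import SVC

from .graphs import edge_index_map

__all__ = ["FeatureMask", "svm_rfe", "apply_mask", "planted_edge_enrichment"]


@dataclass
class FeatureMask:
    """Retained edge-feature subset plus the full RFE ranking.

    ``ranking[j]`` is the elimination order of original feature j: 1 means
    eliminated first; the feature ranked ``n_original`` survived longest.
    ``retained`` is equivalently the set of features with the
    ``len(retained)`` highest ranks, so masks for any smaller/larger keep
    count can be re-derived by thresholding the ranking.
    """

    retained: np.ndarray  # sorted original feature indices
    ranking: np.ndarray  # length n_original, values 1..n_original
    n_original: int

    def __post_init__(self):
        self.retained = np.asarray(self.retained, dtype=int)
        self.ranking = np.asarray(self.ranking, dtype=int)

    @property
    def n_keep(self) -> int:
        return len(self.retained)

    def retained_at(self, n_keep: int) -> np.ndarray:
        """Retained set for an arbitrary keep count, by rank threshold."""
        if not 1 <= n_keep <= self.n_original:
            raise ValueError("n_keep out of range")
        return np.sort(np.flatnonzero(self.ranking > self.n_original - n_keep))

    def apply_vector(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v)
        if v.shape[-1] != self.n_original:
            raise ValueError("vector length does not match mask.n_original")
        return v[..., self.retained]

    def apply_matrix(self, m: np.ndarray) -> np.ndarray:
        """Zero non-retained off-diagonal entries of a symmetric R x R matrix."""
        m = np.asarray(m, dtype=float)
        r = m.shape[0]
        if m.ndim != 2 or m.shape[1] != r or r * (r - 1) // 2 != self.n_original:
            raise ValueError("matrix size does not match mask.n_original")
        pairs = edge_index_map(r)[self.retained]
        keep = np.zeros((r, r), dtype=bool)
        keep[pairs[:, 0], pairs[:, 1]] = True
        keep |= keep.T
        np.fill_diagonal(keep, True)
        return np.where(keep, m, 0.0)

    def to_frame(self, n_roi: int | None = None) -> pd.DataFrame:
        if n_roi is None:
            # invert k = R(R-1)/2
            n_roi = int(round((1 + np.sqrt(1 + 8 * self.n_original)) / 2))
        pairs = edge_index_map(n_roi)
        if len(pairs) != self.n_original:
            raise ValueError("n_roi inconsistent with mask.n_original")
        retained_flags = np.zeros(self.n_original, dtype=bool)
        retained_flags[self.retained] = True
        return pd.DataFrame(
            {
                "edge_index": np.arange(self.n_original),
                "roi_i": pairs[:, 0],
                "roi_j": pairs[:, 1],
                "rank": self.ranking,
                "retained": retained_flags.astype(int),
            }
        )

    def save_csv(self, path: str | Path, n_roi: int | None = None) -> None:
        self.to_frame(n_roi).to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path: str | Path) -> "FeatureMask":
        df = pd.read_csv(path)
        retained = np.sort(df.loc[df["retained"] == 1, "edge_index"].to_numpy())
        return cls(retained=retained, ranking=df["rank"].to_numpy(), n_original=len(df))


def _importance(w: np.ndarray, b: float, mode: str) -> np.ndarray:
    norm = np.linalg.norm(w)
    if norm == 0:
        return np.zeros_like(w)
    if mode == "weight":
        return np.abs(w) / norm
    if mode == "unit_point":
        return np.abs(w + b) / norm
    raise ValueError(f"unknown importance mode: {mode!r}")


def svm_rfe(
    X: np.ndarray,
    y: np.ndarray,
    n_keep: int,
    step_fraction: float = 0.1,
    C: float = 1.0,
    seed: int = 0,
    importance: str = "weight",
) -> FeatureMask:
    """Rank connectome features by recursive linear-SVM elimination.

    Features are z-scored internally; each round fits an SVC with a linear
    kernel on the survivors and drops the ``max(1, floor(step_fraction * m))``
    lowest-importance features (never dropping below ``n_keep``).  Ties are
    broken by eliminating the lower original index first, so masks are fully
    reproducible.  Survivors at termination are ranked by the final fit's
    importances, making the ranking a total order over all features.

    ``seed`` is accepted for interface uniformity; the linear SVC fit is
    deterministic, so it does not influence the result.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (subjects x features)")
    n_features = X.shape[1]
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("y must contain exactly two classes")
    if not 1 <= n_keep <= n_features:
        raise ValueError("n_keep must be in [1, n_features]")
    if not 0.0 < step_fraction <= 1.0:
        raise ValueError("step_fraction must be in (0, 1]")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd

    surviving = np.arange(n_features)
    ranking = np.zeros(n_features, dtype=int)
    next_rank = 1

    while len(surviving) > n_keep:
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xz[:, surviving], y)
        scores = _importance(clf.coef_[0], float(clf.intercept_[0]), importance)
        n_drop = min(max(1, int(step_fraction * len(surviving))), len(surviving) - n_keep)
        # ascending score; ties resolved toward the lower original index
        order = np.lexsort((surviving, scores))
        drop_pos = order[:n_drop]
        for p in drop_pos:
            ranking[surviving[p]] = next_rank
            next_rank += 1
        keep = np.ones(len(surviving), dtype=bool)
        keep[drop_pos] = False
        surviving = surviving[keep]

    if len(surviving) and next_rank <= n_features:
        if len(surviving) > 1:
            clf = SVC(kernel="linear", C=C)
            clf.fit(Xz[:, surviving], y)
            scores = _importance(clf.coef_[0], float(clf.intercept_[0]), importance)
        else:
            scores = np.zeros(1)
        order = np.lexsort((surviving, scores))
        for p in order:
            ranking[surviving[p]] = next_rank
            next_rank += 1

    return FeatureMask(retained=np.sort(surviving), ranking=ranking, n_original=n_features)


def apply_mask(obj: np.ndarray, mask: FeatureMask) -> np.ndarray:
    """Apply a mask to a feature vector (subset) or symmetric matrix (zero-out).

    Vectors (or stacks of vectors, last axis = features) are subset to the
    retained positions.  Square symmetric matrices have non-retained
    off-diagonal entries zeroed in both triangles, diagonal untouched.
    """
    obj = np.asarray(obj)
    if obj.ndim == 2 and obj.shape[0] == obj.shape[1] and obj.shape[0] * (obj.shape[0] - 1) // 2 == mask.n_original:
        return mask.apply_matrix(obj)
    return mask.apply_vector(obj)


def planted_edge_enrichment(mask: FeatureMask, planted_edges, n_roi: int) -> tuple[int, float]:
    """Overlap of the retained set with planted edges, and its hypergeometric
    tail probability under the null of uniformly random retention.

    Returns ``(n_overlap, p_value)`` with p = P[overlap >= observed].
    """
    pairs = edge_index_map(n_roi)
    pair_to_idx = {(int(i), int(j)): k for k, (i, j) in enumerate(pairs)}
    planted_idx = {pair_to_idx[(min(i, j), max(i, j))] for i, j in planted_edges}
    overlap = len(planted_idx & set(mask.retained.tolist()))
    p = float(hypergeom.sf(overlap - 1, mask.n_original, len(planted_idx), mask.n_keep))
    return overlap, p
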