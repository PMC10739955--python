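"""Data-driven Weak / Intermediate / Strong subpopulation assignment.

Cells are partitioned by their pre-stimulus contextual activity with a
non-arbitrary two-step procedure:

1. **Affinity propagation** on the negative squared Euclidean distances,
   with the shared input preference set to the *minimum* of the off-diagonal
   similarities (the conservative choice, yielding few exemplars) and
   damping 0.9.
2. **Exemplar-based agglomerative merging** of the resulting clusters down
   to k = 3: at each step the pair of clusters is merged whose best joint
   exemplar (the member maximizing mean similarity to the merged members)
   scores highest.  The three final clusters are labeled Weak /
   Intermediate / Strong by ascending mean of the clustering feature.

A simpler alternative classifier (:func:`classify_by_sd`) calls cells more
than one standard deviation below/above the population mean Weak/Strong.
Both methods tag their output so downstream tables record provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import AffinityPropagation

logger = logging.getLogger(__name__)

__all__ = [
    "APResult",
    "ClusterAssignment",
    "ConvergenceError",
    "affinity_propagation",
    "agglomerate_exemplars",
    "classify_by_sd",
    "fit_subpopulations",
    "GROUP_ORDER",
]

GROUP_ORDER = ("Weak", "Intermediate", "Strong")


class ConvergenceError(RuntimeError):
    """Affinity propagation failed to converge."""

    def __init__(self, n_iter: int):
        super().__init__(f"affinity propagation did not converge within {n_iter} iterations")
        self.n_iter = n_iter


@dataclass
class APResult:
    labels: np.ndarray            # cluster index per point
    exemplar_indices: np.ndarray  # point index of each cluster's exemplar
    n_iter: int

    @property
    def n_clusters(self) -> int:
        return len(self.exemplar_indices)


@dataclass
class ClusterAssignment:
    """Final grouping: one named label per cell plus exemplars and means."""

    labels: np.ndarray            # group name per cell
    exemplars: dict               # group name -> point index (None for sd method)
    cluster_means: dict           # group name -> mean clustering feature
    method: str                   # "ap_agg" | "sd"

    def to_frame(self, cell_ids=None) -> pd.DataFrame:
        n = len(self.labels)
        if cell_ids is None:
            cell_ids = np.arange(n)
        ex = [self.exemplars.get(lab) for lab in self.labels]
        return pd.DataFrame({"cell_id": cell_ids, "label": self.labels,
                             "exemplar_id": ex, "method": self.method})


def _as_features(features) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    return X


def affinity_propagation(features, damping: float = 0.9,
                         max_iter: int = 1000, preference: str = "min") -> APResult:
    """Exemplar clustering by message passing.

    Similarity is the negative squared Euclidean distance; the shared
    preference is the minimum (default) or median of the off-diagonal
    similarities.  Raises :class:`ConvergenceError` if message passing does
    not settle within ``max_iter`` iterations.
    """
    X = _as_features(features)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells to cluster")
    S = -cdist(X, X, "sqeuclidean")
    off = S[~np.eye(n, dtype=bool)]
    if np.all(off == 0.0):      # all points identical: one cluster by definition
        return APResult(np.zeros(n, dtype=int), np.array([0]), 0)
    pref = float(off.min()) if preference == "min" else float(np.median(off))
    ap = AffinityPropagation(damping=damping, max_iter=max_iter,
                             affinity="precomputed", preference=pref,
                             random_state=0)
    ap.fit(S)
    centers = np.asarray(ap.cluster_centers_indices_)
    if centers is None or centers.size == 0 or np.any(ap.labels_ < 0):
        raise ConvergenceError(ap.n_iter_)
    return APResult(ap.labels_.astype(int), centers.astype(int), int(ap.n_iter_))


def _joint_exemplar_score(S: np.ndarray, members: np.ndarray):
    """Best member as exemplar of `members`: (score, exemplar_index)."""
    sub = S[np.ix_(members, members)]
    means = sub.mean(axis=1)
    best = int(np.argmax(means))
    return float(means[best]), int(members[best])


def agglomerate_exemplars(ap_result: APResult, features, k: int = 3,
                          group_names=GROUP_ORDER) -> ClusterAssignment:
    """Merge affinity-propagation clusters down to ``k`` groups.

    At each step the cluster pair whose merged set has the best joint
    exemplar (highest mean within-cluster similarity) is merged.  Final
    groups are ordered by ascending mean feature and named Weak /
    Intermediate / Strong for k = 3 (generic names otherwise).
    """
    X = _as_features(features)
    S = -cdist(X, X, "sqeuclidean")
    clusters = [np.nonzero(ap_result.labels == c)[0]
                for c in range(ap_result.n_clusters)]
    if len(clusters) < k:
        raise ValueError(
            f"affinity propagation found {len(clusters)} clusters; "
            f"cannot merge up to k={k} — try a lower k")
    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                merged = np.concatenate([clusters[i], clusters[j]])
                score, _ = _joint_exemplar_score(S, merged)
                if best is None or score > best[0]:
                    best = (score, i, j)
        _, i, j = best
        clusters[i] = np.concatenate([clusters[i], clusters[j]])
        del clusters[j]

    feat_1d = X.mean(axis=1)
    order = np.argsort([feat_1d[c].mean() for c in clusters])
    if k == 3:
        names = list(group_names)
    else:
        names = [f"G{r + 1}" for r in range(k)]
    labels = np.empty(X.shape[0], dtype=object)
    exemplars, means = {}, {}
    for rank, ci in enumerate(order):
        members = clusters[ci]
        _, ex = _joint_exemplar_score(S, members)
        labels[members] = names[rank]
        exemplars[names[rank]] = ex
        means[names[rank]] = float(feat_1d[members].mean())
    return ClusterAssignment(labels.astype(str), exemplars, means, "ap_agg")


def classify_by_sd(values, k_sd: float = 1.0) -> ClusterAssignment:
    """Tail classifier: Weak/Strong = more than ``k_sd`` SDs below/above the mean.

    Uses the n-1 sample standard deviation.  Zero-variance input yields all
    Intermediate with a logged warning.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D array of at least 2 values")
    mu, sd = v.mean(), v.std(ddof=1)
    labels = np.full(v.size, "Intermediate", dtype=object)
    if sd == 0:
        logger.warning("zero variance: all cells classified Intermediate")
    else:
        labels[v < mu - k_sd * sd] = "Weak"
        labels[v > mu + k_sd * sd] = "Strong"
    means = {g: float(v[labels == g].mean()) for g in GROUP_ORDER
             if np.any(labels == g)}
    return ClusterAssignment(labels.astype(str), {}, means, "sd")


def fit_subpopulations(features, method: str = "ap_agg", k: int = 3,
                       **kwargs) -> ClusterAssignment:
    """One-call interface: ``ap_agg`` (default) or ``sd``."""
    if method == "ap_agg":
        ap = affinity_propagation(features)
        if ap.n_clusters < k:
            # degenerate fixture (e.g. all identical): keep AP's partition
            X = _as_features(features)
            feat = X.mean(axis=1)
            names = list(GROUP_ORDER)[:ap.n_clusters] if ap.n_clusters < 3 \
                else [f"G{i}" for i in range(ap.n_clusters)]
            labels = np.asarray([names[c] for c in ap.labels], dtype=str)
            means = {names[c]: float(feat[ap.labels == c].mean())
                     for c in range(ap.n_clusters)}
            ex = {names[c]: int(ap.exemplar_indices[c]) for c in range(ap.n_clusters)}
            return ClusterAssignment(labels, ex, means, "ap_agg")
        return agglomerate_exemplars(ap, features, k=k)
    if method == "sd":
        return classify_by_sd(np.asarray(features, dtype=float).squeeze(), **kwargs)
    raise ValueError(f"unknown method {method!r}")
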