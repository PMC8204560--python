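"""KMeans subtype discovery with automatic model-order selection.

For unlabeled cohorts the cluster count k is chosen by maximizing the mean
silhouette score over k = 3..9; when a stage-like label is available, k is
chosen by maximizing the adjusted mutual information (AMI) between the
cluster labels and the provided labels over the same range. The user may
bypass the search with a fixed k (default 3). Clustering itself is
k-means++ / Lloyd, best of several restarts, deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_mutual_info_score, silhouette_score as _sk_silhouette

from .errors import ParameterError, UndefinedResultError, ValidationError

K_RANGE = range(3, 10)  # automatic search bounds, 3..9 inclusive
DEFAULT_K = 3


@dataclass
class SubtypeAssignment:
    k: int
    labels: np.ndarray  # per-sample cluster label in 1..k
    criterion: str  # {"silhouette", "ami", "user"}
    curve: pd.DataFrame | None  # k, score over the search range (None for user mode)
    seed: int
    restarts: int

    def to_frame(self, sample_ids=None) -> pd.DataFrame:
        idx = sample_ids if sample_ids is not None else np.arange(self.labels.size)
        return pd.DataFrame({"sample_id": idx, "cluster": self.labels})


def kmeans_cluster(X, k: int, seed: int = 0, restarts: int = 10) -> np.ndarray:
    """k-means++ / Lloyd clustering, best of ``restarts`` runs by WCSS.

    Returns labels in {1..k}; deterministic per seed.
    """
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > X.shape[0]:
        raise ParameterError(f"k = {k} exceeds the number of samples ({X.shape[0]})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    return km.fit_predict(X) + 1


def silhouette(X, labels) -> float:
    """Mean silhouette (b - a) / max(a, b) with Euclidean distances.

    Singleton clusters contribute 0. Raises on a single-cluster labeling.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise UndefinedResultError("silhouette undefined for a single cluster")
    return float(_sk_silhouette(np.asarray(X, dtype=float), labels))


def ami(labels_a, labels_b) -> float:
    """Adjusted mutual information with arithmetic-mean normalization.

    Any zero-entropy (constant) labeling scores 0 by convention, avoiding the
    0/0 indeterminacy.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValidationError("labelings must have equal length")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return 0.0
    return float(adjusted_mutual_info_score(a, b, average_method="arithmetic"))


def select_k(
    X,
    mode: str = "silhouette",
    labels=None,
    k: int | None = None,
    k_range=K_RANGE,
    seed: int = 0,
    restarts: int = 10,
) -> SubtypeAssignment:
    """Cluster at every k in the search range and keep the argmax of the
    mode's criterion (ties broken toward the smallest k); "user" mode skips
    the search (default k = 3)."""
    X = np.asarray(X, dtype=float)
    if mode == "user":
        kk = DEFAULT_K if k is None else int(k)
        lab = kmeans_cluster(X, kk, seed=seed, restarts=restarts)
        return SubtypeAssignment(kk, lab, "user", None, seed, restarts)
    if mode not in ("silhouette", "ami"):
        raise ParameterError(f"unknown selection mode {mode!r}")
    if mode == "ami":
        if labels is None:
            raise ParameterError("ami mode requires reference labels")
        ref = np.asarray(labels)
        if ref.shape[0] != X.shape[0]:
            raise ValidationError("reference labels must align with samples")

    rows = []
    results: dict[int, np.ndarray] = {}
    for kk in k_range:
        try:
            lab = kmeans_cluster(X, kk, seed=seed, restarts=restarts)
            score = silhouette(X, lab) if mode == "silhouette" else ami(lab, ref)
            results[kk] = lab
            rows.append({"k": kk, "score": score})
        except (ParameterError, UndefinedResultError) as exc:
            rows.append({"k": kk, "score": np.nan, "error": str(exc)})
    curve = pd.DataFrame(rows)
    valid = curve.dropna(subset=["score"])
    if valid.empty:
        raise UndefinedResultError("no k in the search range could be scored")
    best = int(valid.loc[valid["score"].idxmax(), "k"])  # idxmax keeps first = smallest k on ties
    return SubtypeAssignment(best, results[best], mode, curve, seed, restarts)
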