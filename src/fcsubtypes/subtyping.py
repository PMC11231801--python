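"""Neurophysiological subtyping in the 2-D subsyndrome latent plane.

Participants are clustered by k-means on their FC-side latent scores.
The cluster count is screened by Calinski-Harabasz and Silhouette
metrics over many random 90% subsamples; assignment robustness is
quantified by refitting on each subsample, matching the trial clusters
back to the full-data reference by optimal one-to-one centroid
assignment (Hungarian matching), and recording how often each
participant lands away from its reference label.  A Ward-linkage
hierarchical clustering serves as a structural cross-check, and frozen
discovery centroids seed the k-means that transfers subtypes onto a
replication cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    silhouette_score,
)

__all__ = [
    "SubtypeModel",
    "StabilityReport",
    "KSelectionResult",
    "TransferResult",
    "fit_kmeans",
    "select_k",
    "assignment_stability",
    "ward_check",
    "transfer_subtypes",
    "match_labels",
]

#: A silhouette below this, at every k, marks weak cluster structure.
WEAK_STRUCTURE_SILHOUETTE = 0.4

#: Participants whose subsampling reassignment probability exceeds this
#: are flagged unstable (the ">5% chance of a different label" rule).
INSTABILITY_FLAG_THRESHOLD = 0.05


@dataclass
class SubtypeModel:
    """k-means solution in the latent plane."""

    k: int
    centroids: np.ndarray              # k x 2
    labels: np.ndarray                 # per participant, 0-based
    inertia: float
    seed: int

    def predict(self, scores: np.ndarray) -> np.ndarray:
        """Nearest-centroid (Euclidean) assignment."""
        scores = np.asarray(scores, dtype=float)
        d = ((scores[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)


def _check_scores(scores: np.ndarray, k: int) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be an n x d matrix")
    if k < 2:
        raise ValueError("k must be >= 2")
    if scores.shape[0] <= k:
        raise ValueError("need more participants than clusters")
    if np.unique(scores, axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct points")
    return scores


def fit_kmeans(scores: np.ndarray, k: int, n_init: int = 10, seed: int = 0) -> SubtypeModel:
    """Best-of-``n_init`` seeded k-means runs by inertia; deterministic
    given ``seed``."""
    scores = _check_scores(scores, k)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(scores)
    return SubtypeModel(
        k=k, centroids=km.cluster_centers_.copy(),
        labels=km.labels_.copy(), inertia=float(km.inertia_), seed=seed,
    )


@dataclass
class KSelectionResult:
    """Subsampled clustering-quality metrics per candidate k."""

    metrics: pd.DataFrame              # k, trial, silhouette, calinski_harabasz
    per_trial_best_k: np.ndarray       # argmax-silhouette k within each trial
    recommended_k: int
    weak_structure: bool               # every k has median silhouette < 0.4

    def median_table(self) -> pd.DataFrame:
        return self.metrics.groupby("k", as_index=False)[
            ["silhouette", "calinski_harabasz"]
        ].median()


def select_k(
    scores: np.ndarray,
    k_range: range | list[int] = range(2, 7),
    n_trials: int = 1000,
    frac: float = 0.9,
    seed: int = 0,
    n_init: int = 4,
) -> KSelectionResult:
    """Screen candidate cluster counts on random 90% subsamples.

    Each trial subsamples ``floor(frac*n)`` participants without
    replacement, fits k-means for every k, and records both metrics.
    The recommendation maximizes the median Silhouette, with median
    Calinski-Harabasz breaking ties.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    ks = list(k_range)
    m = int(np.floor(frac * n))
    if not ks or min(ks) < 2 or max(ks) >= m:
        raise ValueError("k_range must lie within (1, frac*n)")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    best_k = np.zeros(n_trials, dtype=int)
    for t in range(n_trials):
        idx = rng.choice(n, size=m, replace=False)
        sub = scores[idx]
        sil_by_k = {}
        for k in ks:
            km = KMeans(n_clusters=k, n_init=n_init,
                        random_state=int(rng.integers(2**31 - 1))).fit(sub)
            sil = silhouette_score(sub, km.labels_)
            ch = calinski_harabasz_score(sub, km.labels_)
            sil_by_k[k] = sil
            rows.append({"k": k, "trial": t, "silhouette": sil,
                         "calinski_harabasz": ch})
        best_k[t] = max(sil_by_k, key=sil_by_k.get)
    metrics = pd.DataFrame(rows)
    med = metrics.groupby("k")[["silhouette", "calinski_harabasz"]].median()
    order = med.sort_values(["silhouette", "calinski_harabasz"],
                            ascending=False)
    recommended = int(order.index[0])
    weak = bool((med["silhouette"] < WEAK_STRUCTURE_SILHOUETTE).all())
    return KSelectionResult(
        metrics=metrics, per_trial_best_k=best_k,
        recommended_k=recommended, weak_structure=weak,
    )


def match_labels(
    trial_centroids: np.ndarray, reference_centroids: np.ndarray
) -> np.ndarray:
    """Map trial cluster ids onto reference ids by optimal one-to-one
    centroid assignment (minimum total squared distance).

    Resolves ambiguous nearest-centroid matches — two trial centroids
    closest to the same reference — by the global Hungarian optimum.
    """
    cost = ((trial_centroids[:, None, :] - reference_centroids[None, :, :]) ** 2).sum(
        axis=2
    )
    rows, cols = linear_sum_assignment(cost)
    mapping = np.empty(len(rows), dtype=int)
    mapping[rows] = cols
    return mapping


@dataclass
class StabilityReport:
    """Subsampling-consensus diagnostics for a reference clustering."""

    instability: np.ndarray            # per participant, P(label != reference)
    unstable: np.ndarray               # instability > 0.05
    pairwise_consistency: np.ndarray   # n x n, co-clustering agreement w/ ref
    n_trials: int
    n_appearances: np.ndarray

    def __post_init__(self) -> None:
        assert ((self.instability >= 0) & (self.instability <= 1)).all()


def assignment_stability(
    scores: np.ndarray,
    reference: SubtypeModel,
    n_trials: int = 1000,
    frac: float = 0.9,
    seed: int = 0,
    n_init: int = 4,
) -> StabilityReport:
    """Reassignment probability of every participant under 90% subsampling.

    Per trial: refit k-means on the subsample, Hungarian-match trial
    clusters to the reference, and record whether each retained
    participant keeps its reference label.  ``instability`` is the
    fraction of a participant's appearances with a non-reference label;
    ``pairwise_consistency[i, j]`` is the fraction of trials retaining
    both i and j in which their together/apart relation matches the
    reference clustering.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    m = int(np.floor(frac * n))
    rng = np.random.default_rng(seed)
    mismatches = np.zeros(n)
    appearances = np.zeros(n)
    pair_agree = np.zeros((n, n))
    pair_seen = np.zeros((n, n))
    ref_same = reference.labels[:, None] == reference.labels[None, :]
    for _ in range(n_trials):
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(n_clusters=reference.k, n_init=n_init,
                    random_state=int(rng.integers(2**31 - 1))).fit(scores[idx])
        mapping = match_labels(km.cluster_centers_, reference.centroids)
        labels = mapping[km.labels_]
        appearances[idx] += 1
        mismatches[idx] += labels != reference.labels[idx]
        same = labels[:, None] == labels[None, :]
        agree = same == ref_same[np.ix_(idx, idx)]
        pair_seen[np.ix_(idx, idx)] += 1
        pair_agree[np.ix_(idx, idx)] += agree
    with np.errstate(invalid="ignore"):
        instability = np.where(appearances > 0, mismatches / np.maximum(appearances, 1), 0.0)
        consistency = np.where(pair_seen > 0, pair_agree / np.maximum(pair_seen, 1), np.nan)
    return StabilityReport(
        instability=instability,
        unstable=instability > INSTABILITY_FLAG_THRESHOLD,
        pairwise_consistency=consistency,
        n_trials=n_trials,
        n_appearances=appearances.astype(int),
    )


def ward_check(scores: np.ndarray, k: int, kmeans_labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Ward-linkage hierarchical clustering cut at k, plus its adjusted
    Rand agreement with the k-means labels."""
    scores = _check_scores(scores, k)
    ward = AgglomerativeClustering(n_clusters=k, linkage="ward").fit(scores)
    return ward.labels_.copy(), float(adjusted_rand_score(kmeans_labels, ward.labels_))


@dataclass
class TransferResult:
    """Replication-cohort subtypes seeded by frozen discovery centroids."""

    initial_labels: np.ndarray         # nearest discovery centroid
    labels: np.ndarray                 # after k-means convergence
    centroids: np.ndarray
    empty_clusters: list[int] = field(default_factory=list)


def transfer_subtypes(
    replication_scores: np.ndarray,
    discovery_centroids: np.ndarray,
) -> TransferResult:
    """k-means on replication latent scores initialized (solely) at the
    discovery centroids.

    The scores must already live in the frozen discovery coordinate
    system.  An empty cluster after convergence is reported, never
    silently dropped.
    """
    scores = np.asarray(replication_scores, dtype=float)
    centroids = np.asarray(discovery_centroids, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != centroids.shape[1]:
        raise ValueError("replication scores and centroids disagree in dimension")
    k = centroids.shape[0]
    d = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    initial = d.argmin(axis=1)
    if scores.shape[0] <= k:
        # degenerate tiny cohort: nearest-centroid assignment only
        return TransferResult(initial_labels=initial, labels=initial.copy(),
                              centroids=centroids.copy(),
                              empty_clusters=sorted(set(range(k)) - set(initial)))
    km = KMeans(n_clusters=k, init=centroids, n_init=1).fit(scores)
    empty = sorted(set(range(k)) - set(km.labels_))
    return TransferResult(
        initial_labels=initial,
        labels=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        empty_clusters=empty,
    )
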