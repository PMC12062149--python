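"""Stage-1 candidate selection by clustering per-stimulus feature vectors.

At test time every stimulus yields a five-component, sub-band-fused
correlation feature vector.  Target and non-target stimuli separate in this
feature space, so a small clustering pipeline shortlists candidates:

1. pick the number of clusters ``h`` by fitting Gaussian mixtures over a
   range of ``h`` and keeping the one with the lowest Davies–Bouldin index;
2. partition the feature rows with k-means++;
3. return the cluster with the highest mean feature value — its member
   stimuli are the candidates passed to stage 2.

Tie-breaks are deterministic throughout (smallest h; smaller then
lower-labelled cluster) so classification is reproducible given a seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "CandidateSet",
    "davies_bouldin",
    "select_cluster_count",
    "cluster_features",
    "pick_candidates",
]

DEFAULT_H_RANGE: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
DEFAULT_GMM_RESTARTS = 3


@dataclass
class FeatureMatrix:
    """Per-stimulus fused correlation features, shape (Nf, 5), rows >= 0."""

    values: np.ndarray
    trial_id: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


@dataclass
class CandidateSet:
    """Stimulus indices in the winning cluster, sorted ascending."""

    indices: np.ndarray
    h_selected: int
    cluster_means: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise ValueError("candidate set may not be empty")

    def __len__(self) -> int:
        return int(self.indices.size)


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies–Bouldin index: mean over clusters of the worst dispersion ratio.

    ``DB = (1/h) Σ_i max_{j≠i} (S_i + S_j) / M_ij`` with ``S_i`` the mean
    Euclidean distance of cluster-i points to their centroid and ``M_ij``
    the centroid distance.  Coincident centroids contribute +inf (logged).
    Lower is better.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] != len(labels):
        raise ValueError("one label per point required")
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    cents = np.stack([points[labels == u].mean(axis=0) for u in uniq])
    disp = np.array(
        [
            np.linalg.norm(points[labels == u] - cents[k], axis=1).mean()
            for k, u in enumerate(uniq)
        ]
    )
    h = len(uniq)
    total = 0.0
    for i in range(h):
        worst = 0.0
        for j in range(h):
            if j == i:
                continue
            m = np.linalg.norm(cents[i] - cents[j])
            if m == 0.0:
                logger.warning("coincident centroids in Davies-Bouldin; +inf ratio")
                worst = np.inf
                break
            worst = max(worst, (disp[i] + disp[j]) / m)
        total += worst
    return float(total / h)


def select_cluster_count(
    points: np.ndarray,
    h_range: tuple[int, ...] = DEFAULT_H_RANGE,
    seed: int = 0,
    n_restarts: int = DEFAULT_GMM_RESTARTS,
) -> int:
    """Choose the cluster count by GMM fits scored with Davies–Bouldin.

    For each h in ``h_range`` a full-covariance Gaussian mixture is fitted
    (``n_restarts`` initializations, seeded), points are hard-assigned, and
    the Davies–Bouldin index of that labelling is computed.  The h with the
    lowest index wins; ties break to the smallest h.  An h whose fit fails
    or collapses below two occupied components is skipped; if every h fails,
    fall back to h = 2 with a warning.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    best_h, best_db = None, np.inf
    for h in sorted(h_range):
        if h < 2 or h > points.shape[0]:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gmm = GaussianMixture(
                    n_components=h,
                    covariance_type="full",
                    reg_covar=1e-6,
                    n_init=n_restarts,
                    random_state=seed,
                )
                labels = gmm.fit_predict(points)
            if len(np.unique(labels)) < 2:
                raise ValueError("mixture collapsed to one occupied component")
            db = davies_bouldin(points, labels)
        except Exception as exc:  # fit failure for this h only
            logger.warning("GMM fit skipped at h=%d: %s", h, exc)
            continue
        if db < best_db:  # strict: ties keep the smaller h
            best_h, best_db = h, db
    if best_h is None:
        logger.warning("every GMM fit failed; falling back to h=2")
        return 2
    return best_h


def cluster_features(points: np.ndarray, h: int, seed: int = 0) -> np.ndarray:
    """Partition feature rows with k-means++ (Lloyd iterations, seeded).

    Returns integer labels, deterministic for a given seed.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if h > points.shape[0]:
        raise ValueError("more clusters than points")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(
            n_clusters=h,
            init="k-means++",
            n_init=1,
            max_iter=300,
            tol=1e-8,
            random_state=seed,
        )
        return km.fit_predict(points)


def pick_candidates(points: np.ndarray, labels: np.ndarray) -> CandidateSet:
    """Return the cluster with the highest mean feature value as candidates.

    The per-cluster score is the mean over all feature entries of all member
    rows.  Ties break to the smaller cluster, then to the lower label.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    means = np.array([points[labels == u].mean() for u in uniq])
    sizes = np.array([(labels == u).sum() for u in uniq])
    order = sorted(
        range(len(uniq)), key=lambda k: (-means[k], sizes[k], uniq[k])
    )
    win = order[0]
    indices = np.sort(np.nonzero(labels == uniq[win])[0])
    return CandidateSet(
        indices=indices, h_selected=len(uniq), cluster_means=means
    )
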