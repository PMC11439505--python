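"""Grouping participants by playing pattern from their GAF images.

Domain adaptation transfers data between participants; to keep the
transfer relevant, source participants are drawn only from the target's
cluster of similar playing patterns.  Features are extracted from each
participant's Gramian-angular-field image and grouped with K-means
(K=4 by default).

Two extractors are available.  ``flatten-pca`` (default) flattens the GAF
matrix and projects it onto principal components fitted on the cohort --
deterministic, dependency-free, and sufficient to separate archetypal
playing patterns because the GAF of a play-time series is itself already
a pattern image.  ``vgg16`` denotes a pretrained convolutional feature
extractor; it requires externally supplied weights and raises a clear
error when they are not available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import ExtractorUnavailableError

log = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "ClusterAssignment",
    "extract_features",
    "cluster_participants",
    "source_pool",
]


@dataclass
class FeatureMatrix:
    """One feature vector per participant."""

    values: np.ndarray  # (n_participants, dim)
    participant_ids: list[str]
    extractor_name: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.participant_ids):
            raise ValueError("feature row / participant id count mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusterAssignment:
    """participant_id -> cluster index in [0, K)."""

    K: int
    labels: dict[str, int]
    seed: int
    study_ids: dict[str, str] = field(default_factory=dict)
    inertia: float = float("nan")
    silhouette: float = float("nan")

    def members(self, cluster: int) -> list[str]:
        return [p for p, c in self.labels.items() if c == cluster]


def extract_features(matrices: list[np.ndarray] | dict[str, np.ndarray],
                     extractor_name: str = "flatten-pca",
                     n_components: int = 16,
                     participant_ids: list[str] | None = None,
                     seed: int = 0) -> FeatureMatrix:
    """Deterministic per-participant feature vectors from GAF matrices.

    ``matrices`` may be a dict keyed by participant id or a list paired
    with ``participant_ids``.  All matrices must share one side length
    (one cohort, one study-phase length).
    """
    if isinstance(matrices, dict):
        participant_ids = list(matrices)
        mats = [np.asarray(matrices[p], dtype=float) for p in participant_ids]
    else:
        mats = [np.asarray(m, dtype=float) for m in matrices]
        if participant_ids is None:
            participant_ids = [f"p{i}" for i in range(len(mats))]
    if not mats:
        raise ValueError("empty image collection")
    sides = {m.shape for m in mats}
    if len(sides) > 1:
        raise ValueError(f"GAF matrices of differing shapes: {sorted(sides)}")

    if extractor_name == "flatten-pca":
        flat = np.stack([m.ravel() for m in mats])
        k = min(n_components, flat.shape[0], flat.shape[1])
        # rank can be lower than k for degenerate cohorts; PCA caps it itself
        pca = PCA(n_components=k, svd_solver="full", random_state=seed)
        values = pca.fit_transform(flat)
        return FeatureMatrix(values, participant_ids, extractor_name)
    if extractor_name == "vgg16":
        raise ExtractorUnavailableError(
            "the 'vgg16' extractor needs pretrained convolutional weights, "
            "which are not bundled; use extractor_name='flatten-pca'")
    raise ExtractorUnavailableError(f"unknown extractor {extractor_name!r}")


def cluster_participants(features: FeatureMatrix, K: int = 4,
                         seed: int = 0,
                         study_ids: dict[str, str] | None = None) -> ClusterAssignment:
    """K-means with 10 restarts; deterministic given (features, K, seed)."""
    n = len(features.values)
    if n < K:
        raise ValueError(f"cannot form K={K} clusters from {n} participants")
    # fit in a canonical row order so the assignment is invariant to how the
    # participants happen to be listed (k-means++ seeding is order-sensitive)
    order = np.lexsort(features.values.T[::-1])
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    canon_labels = km.fit_predict(features.values[order])
    labels = np.empty(n, dtype=int)
    labels[order] = canon_labels
    occupied = set(labels.tolist())
    for c in range(K):
        if c not in occupied:
            log.warning("cluster %d is empty", c)
    sil = float("nan")
    if len(occupied) > 1:
        sil = float(silhouette_score(features.values, labels))
    return ClusterAssignment(
        K=K,
        labels={p: int(c) for p, c in zip(features.participant_ids, labels)},
        seed=seed,
        study_ids=dict(study_ids or {}),
        inertia=float(km.inertia_),
        silhouette=sil,
    )


def source_pool(assignment: ClusterAssignment, target: str,
                restrict_study: str | None = None) -> list[str]:
    """Same-cluster participants other than the target.

    ``restrict_study`` implements the cross-trial protocol: only
    participants whose study differs from the given study id (normally the
    target's own) are eligible as sources.
    """
    if target not in assignment.labels:
        raise KeyError(f"target {target!r} not in cluster assignment")
    cluster = assignment.labels[target]
    pool = [p for p, c in assignment.labels.items() if c == cluster and p != target]
    if restrict_study is not None:
        pool = [p for p in pool
                if assignment.study_ids.get(p) != restrict_study]
    if not pool:
        log.warning("empty source pool for target %s (cluster %d)", target, cluster)
    return pool
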