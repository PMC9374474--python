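"""Standard synergies: clustering healthy-cohort synergies and labelling them.

All spatial synergies extracted from every healthy trial are pooled and
clustered by hierarchical agglomerative clustering (average linkage on the
cosine distance ``1 - cos``).  A cluster whose members come from strictly
more than half of the healthy participants defines one standard synergy; its
representative vector is the renormalised element-wise mean of the members.
Each standard synergy is labelled with the anatomical area(s) of its
dominant muscles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .types import ValidationError

log = logging.getLogger(__name__)


class DomainError(ValueError):
    pass


class ClusteringError(RuntimeError):
    """No cluster satisfies the majority rule."""


@dataclass(frozen=True)
class SynergyMember:
    """Provenance of one pooled synergy vector."""

    subject_id: str
    trial_index: int
    synergy_index: int   # column index within its decomposition


@dataclass
class StandardSynergySet:
    """Representative synergies common to the healthy cohort."""

    W_std: np.ndarray                       # (muscles, S), unit-norm columns
    muscle_labels: list[str]
    clusters: list[list[SynergyMember]]     # members per standard synergy
    participant_support: list[int]
    area_labels: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W_std = np.asarray(self.W_std, dtype=float)
        if self.W_std.ndim != 2 or self.W_std.shape[1] < 1:
            raise ValidationError("W_std must be (muscles, S) with S >= 1")
        norms = np.linalg.norm(self.W_std, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValidationError("standard synergy columns must be unit norm")

    @property
    def n_synergies(self) -> int:
        return self.W_std.shape[1]


def synergy_similarity(w1: np.ndarray, w2: np.ndarray) -> float:
    """Cosine similarity of two non-negative synergy vectors, in [0, 1]."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape != w2.shape:
        raise ValidationError("synergy vectors must have the same length")
    n1, n2 = np.linalg.norm(w1), np.linalg.norm(w2)
    if n1 == 0 or n2 == 0:
        raise DomainError("cosine similarity undefined for a zero vector")
    return float(np.dot(w1, w2) / (n1 * n2))


def cluster_synergies(vectors: np.ndarray,
                      members: list[SynergyMember],
                      cut_distance: float = 0.25,
                      linkage_method: str = "average",
                      ) -> list[list[int]]:
    """Group pooled synergy vectors by average-linkage cosine clustering.

    Returns index lists into ``vectors``/``members``, ordered by descending
    participant support and then by first-member order.  The partition is
    invariant to the input order of the vectors.
    """
    vectors = np.asarray(vectors, dtype=float)
    n = vectors.shape[0]
    if n != len(members):
        raise ValidationError("one member record required per vector")
    if n < 2:
        log.warning("fewer than 2 synergy vectors; returning one degenerate cluster")
        return [[0]] if n == 1 else []
    dist = pdist(vectors, metric="cosine")
    dist = np.maximum(dist, 0.0)   # guard tiny negative rounding
    Z = linkage(dist, method=linkage_method)
    labels = fcluster(Z, t=cut_distance, criterion="distance")
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    clusters = list(groups.values())

    def support(idx: list[int]) -> int:
        return len({members[i].subject_id for i in idx})

    clusters.sort(key=lambda idx: (-support(idx), min(idx)))
    return clusters


def derive_standard_synergies(vectors: np.ndarray,
                              members: list[SynergyMember],
                              clusters: list[list[int]],
                              participants: list[str],
                              muscle_labels: list[str],
                              ) -> StandardSynergySet:
    """Retain majority clusters and build their representative synergies.

    A cluster is retained when its members span strictly more than half of
    the distinct healthy participants.  The representative is the
    element-wise mean of the member vectors, renormalised to unit norm.
    """
    n_participants = len(set(participants))
    half = n_participants / 2.0
    reps, kept_clusters, support = [], [], []
    for idx in clusters:
        subjects = {members[i].subject_id for i in idx}
        if len(subjects) > half:
            rep = np.asarray(vectors)[idx].mean(axis=0)
            norm = np.linalg.norm(rep)
            if norm == 0:
                continue
            reps.append(rep / norm)
            kept_clusters.append([members[i] for i in idx])
            support.append(len(subjects))
    if not reps:
        raise ClusteringError(
            "no cluster was shared by more than half of the participants; "
            "consider revisiting cut_distance"
        )
    return StandardSynergySet(
        W_std=np.column_stack(reps),
        muscle_labels=list(muscle_labels),
        clusters=kept_clusters,
        participant_support=support,
    )


def assign_muscle_areas(std: StandardSynergySet,
                        muscle_to_area: dict[str, str],
                        weight_threshold: float = 0.5,
                        ) -> list[list[str]]:
    """Label each standard synergy with the areas of its dominant muscles.

    A muscle contributes when its weight exceeds ``weight_threshold`` times
    the synergy's maximum weight (the 40-60% band of maximal activation);
    labels are the contributing muscles' areas, majority area first.
    """
    if not 0 < weight_threshold < 1:
        raise ValidationError("weight_threshold must be in (0, 1)")
    unmapped = [m for m in std.muscle_labels if m not in muscle_to_area]
    if unmapped:
        raise ConfigurationError(f"muscles without an area mapping: {unmapped}")
    labels: list[list[str]] = []
    for k in range(std.n_synergies):
        w = std.W_std[:, k]
        cutoff = weight_threshold * w.max()
        contributing = [std.muscle_labels[i] for i in np.flatnonzero(w > cutoff)]
        if len(contributing) == len(std.muscle_labels):
            log.warning("synergy %d: all muscles contribute (uniform weights)", k)
        counts: dict[str, int] = {}
        for m in contributing:
            a = muscle_to_area[m]
            counts[a] = counts.get(a, 0) + 1
        ordered = sorted(counts, key=lambda a: (-counts[a], a))
        labels.append(ordered)
    std.area_labels = labels
    return labels


class ConfigurationError(ValueError):
    pass
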