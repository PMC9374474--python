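"""Synergy-task relationship: fixed-basis temporal coefficients and activity maps.

With the spatial basis fixed (standard synergies, or a patient's own
synergies), each envelope frame is fitted by non-negative least squares;
coefficient rows are rescaled to a per-synergy maximum of 1 so the activity
threshold is scale-free.  A synergy counts as active in a task item when its
epoch-averaged coefficient strictly exceeds the threshold, and the group
frequency map is the fraction of trials in which it was active.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .standard import StandardSynergySet
from .types import EnvelopeMatrix, TaskEpochs, ValidationError, N_TASK_ITEMS


@dataclass
class ActivationProfile:
    """Per-task activity of a fixed synergy basis in one trial."""

    coeffs: np.ndarray          # (S, frames), row max 1 unless all-zero
    per_task_mean: np.ndarray   # (S, 37)
    active: np.ndarray          # bool (S, 37)
    activation_threshold: float


@dataclass
class TaskRelationshipMatrix:
    """Fraction of a group's trials in which each synergy was active per task."""

    freq: np.ndarray            # (S, 37) in [0, 1]
    n_trials: int
    group: str


def temporal_coefficients(env: EnvelopeMatrix, basis) -> np.ndarray:
    """Frame-wise NNLS coefficients of the envelope on a fixed synergy basis.

    ``basis`` may be a :class:`StandardSynergySet` or a plain
    (muscles, S) array.  After fitting, each synergy row is rescaled by its
    maximum over the whole sequence (all-zero rows are left at zero).
    """
    if isinstance(basis, StandardSynergySet):
        if basis.muscle_labels != env.muscle_labels:
            raise ValidationError(
                "envelope muscle labels do not match the standard synergy set"
            )
        W = basis.W_std
    else:
        W = np.asarray(basis, dtype=float)
    if W.shape[0] != len(env.muscle_labels):
        raise ValidationError("basis row count does not match envelope muscles")
    frames = env.values          # (T, muscles)
    S = W.shape[1]
    coeffs = np.empty((S, frames.shape[0]))
    for f in range(frames.shape[0]):
        coeffs[:, f], _ = nnls(W, frames[f])
    return rescale_rows(coeffs)


def rescale_rows(coeffs: np.ndarray) -> np.ndarray:
    """Divide each row by its maximum; (numerically) all-zero rows stay zero.

    Rows whose maximum is below 1e-12 of the global maximum are treated as
    silent rather than rescaled, so numerical dust is not amplified to 1.
    """
    mx = coeffs.max(axis=1)
    floor = 1e-12 * max(mx.max(), 0.0)
    live = mx > floor
    out = np.zeros_like(coeffs)
    out[live] = coeffs[live] / mx[live, None]
    return out


def task_activation(coeffs: np.ndarray, epochs: TaskEpochs,
                    activation_threshold: float = 0.3) -> ActivationProfile:
    """Epoch-average rescaled coefficients and apply the strict activity rule."""
    if not 0 < activation_threshold < 1:
        raise ValidationError("activation_threshold must be in (0, 1)")
    S = coeffs.shape[0]
    per_task = np.zeros((S, N_TASK_ITEMS))
    for j, e in enumerate(epochs):
        per_task[:, j] = coeffs[:, e.start_frame:e.end_frame].mean(axis=1)
    active = per_task > activation_threshold
    return ActivationProfile(
        coeffs=coeffs,
        per_task_mean=per_task,
        active=active,
        activation_threshold=activation_threshold,
    )


def activation_frequency(profiles: list[ActivationProfile], group: str = ""
                         ) -> TaskRelationshipMatrix:
    """Fraction of trials in which each synergy was active, per task item."""
    if not profiles:
        raise ValidationError("activation_frequency requires at least one profile")
    S = profiles[0].active.shape[0]
    for p in profiles:
        if p.active.shape[0] != S:
            raise ValidationError("profiles disagree on the number of synergies")
    counts = np.sum([p.active for p in profiles], axis=0)
    return TaskRelationshipMatrix(
        freq=counts / len(profiles), n_trials=len(profiles), group=group
    )


def group_difference(freq_patients: TaskRelationshipMatrix,
                     freq_healthy: TaskRelationshipMatrix) -> np.ndarray:
    """Element-wise patients-minus-healthy recruitment difference, in [-1, 1]."""
    if freq_patients.freq.shape != freq_healthy.freq.shape:
        raise ValidationError("frequency matrices have different shapes")
    return freq_patients.freq - freq_healthy.freq
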