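"""Core domain types shared by every pipeline stage.

Frame indexing is 0-based; task epochs are half-open ``[start, end)`` frame
intervals.  Durations in seconds are derived from the sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

N_TASK_ITEMS = 37
FMA_MAX = 66


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class FormatError(ValueError):
    """An on-disk artifact does not match the documented dialect."""


@dataclass(frozen=True)
class TaskEpoch:
    item_id: int          # 1..37
    start_frame: int      # inclusive
    end_frame: int        # exclusive

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class TaskEpochs:
    """The 37 task-item intervals of one full assessment sequence.

    Intervals are half-open, non-overlapping, and strictly increasing with
    item id; all 37 items must be present exactly once.
    """

    items: list[TaskEpoch]

    def __post_init__(self) -> None:
        ids = [e.item_id for e in self.items]
        if sorted(ids) != list(range(1, N_TASK_ITEMS + 1)):
            missing = set(range(1, N_TASK_ITEMS + 1)) - set(ids)
            dup = {i for i in ids if ids.count(i) > 1}
            raise ValidationError(
                f"epochs must cover items 1..{N_TASK_ITEMS} exactly once "
                f"(missing={sorted(missing)}, duplicated={sorted(dup)})"
            )
        self.items = sorted(self.items, key=lambda e: e.item_id)
        prev_end = -1
        for e in self.items:
            if e.n_frames < 2:
                raise ValidationError(
                    f"epoch {e.item_id} has {e.n_frames} frames; minimum is 2"
                )
            if e.start_frame < 0:
                raise ValidationError(f"epoch {e.item_id} starts before frame 0")
            if e.start_frame < prev_end:
                raise ValidationError(
                    f"epoch {e.item_id} overlaps or precedes the previous epoch"
                )
            prev_end = e.end_frame

    @property
    def max_frame(self) -> int:
        return self.items[-1].end_frame

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class EMGRecording:
    """One trial of raw multichannel surface EMG with task-epoch annotations."""

    subject_id: str
    trial_index: int                    # 1-based
    group: str                          # "healthy" | "stroke"
    fma_score: Optional[int]            # 0..66; None for healthy
    sampling_rate: float                # Hz
    muscle_labels: list[str]
    samples: np.ndarray                 # (frames, muscles), signed amplitude
    epochs: TaskEpochs

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.group not in ("healthy", "stroke"):
            raise ValidationError(f"unknown group {self.group!r}")
        if self.group == "stroke":
            if self.fma_score is None:
                raise ValidationError("stroke recordings require an FMA score")
            if not 0 <= self.fma_score <= FMA_MAX:
                raise ValidationError(
                    f"FMA score {self.fma_score} outside 0..{FMA_MAX}"
                )
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.trial_index < 1:
            raise ValidationError("trial_index is 1-based")
        if self.samples.ndim != 2 or self.samples.shape[0] == 0:
            raise ValidationError("samples must be a non-empty (frames, muscles) matrix")
        if self.samples.shape[1] != len(self.muscle_labels):
            raise FormatError(
                f"{self.samples.shape[1]} sample columns but "
                f"{len(self.muscle_labels)} muscle labels"
            )
        if len(set(self.muscle_labels)) != len(self.muscle_labels):
            raise ValidationError("duplicate muscle labels")
        if self.epochs.max_frame > self.n_frames:
            raise ValidationError(
                f"epochs extend to frame {self.epochs.max_frame} but the "
                f"recording has only {self.n_frames} frames"
            )

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.samples.shape[1]


@dataclass
class EnvelopeMatrix:
    """Non-negative EMG envelope, optionally max-normalised per muscle."""

    values: np.ndarray                   # (frames, muscles), >= 0
    muscle_labels: list[str]
    sampling_rate: float                 # Hz of the envelope frames
    epochs: Optional[TaskEpochs] = None
    normalization: Optional[np.ndarray] = None   # per-muscle maxima divided out
    source: Optional[str] = None         # provenance tag (subject/trial)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("envelope must be 2-D (frames, muscles)")
        if self.values.shape[1] != len(self.muscle_labels):
            raise ValidationError("envelope column count != number of labels")
        if np.any(self.values < -1e-12):
            raise ValidationError("envelope entries must be non-negative")
        self.values = np.maximum(self.values, 0.0)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class SynergyDecomposition:
    """Result of a non-negative factorisation E ~ H @ W.T.

    ``W`` holds the spatial synergies as unit-norm columns (muscles x K);
    ``H`` holds the temporal coefficients (K x frames).  ``vaf`` is the
    uncentred variance accounted for of the reconstruction.
    """

    W: np.ndarray                        # (muscles, K), unit-norm columns
    H: np.ndarray                        # (K, frames)
    K: int
    vaf: float
    vaf_curve: dict[int, float] = field(default_factory=dict)  # K -> best VAF

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.K < 1 or self.W.shape[1] != self.K or self.H.shape[0] != self.K:
            raise ValidationError("inconsistent synergy count K")
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValidationError("W and H must be non-negative")
        norms = np.linalg.norm(self.W, axis=0)
        live = norms > 0
        if np.any(np.abs(norms[live] - 1.0) > 1e-9):
            raise ValidationError("non-zero W columns must have unit norm")


@dataclass
class SubjectRecord:
    """Per-subject metadata: group, FMA score, severity class, trial count."""

    subject_id: str
    group: str
    fma_score: Optional[int] = None
    n_trials: int = 0
    # mean duration of each task item in seconds, item 1..37, optional
    item_durations: Optional[list[float]] = None

    @property
    def severity(self) -> str:
        if self.group != "stroke":
            return "n/a"
        from .stats import severity_class   # local import avoids a cycle
        return severity_class(self.fma_score)
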