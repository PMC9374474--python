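"""EMG envelope extraction and task-epoch segmentation.

The raw signal is band-limited, rectified and smoothed into a non-negative
envelope, then normalised per muscle by its maximum over the full task
sequence.  Filtering is zero-phase (forward-backward) Butterworth, so the
envelope has no group delay and keeps the input frame count.

The default step order is high-pass -> rectify -> low-pass: the interference
EMG carrier lives far above 20 Hz, so a 20 Hz low-pass applied *before*
rectification would remove the signal itself rather than smooth it.  The
literal filters-then-rectify order remains selectable for sensitivity work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import EMGRecording, EnvelopeMatrix, TaskEpochs, ValidationError

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A configuration value is outside its valid range."""


@dataclass
class PreprocessConfig:
    """Envelope-extraction parameters.

    highpass_hz, lowpass_hz : float
        Cutoffs of the zero-phase Butterworth filters (Hz).
    filter_order : int
        Order of each Butterworth stage (before the forward-backward pass,
        which doubles the effective order).
    step_order : {"hp_rect_lp", "hp_lp_rect"}
        Whether rectification happens between the two filters (standard
        envelope extraction, default) or after both.
    normalize : bool
        Divide each muscle by its maximum over the whole sequence.
    envelope_rate_hz : float or None
        If set, the envelope is decimated to this rate (block averaging)
        and epoch boundaries are rescaled accordingly.  Must divide the
        sampling rate.
    """

    highpass_hz: float = 0.1
    lowpass_hz: float = 20.0
    filter_order: int = 4
    step_order: str = "hp_rect_lp"
    normalize: bool = True
    envelope_rate_hz: float | None = None

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ConfigError("need 0 < highpass_hz < lowpass_hz")
        if self.lowpass_hz >= sampling_rate / 2:
            raise ConfigError(
                f"lowpass_hz={self.lowpass_hz} is at or above the Nyquist "
                f"frequency {sampling_rate / 2}"
            )
        if self.step_order not in ("hp_rect_lp", "hp_lp_rect"):
            raise ConfigError(f"unknown step_order {self.step_order!r}")
        if self.envelope_rate_hz is not None:
            factor = sampling_rate / self.envelope_rate_hz
            if abs(factor - round(factor)) > 1e-9 or factor < 1:
                raise ConfigError(
                    "envelope_rate_hz must integer-divide the sampling rate"
                )


def _sos(cutoff_hz: float, order: int, fs: float, btype: str) -> np.ndarray:
    return signal.butter(order, cutoff_hz, btype=btype, fs=fs, output="sos")


def preprocess_emg(rec: EMGRecording, cfg: PreprocessConfig | None = None
                   ) -> EnvelopeMatrix:
    """Turn a raw recording into a normalised non-negative envelope."""
    cfg = cfg or PreprocessConfig()
    cfg.validate(rec.sampling_rate)
    x = rec.samples

    zero_cols = np.flatnonzero(np.all(x == 0, axis=0))
    if zero_cols.size:
        log.warning(
            "all-zero channels kept as zero envelopes: %s",
            [rec.muscle_labels[i] for i in zero_cols],
        )

    hp = _sos(cfg.highpass_hz, cfg.filter_order, rec.sampling_rate, "highpass")
    lp = _sos(cfg.lowpass_hz, cfg.filter_order, rec.sampling_rate, "lowpass")

    y = signal.sosfiltfilt(hp, x, axis=0)
    if cfg.step_order == "hp_rect_lp":
        y = np.abs(y)
        y = signal.sosfiltfilt(lp, y, axis=0)
    else:  # literal filters-then-rectify
        y = signal.sosfiltfilt(lp, y, axis=0)
        y = np.abs(y)
    env = np.maximum(y, 0.0)   # zero-phase low-pass can undershoot slightly

    epochs = rec.epochs
    rate = rec.sampling_rate
    if cfg.envelope_rate_hz is not None:
        factor = int(round(rec.sampling_rate / cfg.envelope_rate_hz))
        env, epochs = _decimate(env, epochs, factor)
        rate = cfg.envelope_rate_hz

    norm = None
    if cfg.normalize:
        norm = env.max(axis=0)
        safe = np.where(norm > 0, norm, 1.0)
        env = env / safe
    return EnvelopeMatrix(
        values=env,
        muscle_labels=list(rec.muscle_labels),
        sampling_rate=rate,
        epochs=epochs,
        normalization=norm,
        source=f"{rec.subject_id}/trial{rec.trial_index}",
    )


def _decimate(env: np.ndarray, epochs: TaskEpochs, factor: int
              ) -> tuple[np.ndarray, TaskEpochs]:
    """Block-average the envelope by an integer factor and rescale epochs."""
    if factor == 1:
        return env, epochs
    n = (env.shape[0] // factor) * factor
    out = env[:n].reshape(-1, factor, env.shape[1]).mean(axis=1)
    from .types import TaskEpoch
    items = []
    for e in epochs:
        start = e.start_frame // factor
        end = max(e.end_frame // factor, start + 2)
        end = min(end, out.shape[0])
        items.append(TaskEpoch(e.item_id, start, end))
    return out, TaskEpochs(items)


def normalize_envelope(env: EnvelopeMatrix) -> EnvelopeMatrix:
    """Per-muscle max normalisation; idempotent, all-zero muscles stay zero."""
    norm = env.values.max(axis=0)
    safe = np.where(norm > 0, norm, 1.0)
    return EnvelopeMatrix(
        values=env.values / safe,
        muscle_labels=env.muscle_labels,
        sampling_rate=env.sampling_rate,
        epochs=env.epochs,
        normalization=norm,
        source=env.source,
    )


def segment_epochs(env: EnvelopeMatrix, epochs: TaskEpochs | None = None
                   ) -> list[tuple[int, np.ndarray]]:
    """Slice the envelope into the 37 per-item sub-matrices, in item order."""
    epochs = epochs if epochs is not None else env.epochs
    if epochs is None:
        raise ValidationError("no task epochs available for segmentation")
    if epochs.max_frame > env.n_frames:
        raise ValidationError(
            f"epochs extend to frame {epochs.max_frame} but envelope has "
            f"{env.n_frames} frames"
        )
    return [(e.item_id, env.values[e.start_frame:e.end_frame]) for e in epochs]


def concatenate_task_epochs(segments: list[tuple[int, np.ndarray]]
                            ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Stack per-item segments into one matrix for factorisation.

    Returns the concatenated (frames, muscles) matrix and a frame map
    assigning each concatenated frame its (item_id, local frame).
    """
    if not segments:
        raise ValidationError("cannot concatenate an empty segment list")
    n_muscles = segments[0][1].shape[1]
    for item_id, seg in segments:
        if seg.shape[1] != n_muscles:
            raise ValidationError(
                f"segment for item {item_id} has {seg.shape[1]} muscles, "
                f"expected {n_muscles}"
            )
    mat = np.vstack([seg for _, seg in segments])
    frame_map = [
        (item_id, i) for item_id, seg in segments for i in range(seg.shape[0])
    ]
    return mat, frame_map


def epoch_concatenated_envelope(env: EnvelopeMatrix) -> tuple[np.ndarray, TaskEpochs]:
    """Concatenate only the epoch-covered frames and re-index the epochs.

    Inter-epoch rest frames are dropped before factorisation; the returned
    epochs address the concatenated frame axis.
    """
    from .types import TaskEpoch
    segs = segment_epochs(env)
    mat, _ = concatenate_task_epochs(segs)
    items, cursor = [], 0
    for item_id, seg in segs:
        items.append(TaskEpoch(item_id, cursor, cursor + seg.shape[0]))
        cursor += seg.shape[0]
    return mat, TaskEpochs(items)
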