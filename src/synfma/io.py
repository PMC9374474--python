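"""Readers and writers for the on-disk trial dialect and cohort manifests.

A trial is a pair of files:

* ``<trial>.csv`` — comma-delimited table, header row, first column ``time``
  in seconds, one further column per muscle in metadata order;
* ``<trial>.meta.json`` — subject fields, sampling rate, muscle labels and
  the 37 task-epoch frame intervals.

A cohort is a ``cohort.manifest.json`` enumerating trial file pairs (paths
relative to the manifest) plus per-subject metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .types import (
    EMGRecording,
    FormatError,
    SubjectRecord,
    TaskEpoch,
    TaskEpochs,
    ValidationError,
)


def _epochs_to_json(epochs: TaskEpochs) -> list[dict]:
    return [
        {"item_id": e.item_id, "start_frame": e.start_frame, "end_frame": e.end_frame}
        for e in epochs
    ]


def _epochs_from_json(items: list[dict]) -> TaskEpochs:
    return TaskEpochs(
        [TaskEpoch(int(d["item_id"]), int(d["start_frame"]), int(d["end_frame"]))
         for d in items]
    )


def write_emg_recording(rec: EMGRecording, data_path, meta_path) -> None:
    """Write one trial as a CSV table plus a JSON metadata document.

    Round-trips through :func:`read_emg_recording` exactly on metadata and
    to within 1e-9 on samples.
    """
    data_path, meta_path = Path(data_path), Path(meta_path)
    meta = {
        "subject_id": rec.subject_id,
        "trial_index": rec.trial_index,
        "group": rec.group,
        "sampling_rate": rec.sampling_rate,
        "muscle_labels": list(rec.muscle_labels),
        "epochs": _epochs_to_json(rec.epochs),
    }
    if rec.fma_score is not None:
        meta["fma_score"] = int(rec.fma_score)
    meta_path.write_text(json.dumps(meta, indent=1))

    t = np.arange(rec.n_frames) / rec.sampling_rate
    table = np.column_stack([t, rec.samples])
    header = ",".join(["time"] + list(rec.muscle_labels))
    np.savetxt(data_path, table, delimiter=",", header=header, comments="",
               fmt="%.10g")


def read_emg_recording(data_path, meta_path) -> EMGRecording:
    """Read and validate one trial from its CSV/JSON file pair."""
    data_path, meta_path = Path(data_path), Path(meta_path)
    if not data_path.exists():
        raise FileNotFoundError(f"trial data file not found: {data_path}")
    if not meta_path.exists():
        raise FileNotFoundError(f"trial metadata file not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    labels = list(meta["muscle_labels"])

    with open(data_path) as fh:
        header = fh.readline().strip().split(",")
        table = np.loadtxt(fh, delimiter=",", ndmin=2)
    if len(header) != len(labels) + 1:
        raise FormatError(
            f"{data_path.name}: {len(header) - 1} data columns but "
            f"{len(labels)} muscle labels in metadata"
        )
    if header[1:] != labels:
        raise FormatError(
            f"{data_path.name}: column labels disagree with metadata order"
        )
    if table.shape[1] != len(labels) + 1:
        raise FormatError(
            f"{data_path.name}: expected {len(labels) + 1} columns, "
            f"found {table.shape[1]}"
        )
    return EMGRecording(
        subject_id=str(meta["subject_id"]),
        trial_index=int(meta["trial_index"]),
        group=str(meta["group"]),
        fma_score=(int(meta["fma_score"]) if "fma_score" in meta else None),
        sampling_rate=float(meta["sampling_rate"]),
        muscle_labels=labels,
        samples=table[:, 1:],
        epochs=_epochs_from_json(meta["epochs"]),
    )


def write_manifest(manifest_path, trials: list[tuple[str, str]],
                   subjects: list[SubjectRecord]) -> None:
    """Write a cohort manifest; ``trials`` holds (data, meta) relative paths."""
    doc = {
        "trials": [{"data": d, "meta": m} for d, m in trials],
        "subjects": [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "fma_score": s.fma_score,
                "n_trials": s.n_trials,
                "item_durations": s.item_durations,
            }
            for s in subjects
        ],
    }
    Path(manifest_path).write_text(json.dumps(doc, indent=1))


def load_cohort(manifest_path) -> tuple[list[EMGRecording], list[SubjectRecord]]:
    """Load every trial listed in a cohort manifest.

    Validates each trial and enforces a single muscle ordering across the
    whole cohort (muscle identity is by label, so a permuted montage in one
    trial is an error, not a silent reindex).
    """
    manifest_path = Path(manifest_path)
    doc = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    recordings: list[EMGRecording] = []
    for entry in doc["trials"]:
        rec = read_emg_recording(root / entry["data"], root / entry["meta"])
        if recordings and rec.muscle_labels != recordings[0].muscle_labels:
            raise ValidationError(
                f"trial {entry['data']} uses a different muscle ordering "
                f"than the first trial"
            )
        recordings.append(rec)
    subjects = [
        SubjectRecord(
            subject_id=str(s["subject_id"]),
            group=str(s["group"]),
            fma_score=(None if s.get("fma_score") is None else int(s["fma_score"])),
            n_trials=int(s.get("n_trials", 0)),
            item_durations=s.get("item_durations"),
        )
        for s in doc.get("subjects", [])
    ]
    if not subjects:
        subjects = subjects_from_recordings(recordings)
    return recordings, subjects


def subjects_from_recordings(recordings: list[EMGRecording]) -> list[SubjectRecord]:
    """Derive per-subject records (group, FMA, trial count) from trials."""
    by_id: dict[str, SubjectRecord] = {}
    for rec in recordings:
        s = by_id.setdefault(
            rec.subject_id,
            SubjectRecord(rec.subject_id, rec.group, rec.fma_score, 0),
        )
        if s.group != rec.group or s.fma_score != rec.fma_score:
            raise ValidationError(
                f"subject {rec.subject_id}: inconsistent group/FMA across trials"
            )
        s.n_trials += 1
    return list(by_id.values())
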