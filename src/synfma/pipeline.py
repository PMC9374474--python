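"""End-to-end orchestration: cohort -> envelopes -> synergies -> standard set
-> task maps -> merging -> statistical screen.

`run_full` is the library entry point; the CLI wraps it.  Stages run in
dependency order and every floating-point stage is deterministic given the
pipeline seed (per-trial extraction seeds are derived from it).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .extraction import ExtractionConfig, select_synergy_number
from .merging import MergingResult, merging_rate, per_task_merging_rate
from .muscles import DEFAULT_MUSCLE_TO_AREA
from .preprocessing import (
    PreprocessConfig,
    epoch_concatenated_envelope,
    preprocess_emg,
)
from .standard import (
    StandardSynergySet,
    SynergyMember,
    assign_muscle_areas,
    cluster_synergies,
    derive_standard_synergies,
)
from .stats import (
    ScreenEntry,
    TaskSubset,
    duration_reduction,
    group_tests,
    outlier_screened_regression,
    robust_regression,
    select_task_subset,
    severity_class,
)
from .tasks import (
    ActivationProfile,
    TaskRelationshipMatrix,
    activation_frequency,
    group_difference,
    rescale_rows,
    task_activation,
    temporal_coefficients,
)
from .types import EMGRecording, SubjectRecord, N_TASK_ITEMS

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(envelope_rate_hz=25.0)
    )
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    cut_distance: float = 0.25
    activation_threshold: float = 0.3
    merging_threshold: float = 0.1
    weight_threshold: float = 0.5
    alpha: float = 0.05
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class TrialAnalysis:
    """Everything derived from one trial before cross-trial aggregation."""

    recording_index: int
    subject_id: str
    trial_index: int
    group: str
    fma_score: Optional[int]
    envelope: np.ndarray            # epoch-concatenated (frames, muscles)
    epochs: "object"                # TaskEpochs on the concatenated axis
    decomposition: "object"         # SynergyDecomposition
    item_durations: np.ndarray      # seconds per item


@dataclass
class PipelineResult:
    config: PipelineConfig
    standard: StandardSynergySet
    trials: list[TrialAnalysis]
    profiles_standard: dict[int, ActivationProfile]    # trial idx -> profile
    freq_healthy: TaskRelationshipMatrix
    freq_by_group: dict[str, TaskRelationshipMatrix]
    differences: dict[str, np.ndarray]
    merging: dict[int, MergingResult]                  # stroke trial idx -> result
    merging_healthy: dict[int, MergingResult]          # healthy trial-1 idx -> result
    per_task: dict[int, np.ndarray]                    # stroke trial idx -> (37,)
    regression: dict[int, "object"]                    # trial series -> RobustFit
    group_report: dict[int, "object"]
    screen: dict[int, list[ScreenEntry]]               # trial series -> 37 entries
    subset: dict[int, TaskSubset]
    reduction_pct: dict[int, float]
    healthy_k: list[int]


def analyze_trials(recordings: list[EMGRecording], config: PipelineConfig
                   ) -> list[TrialAnalysis]:
    """Preprocess and factorise every trial."""
    out = []
    for i, rec in enumerate(recordings):
        env = preprocess_emg(rec, config.preprocess)
        mat, epochs = epoch_concatenated_envelope(env)
        ecfg = ExtractionConfig(**{**asdict(config.extraction)})
        ecfg.seed = int((config.seed * 100003 + i * 1009) % 2**31)
        dec = select_synergy_number(mat, ecfg)
        durations = np.array([e.n_frames for e in rec.epochs]) / rec.sampling_rate
        out.append(TrialAnalysis(
            recording_index=i,
            subject_id=rec.subject_id,
            trial_index=rec.trial_index,
            group=rec.group,
            fma_score=rec.fma_score,
            envelope=mat,
            epochs=epochs,
            decomposition=dec,
            item_durations=durations,
        ))
        log.info("trial %s/%d: K=%d VAF=%.3f", rec.subject_id,
                 rec.trial_index, dec.K, dec.vaf)
    return out


def build_standard_set(trials: list[TrialAnalysis], config: PipelineConfig,
                       muscle_labels: list[str]) -> StandardSynergySet:
    """Pool healthy synergies, cluster, retain majority clusters, label areas."""
    vectors, members = [], []
    participants = []
    for t in trials:
        if t.group != "healthy":
            continue
        participants.append(t.subject_id)
        for k in range(t.decomposition.K):
            vectors.append(t.decomposition.W[:, k])
            members.append(SynergyMember(t.subject_id, t.trial_index, k))
    vectors = np.array(vectors)
    clusters = cluster_synergies(vectors, members, cut_distance=config.cut_distance)
    std = derive_standard_synergies(vectors, members, clusters,
                                    participants, muscle_labels)
    assign_muscle_areas(std, DEFAULT_MUSCLE_TO_AREA, config.weight_threshold)
    return std


def run_full(recordings: list[EMGRecording], subjects: list[SubjectRecord],
             config: PipelineConfig | None = None,
             out_dir=None) -> PipelineResult:
    """Run every stage on an in-memory cohort; optionally write the bundle."""
    config = config or PipelineConfig()
    trials = analyze_trials(recordings, config)
    muscle_labels = recordings[0].muscle_labels
    std = build_standard_set(trials, config, muscle_labels)

    # --- activation of the standard synergies in every trial
    profiles: dict[int, ActivationProfile] = {}
    for t in trials:
        from .types import EnvelopeMatrix
        env = EnvelopeMatrix(values=t.envelope, muscle_labels=muscle_labels,
                             sampling_rate=1.0, epochs=t.epochs)
        coeffs = temporal_coefficients(env, std)
        profiles[t.recording_index] = task_activation(
            coeffs, t.epochs, config.activation_threshold
        )

    healthy_idx = [t.recording_index for t in trials if t.group == "healthy"]
    freq_healthy = activation_frequency(
        [profiles[i] for i in healthy_idx], group="healthy"
    )
    freq_by_group: dict[str, TaskRelationshipMatrix] = {"healthy": freq_healthy}
    differences: dict[str, np.ndarray] = {}
    for sev in ("mild", "severe"):
        idx = [t.recording_index for t in trials
               if t.group == "stroke" and severity_class(t.fma_score) == sev]
        if idx:
            fm = activation_frequency([profiles[i] for i in idx], group=sev)
            freq_by_group[sev] = fm
            differences[sev] = group_difference(fm, freq_healthy)

    # --- merging of stroke synergies on the standard basis
    merging: dict[int, MergingResult] = {}
    per_task: dict[int, np.ndarray] = {}
    for t in trials:
        if t.group != "stroke":
            continue
        res = merging_rate(t.decomposition, std, config.merging_threshold)
        merging[t.recording_index] = res
        own_profile = task_activation(
            rescale_rows(t.decomposition.H), t.epochs, config.activation_threshold
        )
        per_task[t.recording_index] = per_task_merging_rate(res, own_profile)

    # healthy reference merging rates (first trial of each healthy subject)
    merging_healthy: dict[int, MergingResult] = {}
    for t in trials:
        if t.group == "healthy" and t.trial_index == 1:
            merging_healthy[t.recording_index] = merging_rate(
                t.decomposition, std, config.merging_threshold
            )

    # --- statistics per stroke trial series (trial 1 and trial 2 separately)
    regression, group_report, screen, subset, reduction = {}, {}, {}, {}, {}
    stroke_durations = [t.item_durations for t in trials if t.group == "stroke"]
    mean_durations = (np.mean(stroke_durations, axis=0)
                      if stroke_durations else None)
    series_ids = sorted({t.trial_index for t in trials if t.group == "stroke"})
    for series in series_ids:
        ts = [t for t in trials if t.group == "stroke" and t.trial_index == series]
        x = np.array([t.fma_score for t in ts], dtype=float)
        y = np.array([merging[t.recording_index].merging_rate for t in ts])
        sids = [t.subject_id for t in ts]
        valid = ~np.isnan(y)
        regression[series] = robust_regression(x[valid], y[valid])

        by_sev = {"healthy": [merging_healthy[i].merging_rate
                              for i in merging_healthy],
                  "mild": [yy for t, yy in zip(ts, y)
                           if severity_class(t.fma_score) == "mild"],
                  "severe": [yy for t, yy in zip(ts, y)
                             if severity_class(t.fma_score) == "severe"]}
        by_sev = {g: v for g, v in by_sev.items() if len(v) >= 2}
        group_report[series] = group_tests(by_sev) if len(by_sev) >= 2 else None

        entries: list[ScreenEntry] = []
        pvals = np.full(N_TASK_ITEMS, np.nan)
        for task in range(N_TASK_ITEMS):
            yy = np.array([per_task[t.recording_index][task] for t in ts])
            ok = ~np.isnan(yy)
            if ok.sum() >= 6 and np.ptp(x[ok]) > 0:
                entry = outlier_screened_regression(
                    x[ok], yy[ok],
                    [s for s, o in zip(sids, ok) if o],
                    alpha=config.alpha,
                )
                entries.append(entry)
                pvals[task] = entry.p_incline
            else:
                entries.append(None)
        screen[series] = entries
        subset[series] = select_task_subset(pvals, config.alpha)
        removal = subset[series].removed + subset[series].missing
        reduction[series] = duration_reduction(mean_durations, removal)

    result = PipelineResult(
        config=config,
        standard=std,
        trials=trials,
        profiles_standard=profiles,
        freq_healthy=freq_healthy,
        freq_by_group=freq_by_group,
        differences=differences,
        merging=merging,
        merging_healthy=merging_healthy,
        per_task=per_task,
        regression=regression,
        group_report=group_report,
        screen=screen,
        subset=subset,
        reduction_pct=reduction,
        healthy_k=[t.decomposition.K for t in trials if t.group == "healthy"],
    )
    if out_dir is not None:
        write_bundle(result, out_dir)
    return result


# ---------------------------------------------------------------------------
# bundle serialisation


def _clean(obj):
    """Make numpy containers JSON-serialisable; NaN becomes null."""
    if isinstance(obj, np.ndarray):
        return _clean(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return None if np.isnan(obj) else float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    return obj


def write_bundle(result: PipelineResult, out_dir) -> None:
    """Write standard.json, taskmap.json, merging.json, screen.json, report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": result.config.config_hash(),
             "seed": result.config.seed}

    std = result.standard
    (out / "standard.json").write_text(json.dumps(_clean({
        **stamp,
        "W_std": std.W_std,
        "muscle_labels": std.muscle_labels,
        "participant_support": std.participant_support,
        "area_labels": std.area_labels,
        "n_standard": std.n_synergies,
        "healthy_synergy_counts": result.healthy_k,
    }), indent=1))

    (out / "taskmap.json").write_text(json.dumps(_clean({
        **stamp,
        "freq": {g: m.freq for g, m in result.freq_by_group.items()},
        "n_trials": {g: m.n_trials for g, m in result.freq_by_group.items()},
        "difference_vs_healthy": result.differences,
    }), indent=1))

    trials_by_idx = {t.recording_index: t for t in result.trials}
    merging_rows = []
    for i, res in result.merging.items():
        t = trials_by_idx[i]
        merging_rows.append({
            "subject_id": t.subject_id, "trial_index": t.trial_index,
            "fma_score": t.fma_score, "merging_rate": res.merging_rate,
            "merge_counts": res.merge_counts,
            "per_task": result.per_task[i],
        })
    (out / "merging.json").write_text(json.dumps(_clean({
        **stamp,
        "stroke": merging_rows,
        "healthy_reference": [
            {"subject_id": trials_by_idx[i].subject_id,
             "merging_rate": r.merging_rate}
            for i, r in result.merging_healthy.items()
        ],
    }), indent=1))

    screen_doc = {}
    for series, entries in result.screen.items():
        screen_doc[str(series)] = {
            "slope": result.regression[series].slope,
            "p_incline": result.regression[series].p_incline,
            "per_task": [
                None if e is None else {
                    "slope": e.slope, "p": e.p_incline,
                    "removed": e.removed_subjects,
                    "assumptions_met": e.assumptions_met,
                    "diagnostics": e.diagnostics,
                }
                for e in entries
            ],
            "retained_items": result.subset[series].retained,
            "removed_items": result.subset[series].removed,
            "missing_items": result.subset[series].missing,
            "duration_reduction_pct": result.reduction_pct[series],
        }
    (out / "screen.json").write_text(json.dumps(_clean({**stamp, **screen_doc}),
                                                indent=1))
    (out / "report.json").write_text(json.dumps(_clean({
        **stamp,
        "n_trials": len(result.trials),
        "n_standard": std.n_synergies,
        "healthy_k_mean": float(np.mean(result.healthy_k)),
    }), indent=1))
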