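"""Synthetic EMG cohort generator with planted synergy ground truth.

The generator emulates the statistical structure the analysis assumes: each
trial's envelope is a non-negative mixture ``G = W_true @ H`` of
region-sparse spatial synergies driven by smooth per-epoch temporal bumps;
the raw signal is a band-limited white carrier amplitude-modulated by the
envelope, plus low-frequency drift and additive sensor noise.  Stroke
subjects are modelled by merging disjoint pairs of planted synergies (the
merged synergy is the renormalised sum, driven by both activations) at a
rate keyed to an FMA-like score, and by attenuating posterior-trunk
activations in severe subjects.

Ground truth (planted synergies, task-activity table, per-subject merge
schedules) is carried alongside the cohort so every downstream stage can be
tested for parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .io import write_emg_recording, write_manifest
from .muscles import DEFAULT_AREA_MAP, DEFAULT_MUSCLE_LABELS
from .types import (
    EMGRecording,
    SubjectRecord,
    TaskEpoch,
    TaskEpochs,
    N_TASK_ITEMS,
    FMA_MAX,
)


class SimConfigError(ValueError):
    pass


@dataclass
class NoiseConfig:
    """Carrier, drift and noise levels of the raw-signal model.

    ``activation_noise_sd`` sets smooth dip-shaped variability of each
    synergy's temporal drive as a whole (central motor-output fluctuations,
    correlated across the synergy's muscles; dips rather than spikes so a
    synergy's peak activation stays at its planned level).
    ``channel_dropout_depth`` sets bounded multiplicative variability per
    muscle — a smooth factor with uniform marginal on ``[1-depth, 1]``
    (peripheral variability the synergy model does not capture; bounded
    above so peak levels are preserved).  ``snr_db`` sets the additive
    broadband sensor-noise floor relative to the envelope RMS.
    """

    carrier_low_hz: float = 20.0
    carrier_high_hz: float = 450.0
    snr_db: float = 30.0            # envelope power over sensor-noise power
    activation_noise_sd: float = 0.15  # depth scale of per-synergy drive dips
    channel_dropout_depth: float = 0.95  # depth of per-muscle dropout factor
    envelope_noise_hz: float = 8.0   # bandwidth of the smooth noise terms
    drift_amplitude: float = 0.05   # fraction of the peak envelope
    drift_hz: float = 0.05


# (area, number of planted synergies in that area)
DEFAULT_SYNERGY_PLAN: tuple[tuple[str, int], ...] = (
    ("upper arm", 2),
    ("forearm", 2),
    ("finger/thumb", 1),
    ("chest", 2),
    ("abdomen", 3),
    ("posterior trunk", 3),
)


@dataclass
class SimulationConfig:
    sampling_rate: float = 1000.0
    epoch_duration_s: float = 0.8    # nominal task-item duration
    epoch_jitter_s: float = 0.2
    gap_duration_s: float = 0.2      # inter-item rest
    synergy_plan: tuple[tuple[str, int], ...] = DEFAULT_SYNERGY_PLAN
    n_healthy: int = 7
    healthy_trial_counts: tuple[int, ...] = (4, 3, 3, 3, 3, 3, 3)   # 22 trials
    n_stroke: int = 20
    stroke_trials: int = 2
    fma_min: int = 6
    fma_max: int = 66
    posterior_attenuation: float = 0.5   # severe-subject trunk gain
    amplitude_sigma: float = 0.1         # log-normal bump amplitude spread
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    @property
    def k_true(self) -> int:
        return sum(n for _, n in self.synergy_plan)

    def validate(self) -> None:
        if self.k_true > len(DEFAULT_MUSCLE_LABELS):
            raise SimConfigError("more planted synergies than muscles")
        if self.sampling_rate < 2 * self.noise.carrier_high_hz:
            raise SimConfigError(
                "sampling_rate must be at least twice the carrier top frequency"
            )
        if len(self.healthy_trial_counts) != self.n_healthy:
            raise SimConfigError("one trial count required per healthy subject")


@dataclass
class TrueSynergyModel:
    """Planted spatial synergies, task-activity truth table and provenance."""

    W_true: np.ndarray              # (41, K), unit-norm, region-sparse
    task_truth: np.ndarray          # bool (K, 37)
    muscle_labels: list[str]
    synergy_areas: list[str]        # home area per synergy
    posterior_indices: list[int]    # synergies whose home is the posterior trunk
    tonic_indices: list[int] = field(default_factory=list)  # sustained drive
    seed: int = 0

    @property
    def k_true(self) -> int:
        return self.W_true.shape[1]


@dataclass
class StrokeModelParams:
    fma_score: int
    posterior_attenuation: float = 0.5

    def n_merges(self, k_true: int) -> int:
        """Merge count: floor(x + 0.5) of (66-FMA)/66 * K/2, capped at K//2."""
        x = max(0.0, (FMA_MAX - self.fma_score) / FMA_MAX) * k_true / 2.0
        return min(int(np.floor(x + 0.5)), k_true // 2)


@dataclass
class SubjectSynergySet:
    """One subject's effective synergies: groups of planted synergies.

    Healthy subjects have singleton groups (their synergies are the planted
    ones); stroke subjects have ``n_merges`` two-element groups whose
    spatial vector is the renormalised sum of the pair.
    """

    W: np.ndarray                   # (41, K_subject), unit-norm columns
    groups: list[list[int]]         # planted synergy indices per column
    gains: np.ndarray               # (K_true,) temporal gain per planted synergy


def _default_task_truth(k: int) -> np.ndarray:
    """Structured synergy-task table mirroring the assessment's sequence.

    Arm synergies dominate early items, forearm the middle, finger/thumb the
    late items; trunk synergies span broad ranges and one posterior-trunk
    synergy (index 11 of 13) is active in every item.
    """
    truth = np.zeros((k, N_TASK_ITEMS), dtype=bool)
    if k != 13:
        # generic fallback: contiguous disjoint item blocks covering the
        # whole sequence, so every synergy carries an equal, separable share
        bounds = np.linspace(0, N_TASK_ITEMS, k + 1).round().astype(int)
        for s in range(k):
            truth[s, bounds[s]:bounds[s + 1]] = True
        return truth

    def items(ids):
        return [i - 1 for i in ids]

    # item sets are kept nearly disjoint between synergies (aside from the
    # always-on trunk synergy) so each synergy carries distinct variance
    truth[0, items(range(2, 8))] = True                       # upper arm, early
    truth[1, items(range(8, 14))] = True
    truth[2, items(range(14, 20))] = True                     # forearm, middle
    truth[3, items(range(20, 26))] = True
    truth[4, items(range(31, 37))] = True                     # finger/thumb, late
    truth[5, items([1, 6, 12, 18, 26, 33])] = True            # chest
    truth[6, items([3, 8, 15, 22, 29, 36])] = True
    truth[7, items([2, 10, 16, 23, 30, 37])] = True           # abdomen
    truth[8, items([4, 9, 17, 24, 31, 35])] = True
    truth[9, items([5, 11, 19, 27, 32, 34])] = True
    truth[10, items([1, 3, 7, 13, 21, 28, 36])] = True        # posterior trunk
    truth[11, :] = True                                       # always on
    truth[12, items([2, 6, 14, 20, 25, 29, 35, 37])] = True
    return truth


def generate_ground_truth(config: SimulationConfig | None = None,
                          seed: int = 0) -> TrueSynergyModel:
    """Draw the planted synergy basis and task-activity table.

    Each synergy concentrates its weight on a subset of its home region's
    muscles (at least 70% of the squared norm in-region), with light bleed
    onto a few out-of-region muscles.  Deterministic given the seed.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    labels = DEFAULT_MUSCLE_LABELS
    idx_of = {m: i for i, m in enumerate(labels)}
    cols, areas = [], []
    for area, count in config.synergy_plan:
        region_labels = list(DEFAULT_AREA_MAP[area])
        if area == "posterior trunk":
            # neck muscles ride with the posterior trunk so no channel is
            # left without genuine synergy participation
            region_labels += DEFAULT_AREA_MAP["other"]
        region = [idx_of[m] for m in region_labels]
        out_pool = [i for i in range(len(labels)) if i not in region]
        # between 3 and 6 primary muscles per synergy: small subsets are
        # drowned by per-muscle variability, very large ones skew the
        # variance shares across synergies
        size = max(3, min(len(region) // count, 6))
        for j in range(count):
            w = np.zeros(len(labels))
            # staggered primary subsets: disjoint where the region is large
            # enough, minimally overlapping otherwise, always >= 3 muscles
            offset = (j * len(region)) // count
            primary = [region[(offset + i) % len(region)] for i in range(size)]
            w[primary] = rng.uniform(0.6, 1.0, size=len(primary))
            secondary = [i for i in region if i not in primary]
            w[secondary] = rng.uniform(0.0, 0.08, size=len(secondary))
            bleed = rng.choice(out_pool, size=3, replace=False)
            w[bleed] = rng.uniform(0.0, 0.07, size=3)
            # enforce the in-region energy floor
            in_region = np.zeros_like(w, dtype=bool)
            in_region[region] = True
            e_in = np.sum(w[in_region] ** 2)
            e_out = np.sum(w[~in_region] ** 2)
            if e_out > 0 and e_in / (e_in + e_out) < 0.7:
                w[~in_region] *= np.sqrt(e_in * 3 / (7 * e_out))
            cols.append(w / np.linalg.norm(w))
            areas.append(area)
    W = np.column_stack(cols)
    truth = _default_task_truth(config.k_true)
    posterior = [i for i, a in enumerate(areas) if a == "posterior trunk"]
    # synergies recruited by (nearly) every item are modelled as tonic
    # postural drive rather than per-item bursts
    tonic = [int(i) for i in np.flatnonzero(truth.sum(axis=1) >= 30)]
    return TrueSynergyModel(
        W_true=W,
        task_truth=truth,
        muscle_labels=list(labels),
        synergy_areas=areas,
        posterior_indices=posterior,
        tonic_indices=tonic,
        seed=seed,
    )


def apply_stroke_model(truth: TrueSynergyModel, params: StrokeModelParams,
                       seed: int = 0) -> SubjectSynergySet:
    """Build a stroke subject's synergy set by merging planted pairs.

    ``n_merges`` disjoint pairs (drawn without replacement) are each replaced
    by the renormalised sum of the pair; the remaining synergies are kept.
    Severe subjects (FMA < 30) get their posterior-trunk activations
    attenuated.
    """
    k = truth.k_true
    n_merges = params.n_merges(k)
    if 2 * n_merges > k:
        raise SimConfigError("merge count exceeds the available synergy pairs")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    order = rng.permutation(k)
    groups: list[list[int]] = []
    for m in range(n_merges):
        groups.append(sorted(order[2 * m: 2 * m + 2].tolist()))
    for i in sorted(order[2 * n_merges:].tolist()):
        groups.append([i])
    cols = []
    for g in groups:
        v = truth.W_true[:, g].sum(axis=1)
        cols.append(v / np.linalg.norm(v))
    gains = np.ones(k)
    if params.fma_score < 30:
        gains[truth.posterior_indices] = params.posterior_attenuation
    return SubjectSynergySet(W=np.column_stack(cols), groups=groups, gains=gains)


def healthy_synergy_set(truth: TrueSynergyModel) -> SubjectSynergySet:
    return SubjectSynergySet(
        W=truth.W_true.copy(),
        groups=[[i] for i in range(truth.k_true)],
        gains=np.ones(truth.k_true),
    )


def _raised_cosine_bump(n: int, center: float, width: int,
                        flat_fraction: float = 0.7) -> np.ndarray:
    """Flat-topped bump with raised-cosine tapers (Tukey-like profile).

    ``width`` frames wide, centred at ``center`` within an ``n``-frame epoch;
    the central ``flat_fraction`` of the bump sits at 1 so task-level mean
    activation stays high relative to the peak.
    """
    t = np.arange(n)
    half = width / 2.0
    u = np.abs(t - center) / half
    out = np.zeros(n)
    flat = u <= flat_fraction
    taper = (u > flat_fraction) & (u < 1)
    out[flat] = 1.0
    v = (u[taper] - flat_fraction) / (1 - flat_fraction)
    out[taper] = 0.5 * (1 + np.cos(np.pi * v))
    return out


def _planted_activations(truth: TrueSynergyModel, epochs: TaskEpochs,
                         n_frames: int, amplitude_sigma: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Smooth per-epoch temporal bumps for every planted synergy."""
    H = np.zeros((truth.k_true, n_frames))
    # equalise total activation energy across synergies so each planted
    # synergy carries a comparable share of envelope variance regardless of
    # how many items recruit it; broadly recruited (tonic, postural)
    # synergies get a boost because much of their variance is shared with
    # co-active synergies
    n_items = truth.task_truth.sum(axis=1).astype(float)
    scale = 1.0 / np.sqrt(np.maximum(n_items, 1.0))
    tonic = set(truth.tonic_indices)
    # postural synergies are recruited at amplitudes comparable to the
    # phasic bursts, not scaled down by their item count
    typical = np.median(scale[[s for s in range(truth.k_true) if s not in tonic]]) \
        if len(tonic) < truth.k_true else 1.0
    for s in tonic:
        scale[s] = 0.85 * typical
    for e in epochs:
        n = e.n_frames
        for s in range(truth.k_true):
            if s in tonic or not truth.task_truth[s, e.item_id - 1]:
                continue
            width = int(n * rng.uniform(0.8, 0.95))
            center = rng.uniform(0.45, 0.55) * n
            amp = scale[s] * rng.lognormal(mean=0.0, sigma=amplitude_sigma)
            H[s, e.start_frame:e.end_frame] += amp * _raised_cosine_bump(
                n, center, max(width, 2)
            )
    # postural synergies recruited by every item: activation peaks at epoch
    # edges (stabilisation around movement onset and offset), so their time
    # course is complementary to the mid-epoch bursts of the phasic
    # synergies rather than a blend of them
    for s in tonic:
        for e in epochs:
            n = e.n_frames
            # postural amplitude is steadier than phasic bursts
            amp = scale[s] * rng.lognormal(mean=0.0, sigma=0.5 * amplitude_sigma)
            w = max(int(n * rng.uniform(0.72, 0.88)), 2)
            onset = _raised_cosine_bump(n, 0.08 * n, w)
            offset = _raised_cosine_bump(n, 0.92 * n, w)
            H[s, e.start_frame:e.end_frame] += amp * np.maximum(onset, offset)
    return H


def _bandlimited_carrier(shape: tuple[int, int], low: float, high: float,
                         fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-rectified-mean band-limited white noise, one column per muscle."""
    white = rng.standard_normal(shape)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    car = signal.sosfiltfilt(sos, white, axis=0)
    mean_abs = np.mean(np.abs(car), axis=0)
    return car / np.where(mean_abs > 0, mean_abs, 1.0)


def _make_epochs(config: SimulationConfig, rng: np.random.Generator
                 ) -> tuple[TaskEpochs, int]:
    fs = config.sampling_rate
    gap = int(round(config.gap_duration_s * fs))
    items, cursor = [], gap
    for item in range(1, N_TASK_ITEMS + 1):
        dur = config.epoch_duration_s + rng.uniform(
            -config.epoch_jitter_s, config.epoch_jitter_s
        )
        n = max(int(round(dur * fs)), 2)
        items.append(TaskEpoch(item, cursor, cursor + n))
        cursor += n + gap
    return TaskEpochs(items), cursor


def simulate_trial(subject: SubjectSynergySet, truth: TrueSynergyModel,
                   config: SimulationConfig, seed: int,
                   subject_id: str, trial_index: int,
                   group: str, fma_score: int | None,
                   return_envelope: bool = False):
    """Synthesise one raw EMG trial from a subject's synergy set.

    The planted activations drive the subject's (possibly merged) synergies;
    the resulting envelope modulates a band-limited carrier, and drift plus
    additive sensor noise complete the raw signal.  Deterministic given the
    seed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    epochs, n_frames = _make_epochs(config, rng)
    H_true = _planted_activations(truth, epochs, n_frames,
                                  config.amplitude_sigma, rng)
    H_true *= subject.gains[:, None]
    # subject synergy activation = sum of its group members' activations
    H_subj = np.vstack([H_true[g].sum(axis=0) for g in subject.groups])
    G = (subject.W @ H_subj).T          # (frames, muscles), >= 0

    nz = config.noise
    lp = signal.butter(2, nz.envelope_noise_hz, btype="lowpass",
                       fs=config.sampling_rate, output="sos")
    if nz.activation_noise_sd > 0:
        # smooth dip-shaped drive variability, shared by the synergy's muscles
        eta = signal.sosfiltfilt(lp, rng.standard_normal(H_subj.T.shape), axis=0)
        eta = np.abs(eta) * (nz.activation_noise_sd / max(eta.std(), 1e-12))
        H_subj = H_subj * np.clip(1.0 - eta.T, 0.05, 1.0)
        G = (subject.W @ H_subj).T
    if nz.channel_dropout_depth > 0:
        # bounded multiplicative dropout per muscle: a smooth process with a
        # uniform marginal on [1-depth, 1] (Gaussian copula).  Bounded above
        # by 1, it leaves each muscle's peak level intact while carrying a
        # large per-frame variance that is independent across muscles and so
        # cannot be compressed into a few extra components.
        from scipy.special import ndtr
        z = signal.sosfiltfilt(lp, rng.standard_normal(G.shape), axis=0)
        z_std = z.std(axis=0)
        z /= np.where(z_std > 0, z_std, 1.0)
        u = 1.0 - nz.channel_dropout_depth * ndtr(z)
        G = G * u
    carrier = _bandlimited_carrier(G.shape, nz.carrier_low_hz,
                                   nz.carrier_high_hz, config.sampling_rate, rng)
    raw = G * carrier
    peak = G.max() if G.max() > 0 else 1.0
    t = np.arange(n_frames) / config.sampling_rate
    phases = rng.uniform(0, 2 * np.pi, size=G.shape[1])
    drift = nz.drift_amplitude * peak * np.sin(
        2 * np.pi * nz.drift_hz * t[:, None] + phases[None, :]
    )
    rms = np.sqrt(np.mean(G**2))
    noise_std = rms / (10 ** (nz.snr_db / 20.0))
    raw = raw + drift + noise_std * rng.standard_normal(G.shape)
    rec = EMGRecording(
        subject_id=subject_id,
        trial_index=trial_index,
        group=group,
        fma_score=fma_score,
        sampling_rate=config.sampling_rate,
        muscle_labels=list(truth.muscle_labels),
        samples=raw,
        epochs=epochs,
    )
    if return_envelope:
        # realised (post-variability) envelope: the ground truth that the
        # preprocessing stage should recover up to scale
        return rec, G
    return rec


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground-truth sidecar."""

    recordings: list[EMGRecording]
    subjects: list[SubjectRecord]
    truth: TrueSynergyModel
    subject_sets: dict[str, SubjectSynergySet]
    merge_schedule: dict[str, int]      # subject_id -> planted merge count
    config: SimulationConfig
    seed: int


def simulate_cohort(config: SimulationConfig | None = None, seed: int = 42
                    ) -> SyntheticCohort:
    """Generate the default cohort: 22 healthy trials (7 subjects) and
    40 stroke trials (20 subjects, two trials each, FMA spread over 6..66)."""
    config = config or SimulationConfig()
    config.validate()
    truth = generate_ground_truth(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))

    recordings: list[EMGRecording] = []
    subjects: list[SubjectRecord] = []
    subject_sets: dict[str, SubjectSynergySet] = {}
    merge_schedule: dict[str, int] = {}
    trial_seed = 0

    for h in range(config.n_healthy):
        sid = f"H{h + 1:02d}"
        sset = healthy_synergy_set(truth)
        subject_sets[sid] = sset
        merge_schedule[sid] = 0
        n_trials = config.healthy_trial_counts[h]
        for tr in range(1, n_trials + 1):
            trial_seed += 1
            recordings.append(simulate_trial(
                sset, truth, config, seed=int((seed * 10007 + trial_seed) % 2**31),
                subject_id=sid, trial_index=tr, group="healthy", fma_score=None,
            ))
        subjects.append(SubjectRecord(sid, "healthy", None, n_trials))

    # FMA scores uniform over the configured range; redraw until both
    # severity classes are populated (deterministic given the seed)
    while True:
        scores = rng.integers(config.fma_min, config.fma_max + 1,
                              size=config.n_stroke)
        if (scores < 30).any() and (scores >= 30).any():
            break
    for p in range(config.n_stroke):
        sid = f"S{p + 1:02d}"
        fma = int(scores[p])
        params = StrokeModelParams(
            fma_score=fma, posterior_attenuation=config.posterior_attenuation
        )
        sset = apply_stroke_model(truth, params,
                                  seed=int((seed * 131 + p) % 2**31))
        subject_sets[sid] = sset
        merge_schedule[sid] = params.n_merges(truth.k_true)
        for tr in range(1, config.stroke_trials + 1):
            trial_seed += 1
            recordings.append(simulate_trial(
                sset, truth, config, seed=int((seed * 10007 + trial_seed) % 2**31),
                subject_id=sid, trial_index=tr, group="stroke", fma_score=fma,
            ))
        subjects.append(SubjectRecord(sid, "stroke", fma, config.stroke_trials))

    _attach_item_durations(recordings, subjects)
    return SyntheticCohort(
        recordings=recordings, subjects=subjects, truth=truth,
        subject_sets=subject_sets, merge_schedule=merge_schedule,
        config=config, seed=seed,
    )


def _attach_item_durations(recordings: list[EMGRecording],
                           subjects: list[SubjectRecord]) -> None:
    """Record each subject's mean per-item duration in seconds."""
    by_subject: dict[str, list[np.ndarray]] = {}
    for rec in recordings:
        durs = np.array([e.n_frames for e in rec.epochs]) / rec.sampling_rate
        by_subject.setdefault(rec.subject_id, []).append(durs)
    for s in subjects:
        if s.subject_id in by_subject:
            s.item_durations = np.mean(by_subject[s.subject_id], axis=0).tolist()


def generate_cohort(config: SimulationConfig | None = None, seed: int = 42,
                    out_dir=None) -> SyntheticCohort:
    """Generate a cohort and, if ``out_dir`` is given, write trials, the
    manifest, and the ground-truth sidecar (``ground_truth.json``)."""
    cohort = simulate_cohort(config, seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trials = []
        for rec in cohort.recordings:
            stem = f"{rec.subject_id}_t{rec.trial_index}"
            write_emg_recording(rec, out / f"{stem}.csv", out / f"{stem}.meta.json")
            trials.append((f"{stem}.csv", f"{stem}.meta.json"))
        write_manifest(out / "cohort.manifest.json", trials, cohort.subjects)
        sidecar = {
            "seed": cohort.seed,
            "k_true": cohort.truth.k_true,
            "W_true": cohort.truth.W_true.tolist(),
            "task_truth": cohort.truth.task_truth.astype(int).tolist(),
            "synergy_areas": cohort.truth.synergy_areas,
            "merge_schedule": cohort.merge_schedule,
            "subject_groups": {
                sid: sset.groups for sid, sset in cohort.subject_sets.items()
            },
        }
        (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
    return cohort
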