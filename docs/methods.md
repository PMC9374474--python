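# Methods

`synfma` implements a muscle-synergy analysis of the upper-extremity
Fugl-Meyer Assessment (FMA): 37 task items performed in sequence while
surface EMG is recorded from 41 muscles of the arm, hand and trunk. This
note documents the model at each stage, the tunable parameters and their
defaults, the synthetic-cohort generator and what it does and does not
emulate, and the numerical and design choices that were genuinely open.

## Envelope extraction

Raw EMG is modelled as a broadband interference signal amplitude-modulated
by a non-negative activation envelope. The default processing chain is a
zero-phase 4th-order Butterworth high-pass at 0.1 Hz (drift/offset
removal), full-wave rectification, and a zero-phase 4th-order Butterworth
low-pass at 20 Hz (demodulation). Rectification must sit between the two
filters: the EMG carrier lives far above 20 Hz, so low-passing first would
remove the signal rather than smooth it. A literal filters-then-rectify
order (`hp_lp_rect`) is selectable for sensitivity analyses. Each muscle is
then normalised by its maximum over the full task sequence, so amplitudes
are comparable across muscles and sessions; all-zero channels are kept (as
zero) so the muscle dimension is stable across trials.

For factorisation the envelope is decimated by block averaging to 25 Hz
(any integer divisor of the sampling rate is accepted) and only the
epoch-covered frames are used, concatenated in item order. Synergy
structure lives well below 10 Hz, and the decimation keeps the default
62-trial cohort analysis at desk scale.

## Synergy extraction and model order

The concatenated envelope `E` (frames × muscles) is factorised as
`E ≈ (W H)ᵀ` with `W` (muscles × K) the spatial synergies and `H`
(K × frames) their temporal coefficients, both non-negative. The criterion
is the uncentred variance accounted for,

    VAF = 1 − ‖E − (W H)ᵀ‖²_F / ‖E‖²_F ,

and the number of synergies is the smallest K with VAF > 0.8 (threshold
configurable; the sensitivity grid 0.8/0.85/0.9 is supported).

Factorisation uses multiplicative updates for the Frobenius objective with
20 random restarts (uniform non-negative initialisation; restart *i* draws
from seed + *i*), a relative-objective convergence tolerance of 1e-6
checked every 10 iterations, and at most 1000 iterations. The best restart
by VAF wins; ties go to the lowest restart index, so a seed fully
determines the result. Columns of `W` are rescaled to unit Euclidean norm
with the scale folded into `H`.

Model-order search scans K upward from 1 but first computes the singular
value spectrum of `E`: the rank-K truncated SVD is the unconstrained
optimum, so its cumulative energy share upper-bounds the NMF VAF at K, and
any K whose bound already fails the threshold is skipped without fitting.
This changes nothing about which K is selected and roughly halves the cost
of the search.

## Standard synergies

All spatial synergies from every healthy trial (healthy subjects repeat the
full sequence three or four times, and all repetitions enter) are pooled
and clustered by average-linkage agglomerative clustering on the cosine
distance `1 − cos`, cut at distance 0.25. A cluster whose members come from
strictly more than half of the healthy participants (participants, not
trials) defines one standard synergy; its representative is the
renormalised element-wise mean of the member vectors. Each standard synergy
is labelled with the anatomical areas of its dominant muscles — those whose
weight exceeds 50% (configurable 40–60%) of the synergy's maximum weight —
majority area first.

Linkage, metric and cut rule are conventional for the synergy literature
and are exposed in configuration; nothing in the analysis depends on the
clusters beyond the majority rule and the representatives.

## Synergy–task relationship

With the spatial basis fixed (the standard set, or a patient's own
synergies), each envelope frame is fitted by non-negative least squares.
Coefficient rows are rescaled to a per-synergy maximum of 1, making the
activity threshold scale-free; rows whose maximum is numerical dust
(< 1e-12 of the global maximum) are treated as silent rather than
amplified. A synergy is *active* in an item when its epoch-averaged
coefficient strictly exceeds 0.3 (sweep grid 0.1/0.2/0.4/0.5 supported —
the active set is monotone non-increasing in the threshold). Group maps
report the fraction of trials in which each synergy was active per item,
and group differences are element-wise patient-minus-healthy fractions.

## Merging analysis

Each unit-norm patient synergy is decomposed by NNLS onto the standard
basis; the merge count is the number of coefficients strictly above 0.1
(sweep 0.08–0.12 supported), and a trial's merging rate is the mean count
over represented synergies (count ≥ 1; non-represented synergies are
reported and excluded, NaN if none remain). Per-item merging rates average
the counts of the patient synergies active in that item (activity from the
patient's own rescaled coefficients); items with no active represented
synergy are missing, mirroring the grey cells of the study-style matrices.
The NNLS coefficient vector is unconstrained (no sum constraint); the
reconstruction cosine between the synergy and `W_std · c` is reported and
an optional minimum-cosine exclusion is available but off by default.

## Statistical evaluation

Severity classes: severe is FMA < 30, mild is FMA ≥ 30.

The merging-rate-versus-FMA relationship is fitted by robust linear
regression with Tukey bisquare weights (tuning constant 4.685) by
iteratively reweighted least squares: scale is the MAD (normal-consistent,
excluding the two smallest absolute residuals — they are pinned by the
2-parameter fit), residuals are leverage-adjusted by 1/√(1−h), and
convergence is a relative coefficient change below 1e-8 (flagged after 100
iterations). The slope P-value uses the asymptotic M-estimator covariance
with Huber's small-sample correction, referred to a t distribution with
n − 2 degrees of freedom. Under a normal null at n = 20 this is calibrated
to within Monte-Carlo error of the nominal 5% level.

Residual diagnostics are Breusch–Pagan (homoskedasticity), Durbin–Watson
with the N(2, 4/n) approximation (independence), and Anderson–Darling
(normality), all applied to the leverage-adjusted residuals. The per-item
screen refits after removing, at most twice, the subject with the largest
influence on the slope — the largest absolute leave-one-out slope change
(OLS DFBETA) — whenever any diagnostic P ≤ 0.05. Influence, not raw
residual size, decides the removal: a planted gross outlier is still the
most influential point and is removed exactly, but repeatedly truncating
the largest residual systematically shrinks the scale estimate and
inflates the screen's null type-I rate beyond its nominal level, while
influence-based removal leaves it calibrated. If assumptions still fail
after two removals the entry is flagged and retained.

Group comparisons use one-way ANOVA with Tukey–Kramer pairwise comparisons
(studentized range, honouring unequal group sizes), additive two-way ANOVA
for body-region × participant-type effects, and Student t-tests (Welch
selectable). No multiple-testing correction is applied across the 37
per-item regressions; raw P bands (0.05, 0.01) are reported. Items with
P ≥ 0.05 (or with no evaluable data) are removal candidates, and the time
saving is the removed items' share of the summed mean item durations.
Trial series 1 and 2 are screened separately.

## Synthetic cohort generator

No public EMG corpus matches this protocol, so the generator produces
cohorts with the statistical structure the analysis assumes, with full
ground truth for every downstream stage. Defaults mirror the study design:
7 healthy participants (one with 4 trials, six with 3; 22 trials) and 20
stroke subjects with 2 trials each (40 trials), 41 muscles, 37 items, FMA
scores drawn uniformly on {6..66} with both severity classes guaranteed.

**Spatial model.** Thirteen planted synergies: upper arm ×2, forearm ×2,
finger/thumb ×1, chest ×2, abdomen ×3, posterior trunk ×3. Each synergy
concentrates ≥ 70% of its squared norm on a staggered subset (≥ 3 muscles)
of its home region, with light bleed elsewhere; the two neck muscles ride
with the posterior trunk so no channel lacks genuine synergy content
(a pure-noise channel, max-normalised, would otherwise spawn a spurious
cluster).

**Temporal model.** Phasic synergies are recruited in nearly disjoint item
sets that follow the assessment's sequence (shoulder/arm early, forearm
middle, finger/thumb late; trunk synergies scattered throughout), with one
posterior-trunk synergy recruited by every item. Within an active epoch a
synergy follows a flat-topped raised-cosine burst (duty ~0.8–0.95) with
log-normal amplitude. Per-synergy energies are equalised across item
counts so every synergy carries a recoverable variance share. The always
recruited synergy is modelled as postural activity peaking at epoch edges
(stabilisation around movement onset and offset) with a steadier
amplitude: a flat tonic profile is *non-identifiable* — it lies in the
non-negative span of the phasic rows and any factorisation absorbs it —
whereas the edge-peaked profile is temporally complementary to the
mid-epoch bursts.

**Noise model.** Three components: (i) mild smooth dip-shaped variability
of each synergy's drive as a whole (central motor-output fluctuation,
shared across the synergy's muscles; SD 0.15); (ii) bounded multiplicative
dropout per muscle — a smooth process (≈8 Hz bandwidth) with uniform
marginal on [1−d, 1], default depth d = 0.95 — representing peripheral
variability the synergy model does not capture. Boundedness matters: the
activity rule thresholds epoch means against the per-synergy coefficient
*maximum*, and any unbounded noise inflates that maximum until the
threshold rule breaks at noise levels far below those needed to drive the
VAF model order; bounded dropout carries the required unexplained variance
while leaving peak levels intact. (iii) A broadband sensor floor 30 dB
below the envelope RMS (the rectified floor is deliberately small: its
near-constant baseline is a rank-one structure that low-order fits exploit,
which biases the model order downward). The raw signal is the envelope
modulating a band-limited white carrier (20–450 Hz at 1 kHz sampling) plus
slow sinusoidal drift (removed by the 0.1 Hz high-pass).

**Stroke model.** A subject with FMA score f merges
`n = floor((66−f)/66 · K/2 + 0.5)` disjoint random pairs of planted
synergies (capped at ⌊K/2⌋; half-up rounding fixed to avoid platform
ambiguity): each pair is replaced by the renormalised sum, driven by both
activations. Severe subjects (f < 30) additionally have posterior-trunk
activations attenuated by 0.5, emulating reduced trunk-stability drive.

**What the generator does not emulate** — and hence what passing tests do
not establish about real recordings: electrode crosstalk and electrode
shift, movement artifacts, task-dependent synergy reorganisation (planted
spatial synergies are fixed within a subject), compensatory recruitment of
*new* synergies after stroke (only merging and attenuation are modelled),
inter-subject anatomical variability of the synergy vectors themselves
(all subjects share one planted basis), and realistic item semantics
(item durations ~0.8 s rather than the clinical ~15 s, and the
task-synergy table is structured but synthetic).

**Problem sizes.** Default epochs are 0.8 ± 0.2 s at 1 kHz with 0.2 s
inter-item rest (≈ 37 s per trial), and factorisation runs on the 25 Hz
envelope (~750 frames per trial). These sizes make the full 62-trial
pipeline a minutes-scale computation while leaving every recovery property
intact; they are the package's standing test conditions, not tuned per
experiment.

## Known limitations

- The VAF model-order rule on realistic envelopes has ±1 trial-to-trial
  spread; the healthy consensus (standard set) is the stable quantity, and
  per-trial synergy counts should be read with that spread in mind.
- The Durbin–Watson P-value is a normal approximation; exact distributions
  (Imhof) are out of scope.
- The robust-regression P-value is asymptotic with small-sample
  corrections; it is calibrated at the cohort sizes used here but has no
  exact finite-sample guarantee.
- The screen's outlier handling follows the source procedure (up to two
  removals, diagnostics-driven); it is calibrated under a clean null but,
  like any data-driven removal, is not exact.
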