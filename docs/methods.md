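# Methods

This note documents the models, conventions, and design choices behind
the pipeline, in the order the data flows.

## Synthetic EMG model

Each electrode channel is simulated as

    x_c(t) = e_m(t) · g_{c,m} · s_c · w_c(t) + n_c(t)

where `w_c` is unit-RMS Gaussian noise band-limited to 100–500 Hz (the
energy band of volitional EMG; a 4th-order Butterworth applied
forward-backward), `g_{c,m}` is the channel's full-effort EMG RMS (µV)
for movement `m`, `s_c` a per-session amplitude factor, `e_m(t)` a
trapezoidal activation envelope, and `n_c` an independent band-limited
noise floor at the channel's resting RMS. Because carrier and noise are
independent, a plateau segment has RMS `sqrt((g·s)² + noise²)` — the
property the generator's tests check directly.

Choices worth stating:

- **Noise floor in-band.** The resting noise is generated inside the
  analysis band and normalised to its configured RMS (default 1.43 µV,
  the stable median resting level of implanted bipolar electrodes, with
  an IQR of ~0.4 µV). The configured value is therefore exactly what the
  decoding path and any resting-RMS measurement see after band-pass
  filtering; a broadband floor would lose most of its power at the
  filter and make the configured level meaningless downstream.
- **Envelope.** Rise time defaults to 200 ms; the plateau is held to the
  trial boundary (fall time defaults to 0, configurable), with the
  inter-trial rest gap supplying the rest segment. Holding the plateau to
  the boundary keeps the movement-labelled samples representative of
  full effort, so calibration statistics estimate plateau parameters
  rather than a rise-diluted mixture.
- **Activation gains.** The default six-channel table (median RPNI,
  ulnar RPNI 1–2, FDL, FDP-index, EDC) encodes the selectivity of
  intramuscular bipolar electrodes: each functional grip is dominated by
  a distinct channel subset at ≥5× contrast, intrinsic-hand movements
  (thumb opposition, finger ab/adduction) load mostly or entirely on the
  RPNI channels (their native muscles are lost to amputation), and the
  classically confusable pairs — abduction vs adduction, neighbouring
  finger flexions — are deliberately close. Magnitudes sit in the tens
  of µV, matching the reported between-session median EMG RMS (~40 µV).
- **Session drift.** Each session draws one multiplicative factor per
  channel, i.i.d. lognormal(0, σ²), default σ = 0.5 — a relative spread
  consistent with a between-session EMG-RMS IQR comparable to its
  median. Scaling is per-channel, not per-movement, so the relative
  activation pattern across movements is untouched within a session.
  The calibration session is the baseline and is generated at unit
  scale; decoders are trained there and reused, mirroring the
  one-calibration protocol whose stability the pipeline studies.
- **Effort.** Within-session effort is fixed at full scale (repetitions
  differ only in carrier/noise realisation); effort variability is not
  modelled.
- **Seeding.** One root seed; per-session and per-trial seeds are
  derived by `SeedSequence.spawn`, so any trial is independently
  reproducible and identical configuration + seed yields bit-identical
  arrays.
- **Fast path.** Raw generation defaults to 30 kSps to exercise the
  band-pass + decimation path; generation directly at 1 kSps (carrier
  band capped at 0.45·fs) is used for simulation-heavy experiments,
  since the features the decoder consumes are identical in
  distribution.

What the generator does *not* emulate: motor-unit spike structure,
electrode shift or impedance change, fatigue, effort modulation under
visual feedback, and any arm-position-specific signal change (arm
position is a categorical label only). Passing tests therefore show that
the *analysis* behaves correctly under the stated statistical structure,
not that real tissue behaves like the generator.

## Features and SNR

Preprocessing band-passes 100–500 Hz and decimates by stride to 1 kSps
(the 500 Hz cutoff already satisfies Nyquist). MAV is the mean of
rectified samples in 50 ms non-overlapping bins; trailing partial bins
are discarded, never padded. SNR is RMS during volitional movement
divided by the resting noise-floor RMS, per channel. EMG onset is the
first bin in which any channel's MAV exceeds its resting mean + 3 SD for
two consecutive bins (k and the run length are parameters; the rule is
deliberately simple and is logged with its settings).

## The HMM-NB decoder

Latent states map onto movement classes (`states_per_class` each,
default 1; runs are split into equal temporal chunks when more are
requested). Training is supervised: emissions by per-state per-channel
maximum likelihood with a variance floor (1e-4), transitions from
labelled bin-to-bin counts with add-one smoothing (which keeps the chain
ergodic), uniform initial distribution. Decoding is the causal forward
recursion in log space; the per-bin class posterior sums the filtered
state posteriors, and argmax ties break toward the earliest class in the
class list.

**Emission domain.** Emissions are Gaussian on log-MAV by default.
The reason is the drift model itself: between-session amplitude change
is multiplicative, so in the log domain it is an additive shift whose
size does not depend on a channel's level, and the decoder budgets for
it by adding `drift_tolerance²` (default 0.5², in lognormal-σ units —
the same order as the observed between-session spread) to every
emission variance. Linear-domain Gaussians with variances fitted within
one calibration session are structurally fragile here: a low-gain
channel has a tiny absolute variance, so an ordinary 2–3× amplitude
swing on it produces enormous z-scores, and the class with the largest
means (hence the widest variances) becomes a catch-all for any broadly
elevated pattern. A linear-domain mode (`emission_domain="linear"`,
drift budget `(drift_tolerance·mean)²`) is retained for comparison.
Model parameters are stored in the fitted domain; `mav_means` exposes
the µV-scale emission means (the lognormal mean `exp(µ + σ²/2)` in the
log domain) for parameter-recovery checks and reporting.

The NB and LDA baselines are single-state: per-class diagonal Gaussian
MLE (NB) and pooled within-class covariance with ridge
`ε = 1e-6·trace(Σ)/d` (LDA; an absolute `1e-6·I` fallback keeps
degenerate constant-feature classes invertible). They are retrained
wherever they are used across sessions, so they carry no drift budget.
Per-trial prediction follows the open-loop convention: NB/LDA classify
the trial-averaged MAV vector, the HMM-NB takes the mode of its per-bin
outputs (ties to the earliest-achieved class).

## Virtual task conventions

Trials stream the cued movement after a 500 ms rest lead-in and are
logged for the full 5 s timeout window; a trial succeeds at the first
uninterrupted 1 s run of correct outputs within the window. The analyzed
set T_c runs from EMG onset to the end of the logged window, so
per-timestep accuracy reflects both how fast the decoder locks onto the
cue and how cleanly it holds it; trials without detected onset are
excluded and flagged. Latency is onset to the *start* of the completed
hold (hold start rather than hold completion; configurable via the
logged success bin). Cues are drawn uniformly without immediate
repetition from the non-rest grips — a rest cue has no EMG onset, so its
analyzed window would be empty under the onset-anchored definition. Arm
position is carried as a label on each trial block and may be mapped to
distinct drift factors; no biomechanical model is attached.

## Controller conventions

The grip-selection filter requires a strictly continuous 250 ms
(five-bin) run of a new decoded grip before actuating it; a single bin
of any other class resets the candidate clock. The velocity ramp is
linear over 500 ms, evaluated before the ramp clock advances, so
commanded speed is exactly 0 on the actuation bin and reaches the raw
proportional input only after the full ramp. In the segmented task, a
repetition is scored correct iff the first actuated grip equals the
segment's required grip (no actuation counts as incorrect), the hand is
reset to open between repetitions, and the headline accuracy is reported
both rounded to the nearest integer and unrounded.

## Longitudinal statistics

The trend test is closed-form OLS with the F-test of zero slope
(identically t², verified against `scipy.stats.linregress`); the verdict
is "no-trend" iff p ≥ α (default 0.05), otherwise the slope's sign.
Arm-position comparisons use one-way ANOVA on transition errors per
trial with pairwise pooled-variance t-tests, Bonferroni-multiplied and
capped at 1. The rank-sum comparison uses exact enumeration for pooled
samples of ≤12 tie-free values and the tie-corrected normal
approximation otherwise (backed by `scipy.stats.mannwhitneyu`).

**Ablation.** Channel-subset decoders are retrained per session and
evaluated per trial on the *following* session, averaged unweighted
across evaluations. Held-out-trial evaluation within a single session is
not used when several sessions are available because it is
anti-correlated under the null: removing the held-out trial pulls its
own class mean away from it, which drives null-level accuracy to ~0
rather than 1/n_classes. Cross-session evaluation restores exact
chance-level behaviour for uninformative channel sets and matches the
across-sessions framing of the analysis.

**ICA-PCA.** Trial-level channel features are centred, projected onto
the top two principal components (SVD), and rotated by infomax ICA
within that plane (mne's implementation, seeded). Components are ordered
by projected variance and signed so each component's largest-magnitude
channel loading is positive; channel contribution vectors are the
back-projected loadings `V₂ W⁻¹`.

**F-test calibration.** The type-I-error check simulates the null as
i.i.d. Gaussian session summaries (constant mean accuracy + noise) over
the standard 16-session day grid; the quantity under test is the F-test
itself, so replicating the full decoding pipeline per replicate would
add cost without changing the statistic's null distribution.

## Problem sizes

The simulation-heavy checks run at deliberately modest sizes chosen to
make the suite quick to iterate on: calibration sessions of 5 reps ×
2 s trials at 1 kSps, 8–20 virtual-task trials per session, 16-session
longitudinal series, 1000 replicates for the F-test calibration, and
10 000 random sequences for the controller property. All sizes are
parameters; scaling them up changes runtimes, not conventions.

## Known limitations

- The generator's drift is purely multiplicative and per-channel;
  pattern rotation (electrode migration) and impedance-driven noise
  change are out of scope, so the stability results bound only
  amplitude-drift robustness.
- The HMM topology is a declared default (one state per class, uniform
  initial distribution), not an inference from any reference system.
- Rest is never cued in the virtual task, so rest rows appear in
  confusion matrices only as decoder outputs.
- The proportional-control input is a pluggable function; no claim is
  made about the aperture dynamics of a physical hand.
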