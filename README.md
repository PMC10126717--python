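# rpnidecode

Longitudinal analysis pipeline for intramuscular-EMG prosthetic hand
control, built around signals from Regenerative Peripheral Nerve
Interfaces (RPNIs — free muscle grafts reinnervated by a transected
nerve, acting as bioamplifiers of efferent motor commands) and residual
innervated forearm muscles. The central question the pipeline addresses
is *stability*: can a grasp decoder calibrated once keep working for
hundreds of days, across arm positions and day-to-day amplitude drift,
without recalibration?

The package is aimed at neuroprosthetics researchers who want to study
that question computationally. Real percutaneous recordings of this kind
are not publicly deposited, so the pipeline ships a first-class
synthetic-EMG generator whose statistical structure matches what the
analysis consumes, and every downstream stage is exercised against it.

## What it implements

- **`synth_emg`** — six-channel synthetic intramuscular EMG (3 RPNIs +
  3 residual muscles): band-limited (100–500 Hz) Gaussian carriers,
  amplitude-modulated by trapezoidal movement envelopes over a 1.43 µV
  resting noise floor, with per-channel lognormal session-to-session
  amplitude drift.
- **`signal_processing`** — band-pass (100–500 Hz, 4th-order
  Butterworth) and decimation from 30 kSps to 1 kSps; mean-absolute-value
  (MAV) features in 50 ms non-overlapping bins; RMS;
  SNR = RMS(movement) / RMS(rest noise floor); EMG onset detection.
- **`decoders`** — the streaming HMM-NB grasp classifier (hidden Markov
  model with channel-independent Gaussian emissions on log-MAV, causal
  forward filtering every 50 ms), plus single-state Naïve Bayes and LDA
  baselines with per-trial (trial-averaged / mode) prediction and
  leave-one-out cross-validation.
- **`task_metrics`** — the virtual posture-matching task (hold a cued
  grip 1 s within a 5 s timeout) and its metrics: per-timestep accuracy
  A_c = 100·Σ_{i∈T_c}[x_i = c]/n(T_c) over the analyzed window from EMG
  onset to trial end, transition-error counts, onset-to-hold latency,
  and confusion matrices.
- **`controller`** — the physical-prosthesis layer: a grip-selection
  filter (a new grip must persist 250 ms before actuation), a 500 ms
  linear velocity ramp on the proportional speed command, and the
  segmented activity-of-daily-living ("coffee task") accounting
  (5 segments × 5 repetitions × 5 trials ⇒ at most 125 transition
  errors).
- **`longitudinal`** — session statistics: OLS trend with an F-test of
  zero slope, one-way ANOVA across arm positions with Bonferroni-adjusted
  pairwise comparisons, Wilcoxon rank-sum (exact for small tie-free
  samples), RPNI channel ablation with per-session retraining, and a 2D
  ICA-on-PCA embedding of the channel features.
- **`pipeline_io`** — HDF5 + JSON-sidecar recordings, JSON models,
  NDJSON trial logs, CSV summaries, and a seeded end-to-end experiment
  runner that emits a content-hash manifest.

A thin CLI (`rpni-decode simulate|process|train|task|coffee-task|analyze|run`)
wraps the library.

## Worked example

Calibrate a four-grip decoder once, then run the virtual posture-matching
task on drifted later sessions without recalibration:

```python
import numpy as np
import rpnidecode as rd
from rpnidecode import synth_emg as se, signal_processing as sp, task_metrics as tm

cfg = rd.default_config(sample_rate=1000)          # 3 RPNIs + 3 residual muscles
cal = se.generate_calibration_session(             # 5 reps per grip, day 0
    cfg.movements, 5, cfg.channels, se.identity_session(cfg.channels, seed=0),
    sample_rate=1000,
)
feats = sp.compute_mav(cal.samples, sample_rate=1000)
labels = sp.bin_labels(cal.labels, 1000)[: feats.n_bins]
model = rd.train_hmm_nb(feats, labels, classes=list(cfg.movements))
rest = sp.rest_mav_stats(feats, labels)

series = se.generate_longitudinal_series(16, 0.5, cfg, seed=1)  # 604-day span
for spec, _rec in series[:3] + series[-1:]:
    source = tm.default_stream_source(cfg.channels, spec.amplitude_scale, sample_rate=1000)
    logs = tm.run_virtual_task(model, source, tm.TaskConfig(n_trials=10), rest, seed=spec.seed)
    acc = tm.compute_accuracy(logs)
    lat = [tm.compute_latency(l) for l in logs if l.success]
    print(f"day {spec.day:3d}: accuracy {acc.overall:5.2f}%  "
          f"holds {sum(l.success for l in logs)}/10  median latency {np.median(lat):.0f} ms")
```

Output:

```
day   0: accuracy 98.89%  holds 10/10  median latency 50 ms
day  40: accuracy 98.89%  holds 10/10  median latency 50 ms
day  81: accuracy 98.89%  holds 10/10  median latency 50 ms
day 604: accuracy 98.89%  holds 10/10  median latency 50 ms
```

Accuracy is the percentage of 50 ms timesteps from EMG onset to trial end
on which the decoder output matched the cue; "holds" counts trials where
the cued posture was held 1 s continuously within the 5 s timeout; the
latency is the time from EMG onset to the start of the completed hold.
Although each later session's per-channel amplitudes are scaled by an
independent lognormal factor (σ = 0.5), the once-calibrated decoder keeps
per-timestep accuracy near 99% throughout the 604-day span — the
no-recalibration stability property the pipeline is built to study.

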