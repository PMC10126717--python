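"""Synthetic intramuscular EMG generation.

Emulates multichannel recordings from implanted bipolar electrodes in
RPNIs (regenerative peripheral nerve interfaces — free muscle grafts
reinnervated by a transected nerve) and residual innervated forearm
muscles. The generator is statistical, not physiological: each channel is
a stationary in-band noise floor (its RMS is the resting level the
decoding path sees) plus a band-limited (100–500 Hz) Gaussian carrier
amplitude-modulated by a movement envelope. That is exactly the
structure the downstream analysis
consumes — RMS/SNR and mean-absolute-value (MAV) features — so motor-unit
level detail is deliberately out of scope.

Amplitudes are in µV throughout. Session-to-session amplitude drift is
modelled as a per-channel multiplicative lognormal factor, which preserves
the relative activation pattern across channels within a session (the
property that makes pattern-recognition control stable across days even
when absolute voltages move).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

# Canonical movement vocabulary. "rest" is always a valid class and is
# silence by construction.
MOVEMENT_LABELS: tuple[str, ...] = (
    "rest",
    "fist",
    "pinch",
    "point",
    "open",
    "thumb_flex",
    "index_flex",
    "middle_flex",
    "ring_flex",
    "small_flex",
    "wrist_flex",
    "abduction",
    "adduction",
    "thumb_opposition",
)

#: The four functional grips used for online grasp control.
FUNCTIONAL_GRIPS: tuple[str, ...] = ("rest", "fist", "pinch", "point")

#: Grip set for the physical (coffee) task controller: the four grips plus
#: an active hand open (finger abduction) used to release objects.
CONTROLLER_GRIPS: tuple[str, ...] = ("rest", "fist", "pinch", "point", "open")

#: Nine-movement set for the offline individual-finger analysis.
NINE_MOVEMENTS: tuple[str, ...] = (
    "rest",
    "thumb_flex",
    "index_flex",
    "middle_flex",
    "ring_flex",
    "small_flex",
    "wrist_flex",
    "abduction",
    "adduction",
)

#: Intrinsic-hand movement set: thumb/finger movements driven by muscles
#: lost to amputation (captured only via RPNIs) contrasted with extrinsic
#: flexion and rest.
INTRINSIC_MOVEMENTS: tuple[str, ...] = (
    "rest",
    "thumb_flex",
    "index_flex",
    "abduction",
    "adduction",
    "thumb_opposition",
)

DEFAULT_NOISE_FLOOR_RMS = 1.43  # µV, median resting noise floor
DEFAULT_SAMPLE_RATE = 30_000  # raw acquisition rate, samples/s
CARRIER_BAND = (100.0, 500.0)  # Hz, energy band of volitional EMG


@dataclass(frozen=True)
class ChannelSpec:
    """One implanted bipolar electrode channel.

    ``activation_gain`` maps each movement label to the channel's EMG RMS
    (µV) at full effort; rest must map to 0. ``source_kind`` is ``"rpni"``
    or ``"residual_muscle"`` and is carried as metadata for ablation
    analyses.
    """

    name: str
    source_kind: str
    noise_floor_rms: float = DEFAULT_NOISE_FLOOR_RMS
    activation_gain: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source_kind not in ("rpni", "residual_muscle"):
            raise ValueError(f"unknown source_kind {self.source_kind!r}")
        if self.noise_floor_rms < 0:
            raise ValueError("noise_floor_rms must be >= 0")
        if self.activation_gain.get("rest", 0.0) != 0.0:
            raise ValueError(f"channel {self.name}: rest gain must be 0")

    def gain(self, movement: str) -> float:
        if movement == "rest":
            return 0.0
        try:
            return float(self.activation_gain[movement])
        except KeyError:
            raise KeyError(
                f"channel {self.name!r} has no activation gain for "
                f"movement {movement!r}"
            ) from None


@dataclass(frozen=True)
class SessionSpec:
    """One experiment session: day post-implant, per-channel drift, seed."""

    day: int
    amplitude_scale: Mapping[str, float]
    seed: int

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if any(v <= 0 for v in self.amplitude_scale.values()):
            raise ValueError("amplitude_scale factors must be > 0")

    def scale_for(self, channel: str) -> float:
        return float(self.amplitude_scale.get(channel, 1.0))


@dataclass
class SyntheticRecording:
    """Multichannel raw EMG with per-sample ground-truth labels.

    ``trials`` holds half-open sample intervals ``(start, end, cue)``;
    intervals are non-overlapping and within bounds. Labels mark
    envelope-active samples with the movement, everything else rest.
    """

    samples: np.ndarray  # channels x time, µV
    sample_rate: float
    labels: np.ndarray  # time, unicode labels
    trials: list[tuple[int, int, str]]
    channel_specs: list[ChannelSpec]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channel_specs]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sample_rate

    def validate(self) -> None:
        n = self.samples.shape[1]
        if len(self.labels) != n:
            raise ValueError("labels length must equal time dimension")
        prev_end = 0
        for start, end, _cue in sorted(self.trials):
            if start < prev_end or end > n or start >= end:
                raise ValueError("trial intervals must be non-overlapping and in bounds")
            prev_end = end


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator."""

    channels: tuple[ChannelSpec, ...]
    movements: tuple[str, ...] = FUNCTIONAL_GRIPS
    sample_rate: int = DEFAULT_SAMPLE_RATE
    rise_ms: float = 200.0
    fall_ms: float = 0.0
    trial_duration_s: float = 2.0
    rest_gap_s: float = 1.0
    reps: int = 5
    drift_sigma: float = 0.5
    n_sessions: int = 16
    span_days: int = 604


# Full-effort EMG RMS (µV) per movement per channel. Channel order:
# median RPNI, ulnar RPNI 1, ulnar RPNI 2, FDL, FDP-index, EDC.
# Values sit in the tens of µV (the reported between-session median EMG RMS
# was ~40 µV with a ~40 µV IQR). Intramuscular bipolar electrodes are
# highly selective, so each functional grip is dominated by a distinct
# subset of channels at large (>=5x) contrast — the property that keeps
# grip clusters separable when per-channel amplitudes drift between
# sessions. Intrinsic-hand movements (thumb opposition, ab/adduction)
# load mostly or entirely on RPNI channels since their native muscles are
# lost to amputation; extrinsic flexions load on the residual muscles.
# Abduction/adduction patterns are deliberately close — they share ulnar
# innervation and are the classically confusable pair, as are the
# neighbouring-finger flexions.
_GAIN_TABLE: dict[str, tuple[float, float, float, float, float, float]] = {
    "rest": (0, 0, 0, 0, 0, 0),
    "fist": (25, 45, 35, 70, 45, 5),
    "pinch": (65, 5, 4, 12, 50, 8),
    "point": (8, 30, 6, 35, 10, 60),
    "open": (5, 55, 45, 6, 8, 50),
    "thumb_flex": (70, 4, 3, 30, 6, 5),
    "index_flex": (10, 4, 5, 8, 65, 10),
    "middle_flex": (6, 25, 8, 50, 30, 5),
    "ring_flex": (4, 50, 20, 45, 6, 6),
    "small_flex": (3, 30, 60, 25, 4, 5),
    "wrist_flex": (8, 10, 6, 60, 12, 4),
    "abduction": (10, 45, 40, 5, 7, 30),
    "adduction": (8, 50, 35, 4, 6, 12),
    "thumb_opposition": (55, 25, 20, 0, 0, 0),
}

_CHANNEL_ROSTER: tuple[tuple[str, str], ...] = (
    ("median_rpni", "rpni"),
    ("ulnar_rpni_1", "rpni"),
    ("ulnar_rpni_2", "rpni"),
    ("fdl", "residual_muscle"),
    ("fdp_index", "residual_muscle"),
    ("edc", "residual_muscle"),
)


def default_config(
    movements: Sequence[str] = FUNCTIONAL_GRIPS,
    noise_floor_rms: float = DEFAULT_NOISE_FLOOR_RMS,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    **overrides,
) -> GeneratorConfig:
    """Six-channel configuration (3 RPNIs + 3 residual muscles).

    Every channel defaults to the 1.43 µV resting noise floor; activation
    gains give each movement in the canonical vocabulary a distinct
    cross-channel pattern.
    """
    movements = tuple(movements)
    if "rest" not in movements:
        raise ValueError('movement set must contain "rest"')
    unknown = set(movements) - set(MOVEMENT_LABELS)
    if unknown:
        raise ValueError(f"unknown movements: {sorted(unknown)}")
    channels = tuple(
        ChannelSpec(
            name=name,
            source_kind=kind,
            noise_floor_rms=noise_floor_rms,
            activation_gain={m: _GAIN_TABLE[m][i] for m in MOVEMENT_LABELS},
        )
        for i, (name, kind) in enumerate(_CHANNEL_ROSTER)
    )
    return GeneratorConfig(
        channels=channels, movements=movements, sample_rate=sample_rate, **overrides
    )


def _carrier_sos(sample_rate: float):
    """4th-order Butterworth band-pass for the EMG carrier band."""
    nyq = sample_rate / 2.0
    hi = min(CARRIER_BAND[1], 0.45 * sample_rate)
    return sps.butter(4, [CARRIER_BAND[0] / nyq, hi / nyq], btype="bandpass", output="sos")


def _envelope(n: int, sample_rate: float, rise_ms: float, fall_ms: float) -> np.ndarray:
    """Trapezoidal activation envelope in [0, 1] over n samples."""
    t = np.arange(n, dtype=float)
    rise = max(1.0, rise_ms * 1e-3 * sample_rate)
    env = np.minimum(1.0, t / rise)
    if fall_ms > 0:
        fall = max(1.0, fall_ms * 1e-3 * sample_rate)
        env = np.minimum(env, np.minimum(1.0, (n - 1 - t) / fall))
    return np.clip(env, 0.0, 1.0)


def generate_trial(
    movement: str,
    duration: float,
    channels: Sequence[ChannelSpec],
    scale: Mapping[str, float] | None = None,
    seed: int | np.random.SeedSequence = 0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    rise_ms: float = 200.0,
    fall_ms: float = 0.0,
) -> SyntheticRecording:
    """One cued-movement trial.

    Each channel is a stationary noise floor at ``noise_floor_rms`` plus
    an independent Gaussian carrier, both band-limited to 100–500 Hz and
    RMS-normalised; the carrier is modulated by the trapezoidal envelope
    up to ``gain × session scale``. The noise floor is modelled within
    the analysis band — its configured RMS is what the decoding path (and
    the resting-RMS measurement) sees after band-pass filtering.
    Independence of carrier and noise makes segment RMS obey
    ``sqrt(gain² + noise_floor²)`` on the plateau.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    scale = scale or {}
    env = np.zeros(n) if movement == "rest" else _envelope(n, sample_rate, rise_ms, fall_ms)
    sos = _carrier_sos(sample_rate)

    def band_noise(rms: float) -> np.ndarray | float:
        if rms <= 0:
            return 0.0
        x = sps.sosfiltfilt(sos, rng.standard_normal(n))
        xrms = np.sqrt(np.mean(x**2))
        return x * (rms / xrms) if xrms > 0 else x

    samples = np.empty((len(channels), n))
    for i, ch in enumerate(channels):
        gain = ch.gain(movement) * float(scale.get(ch.name, 1.0))
        carrier = band_noise(gain) if gain > 0 else 0.0
        samples[i] = env * carrier + band_noise(ch.noise_floor_rms)

    labels = np.where(env > 0, movement, "rest").astype("U24")
    return SyntheticRecording(
        samples=samples,
        sample_rate=float(sample_rate),
        labels=labels,
        trials=[(0, n, movement)],
        channel_specs=list(channels),
    )


def generate_calibration_session(
    movements: Sequence[str],
    reps: int,
    channels: Sequence[ChannelSpec],
    session: SessionSpec,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    trial_duration_s: float = 2.0,
    rest_gap_s: float = 1.0,
    rise_ms: float = 200.0,
) -> SyntheticRecording:
    """Calibration recording: ``reps`` repetitions per movement in
    pseudo-random order, each trial followed by an inter-trial rest gap.

    A trial's annotated interval spans the cued segment plus its trailing
    rest gap, so trial intervals partition the recording.
    """
    movements = list(movements)
    if not movements:
        raise ValueError("movement set must be nonempty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    root = np.random.SeedSequence(session.seed)
    order_rng = np.random.default_rng(root.spawn(1)[0])
    order = [m for m in movements for _ in range(reps)]
    order_rng.shuffle(order)
    trial_seeds = root.spawn(2 * len(order))

    chunks, label_chunks, trials = [], [], []
    pos = 0
    for k, mov in enumerate(order):
        rec = generate_trial(
            mov,
            trial_duration_s,
            channels,
            scale=session.amplitude_scale,
            seed=trial_seeds[2 * k],
            sample_rate=sample_rate,
            rise_ms=rise_ms,
        )
        seg_len = rec.samples.shape[1]
        chunks.append(rec.samples)
        label_chunks.append(rec.labels)
        end = pos + seg_len
        if rest_gap_s > 0:
            gap = generate_trial(
                "rest",
                rest_gap_s,
                channels,
                scale=session.amplitude_scale,
                seed=trial_seeds[2 * k + 1],
                sample_rate=sample_rate,
            )
            chunks.append(gap.samples)
            label_chunks.append(gap.labels)
            end += gap.samples.shape[1]
        trials.append((pos, end, mov))
        pos = end

    rec = SyntheticRecording(
        samples=np.concatenate(chunks, axis=1),
        sample_rate=float(sample_rate),
        labels=np.concatenate(label_chunks),
        trials=trials,
        channel_specs=list(channels),
    )
    rec.validate()
    return rec


def generate_longitudinal_series(
    n_sessions: int,
    drift_sigma: float,
    config: GeneratorConfig,
    seed: int = 0,
    days: Sequence[int] | None = None,
) -> list[tuple[SessionSpec, SyntheticRecording]]:
    """Session series with per-channel lognormal amplitude drift.

    Each session draws one multiplicative scale per channel from
    ``lognormal(0, drift_sigma²)`` — amplitudes move between sessions, but
    the relative activation pattern across channels within a session is
    untouched. Days default to an even spread over ``config.span_days``
    (the 16-session default spans 604 days).
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if drift_sigma < 0:
        raise ValueError("drift sigma must be >= 0")
    if days is None:
        if n_sessions == 1:
            days = [0]
        else:
            days = np.round(np.linspace(0, config.span_days, n_sessions)).astype(int)
            days = np.maximum.accumulate(days + np.arange(n_sessions) * 0)  # monotone
            # guarantee strict increase even under rounding collisions
            for i in range(1, n_sessions):
                if days[i] <= days[i - 1]:
                    days[i] = days[i - 1] + 1
    days = [int(d) for d in days]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing")

    root = np.random.SeedSequence(seed)
    drift_rng = np.random.default_rng(root.spawn(1)[0])
    session_seeds = root.spawn(n_sessions)
    names = [c.name for c in config.channels]

    out = []
    for i in range(n_sessions):
        factors = drift_rng.lognormal(mean=0.0, sigma=drift_sigma, size=len(names))
        spec = SessionSpec(
            day=days[i],
            amplitude_scale=dict(zip(names, factors.tolist())),
            seed=int(session_seeds[i].generate_state(1)[0] % (2**31)),
        )
        rec = generate_calibration_session(
            config.movements,
            config.reps,
            config.channels,
            spec,
            sample_rate=config.sample_rate,
            trial_duration_s=config.trial_duration_s,
            rest_gap_s=config.rest_gap_s,
            rise_ms=config.rise_ms,
        )
        out.append((spec, rec))
    return out


def plateau_mav(channel: ChannelSpec, movement: str, scale: float = 1.0) -> float:
    """Expected plateau MAV (µV) for a channel: E|X| of a zero-mean
    Gaussian whose variance is gain² + noise_floor²."""
    g = channel.gain(movement) * scale
    s = np.sqrt(g**2 + channel.noise_floor_rms**2)
    return float(s * np.sqrt(2.0 / np.pi))


def identity_session(channels: Sequence[ChannelSpec], day: int = 0, seed: int = 0) -> SessionSpec:
    """SessionSpec with unit amplitude scale on every channel."""
    return SessionSpec(day=day, amplitude_scale={c.name: 1.0 for c in channels}, seed=seed)
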