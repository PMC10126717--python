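"""EMG preprocessing, MAV features, RMS/SNR, and onset detection.

The streaming decoder consumes mean-absolute-value (MAV) features in
50 ms non-overlapping bins computed from 1 kSps EMG that has been
band-pass filtered to 100–500 Hz. SNR is defined as the RMS of the EMG
during volitional movement divided by the RMS of the channel's resting
noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

TARGET_RATE = 1000  # samples/s after decimation
DEFAULT_BIN_MS = 50.0


@dataclass
class EmgRecording:
    """Minimal multichannel EMG container (channels × time, µV)."""

    samples: np.ndarray
    sample_rate: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")


@dataclass
class FeatureSequence:
    """Per-channel MAV in consecutive non-overlapping bins (µV ≥ 0)."""

    mav: np.ndarray  # channels x bins
    bin_width_ms: float = DEFAULT_BIN_MS
    origin: int = 0  # sample index of the first bin
    channel_names: list[str] | None = None

    @property
    def n_bins(self) -> int:
        return self.mav.shape[1]

    @property
    def n_channels(self) -> int:
        return self.mav.shape[0]


@dataclass
class SnrReport:
    """Per-channel SNR with its numerator and denominator (µV)."""

    snr: np.ndarray
    emg_rms: np.ndarray
    noise_rms: np.ndarray


def _as_samples(x) -> tuple[np.ndarray, float | None]:
    if hasattr(x, "samples"):
        return np.atleast_2d(np.asarray(x.samples, dtype=float)), float(x.sample_rate)
    return np.atleast_2d(np.asarray(x, dtype=float)), None


def bandpass_sos(sample_rate: float, low: float = 100.0, high: float = 500.0):
    """4th-order Butterworth band-pass; the high edge is pulled below
    Nyquist for recordings already at or near 1 kSps."""
    nyq = sample_rate / 2.0
    high = min(high, 0.45 * sample_rate)
    if low >= high:
        raise ValueError("invalid band for this sample rate")
    return sps.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")


def preprocess(raw, causal: bool = False) -> EmgRecording:
    """Band-pass 100–500 Hz then decimate to 1 kSps by stride.

    The 500 Hz cutoff already satisfies Nyquist at the 1 kSps target, so
    decimation is a simple stride after filtering. Zero-phase
    (forward-backward) filtering is used for offline analysis; ``causal``
    switches to a single forward pass for the streaming path.
    """
    samples, rate = _as_samples(raw)
    if rate is None:
        raise ValueError("preprocess needs a recording with a sample_rate")
    if rate < TARGET_RATE:
        raise ValueError(f"sample rate {rate} below {TARGET_RATE} sps")
    if rate % TARGET_RATE:
        raise ValueError(f"sample rate {rate} not divisible by {TARGET_RATE}")
    ratio = int(rate) // TARGET_RATE
    sos = bandpass_sos(rate)
    filt = sps.sosfilt(sos, samples, axis=1) if causal else sps.sosfiltfilt(sos, samples, axis=1)
    out = filt[:, ::ratio]
    names = getattr(raw, "channel_names", None)
    return EmgRecording(out, float(TARGET_RATE), list(names) if names else None)


def compute_mav(x, bin_width_ms: float = DEFAULT_BIN_MS, sample_rate: float | None = None) -> FeatureSequence:
    """MAV per channel in non-overlapping bins; a trailing partial bin is
    discarded, never padded."""
    samples, rate = _as_samples(x)
    rate = sample_rate if rate is None else rate
    if rate is None:
        raise ValueError("sample_rate required for plain arrays")
    bin_len = int(round(bin_width_ms * 1e-3 * rate))
    if bin_len < 1 or samples.shape[1] < bin_len:
        raise ValueError("recording shorter than one bin")
    n_bins = samples.shape[1] // bin_len
    trimmed = np.abs(samples[:, : n_bins * bin_len])
    mav = trimmed.reshape(samples.shape[0], n_bins, bin_len).mean(axis=2)
    names = getattr(x, "channel_names", None)
    return FeatureSequence(mav, bin_width_ms, 0, list(names) if names else None)


def bin_labels(labels: Sequence[str], sample_rate: float, bin_width_ms: float = DEFAULT_BIN_MS) -> np.ndarray:
    """Majority label per feature bin (ties broken by first occurrence
    within the bin); trailing partial bin discarded to mirror compute_mav."""
    labels = np.asarray(labels)
    bin_len = int(round(bin_width_ms * 1e-3 * sample_rate))
    n_bins = len(labels) // bin_len
    out = np.empty(n_bins, dtype=labels.dtype)
    for b in range(n_bins):
        chunk = labels[b * bin_len : (b + 1) * bin_len]
        vals, first_idx, counts = np.unique(chunk, return_index=True, return_counts=True)
        best = np.lexsort((first_idx, -counts))[0]
        out[b] = vals[best]
    return out


def compute_rms(segment) -> np.ndarray:
    """Root-mean-square along time; works per-channel on 2D input."""
    arr = np.asarray(segment, dtype=float)
    if arr.size == 0:
        raise ValueError("empty segment")
    return np.sqrt(np.mean(arr**2, axis=-1))


def compute_snr(movement_segment, rest_segment) -> SnrReport:
    """SNR per channel: movement RMS divided by resting noise-floor RMS."""
    emg_rms = np.atleast_1d(compute_rms(movement_segment))
    noise_rms = np.atleast_1d(compute_rms(rest_segment))
    if np.any(noise_rms == 0):
        raise ValueError("degenerate noise floor: rest RMS is zero")
    return SnrReport(snr=emg_rms / noise_rms, emg_rms=emg_rms, noise_rms=noise_rms)


@dataclass
class RestStats:
    """Per-channel mean and SD of MAV during rest."""

    mean: np.ndarray
    sd: np.ndarray
    n_bins: int


def rest_mav_stats(features: FeatureSequence, labels_per_bin: Sequence[str]) -> RestStats:
    """Summarise the resting MAV distribution used by onset detection."""
    mask = np.asarray(labels_per_bin) == "rest"
    if mask.sum() < 1:
        raise ValueError("no rest bins")
    rest = features.mav[:, mask]
    return RestStats(mean=rest.mean(axis=1), sd=rest.std(axis=1), n_bins=int(mask.sum()))


def detect_onset(
    features: FeatureSequence,
    rest_stats: RestStats,
    k: float = 3.0,
    n_consecutive: int = 2,
) -> int | None:
    """First bin where any channel's MAV exceeds rest mean + k·SD for
    ``n_consecutive`` consecutive bins; None if never."""
    thresh = rest_stats.mean + k * rest_stats.sd
    active = np.any(features.mav > thresh[:, None], axis=0)
    run = 0
    for i, a in enumerate(active):
        run = run + 1 if a else 0
        if run >= n_consecutive:
            return i - n_consecutive + 1
    return None
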