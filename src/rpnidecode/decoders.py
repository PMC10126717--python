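"""Grasp decoders: streaming HMM-NB and single-state NB / LDA baselines.

The primary decoder is a hidden Markov model whose emissions factorise
over channels as independent Gaussians on the MAV feature (the
"Naïve Bayes" emission model). Latent states map onto movement classes
(``states_per_class`` states each); decoding is the causal forward
recursion, so each 50 ms bin's class posterior uses only past and present
evidence — the same computation a real-time controller runs.

The baselines are a single-state diagonal-Gaussian NB and an LDA with
pooled within-class covariance, trained on binned MAV features and applied
per trial to trial-averaged features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .signal_processing import FeatureSequence

VAR_FLOOR = 1e-4  # µV², prevents degenerate emission likelihoods
LDA_RIDGE = 1e-6  # ridge scale: eps = LDA_RIDGE * trace(cov) / d

Trial = tuple[np.ndarray, str]  # (channels x bins MAV, class label)


def _as_mav(features) -> np.ndarray:
    if isinstance(features, FeatureSequence):
        return np.asarray(features.mav, dtype=float)
    return np.atleast_2d(np.asarray(features, dtype=float))


# ---------------------------------------------------------------------------
# HMM-NB
# ---------------------------------------------------------------------------

LOG_EPS = 1e-6  # µV, clamp before log transform


@dataclass
class HmmNbModel:
    """Latent-state grasp classifier with channel-independent emissions.

    Emissions are per-state per-channel Gaussians on the MAV feature,
    evaluated by default in the log domain (``emission_domain="log"``):
    between-session amplitude change is multiplicative, so log-MAV turns
    drift into an additive shift whose size is independent of a channel's
    level, and ``drift_tolerance`` (the relative amplitude budget, in
    lognormal sigma units) enters the emission variance additively.
    ``emission_domain="linear"`` gives plain Gaussians on MAV (µV) with
    the drift budget entering as ``(drift_tolerance·mean)²``.
    """

    classes: list[str]
    states_per_class: int
    initial: np.ndarray  # (S,)
    transition: np.ndarray  # (S, S), row-stochastic
    means: np.ndarray  # (S, C); log-µV or µV per emission_domain
    variances: np.ndarray  # (S, C); MLE (floored), drift budget excluded
    state_to_class: np.ndarray  # (S,) index into classes
    emission_domain: str = "log"
    drift_tolerance: float = 0.5

    @property
    def n_states(self) -> int:
        return len(self.initial)

    @property
    def n_channels(self) -> int:
        return self.means.shape[1]

    @property
    def mav_means(self) -> np.ndarray:
        """Per-state per-channel emission means on the MAV scale (µV)."""
        if self.emission_domain == "log":
            return np.exp(self.means + self.variances / 2.0)
        return self.means

    def validate(self) -> None:
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")


@dataclass
class DecodedStream:
    """Per-bin class posteriors and the argmax class sequence."""

    classes: list[str]
    posterior: np.ndarray  # bins x classes, rows sum to 1
    argmax: np.ndarray  # bins, class indices

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.classes)[self.argmax]


def _sequences(features, labels) -> list[tuple[np.ndarray, np.ndarray]]:
    """Normalise (features, labels) into a list of aligned sequences."""
    if isinstance(features, (list, tuple)) and not isinstance(features, np.ndarray):
        return [(_as_mav(f), np.asarray(l)) for f, l in zip(features, labels)]
    return [(_as_mav(features), np.asarray(labels))]


DRIFT_TOLERANCE = 0.5  # relative between-session amplitude budget


def train_hmm_nb(
    features,
    labels,
    classes: Sequence[str] | None = None,
    states_per_class: int = 1,
    var_floor: float = VAR_FLOOR,
    drift_tolerance: float = DRIFT_TOLERANCE,
    emission_domain: str = "log",
) -> HmmNbModel:
    """Supervised HMM-NB training from labelled calibration bins.

    Emission means and variances are per-state per-channel maximum
    likelihood (with a variance floor) in the chosen emission domain; the
    transition matrix comes from labelled bin-to-bin transition counts
    with add-one smoothing (keeping the chain ergodic); the initial
    distribution is uniform. ``features``/``labels`` may be a single
    aligned sequence or a list of sequences (transitions are never counted
    across sequence boundaries).

    Because this decoder is meant to be calibrated once and reused across
    sessions without recalibration, decoding budgets for between-session
    amplitude drift via ``drift_tolerance``: EMG amplitudes move
    multiplicatively between days (the reported between-session EMG-RMS
    interquartile spread is comparable to its median, i.e. a relative SD
    of order 50%), so the default log-domain emissions add
    ``drift_tolerance²`` to the emission variance — exactly the extra
    variance a lognormal amplitude factor of that sigma contributes in
    log-MAV. Set ``drift_tolerance=0`` for a pure within-session model.
    """
    if emission_domain not in ("log", "linear"):
        raise ValueError(f"unknown emission domain {emission_domain!r}")
    seqs = _sequences(features, labels)
    all_labels = np.concatenate([y for _, y in seqs])
    if classes is None:
        _, first = np.unique(all_labels, return_index=True)
        classes = [str(all_labels[i]) for i in sorted(first)]
    classes = list(classes)
    for c in classes:
        if not np.any(all_labels == c):
            raise ValueError(f"class {c!r} has no labelled bins")

    S = len(classes) * states_per_class
    n_channels = seqs[0][0].shape[0]
    state_to_class = np.repeat(np.arange(len(classes)), states_per_class)

    # Assign each bin to a state: within each contiguous same-class run,
    # split the run into states_per_class equal temporal chunks.
    assigned: list[np.ndarray] = []
    for X, y in seqs:
        st = np.empty(X.shape[1], dtype=int)
        start = 0
        for i in range(1, len(y) + 1):
            if i == len(y) or y[i] != y[start]:
                ci = classes.index(str(y[start]))
                run = i - start
                sub = np.minimum((np.arange(run) * states_per_class) // max(run, 1),
                                 states_per_class - 1)
                st[start:i] = ci * states_per_class + sub
                start = i
        assigned.append(st)

    X_all = np.concatenate([X for X, _ in seqs], axis=1)
    if emission_domain == "log":
        X_all = np.log(np.maximum(X_all, LOG_EPS))
    st_all = np.concatenate(assigned)
    means = np.zeros((S, n_channels))
    variances = np.full((S, n_channels), var_floor)
    for s in range(S):
        sel = X_all[:, st_all == s]
        if sel.shape[1] == 0:
            raise ValueError(
                f"class {classes[state_to_class[s]]!r} has no data for state {s}"
            )
        means[s] = sel.mean(axis=1)
        variances[s] = np.maximum(sel.var(axis=1), var_floor)

    counts = np.ones((S, S))  # add-one smoothing
    for st in assigned:
        np.add.at(counts, (st[:-1], st[1:]), 1)
    transition = counts / counts.sum(axis=1, keepdims=True)

    model = HmmNbModel(
        classes=classes,
        states_per_class=states_per_class,
        initial=np.full(S, 1.0 / S),
        transition=transition,
        means=means,
        variances=variances,
        state_to_class=state_to_class,
        emission_domain=emission_domain,
        drift_tolerance=drift_tolerance,
    )
    model.validate()
    return model


def _emission_loglik(model: HmmNbModel, X: np.ndarray) -> np.ndarray:
    """log p(x_t | state) for every bin; shape (bins, states)."""
    if model.emission_domain == "log":
        X = np.log(np.maximum(X, LOG_EPS))
        v = model.variances + model.drift_tolerance**2
    else:
        v = model.variances + (model.drift_tolerance * model.means) ** 2
    # (S, C) broadcast against (C, B) -> (B, S)
    d = X.T[:, None, :] - model.means[None, :, :]
    v = v[None, :, :]
    ll = -0.5 * (np.log(2 * np.pi * v) + d**2 / v)
    return ll.sum(axis=2)


def forward_filter(model: HmmNbModel, features) -> DecodedStream:
    """Causal forward recursion in log space.

    Per-bin class posterior is the filtered state posterior summed over
    the states mapped to each class. Argmax ties break toward the earliest
    class in the model's class list.
    """
    X = _as_mav(features)
    if X.shape[0] != model.n_channels:
        raise ValueError(
            f"feature channel count {X.shape[0]} != model channels {model.n_channels}"
        )
    ll = _emission_loglik(model, X)  # (B, S)
    logT = np.log(model.transition)
    log_alpha = np.log(model.initial) + ll[0]
    B = X.shape[1]
    K = len(model.classes)
    post = np.empty((B, K))
    class_masks = [model.state_to_class == k for k in range(K)]
    for t in range(B):
        if t > 0:
            log_alpha = logsumexp(log_alpha[:, None] + logT, axis=0) + ll[t]
        log_alpha = log_alpha - logsumexp(log_alpha)
        p_state = np.exp(log_alpha)
        for k in range(K):
            post[t, k] = p_state[class_masks[k]].sum()
    post /= post.sum(axis=1, keepdims=True)
    return DecodedStream(classes=list(model.classes), posterior=post, argmax=post.argmax(axis=1))


# ---------------------------------------------------------------------------
# Static baselines: NB and LDA
# ---------------------------------------------------------------------------

@dataclass
class StaticModel:
    kind: str  # "nb" | "lda"
    classes: list[str]
    means: np.ndarray  # (K, C)
    priors: np.ndarray  # (K,)
    variances: np.ndarray | None = None  # nb: (K, C)
    covariance: np.ndarray | None = None  # lda: (C, C)
    _cov_inv: np.ndarray | None = field(default=None, repr=False)

    def cov_inv(self) -> np.ndarray:
        if self._cov_inv is None:
            self._cov_inv = np.linalg.inv(self.covariance)
        return self._cov_inv


def train_static(
    trials: Sequence[Trial],
    kind: str,
    var_floor: float = VAR_FLOOR,
    ridge: float = LDA_RIDGE,
    classes: Sequence[str] | None = None,
) -> StaticModel:
    """Train a single-state NB or LDA baseline on labelled trials.

    NB fits a per-class diagonal Gaussian by maximum likelihood (variance
    floored); LDA fits class means with a pooled within-class covariance
    regularised by ``ridge · trace(Σ)/d · I``. Priors are trial
    frequencies. Training uses all bins of every trial.
    """
    if kind not in ("nb", "lda"):
        raise ValueError(f"unknown model kind {kind!r}")
    labels = [str(c) for _, c in trials]
    if classes is None:
        seen: dict[str, None] = {}
        for c in labels:
            seen.setdefault(c, None)
        classes = list(seen)
    classes = list(classes)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: labels.count(c) for c in classes}
    if any(v < 2 for v in counts.values()):
        raise ValueError("need at least 2 trials per class")

    C = _as_mav(trials[0][0]).shape[0]
    K = len(classes)
    X_by_class = {
        c: np.concatenate([_as_mav(X) for X, lab in trials if str(lab) == c], axis=1)
        for c in classes
    }
    means = np.stack([X_by_class[c].mean(axis=1) for c in classes])
    priors = np.array([counts[c] for c in classes], dtype=float)
    priors /= priors.sum()

    if kind == "nb":
        variances = np.stack(
            [np.maximum(X_by_class[c].var(axis=1), var_floor) for c in classes]
        )
        return StaticModel(kind, classes, means, priors, variances=variances)

    n_total = sum(X_by_class[c].shape[1] for c in classes)
    sw = np.zeros((C, C))
    for k, c in enumerate(classes):
        d = X_by_class[c] - means[k][:, None]
        sw += d @ d.T
    cov = sw / max(n_total - K, 1)
    # absolute fallback keeps degenerate (constant-feature) classes invertible
    eps = ridge * np.trace(cov) / C if np.trace(cov) > 0 else ridge
    cov = cov + eps * np.eye(C)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance singular after regularization") from exc
    return StaticModel(kind, classes, means, priors, covariance=cov)


def _static_scores(model: StaticModel, x: np.ndarray) -> np.ndarray:
    """Per-class discriminant scores for one feature vector (C,)."""
    if model.kind == "nb":
        d = x[None, :] - model.means
        ll = -0.5 * (np.log(2 * np.pi * model.variances) + d**2 / model.variances)
        return ll.sum(axis=1) + np.log(model.priors)
    ci = model.cov_inv()
    # linear discriminant: x' Σ⁻¹ μ_k − ½ μ_k' Σ⁻¹ μ_k + log π_k
    lin = model.means @ ci @ x
    quad = 0.5 * np.einsum("kc,cd,kd->k", model.means, ci, model.means)
    return lin - quad + np.log(model.priors)


def predict_static(model: StaticModel, x) -> str:
    """Classify a single feature vector (ties → earliest class)."""
    scores = _static_scores(model, np.asarray(x, dtype=float).ravel())
    return model.classes[int(np.argmax(scores))]


def predict_trial(model, trial_features) -> str:
    """Per-trial prediction.

    NB/LDA classify the trial-averaged MAV vector; the HMM-NB prediction
    is the most frequent argmax class over the trial's bins (ties broken
    by the earliest-achieved class).
    """
    X = _as_mav(trial_features)
    if X.shape[1] < 1:
        raise ValueError("trial must have at least one bin")
    if isinstance(model, HmmNbModel):
        stream = forward_filter(model, X)
        idx = stream.argmax
        vals, first_idx, counts = np.unique(idx, return_index=True, return_counts=True)
        best = vals[np.lexsort((first_idx, -counts))[0]]
        return model.classes[int(best)]
    return predict_static(model, X.mean(axis=1))


def _train_any(trials: Sequence[Trial], kind: str, classes=None, **kwargs):
    if kind == "hmm":
        feats = [X for X, _ in trials]
        labs = [np.full(_as_mav(X).shape[1], str(c)) for X, c in trials]
        return train_hmm_nb(feats, labs, classes=classes, **kwargs)
    return train_static(trials, kind, classes=classes, **kwargs)


def loo_cross_validate(trials: Sequence[Trial], kind: str, **kwargs) -> float:
    """Leave-one-out accuracy: one trial held out per fold, the model
    retrained on the rest, the held-out trial predicted per-trial."""
    labels = [str(c) for _, c in trials]
    correct = 0
    for i in range(len(trials)):
        rest = [t for j, t in enumerate(trials) if j != i]
        model = _train_any(rest, kind, **kwargs)
        if predict_trial(model, trials[i][0]) == labels[i]:
            correct += 1
    return correct / len(trials)


def trials_from_recording(recording, features, labels_per_bin, bin_width_ms: float = 50.0) -> list[Trial]:
    """Build per-trial feature matrices from an annotated recording.

    For each annotated trial interval, keeps the feature bins inside the
    interval whose majority label equals the cue (so trailing rest gaps
    never contaminate movement trials).
    """
    mav = _as_mav(features)
    labs = np.asarray(labels_per_bin)
    bin_len = bin_width_ms * 1e-3 * recording.sample_rate
    out: list[Trial] = []
    for start, end, cue in recording.trials:
        b0 = int(np.ceil(start / bin_len))
        b1 = min(int(end // bin_len), mav.shape[1])
        if b1 <= b0:
            continue
        sel = np.arange(b0, b1)[labs[b0:b1] == cue]
        if sel.size:
            out.append((mav[:, sel], cue))
    return out
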