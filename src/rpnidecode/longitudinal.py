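"""Session-level statistics and visualisation.

Covers the longitudinal questions the pipeline answers: does SNR or
decoder accuracy trend over days (OLS slope + F-test); do arm positions
differ in transition errors (one-way ANOVA with Bonferroni-corrected
pairwise comparisons); do decoders differ (Wilcoxon rank-sum); how much
do RPNI channels contribute (channel ablation with per-session
retraining); and a 2D ICA-on-PCA embedding of the channel features for
cluster visualisation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decoders import Trial, loo_cross_validate, predict_trial, _train_any

ALPHA = 0.05


@dataclass
class TrendResult:
    slope: float  # per day
    intercept: float
    f_statistic: float
    p_value: float
    verdict: str  # increasing | decreasing | no-trend
    alpha: float = ALPHA


def fit_trend(days: Sequence[float], values: Sequence[float], alpha: float = ALPHA) -> TrendResult:
    """OLS of value on day with an F-test of zero slope.

    The verdict is "no-trend" iff p >= alpha, otherwise the slope's sign
    gives the direction. For simple regression the F statistic equals the
    squared t statistic of the slope.
    """
    x = np.asarray(days, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 sessions")
    if np.ptp(x) == 0:
        raise ValueError("days must not be constant")
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = yc - slope * xc
    sse = float(resid @ resid)
    ssr = slope**2 * sxx
    df = n - 2
    if sse <= 0:  # perfect fit
        f = np.inf if ssr > 0 else 0.0
        p = 0.0 if ssr > 0 else 1.0
    else:
        f = ssr / (sse / df)
        p = float(stats.f.sf(f, 1, df))
    if p >= alpha or slope == 0:
        verdict = "no-trend"
    else:
        verdict = "increasing" if slope > 0 else "decreasing"
    return TrendResult(slope, intercept, f, p, verdict, alpha)


@dataclass
class PositionComparison:
    anova_f: float
    anova_p: float
    pairwise: dict[tuple[str, str], float]  # Bonferroni-adjusted p, capped at 1
    alpha: float = ALPHA


def compare_positions(groups: Mapping[str, Sequence[float]], alpha: float = ALPHA) -> PositionComparison:
    """One-way ANOVA across arm positions with Bonferroni-adjusted
    pairwise pooled-variance t-tests (adjusted p capped at 1)."""
    names = list(groups)
    if len(names) < 2 or any(len(groups[g]) < 2 for g in names):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    f, p = stats.f_oneway(*arrays)
    m = len(names) * (len(names) - 1) // 2
    pairwise: dict[tuple[str, str], float] = {}
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        res = stats.ttest_ind(arrays[i], arrays[j], equal_var=True)
        pairwise[(a, b)] = min(1.0, float(res.pvalue) * m)
    return PositionComparison(float(f), float(p), pairwise, alpha)


def rank_sum_compare(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration of the rank-sum distribution for m + n <= 12 when
    the pooled sample is tie-free; the normal approximation with tie
    correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


@dataclass
class AblationResult:
    movement_set: str
    accuracy_full: float  # percent, averaged over sessions
    accuracy_reduced: float
    delta: float  # percentage points, full - reduced
    per_class_full: pd.DataFrame  # pooled confusion, percent rows
    per_class_reduced: pd.DataFrame


def _subset_trials(trials: Sequence[Trial], channel_names: Sequence[str], keep: Sequence[str]) -> list[Trial]:
    idx = [list(channel_names).index(c) for c in keep]
    return [(np.asarray(X)[idx], c) for X, c in trials]


def _loo_with_confusion(trials: Sequence[Trial], kind: str) -> tuple[float, pd.DataFrame]:
    labels = [str(c) for _, c in trials]
    classes = sorted(set(labels))
    counts = pd.DataFrame(0.0, index=classes, columns=classes)
    correct = 0
    for i in range(len(trials)):
        rest = [t for j, t in enumerate(trials) if j != i]
        model = _train_any(rest, kind)
        pred = predict_trial(model, trials[i][0])
        counts.loc[labels[i], pred] += 1
        correct += pred == labels[i]
    return correct / len(trials), counts


def _cross_session_with_confusion(
    train: Sequence[Trial], test: Sequence[Trial], kind: str
) -> tuple[float, pd.DataFrame]:
    labels = sorted({str(c) for _, c in train} | {str(c) for _, c in test})
    counts = pd.DataFrame(0.0, index=labels, columns=labels)
    model = _train_any(train, kind)
    correct = 0
    for X, c in test:
        pred = predict_trial(model, X)
        counts.loc[str(c), pred] += 1
        correct += pred == str(c)
    return correct / len(test), counts


def ablate_channels(
    sessions: Sequence[Sequence[Trial]],
    channel_names: Sequence[str],
    keep_channels: Sequence[str],
    kind: str = "lda",
) -> tuple[float, pd.DataFrame]:
    """Per-trial accuracy restricted to a channel subset.

    A decoder of the given kind is retrained per session on the kept
    channels and evaluated per trial on the following session (the
    analysis is an across-sessions one, and held-out-trial evaluation
    within a single session is anti-correlated under the null: removing
    the test trial pulls its own class mean away from it, biasing
    null-level accuracy below chance). With a single session, per-trial
    leave-one-out within it is used instead. Accuracy is averaged over
    evaluations unweighted. Returns (mean accuracy fraction, pooled
    row-normalised confusion in percent).
    """
    if not keep_channels:
        raise ValueError("channel subset must be nonempty")
    subs = [_subset_trials(trials, channel_names, keep_channels) for trials in sessions]
    accs = []
    pooled: pd.DataFrame | None = None
    if len(subs) == 1:
        acc, pooled = _loo_with_confusion(subs[0], kind)
        accs.append(acc)
    else:
        for train, test in zip(subs, subs[1:]):
            acc, counts = _cross_session_with_confusion(train, test, kind)
            accs.append(acc)
            pooled = counts if pooled is None else pooled.add(counts, fill_value=0.0)
    row = pooled.sum(axis=1)
    confusion = pooled.div(row.where(row > 0), axis=0) * 100.0
    return float(np.mean(accs)), confusion


def rpni_ablation(
    sessions: Sequence[Sequence[Trial]],
    channel_names: Sequence[str],
    rpni_channels: Sequence[str],
    movement_set: str = "grips",
    kind: str = "lda",
) -> AblationResult:
    """Compare decoders using all channels against residual-muscle-only
    decoders; the movements most hurt by RPNI removal are the ones the
    RPNIs contribute most to."""
    residual = [c for c in channel_names if c not in set(rpni_channels)]
    acc_full, conf_full = ablate_channels(sessions, channel_names, channel_names, kind)
    acc_red, conf_red = ablate_channels(sessions, channel_names, residual, kind)
    return AblationResult(
        movement_set=movement_set,
        accuracy_full=100.0 * acc_full,
        accuracy_reduced=100.0 * acc_red,
        delta=100.0 * (acc_full - acc_red),
        per_class_full=conf_full,
        per_class_reduced=conf_red,
    )


@dataclass
class IcaPcaResult:
    coords: np.ndarray  # trials x 2
    channel_vectors: np.ndarray  # channels x 2, back-projected loadings
    variance_captured_pct: float


def icapca_2d(features: np.ndarray, seed: int = 0) -> IcaPcaResult:
    """Decompose per-trial channel features into 2D: PCA to the top two
    components, then an infomax ICA rotation within that plane.

    Component sign is fixed by making each component's largest-magnitude
    channel loading positive; component order is descending projected
    variance. ``features`` is trials × channels.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 10 or X.shape[1] < 2:
        raise ValueError("need >= 10 trials and >= 2 channels")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("feature matrix has rank < 2")
    scores = Xc @ Vt[:2].T  # trials x 2
    var_captured = float(100.0 * (s[:2] ** 2).sum() / (s**2).sum())

    from mne.preprocessing import infomax  # heavy import kept lazy

    W = infomax(scores, random_state=seed, verbose="error")  # 2x2 unmixing
    coords = scores @ W.T
    # channel back-projection: columns of V2 @ W^{-1} are each component's
    # loading pattern across channels
    vectors = Vt[:2].T @ np.linalg.inv(W)

    order = np.argsort(-coords.var(axis=0))
    coords, vectors = coords[:, order], vectors[:, order]
    for j in range(2):
        lead = np.argmax(np.abs(vectors[:, j]))
        if vectors[lead, j] < 0:
            vectors[:, j] *= -1
            coords[:, j] *= -1
    return IcaPcaResult(coords=coords, channel_vectors=vectors, variance_captured_pct=var_captured)


def null_trend_rejection_rate(
    n_replicates: int = 1000,
    n_sessions: int = 16,
    span_days: int = 604,
    noise_sd: float = 1.0,
    mean: float = 95.0,
    alpha: float = ALPHA,
    seed: int = 0,
) -> float:
    """Type-I error of the slope F-test under a drift-free null.

    Session accuracies are simulated as i.i.d. Gaussian around a constant
    mean over the standard session-day grid; the returned fraction of
    replicates with p < alpha should sit near alpha for a calibrated test.
    """
    rng = np.random.default_rng(seed)
    days = np.round(np.linspace(0, span_days, n_sessions))
    rejections = 0
    for _ in range(n_replicates):
        y = mean + noise_sd * rng.standard_normal(n_sessions)
        if fit_trend(days, y, alpha).p_value < alpha:
            rejections += 1
    return rejections / n_replicates
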