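"""Electrical-activity burden of bipolar electrograms.

The burden of a channel is the fraction of time it shows electrical
activity, scored in [0, 1] by a fully unsupervised two-state Gaussian
hidden Markov model on framed log-energy features: 0 means no activity in
the window, 1 continuous activity. The state with the larger emission mean
is "active" and the score is the active fraction of the most-probable
(Viterbi) state path.

Two-state models are meaningless on single-regime channels (pure silence,
or activity filling the whole window): the fitted means collapse. When the
state means are inseparable the channel is classified whole by the excess
kurtosis of its raw samples — Gaussian noise has excess kurtosis ~0 while
an impulsive electrogram train is heavy-tailed — which keeps the score
invariant to global amplitude rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM

# EM stopping on a sub-tolerance likelihood dip is expected with floored
# variances; the restart protocol already guards against bad optima
logging.getLogger("hmmlearn").setLevel(logging.ERROR)
from scipy import stats as sps
from sklearn.cluster import KMeans

from .errors import UndefinedBurdenError
from .simulate import Acquisition

LOG_ENERGY_EPS = 1e-12  # mV^2


@dataclass(frozen=True)
class ActivityFeatureSeries:
    """Framed activity feature of one channel (log mean-square amplitude)."""

    frame_values: np.ndarray
    frame_ms: float
    hop_ms: float

    def __len__(self):
        return len(self.frame_values)


@dataclass
class BurdenResult:
    score: float
    state_path: np.ndarray  # 1 = active per frame
    means: np.ndarray
    variances: np.ndarray
    transmat: np.ndarray
    log_likelihood: float
    n_restarts_used: int
    seed: int | None
    states_separated: bool = True
    variance_floored: bool = False


def extract_activity_features(
    channel: np.ndarray,
    sampling_rate_hz: float,
    frame_ms: float = 50.0,
    hop_ms: float = 25.0,
) -> ActivityFeatureSeries:
    """Per-frame ``log(eps + mean squared amplitude)`` of a channel.

    Frames of ``frame_ms`` advance by ``hop_ms``; a channel shorter than one
    frame falls back to a single frame covering all of it.
    """
    x = np.asarray(channel, dtype=float)
    frame = int(round(frame_ms * sampling_rate_hz / 1000.0))
    hop = int(round(hop_ms * sampling_rate_hz / 1000.0))
    if len(x) < frame:
        vals = np.array([np.log(LOG_ENERGY_EPS + np.mean(x**2))])
        return ActivityFeatureSeries(vals, frame_ms=len(x) * 1000.0 / sampling_rate_hz, hop_ms=hop_ms)
    n_frames = (len(x) - frame) // hop + 1
    starts = np.arange(n_frames) * hop
    vals = np.array(
        [np.log(LOG_ENERGY_EPS + np.mean(x[s : s + frame] ** 2)) for s in starts]
    )
    return ActivityFeatureSeries(vals, frame_ms=frame_ms, hop_ms=hop_ms)


def fit_burden_hmm(
    features: ActivityFeatureSeries,
    n_states: int = 2,
    n_restarts: int = 5,
    seed: int | None = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    min_state_separation: float = 1.0,
) -> BurdenResult:
    """Fit the two-state Gaussian HMM by EM with k-means-initialized restarts.

    Each restart initializes the state means with a seeded k-means on the
    features; the restart with the best final log-likelihood wins. The state
    path is decoded by Viterbi. ``min_state_separation`` (in log-energy
    nats) is the mean gap below which the two states are declared
    indistinguishable (single-regime channel, ``states_separated=False``);
    the caller then needs channel-level context to assign 0 or 1
    (see :func:`score_channel`).
    """
    v = np.asarray(features.frame_values, dtype=float).reshape(-1, 1)
    if len(v) < 10:
        raise ValueError("need >= 10 frames to fit the burden HMM")
    feat_var = float(np.var(v))
    var_floor = max(1e-6 * feat_var, 1e-12)
    rng = np.random.default_rng(seed)

    best = None
    floored = False
    for _ in range(n_restarts):
        rs = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=n_states, n_init=1, random_state=rs).fit(v)
        means = km.cluster_centers_.copy()
        covs = np.empty((n_states, 1))
        for k in range(n_states):
            pts = v[km.labels_ == k]
            covs[k, 0] = np.var(pts) if len(pts) > 1 else feat_var
        if np.any(covs < var_floor):
            floored = True
        covs = np.maximum(covs, var_floor)

        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=max_iter,
            tol=tol,
            init_params="",
            random_state=rs,
        )
        model.startprob_ = np.full(n_states, 1.0 / n_states)
        model.transmat_ = np.full((n_states, n_states), 0.1 / (n_states - 1))
        np.fill_diagonal(model.transmat_, 0.9)
        model.means_ = means
        model.covars_ = covs
        try:
            model.fit(v)
            ll = float(model.score(v))
        except (ValueError, np.linalg.LinAlgError):
            continue
        if best is None or ll > best[0]:
            best = (ll, model)

    if best is None:
        raise UndefinedBurdenError("every EM restart failed")
    ll, model = best
    means = model.means_.ravel()
    variances = np.maximum(np.asarray(model.covars_).reshape(n_states, -1)[:, 0], var_floor)
    active = int(np.argmax(means))
    path = (model.predict(v) == active).astype(int)
    separated = bool(abs(means.max() - means.min()) >= min_state_separation)
    return BurdenResult(
        score=float(path.mean()),
        state_path=path,
        means=means,
        variances=variances,
        transmat=np.asarray(model.transmat_),
        log_likelihood=ll,
        n_restarts_used=n_restarts,
        seed=seed,
        states_separated=separated,
        variance_floored=floored,
    )


def _excess_kurtosis(x: np.ndarray) -> float:
    return float(sps.kurtosis(x, fisher=True, bias=False))


def score_channel(
    channel: np.ndarray,
    sampling_rate_hz: float,
    frame_ms: float = 50.0,
    hop_ms: float = 25.0,
    seed: int | None = 0,
    kurtosis_threshold: float = 1.0,
    **hmm_kwargs,
) -> BurdenResult:
    """Burden of one bipolar channel: features, HMM fit, single-regime guard.

    When the fitted states are inseparable the whole window is one regime;
    the channel scores 1.0 if its raw samples are impulsive (excess kurtosis
    above ``kurtosis_threshold``) and 0.0 if they are Gaussian-like noise.
    """
    feats = extract_activity_features(channel, sampling_rate_hz, frame_ms, hop_ms)
    res = fit_burden_hmm(feats, seed=seed, **hmm_kwargs)
    if not res.states_separated:
        single = 1.0 if _excess_kurtosis(np.asarray(channel, float)) > kurtosis_threshold else 0.0
        res.score = single
        res.state_path = np.full(len(res.state_path), int(single))
    return res


def burden_per_acquisition(
    acquisition: Acquisition,
    seed: int | None = 0,
    **kwargs,
):
    """Mean burden over the bipolar channels of an acquisition.

    Channels whose fit fails are excluded and counted. Returns
    ``(mean_score, per_channel_scores, n_failed)``; raises
    :class:`UndefinedBurdenError` if every channel fails.
    """
    scores, n_failed = [], 0
    for j in range(acquisition.bipolar.shape[1]):
        try:
            r = score_channel(
                acquisition.bipolar[:, j],
                acquisition.sampling_rate_hz,
                seed=None if seed is None else seed + j,
                **kwargs,
            )
            scores.append(r.score)
        except (ValueError, UndefinedBurdenError):
            n_failed += 1
    if not scores:
        raise UndefinedBurdenError("all bipolar channels failed the burden fit")
    return float(np.mean(scores)), np.array(scores), n_failed
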