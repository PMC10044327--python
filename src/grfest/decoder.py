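"""Early-phase stepping-direction decoding from the estimated GRF.

Because the ground reaction force changes before the centre of mass moves, the
direction of an incipient step (left / right / forward) can be read from the
estimated wrench within the first ~200 ms of the shear-force onset. Onsets are
detected where the horizontal force magnitude sqrt(Fx^2 + Fy^2) crosses a
threshold (default 5% of body weight) after a quiet period; each episode is
summarized by the mean and slope of every wrench channel over the early
window, and a linear one-vs-rest support vector machine separates the three
directions. Decoding operates on the *estimated* wrench only — the measured
plate signal is never required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .errors import ConfigurationError, DataError, ModelError
from .dataset import WRENCH_CHANNELS
from .synth import FS_FEATURE, G, STEP_DIRECTIONS

DEFAULT_WINDOW_S = 0.2
N_FEATURES = 2 * len(WRENCH_CHANNELS)  # mean + slope per channel


@dataclass
class StepEpisode:
    """One detected step: onset time, early wrench window, optional label."""

    onset_time: float
    feature_window: np.ndarray       # (n_frames, 6) estimated wrench
    label: str | None = None

    def __post_init__(self):
        if self.label is not None and self.label not in STEP_DIRECTIONS:
            raise DataError(f"label must be one of {STEP_DIRECTIONS}")


def detect_step_onsets(wrench: np.ndarray, body_mass_kg: float,
                       fs: float = FS_FEATURE,
                       threshold_frac: float = 0.05,
                       quiet_s: float = 0.5,
                       refractory_s: float = 1.0) -> np.ndarray:
    """Onset times where |F_horizontal| crosses threshold after a quiet spell.

    The horizontal shear is measured relative to its session median so slow
    sway offsets do not mask step transients. Returns onset times in seconds.
    """
    if threshold_frac <= 0:
        raise ConfigurationError("threshold_frac must be positive")
    wrench = np.asarray(wrench, dtype=float)
    fx = wrench[:, 0] - np.median(wrench[:, 0])
    fy = wrench[:, 1] - np.median(wrench[:, 1])
    mag = np.hypot(fx, fy)
    thr = threshold_frac * body_mass_kg * G
    above = mag > thr
    quiet_n = max(1, int(round(quiet_s * fs)))
    refr_n = max(1, int(round(refractory_s * fs)))
    onsets = []
    last = -refr_n
    for k in range(quiet_n, len(mag)):
        if above[k] and not above[k - quiet_n:k].any() and k - last >= refr_n:
            onsets.append(k)
            last = k
    return np.asarray(onsets) / fs


def extract_episodes(wrench: np.ndarray, onset_times, fs: float = FS_FEATURE,
                     window_s: float = DEFAULT_WINDOW_S,
                     labels=None) -> list:
    """Cut the early window after each onset; truncated windows are skipped."""
    wrench = np.asarray(wrench, dtype=float)
    w = max(2, int(round(window_s * fs)))
    episodes = []
    for j, t0 in enumerate(onset_times):
        k = int(round(t0 * fs))
        if k + w > len(wrench):
            import warnings
            warnings.warn(f"episode at {t0:.2f}s truncated by session end; skipped")
            continue
        episodes.append(StepEpisode(
            onset_time=float(t0), feature_window=wrench[k:k + w],
            label=None if labels is None else labels[j]))
    return episodes


def featurize_episode(episode: StepEpisode) -> np.ndarray:
    """Per-channel mean and slope over the early window (12 values)."""
    win = episode.feature_window
    t = np.arange(len(win), dtype=float)
    t = t - t.mean()
    denom = float((t * t).sum())
    means = win.mean(axis=0)
    slopes = (t @ win) / denom if denom > 0 else np.zeros(win.shape[1])
    return np.concatenate([means, slopes])


@dataclass
class DecoderModel:
    """Standardizer + linear one-vs-rest SVM over episode features."""

    pipeline: object = None
    classes_: tuple = field(default_factory=tuple)

    @property
    def fitted(self) -> bool:
        return self.pipeline is not None


def fit_decoder(episodes, seed: int = 0) -> DecoderModel:
    """Fit the maximum-margin linear classifier on labelled episodes."""
    episodes = list(episodes)
    labels = [e.label for e in episodes]
    if any(l is None for l in labels):
        raise DataError("all training episodes must carry a direction label")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise DataError("need at least 2 direction classes to fit the decoder")
    for c in classes:
        if labels.count(c) < 3:
            raise DataError(f"need >= 3 episodes per class; class {c!r} has "
                            f"{labels.count(c)}")
    X = np.stack([featurize_episode(e) for e in episodes])
    pipe = make_pipeline(
        StandardScaler(),
        LinearSVC(C=1.0, multi_class="ovr", random_state=seed, max_iter=10000),
    )
    pipe.fit(X, labels)
    return DecoderModel(pipeline=pipe, classes_=tuple(classes))


def predict_direction(model: DecoderModel, episode: StepEpisode) -> str:
    """Deterministic direction label for one episode."""
    if not model.fitted:
        raise ModelError("decoder has not been fitted")
    x = featurize_episode(episode)[None]
    return str(model.pipeline.predict(x)[0])


def decoder_accuracy(model: DecoderModel, episodes) -> float:
    """Fraction of labelled episodes whose prediction matches the label."""
    episodes = [e for e in episodes if e.label is not None]
    if not episodes:
        raise DataError("no labelled episodes to score")
    hits = sum(predict_direction(model, e) == e.label for e in episodes)
    return hits / len(episodes)


def match_events(onset_times, true_times, tol_s: float = 0.1):
    """Greedy one-to-one matching of detected onsets to true event times.

    Returns indices into ``true_times`` (or -1) for each detected onset.
    """
    onset_times = np.asarray(onset_times, dtype=float)
    true_times = np.asarray(true_times, dtype=float)
    taken = np.zeros(len(true_times), dtype=bool)
    out = []
    for t0 in onset_times:
        d = np.abs(true_times - t0)
        d[taken] = np.inf
        j = int(np.argmin(d)) if len(d) else -1
        if j >= 0 and d[j] <= tol_s:
            taken[j] = True
            out.append(j)
        else:
            out.append(-1)
    return np.asarray(out)
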