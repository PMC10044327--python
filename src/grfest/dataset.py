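"""Model-ready sequence assembly: input patterns, split, scaling, windows.

Six sensor-combination patterns are studied (EMG sensors are numbered per
muscle, IMUs sit on shanks {1,4} and thighs {7,9}):

====  ==========  ===========  ======================================
id    EMG         IMU          remark
====  ==========  ===========  ======================================
1     1-10        --           all muscles
2     --          1,4,7,9      IMUs on thighs and shanks
3     1-10        1,4,7,9      all muscles + all IMUs
4     1-6         --           below-knee muscles (TA, GAS, PL)
5     --          1,4          IMUs on shanks
6     1-6         1,4          below-knee muscles + shank IMUs
====  ==========  ===========  ======================================

The session is split chronologically 50/50 into train and test halves (random
splitting of overlapping windows would leak temporal context across the
boundary). Inputs are z-scored with statistics from the training half only;
targets stay in physical units at this stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

WRENCH_CHANNELS = ("Fx", "Fy", "Fz", "Mx", "My", "Mz")
IMU_AXES = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")

DEFAULT_WINDOW_LENGTH = 128  # frames (~1.7 s at 74.074 Hz)


@dataclass(frozen=True)
class InputPattern:
    """One sensor-combination row: which EMG and IMU sensors feed the model."""

    id: int
    emg_sensors: tuple
    imu_sensors: tuple

    def __post_init__(self):
        if not self.emg_sensors and not self.imu_sensors:
            raise ConfigurationError("a pattern must select at least one sensor")

    @property
    def dim(self) -> int:
        """Input dimensionality: one envelope per EMG sensor + 6 per IMU."""
        return len(self.emg_sensors) + 6 * len(self.imu_sensors)

    @property
    def columns(self) -> list:
        cols = [f"env{s}" for s in self.emg_sensors]
        for s in self.imu_sensors:
            cols += [f"imu{s}_{ax}" for ax in IMU_AXES]
        return cols


PATTERNS = {
    1: InputPattern(1, tuple(range(1, 11)), ()),
    2: InputPattern(2, (), (1, 4, 7, 9)),
    3: InputPattern(3, tuple(range(1, 11)), (1, 4, 7, 9)),
    4: InputPattern(4, tuple(range(1, 7)), ()),
    5: InputPattern(5, (), (1, 4)),
    6: InputPattern(6, tuple(range(1, 7)), (1, 4)),
}


def get_pattern(pattern_id: int) -> InputPattern:
    try:
        return PATTERNS[pattern_id]
    except KeyError:
        raise ConfigurationError(f"pattern_id must be 1..6, got {pattern_id}")


def select_pattern(features: pd.DataFrame, pattern: InputPattern) -> pd.DataFrame:
    """Restrict the feature frame to the pattern's columns (plus time)."""
    missing = [c for c in pattern.columns if c not in features.columns]
    if missing:
        raise DataError(f"feature frame is missing channel(s): {', '.join(missing)}")
    return features[["t"] + pattern.columns].copy()


def split_half(frame: pd.DataFrame, fraction: float = 0.5):
    """Chronological split: first ``fraction`` of frames train, rest test."""
    if len(frame) < 2:
        raise DataError("need at least 2 frames to split")
    n_train = int(len(frame) * fraction)
    return (frame.iloc[:n_train].reset_index(drop=True),
            frame.iloc[n_train:].reset_index(drop=True))


@dataclass
class ChannelStats:
    """Per-channel mean/scale learned on the training split."""

    mean: np.ndarray
    scale: np.ndarray
    columns: list

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.scale

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale + self.mean


def compute_stats(train: np.ndarray, columns) -> ChannelStats:
    mean = train.mean(axis=0)
    scale = train.std(axis=0, ddof=0)
    zero = scale == 0
    if zero.any():
        bad = [c for c, z in zip(columns, zero) if z]
        warnings.warn(f"zero-variance channel(s) {bad}; scale set to 1")
        scale = np.where(zero, 1.0, scale)
    return ChannelStats(mean=mean, scale=scale, columns=list(columns))


def standardize(train: pd.DataFrame, test: pd.DataFrame):
    """z-score both halves with train-only stats (time column untouched)."""
    cols = [c for c in train.columns if c != "t"]
    stats = compute_stats(train[cols].to_numpy(dtype=float), cols)
    out = []
    for frame in (train, test):
        f = frame.copy()
        f[cols] = stats.transform(f[cols].to_numpy(dtype=float))
        out.append(f)
    return out[0], out[1], stats


def make_windows(x: np.ndarray, window_length: int) -> list:
    """Non-overlapping contiguous windows; last partial window kept."""
    if window_length < 1:
        raise ConfigurationError("window_length must be >= 1")
    return [x[i:i + window_length] for i in range(0, len(x), window_length)]


@dataclass
class SequenceDataset:
    """Standardized inputs + physical-unit targets for one pattern.

    X_* are (n_frames, d) float arrays on the 74.074 Hz timebase; Y_* are
    (n_frames, 6) wrench arrays in N / N*m. The split is chronological and
    the two halves are contiguous and disjoint.
    """

    pattern: InputPattern
    X_train: np.ndarray
    Y_train: np.ndarray
    X_test: np.ndarray
    Y_test: np.ndarray
    t_train: np.ndarray
    t_test: np.ndarray
    input_stats: ChannelStats
    window_length: int = DEFAULT_WINDOW_LENGTH
    split_fraction: float = 0.5

    @property
    def dim(self) -> int:
        return self.X_train.shape[1]

    def train_windows(self):
        return (make_windows(self.X_train, self.window_length),
                make_windows(self.Y_train, self.window_length))


def build_dataset(features: pd.DataFrame, targets: pd.DataFrame,
                  pattern_id: int, window_length: int = DEFAULT_WINDOW_LENGTH,
                  split_fraction: float = 0.5) -> SequenceDataset:
    """Pattern selection -> chronological split -> input standardization."""
    if len(features) != len(targets):
        raise DataError(
            f"features ({len(features)}) and targets ({len(targets)}) differ in length")
    pattern = get_pattern(pattern_id)
    sel = select_pattern(features, pattern)
    f_train, f_test = split_half(sel, split_fraction)
    y_train, y_test = split_half(targets, split_fraction)
    f_train_s, f_test_s, stats = standardize(f_train, f_test)
    cols = pattern.columns
    return SequenceDataset(
        pattern=pattern,
        X_train=f_train_s[cols].to_numpy(dtype=float),
        Y_train=y_train[list(WRENCH_CHANNELS)].to_numpy(dtype=float),
        X_test=f_test_s[cols].to_numpy(dtype=float),
        Y_test=y_test[list(WRENCH_CHANNELS)].to_numpy(dtype=float),
        t_train=f_train["t"].to_numpy(),
        t_test=f_test["t"].to_numpy(),
        input_stats=stats,
        window_length=window_length,
        split_fraction=split_fraction,
    )
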