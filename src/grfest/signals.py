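"""Filtering, EMG envelope extraction and multi-rate resampling.

The chain mirrors standard surface-EMG conditioning: a 4th-order Butterworth
band-pass (20-450 Hz) removes baseline drift and motion artifact from the raw
EMG, full-wave rectification followed by a 4th-order 3 Hz Butterworth low-pass
yields the linear envelope, and the same 3 Hz low-pass denoises the IMU and
wrench streams. All streams are then decimated onto a common 74.074 Hz
timebase (EMG by 15, IMU/wrench by 2); the 3 Hz low-pass doubles as the
anti-alias stage, so plain every-k-th-sample decimation is exact.

All offline filtering is zero-phase (forward-backward), so the EMG-to-force
timing encoded by the generator survives preprocessing. ``causal=True``
switches to a single forward pass for streaming-style use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigurationError, DataError
from .synth import FS_EMG, FS_IMU, FS_WRENCH, MUSCLE_BY_SENSOR, MultiRateRecording

EMG_BAND_HZ = (20.0, 450.0)
ENVELOPE_CUTOFF_HZ = 3.0
FILTER_ORDER = 4

#: integer decimation factors onto the 74.074 Hz feature timebase
DECIMATION = {"emg": 15, "imu": 2, "wrench": 2}


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter description. kind: 'bandpass' | 'lowpass'."""

    kind: str
    order: int
    cutoffs_hz: tuple

    def __post_init__(self):
        if self.kind not in ("bandpass", "lowpass"):
            raise ConfigurationError(f"unknown filter kind {self.kind!r}")
        n_expected = 2 if self.kind == "bandpass" else 1
        if len(self.cutoffs_hz) != n_expected:
            raise ConfigurationError(
                f"{self.kind} filter needs {n_expected} cutoff(s)")
        if self.kind == "bandpass" and not self.cutoffs_hz[0] < self.cutoffs_hz[1]:
            raise ConfigurationError("bandpass cutoffs must be increasing")
        if min(self.cutoffs_hz) <= 0:
            raise ConfigurationError("cutoffs must be positive")


EMG_BANDPASS = FilterSpec("bandpass", FILTER_ORDER, EMG_BAND_HZ)
ENVELOPE_LOWPASS = FilterSpec("lowpass", FILTER_ORDER, (ENVELOPE_CUTOFF_HZ,))


def design_filter(spec: FilterSpec, fs: float):
    """Butterworth (b, a) coefficients for the spec at sampling rate fs."""
    nyq = fs / 2.0
    if max(spec.cutoffs_hz) >= nyq:
        raise ConfigurationError(
            f"cutoff {max(spec.cutoffs_hz)} Hz >= Nyquist {nyq} Hz")
    wn = spec.cutoffs_hz if spec.kind == "bandpass" else spec.cutoffs_hz[0]
    return signal.butter(spec.order, wn, btype=spec.kind, fs=fs)


def apply_filter(x: np.ndarray, spec: FilterSpec, fs: float,
                 causal: bool = False) -> np.ndarray:
    """Filter along the last axis; zero-phase forward-backward by default."""
    b, a = design_filter(spec, fs)
    if causal:
        return signal.lfilter(b, a, x, axis=-1)
    return signal.filtfilt(b, a, x, axis=-1)


def bandpass_emg(emg: pd.DataFrame, fs: float = FS_EMG,
                 causal: bool = False) -> pd.DataFrame:
    """20-450 Hz band-pass on every EMG channel (columns except 't')."""
    out = emg.copy()
    for c in out.columns:
        if c == "t":
            continue
        out[c] = apply_filter(out[c].to_numpy(), EMG_BANDPASS, fs, causal)
    return out


def envelope(filtered_emg: pd.DataFrame, fs: float = FS_EMG,
             causal: bool = False) -> pd.DataFrame:
    """Linear envelope: full-wave rectification then the 3 Hz low-pass."""
    out = filtered_emg.copy()
    for c in out.columns:
        if c == "t":
            continue
        out[c] = apply_filter(np.abs(out[c].to_numpy()),
                              ENVELOPE_LOWPASS, fs, causal)
    return out


def lowpass_aux(stream: pd.DataFrame, fs: float,
                causal: bool = False) -> pd.DataFrame:
    """3 Hz low-pass denoising for IMU and wrench streams."""
    out = stream.copy()
    for c in out.columns:
        if c == "t":
            continue
        out[c] = apply_filter(out[c].to_numpy(), ENVELOPE_LOWPASS, fs, causal)
    return out


def decimate(stream: pd.DataFrame, factor: int) -> pd.DataFrame:
    """Every factor-th sample (anti-aliasing done by the prior 3 Hz low-pass)."""
    if factor < 1 or int(factor) != factor:
        raise ConfigurationError(f"decimation factor must be a positive integer, got {factor}")
    return stream.iloc[::int(factor)].reset_index(drop=True)


def _check_rate(name: str, fs: float, expected: float) -> None:
    if abs(fs - expected) > 1e-3 * expected:
        raise DataError(f"{name} stream rate {fs} Hz != expected {expected} Hz")


def resample_to_common(emg_env: pd.DataFrame, imu: pd.DataFrame,
                       wrench: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decimate all low-passed streams onto the shared 74.074 Hz timebase.

    Returns (features, targets): features holds the EMG envelopes (renamed
    env1..env10) and all IMU channels; targets holds the 6 wrench channels.
    Both carry the common 't' column and are truncated to equal length.
    """
    emg_d = decimate(emg_env, DECIMATION["emg"])
    imu_d = decimate(imu, DECIMATION["imu"])
    wrench_d = decimate(wrench, DECIMATION["wrench"])
    n = min(len(emg_d), len(imu_d), len(wrench_d))
    if max(len(emg_d), len(imu_d), len(wrench_d)) - n > 1:
        raise DataError("streams disagree in duration by more than one feature sample")
    emg_d, imu_d, wrench_d = emg_d.iloc[:n], imu_d.iloc[:n], wrench_d.iloc[:n]

    feats = {"t": emg_d["t"].to_numpy()}
    for s in sorted(MUSCLE_BY_SENSOR):
        feats[f"env{s}"] = emg_d[f"emg{s}"].to_numpy()
    for c in imu_d.columns:
        if c != "t":
            feats[c] = imu_d[c].to_numpy()
    features = pd.DataFrame(feats)
    targets = wrench_d.reset_index(drop=True).copy()
    targets["t"] = features["t"].to_numpy()  # shared timebase
    return features, targets


def preprocess_session(rec: MultiRateRecording,
                       causal: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full conditioning chain raw recording -> (features, targets) @ 74.074 Hz."""
    _check_rate("emg", rec.rates["emg"], FS_EMG)
    _check_rate("imu", rec.rates["imu"], FS_IMU)
    _check_rate("wrench", rec.rates["wrench"], FS_WRENCH)
    env = envelope(bandpass_emg(rec.emg, rec.rates["emg"], causal),
                   rec.rates["emg"], causal)
    imu_f = lowpass_aux(rec.imu, rec.rates["imu"], causal)
    wrench_f = lowpass_aux(rec.wrench, rec.rates["wrench"], causal)
    return resample_to_common(env, imu_f, wrench_f)
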