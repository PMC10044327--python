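"""Session, feature and model (de)serialization.

A session directory holds one CSV per stream plus a JSON sidecar:

    emg.csv       t + emg1..emg10           @ 1,111.11 Hz
    imu.csv       t + imu{n}_{acc,gyro}_{x,y,z} for n in {1,4,7,9} @ 148.148 Hz
    wrench.csv    t + Fx Fy Fz Mx My Mz     @ 148.148 Hz
    session.json  config, seed, rates, sensor-to-muscle channel map

Models are stored as an .npz of arrays plus a JSON hyperparameter sidecar and
a JSONL training log.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .synth import (FS_EMG, FS_IMU, FS_WRENCH, MUSCLE_BY_SENSOR, IMU_SEGMENT,
                    MultiRateRecording, SessionConfig)
from .lstm import LSTMParams, TrainConfig, TrainedModel

_FLOAT_FMT = "%.8g"


def write_session(rec: MultiRateRecording, config: SessionConfig,
                  outdir) -> Path:
    """Write the three stream CSVs and the metadata sidecar; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec.emg.to_csv(outdir / "emg.csv", index=False, float_format=_FLOAT_FMT)
    rec.imu.to_csv(outdir / "imu.csv", index=False, float_format=_FLOAT_FMT)
    rec.wrench.to_csv(outdir / "wrench.csv", index=False, float_format=_FLOAT_FMT)
    meta = {
        "config": config.to_dict(),
        "seed": config.seed,
        "rates": rec.rates,
        "channel_map": {str(k): v for k, v in rec.channel_map.items()},
        "n_samples": {"emg": len(rec.emg), "imu": len(rec.imu),
                      "wrench": len(rec.wrench)},
    }
    (outdir / "session.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return outdir


def _expect_columns(df: pd.DataFrame, cols, fname: str) -> None:
    for c in cols:
        if c not in df.columns:
            extra = ""
            if c.startswith("emg"):
                n = int(c[3:])
                muscle = MUSCLE_BY_SENSOR[n].replace("_R", " right").replace("_L", " left")
                extra = f" ({muscle} / sensor {n})"
            raise DataError(f"{fname} is missing channel {c!r}{extra}")


def read_session(session_dir) -> tuple[MultiRateRecording, SessionConfig]:
    """Load and validate a session directory written by :func:`write_session`."""
    session_dir = Path(session_dir)
    meta_path = session_dir / "session.json"
    if not meta_path.exists():
        raise DataError(f"no session.json in {session_dir}")
    meta = json.loads(meta_path.read_text())
    config = SessionConfig.from_dict(meta["config"])
    rates = meta.get("rates", {"emg": FS_EMG, "imu": FS_IMU, "wrench": FS_WRENCH})
    for name, expected in (("emg", FS_EMG), ("imu", FS_IMU), ("wrench", FS_WRENCH)):
        if abs(rates[name] - expected) > 1e-3 * expected:
            raise DataError(f"{name} rate {rates[name]} Hz != expected {expected} Hz")

    emg = pd.read_csv(session_dir / "emg.csv")
    imu = pd.read_csv(session_dir / "imu.csv")
    wrench = pd.read_csv(session_dir / "wrench.csv")
    _expect_columns(emg, ["t"] + [f"emg{n}" for n in sorted(MUSCLE_BY_SENSOR)],
                    "emg.csv")
    imu_cols = ["t"] + [f"imu{n}_{k}_{ax}" for n in IMU_SEGMENT
                        for k in ("acc", "gyro") for ax in "xyz"]
    _expect_columns(imu, imu_cols, "imu.csv")
    _expect_columns(wrench, ["t", "Fx", "Fy", "Fz", "Mx", "My", "Mz"],
                    "wrench.csv")

    dur = config.duration_s
    for name, df, fs in (("emg", emg, FS_EMG), ("imu", imu, FS_IMU),
                         ("wrench", wrench, FS_WRENCH)):
        expected_n = int(round(dur * fs))
        if abs(len(df) - expected_n) > 1:
            raise DataError(
                f"{name}.csv has {len(df)} rows; expected {expected_n} "
                f"for a {dur} s stream at {fs} Hz (ragged/truncated file?)")
    if abs(len(imu) - len(wrench)) > 1:
        raise DataError("imu.csv and wrench.csv lengths disagree")

    rec = MultiRateRecording(
        emg=emg, imu=imu, wrench=wrench, rates=dict(rates),
        channel_map={int(k): v for k, v in meta["channel_map"].items()},
    )
    return rec, config


def write_features(features: pd.DataFrame, targets: pd.DataFrame, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    features.to_csv(outdir / "features.csv", index=False, float_format=_FLOAT_FMT)
    targets.to_csv(outdir / "targets.csv", index=False, float_format=_FLOAT_FMT)
    return outdir


def read_features(indir) -> tuple[pd.DataFrame, pd.DataFrame]:
    indir = Path(indir)
    return (pd.read_csv(indir / "features.csv"),
            pd.read_csv(indir / "targets.csv"))


_PARAM_KEYS = ("Wxf", "Wxg", "Wxi", "Wxo", "Whf", "Whg", "Whi", "Who",
               "bf", "bg", "bi", "bo", "Wout", "bout")


def save_model(model: TrainedModel, outdir) -> Path:
    """Portable checkpoint: arrays in .npz, hyperparameters in JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays = {k: getattr(model.params, k) for k in _PARAM_KEYS}
    arrays["target_mean"] = model.target_mean
    arrays["target_scale"] = model.target_scale
    np.savez(outdir / "model.npz", **arrays)
    meta = {
        "pattern_id": model.pattern_id,
        "g_gate": model.params.g_gate,
        "train_config": {k: getattr(model.train_config, k)
                         for k in ("batch_size", "learning_rate", "dropout_p",
                                   "max_epochs", "patience", "val_fraction",
                                   "seed", "hidden_size", "g_gate")},
    }
    (outdir / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    with open(outdir / "training_log.jsonl", "w") as fh:
        for row in model.log:
            fh.write(json.dumps(row) + "\n")
    return outdir


def load_model(indir) -> TrainedModel:
    indir = Path(indir)
    meta = json.loads((indir / "model.json").read_text())
    with np.load(indir / "model.npz") as z:
        arrays = {k: z[k] for k in z.files}
    params = LSTMParams(**{k: arrays[k] for k in _PARAM_KEYS},
                        g_gate=meta["g_gate"])
    log = []
    log_path = indir / "training_log.jsonl"
    if log_path.exists():
        log = [json.loads(line) for line in log_path.read_text().splitlines()
               if line.strip()]
    return TrainedModel(
        params=params,
        target_mean=arrays["target_mean"],
        target_scale=arrays["target_scale"],
        pattern_id=meta["pattern_id"],
        train_config=TrainConfig(**meta["train_config"]),
        log=log,
    )
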