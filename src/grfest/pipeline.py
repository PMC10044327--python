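"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate -> decode.

`run_single` trains and scores one input pattern on one session;
`run_experiment` sweeps all six sensor-combination patterns on the same
session and renders the 6-row results table. `run_decoding_benchmark` trains
the wrench estimator on a stepping session, decodes step direction from the
*estimated* GRF on the held-out half, and reports held-out accuracy next to a
label-permutation control. Everything is deterministic given the config seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decoder as dec
from .dataset import SequenceDataset, build_dataset, PATTERNS
from .evaluation import EvalReport, evaluate_wrench, render_table
from .lstm import TrainConfig, TrainedModel, mean_predictor_baseline, predict_wrench, train_model
from .signals import preprocess_session
from .synth import FS_FEATURE, GroundTruthBundle, SessionConfig, generate_session

log = logging.getLogger("grfest")


@dataclass
class RunConfig:
    """Reproducible description of a full experiment run."""

    session: SessionConfig = field(default_factory=SessionConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    pattern_ids: tuple = (1, 2, 3, 4, 5, 6)
    window_length: int = 128
    normalization: str = "range"

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        d["pattern_ids"] = list(self.pattern_ids)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("session"), dict):
            d["session"] = SessionConfig.from_dict(d["session"])
        if isinstance(d.get("train"), dict):
            d["train"] = TrainConfig(**d["train"])
        if "pattern_ids" in d:
            d["pattern_ids"] = tuple(d["pattern_ids"])
        return cls(**d)


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from a YAML file (a run is reproducible from it)."""
    import yaml
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_run_config(config: RunConfig, path) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


@dataclass
class SingleRunResult:
    report: EvalReport
    model: TrainedModel
    dataset: SequenceDataset
    estimated: np.ndarray       # test-half wrench estimate, physical units
    baseline_report: EvalReport


def prepare_features(session_config: SessionConfig):
    """Simulate and preprocess one session; returns (features, targets, bundle)."""
    rec, bundle = generate_session(session_config)
    features, targets = preprocess_session(rec)
    return features, targets, bundle


def run_single(features: pd.DataFrame, targets: pd.DataFrame,
               session_config: SessionConfig, pattern_id: int,
               train_config: TrainConfig | None = None,
               window_length: int = 128,
               normalization: str = "range") -> SingleRunResult:
    """Train and evaluate one pattern on preprocessed features."""
    train_config = train_config or TrainConfig()
    ds = build_dataset(features, targets, pattern_id, window_length)
    log.info("pattern %d: training (d=%d, %d train frames)",
             pattern_id, ds.dim, len(ds.X_train))
    model = train_model(ds, train_config)
    est = predict_wrench(model, ds.X_test)
    report = evaluate_wrench(est, ds.Y_test, pattern_id,
                             session_config.motion_type, normalization)
    baseline = evaluate_wrench(mean_predictor_baseline(ds.Y_train, ds.Y_test),
                               ds.Y_test, pattern_id,
                               session_config.motion_type, normalization)
    log.info("pattern %d: GRF %.2f%% +- %.2f%%, GRM %.2f%% +- %.2f%%",
             pattern_id, report.grf_mean, report.grf_se,
             report.grm_mean, report.grm_se)
    return SingleRunResult(report=report, model=model, dataset=ds,
                           estimated=est, baseline_report=baseline)


def run_experiment(config: RunConfig):
    """All requested patterns on one session -> (reports, table df, table text)."""
    features, targets, _ = prepare_features(config.session)
    reports = []
    for pid in config.pattern_ids:
        res = run_single(features, targets, config.session, pid,
                         config.train, config.window_length,
                         config.normalization)
        reports.append(res.report)
    if set(config.pattern_ids) == set(PATTERNS):
        df, text = render_table(reports)
    else:
        df, text = None, None
    return reports, df, text


def run_decoding_benchmark(session_config: SessionConfig,
                           result: SingleRunResult,
                           bundle: GroundTruthBundle,
                           window_s: float = 0.2,
                           seed: int = 0,
                           permute: bool = False,
                           n_permutations: int = 10) -> dict:
    """Early-window direction decoding from the estimated GRF, held-out scored.

    Steps are detected on the test-half *estimate*, matched to ground-truth
    events for labels, split chronologically into decoder train/test halves,
    and scored. ``permute=True`` refits with shuffled training labels
    ``n_permutations`` times and reports the mean held-out accuracy — the
    chance-level control.
    """
    ds = result.dataset
    t0 = ds.t_test[0]
    onsets = dec.detect_step_onsets(result.estimated,
                                    session_config.body_mass_kg) + t0
    true_times = np.array([ev.time_s for ev in bundle.step_events])
    true_labels = [ev.direction for ev in bundle.step_events]
    matches = dec.match_events(onsets, true_times, tol_s=0.25)
    keep = matches >= 0
    onsets, matches = onsets[keep], matches[keep]
    labels = [true_labels[j] for j in matches]
    episodes = dec.extract_episodes(result.estimated, onsets - t0,
                                    fs=FS_FEATURE, window_s=window_s,
                                    labels=labels)
    # chronological half-split within each class keeps the three directions
    # represented on both sides even for short sessions
    train_eps, test_eps = [], []
    for cls in sorted({e.label for e in episodes}):
        eps_c = [e for e in episodes if e.label == cls]
        n_tr = (len(eps_c) + 1) // 2
        train_eps += eps_c[:n_tr]
        test_eps += eps_c[n_tr:]
    train_eps.sort(key=lambda e: e.onset_time)
    test_eps.sort(key=lambda e: e.onset_time)
    rng = np.random.default_rng(seed)
    n_fits = n_permutations if permute else 1
    accs = []
    for _ in range(n_fits):
        fit_eps = train_eps
        if permute:
            shuffled = [e.label for e in train_eps]
            rng.shuffle(shuffled)
            fit_eps = [dec.StepEpisode(e.onset_time, e.feature_window, l)
                       for e, l in zip(train_eps, shuffled)]
        model = dec.fit_decoder(fit_eps, seed=seed)
        accs.append(dec.decoder_accuracy(model, test_eps))
    return {"n_episodes": len(episodes), "n_train": len(train_eps),
            "n_test": len(test_eps), "accuracy": float(np.mean(accs)),
            "n_fits": n_fits, "permuted": permute}


def reports_to_frame(reports) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"pattern_id": r.pattern_id, "motion_type": r.motion_type,
               **r.per_axis_pct_rmse,
               "grf_mean": r.grf_mean, "grf_se": r.grf_se,
               "grm_mean": r.grm_mean, "grm_se": r.grm_se,
               "accuracy_pct": r.accuracy_pct}
        rows.append(row)
    return pd.DataFrame(rows)
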