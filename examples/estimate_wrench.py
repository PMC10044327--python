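"""Train the LSTM wrench estimator on a synthetic sway session.

Simulates 120 s of posture-control motion, extracts EMG envelopes and IMU
channels at 74.074 Hz, trains the pattern-6 model (below-knee muscles + shank
IMUs, 18 inputs) on the first half, and reports per-axis %RMSE on the second
half. Expect a few minutes of CPU time.
"""

from grfest import SessionConfig, TrainConfig, prepare_features, run_single

cfg = SessionConfig(motion_type="pcm", duration_s=120.0, seed=1)
features, targets, _ = prepare_features(cfg)
res = run_single(features, targets, cfg, pattern_id=6,
                 train_config=TrainConfig(seed=1))

rep = res.report
print(f"trained {len(res.model.log)} epochs on {len(res.dataset.X_train)} frames")
print("\ntest-half %RMSE per axis (range-normalized):")
for ax, v in rep.per_axis_pct_rmse.items():
    print(f"  {ax}: {v:6.2f} %")
print(f"\nGRF (forces)  : {rep.grf_mean:.2f} % +- {rep.grf_se:.2f} % (mean +- SE)")
print(f"GRM (moments) : {rep.grm_mean:.2f} % +- {rep.grm_se:.2f} %")
print(f"accuracy      : {rep.accuracy_pct:.2f} %  (= 100 - GRF mean)")
print("\nmean-predictor baseline for reference:")
for ax, v in res.baseline_report.per_axis_pct_rmse.items():
    print(f"  {ax}: {v:6.2f} %")
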