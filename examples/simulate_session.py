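"""Generate a synthetic posture-control session and inspect its streams.

Builds 30 s of quasi-periodic sway for a 70 kg subject, synthesizes the ten
EMG channels, four 6-axis IMUs and the force-plate wrench at their native
rates, and prints basic physical sanity numbers.
"""

import numpy as np

from grfest import SessionConfig, generate_session

cfg = SessionConfig(motion_type="pcm", duration_s=30.0, seed=42)
rec, truth = generate_session(cfg)

print(f"EMG    : {rec.emg.shape[0]:7d} samples @ {rec.rates['emg']} Hz, "
      f"{rec.emg.shape[1] - 1} channels")
print(f"IMU    : {rec.imu.shape[0]:7d} samples @ {rec.rates['imu']} Hz, "
      f"{rec.imu.shape[1] - 1} channels")
print(f"wrench : {rec.wrench.shape[0]:7d} samples @ {rec.rates['wrench']} Hz")

bw = cfg.body_mass_kg * 9.81
print(f"\nmean Fz = {rec.wrench['Fz'].mean():.1f} N "
      f"(body weight {bw:.1f} N)  -> the plate supports the subject")
print(f"Fx swing = +-{rec.wrench['Fx'].std() * 2:.1f} N "
      "-> anteroposterior sway inertia")
act = truth.activations.drop(columns='t').to_numpy()
print(f"activations in [{act.min():.2f}, {act.max():.2f}] "
      "-> muscle drives stay physiological (0..1)")
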