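"""Synthetic session generator: determinism, physics, and timing structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram

from grfest import (FS_EMG, FS_FEATURE, FS_IMU, MUSCLE_BY_SENSOR,
                    NoiseLevels, SessionConfig, generate_activations,
                    generate_kinematics, generate_session, synthesize_emg,
                    synthesize_imu, synthesize_wrench)
from grfest.errors import ConfigurationError
from grfest.io import write_session

QUIET = NoiseLevels(emg=0.0, imu=0.0, wrench=0.0)


def quiet_cfg(**kw):
    base = dict(motion_type="pcm", duration_s=30.0, seed=3, noise=QUIET,
                artifact_amplitude=0.0)
    base.update(kw)
    return SessionConfig(**base)


class TestActivations:
    def test_zero_sway_gives_constant_baseline(self):
        act = generate_activations(quiet_cfg(sway_amplitude_deg=0.0))
        for n in MUSCLE_BY_SENSOR:
            a = act[f"act{n}"].to_numpy()
            assert np.allclose(a, a[0])

    def test_bounded_and_deterministic(self):
        cfg = SessionConfig(motion_type="pcm", duration_s=20.0, seed=7)
        a1 = generate_activations(cfg)
        a2 = generate_activations(cfg)
        pd.testing.assert_frame_equal(a1, a2)
        vals = a1.drop(columns="t").to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_unknown_motion_type_rejected(self):
        with pytest.raises(ConfigurationError):
            SessionConfig(motion_type="walking").validate()

    def test_sm_burst_lead_measured_by_cross_correlation(self):
        """Activation bursts precede the shear-force onset by 50-150 ms."""
        cfg = quiet_cfg(motion_type="sm", duration_s=60.0, seed=5)
        com, events = generate_kinematics(cfg)
        act = generate_activations(cfg, com, events)
        wrench = synthesize_wrench(act, com, events, cfg)
        t_w = wrench["t"].to_numpy()
        shear = np.hypot(wrench["Fx"] - np.median(wrench["Fx"]),
                         wrench["Fy"] - np.median(wrench["Fy"]))
        t_a = act["t"].to_numpy()
        prime_mover = {"forward": "act1", "left": "act6", "right": "act3"}
        fs = len(t_w) / cfg.duration_s
        leads = []
        for ev in events[:10]:
            drive = np.interp(t_w, t_a, act[prime_mover[ev.direction]].to_numpy())
            lo, hi = ev.time_s - 0.4, ev.time_s + 0.45
            m = (t_w >= lo) & (t_w <= hi)
            a_win = drive[m] - drive[m].mean()
            s_win = shear[m] - shear[m].mean()
            lags = np.arange(-len(a_win) + 1, len(a_win)) / fs
            xc = np.correlate(s_win, a_win, mode="full")
            # positive lag: shear follows the activation burst
            leads.append(lags[np.argmax(xc)])
        leads = np.array(leads)
        assert np.all(leads >= 0.050) and np.all(leads <= 0.150)


class TestEMG:
    def test_zero_activation_zero_noise_gives_zero_signal(self):
        cfg = quiet_cfg(duration_s=5.0)
        t = np.arange(int(round(5.0 * FS_FEATURE))) / FS_FEATURE
        act = pd.DataFrame({"t": t, **{f"act{n}": np.zeros_like(t)
                                       for n in sorted(MUSCLE_BY_SENSOR)}})
        emg = synthesize_emg(act, cfg)
        assert np.allclose(emg.drop(columns="t").to_numpy(), 0.0)

    def test_constant_activation_power_in_emg_band(self):
        """>= 95% of spectral power between 20 and 450 Hz at full drive."""
        cfg = quiet_cfg(duration_s=10.0)
        t = np.arange(int(round(10.0 * FS_FEATURE))) / FS_FEATURE
        act = pd.DataFrame({"t": t, **{f"act{n}": np.ones_like(t)
                                       for n in sorted(MUSCLE_BY_SENSOR)}})
        emg = synthesize_emg(act, cfg)
        freqs, pxx = periodogram(emg["emg1"].to_numpy(), fs=FS_EMG)
        band = (freqs >= 20) & (freqs <= 450)
        assert pxx[band].sum() / pxx.sum() >= 0.95


class TestIMU:
    def test_static_upright_reads_gravity(self):
        cfg = quiet_cfg(sway_amplitude_deg=0.0)
        com, events = generate_kinematics(cfg)
        imu = synthesize_imu(com, events, cfg)
        assert np.allclose(imu["imu1_acc_z"], 9.81, atol=1e-9)
        for ax in ("x", "y", "z"):
            assert np.allclose(imu[f"imu1_gyro_{ax}"], 0.0, atol=1e-12)

    def test_sway_dominates_gyro_pitch_spectrum(self):
        cfg = quiet_cfg(duration_s=60.0)
        com, events = generate_kinematics(cfg)
        imu = synthesize_imu(com, events, cfg)
        freqs, pxx = periodogram(imu["imu7_gyro_y"].to_numpy(), fs=FS_IMU)
        assert abs(freqs[np.argmax(pxx[1:]) + 1] - 0.25) < 0.02

    def test_seed_determinism(self):
        cfg = SessionConfig(motion_type="pcm", duration_s=10.0, seed=7)
        com, ev = generate_kinematics(cfg)
        i1 = synthesize_imu(com, ev, cfg)
        i2 = synthesize_imu(com, ev, cfg)
        pd.testing.assert_frame_equal(i1, i2)


class TestWrench:
    def test_quiet_stance_supports_body_weight(self):
        cfg = quiet_cfg(sway_amplitude_deg=0.0)
        com, ev = generate_kinematics(cfg)
        act = generate_activations(cfg, com, ev)
        w = synthesize_wrench(act, com, ev, cfg)
        bw = cfg.body_mass_kg * 9.81
        assert abs(w["Fz"].mean() - bw) / bw < 0.01

    def test_pcm_fx_integrates_to_zero_over_sway_cycles(self):
        cfg = quiet_cfg(duration_s=40.0)
        com, ev = generate_kinematics(cfg)
        act = generate_activations(cfg, com, ev)
        w = synthesize_wrench(act, com, ev, cfg)
        fx = w["Fx"].to_numpy()
        dt = float(w["t"].iloc[1] - w["t"].iloc[0])
        net = abs(np.trapezoid(fx, dx=dt))
        assert net < 0.02 * np.sqrt(np.mean(fx ** 2)) * cfg.duration_s

    def test_left_step_shear_sign_matches_convention(self):
        """+y is left: a leftward step shows a positive Fy transient at onset."""
        cfg = quiet_cfg(motion_type="sm", duration_s=60.0)
        com, events = generate_kinematics(cfg)
        act = generate_activations(cfg, com, events)
        w = synthesize_wrench(act, com, events, cfg)
        t = w["t"].to_numpy()
        fy = w["Fy"].to_numpy()
        for ev in events:
            if ev.direction != "left":
                continue
            m = (t >= ev.time_s) & (t <= ev.time_s + 0.3)
            assert fy[m].max() > 0.05 * cfg.body_mass_kg * 9.81
            assert fy[m].mean() > 0


class TestSession:
    def test_stream_lengths_follow_rates(self):
        cfg = SessionConfig(motion_type="pcm", duration_s=30.0, seed=1)
        rec, _ = generate_session(cfg)
        assert len(rec.emg) == round(30.0 * 1111.11)
        assert len(rec.imu) == round(30.0 * 148.148)
        assert rec.rates["emg"] == FS_EMG

    def test_sm_event_count_tracks_step_rate(self):
        cfg = SessionConfig(motion_type="sm", duration_s=60.0, seed=2)
        _, bundle = generate_session(cfg)
        expected = round(60.0 * cfg.step_rate_hz)
        assert abs(len(bundle.step_events) - expected) <= 1

    def test_pcm_has_no_step_events(self):
        _, bundle = generate_session(
            SessionConfig(motion_type="pcm", duration_s=10.0, seed=2))
        assert bundle.step_events == []

    def test_same_seed_writes_byte_identical_csv(self, tmp_path):
        cfg = SessionConfig(motion_type="sm", duration_s=8.0, seed=4)
        for d in ("a", "b"):
            rec, _ = generate_session(cfg)
            write_session(rec, cfg, tmp_path / d)
        for f in ("emg.csv", "imu.csv", "wrench.csv", "session.json"):
            assert (tmp_path / "a" / f).read_bytes() == \
                (tmp_path / "b" / f).read_bytes()
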