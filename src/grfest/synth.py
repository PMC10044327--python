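"""Synthetic posture-control and stepping-motion session generator.

Emulates the statistical structure of a lower-limb wearable-sensing experiment:
ten surface-EMG channels (tibialis anterior, gastrocnemius medialis, peroneus
longus, rectus femoris, semitendinosus, both legs) sampled at 1,111.11 Hz,
four 6-axis IMUs on shanks and thighs at 148.148 Hz, and a 6-channel
force-plate wrench (Fx, Fy, Fz, Mx, My, Mz).

Two motion types are simulated:

* **PCM** (posture-control motion): quasi-periodic anteroposterior and
  mediolateral sway of an inverted pendulum pivoting at the ankle, with
  antagonist muscle pairs phase-locked to the sway.
* **SM** (stepping motion): quiet stance plus discrete step episodes to the
  left, right, or forward, each preceded by a muscle-activation burst
  (electromechanical lead ~100 ms) and accompanied by a shear-force transient
  in the stepped direction and a vertical unloading/loading sequence.

Muscle activation is the latent ground truth; EMG is an amplitude-modulated
band-limited (20-450 Hz) Gaussian carrier, IMU channels follow segment
kinematics with gravity projection, and the wrench follows pendulum dynamics
with a centre-of-pressure excursion driven by ankle-muscle activation
differences.

Coordinate convention (fixed throughout the package): x = anteroposterior
(+forward), y = mediolateral (+left), z = vertical (+up); moments are
right-handed about these axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigurationError

# Native stream sampling rates, Hz.
FS_EMG = 1111.11
FS_IMU = 148.148
FS_WRENCH = 148.148   # plate stream shares the IMU timebase
FS_FEATURE = 74.074   # common timebase after decimation (EMG /15, IMU /2)

G = 9.81  # m/s^2

#: Sensor-number -> muscle mapping (right leg 1,2,3,7,8; left leg 4,5,6,9,10).
MUSCLE_BY_SENSOR = {
    1: "TA_R", 2: "GAS_R", 3: "PL_R", 7: "RF_R", 8: "ST_R",
    4: "TA_L", 5: "GAS_L", 6: "PL_L", 9: "RF_L", 10: "ST_L",
}

#: IMU sensor numbers and the body segment each is strapped to.
IMU_SEGMENT = {1: "shank_R", 4: "shank_L", 7: "thigh_R", 9: "thigh_L"}
_SEGMENT_GAIN = {"shank": 0.6, "thigh": 1.0}   # segment tilt / pendulum tilt
_SEGMENT_LEVER = {"shank": 0.25, "thigh": 0.6}  # m, sensor height above ankle

STEP_DIRECTIONS = ("left", "right", "forward")

# rng stream ids so each synthesis stage is independently reproducible
_RNG_KIN, _RNG_ACT, _RNG_EMG, _RNG_IMU, _RNG_WRENCH = 11, 12, 13, 14, 15


def n_samples(duration_s: float, fs: float) -> int:
    """Number of samples in a stream of the given duration (round-to-nearest)."""
    return int(round(duration_s * fs))


def time_grid(duration_s: float, fs: float) -> np.ndarray:
    return np.arange(n_samples(duration_s, fs)) / fs


@dataclass(frozen=True)
class NoiseLevels:
    """Per-stream relative noise amplitudes.

    emg : baseline white noise relative to the unit-RMS carrier at full drive
    imu : accelerometer white noise relative to g (gyro noise scales with it)
    wrench : force-plate noise relative to body weight
    """

    emg: float = 0.05
    imu: float = 0.01
    wrench: float = 0.003


@dataclass(frozen=True)
class SessionConfig:
    """Full description of one synthetic recording session."""

    motion_type: str = "pcm"            # "pcm" | "sm"
    duration_s: float = 120.0
    seed: int = 0
    sway_frequency_hz: float = 0.25
    sway_amplitude_deg: float = 3.0
    step_rate_hz: float = 0.4
    body_mass_kg: float = 70.0
    com_height_m: float = 1.0
    noise: NoiseLevels = field(default_factory=NoiseLevels)
    artifact_amplitude: float = 0.1     # sub-20 Hz EMG contamination, rel. units
    lead_time_s: float = 0.100          # activation precedes force by this
    lead_jitter_s: float = 0.040        # per-step uniform jitter on the lead

    def validate(self) -> None:
        if self.motion_type not in ("pcm", "sm"):
            raise ConfigurationError(
                f"unknown motion_type {self.motion_type!r}; expected 'pcm' or 'sm'")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if min(self.noise.emg, self.noise.imu, self.noise.wrench) < 0:
            raise ConfigurationError("noise amplitudes must be non-negative")
        if self.artifact_amplitude < 0:
            raise ConfigurationError("artifact_amplitude must be non-negative")
        if self.sway_amplitude_deg < 0:
            raise ConfigurationError("sway_amplitude_deg must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        if isinstance(d.get("noise"), dict):
            d["noise"] = NoiseLevels(**d["noise"])
        return cls(**d)


@dataclass(frozen=True)
class StepEvent:
    """One stepping episode: wrench transient onset, direction, activation lead."""

    time_s: float
    direction: str          # "left" | "right" | "forward"
    lead_s: float           # activation burst precedes time_s by this much
    amplitude: float = 1.0  # per-step relative vigour


@dataclass
class ComState:
    """Centre-of-mass sway as a two-tone quasi-periodic inverted pendulum.

    The tilt angles are stored analytically (amplitudes, frequencies, phases)
    so kinematics can be evaluated exactly on any time grid; the arrays cache
    the evaluation on the 74.074 Hz feature grid.
    """

    amp_ap: float
    amp_ml: float
    w_main: float
    w_ap2: float
    w_ml2: float
    ph_ap2: float
    ph_ml: float
    t: np.ndarray
    theta_ap: np.ndarray = field(default=None, repr=False)
    theta_ml: np.ndarray = field(default=None, repr=False)
    omega_ap: np.ndarray = field(default=None, repr=False)
    omega_ml: np.ndarray = field(default=None, repr=False)
    alpha_ap: np.ndarray = field(default=None, repr=False)
    alpha_ml: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        k = self.eval(self.t)
        self.theta_ap, self.theta_ml = k["theta_ap"], k["theta_ml"]
        self.omega_ap, self.omega_ml = k["omega_ap"], k["omega_ml"]
        self.alpha_ap, self.alpha_ml = k["alpha_ap"], k["alpha_ml"]

    def eval(self, t: np.ndarray) -> dict:
        """Tilt angle, angular velocity and acceleration on an arbitrary grid."""
        t = np.asarray(t, dtype=float)
        w1, w2, w3 = self.w_main, self.w_ap2, self.w_ml2
        a, b = self.amp_ap, self.amp_ml
        th_ap = a * (np.sin(w1 * t) + 0.25 * np.sin(w2 * t + self.ph_ap2))
        om_ap = a * (w1 * np.cos(w1 * t) + 0.25 * w2 * np.cos(w2 * t + self.ph_ap2))
        al_ap = -a * (w1 ** 2 * np.sin(w1 * t)
                      + 0.25 * w2 ** 2 * np.sin(w2 * t + self.ph_ap2))
        th_ml = b * (np.sin(w1 * t + self.ph_ml) + 0.25 * np.sin(w3 * t))
        om_ml = b * (w1 * np.cos(w1 * t + self.ph_ml) + 0.25 * w3 * np.cos(w3 * t))
        al_ml = -b * (w1 ** 2 * np.sin(w1 * t + self.ph_ml)
                      + 0.25 * w3 ** 2 * np.sin(w3 * t))
        return {"theta_ap": th_ap, "theta_ml": th_ml,
                "omega_ap": om_ap, "omega_ml": om_ml,
                "alpha_ap": al_ap, "alpha_ml": al_ml}


@dataclass
class GroundTruthBundle:
    """Latent state behind a synthetic session.

    activations : DataFrame (t + act1..act10) in [0, 1] at 74.074 Hz
    com_state   : pendulum sway kinematics
    step_events : stepping episodes (empty for PCM sessions)
    """

    activations: pd.DataFrame
    com_state: ComState
    step_events: list


@dataclass
class MultiRateRecording:
    """Raw multi-rate session: EMG, IMU and wrench streams with labels."""

    emg: pd.DataFrame      # t + emg1..emg10 @ 1,111.11 Hz
    imu: pd.DataFrame      # t + imu{n}_{acc,gyro}_{x,y,z} @ 148.148 Hz
    wrench: pd.DataFrame   # t + Fx..Mz @ 148.148 Hz
    rates: dict            # stream -> Hz
    channel_map: dict      # EMG sensor number -> muscle label


# ---------------------------------------------------------------------------
# kinematics and activations
# ---------------------------------------------------------------------------

def _smooth_relu(x: np.ndarray, eps: float = 0.02) -> np.ndarray:
    # smooth half-wave rectifier, zero at x=0 so zero drive -> zero output
    return 0.5 * (x + np.sqrt(x * x + eps * eps)) - 0.5 * eps


def generate_kinematics(config: SessionConfig):
    """Build the sway ComState and (for SM) the step-event schedule."""
    config.validate()
    rng = np.random.default_rng([config.seed, _RNG_KIN])
    f = config.sway_frequency_hz
    amp = math.radians(config.sway_amplitude_deg)
    if config.motion_type == "sm":
        amp = math.radians(0.4)  # residual quiet-stance sway between steps
    com = ComState(
        amp_ap=amp,
        amp_ml=0.6 * amp,
        w_main=2 * math.pi * f,
        w_ap2=2 * math.pi * 0.62 * f,
        w_ml2=2 * math.pi * 0.41 * f,
        ph_ap2=float(rng.uniform(0, 2 * math.pi)),
        ph_ml=float(rng.uniform(0.5, 2 * math.pi)),
        t=time_grid(config.duration_s, FS_FEATURE),
    )
    events: list[StepEvent] = []
    if config.motion_type == "sm":
        n_steps = int(round(config.duration_s * config.step_rate_hz))
        # balanced direction sequence (cycle of the three, shuffled)
        dirs = [STEP_DIRECTIONS[i % 3] for i in range(n_steps)]
        rng.shuffle(dirs)
        spacing = 1.0 / config.step_rate_hz
        for k in range(n_steps):
            t0 = (k + 0.55) * spacing + float(rng.uniform(-0.12, 0.12)) * spacing
            t0 = min(max(t0, 1.0), config.duration_s - 1.5)
            lead = config.lead_time_s + float(
                rng.uniform(-config.lead_jitter_s, config.lead_jitter_s))
            events.append(StepEvent(time_s=t0, direction=dirs[k], lead_s=lead,
                                    amplitude=float(rng.uniform(0.85, 1.15))))
    return com, events


# per-direction burst weight on each muscle (sensor number -> weight)
_STEP_MUSCLE_WEIGHTS = {
    "forward": {1: 0.70, 4: 0.70, 7: 0.40, 9: 0.40, 3: 0.15, 6: 0.15},
    "left":    {4: 0.55, 6: 0.65, 9: 0.40, 5: 0.20, 10: 0.15},
    "right":   {1: 0.55, 3: 0.65, 7: 0.40, 2: 0.20, 8: 0.15},
}
_STEP_RISE_S = 0.15    # fast loading edge of a step pulse
_STEP_FALL_S = 0.35    # slower decay
_ACT_BASELINE = 0.08


def _burst_shape(t: np.ndarray, t0: float,
                 rise: float = _STEP_RISE_S,
                 fall: float = _STEP_FALL_S) -> np.ndarray:
    """Fast-rise / slow-decay unit pulse starting at t0 (0 outside)."""
    out = np.zeros_like(t)
    u1 = (t - t0) / rise
    m1 = (u1 >= 0) & (u1 < 1)
    out[m1] = np.sin(0.5 * math.pi * u1[m1]) ** 2
    u2 = (t - t0 - rise) / fall
    m2 = (u2 >= 0) & (u2 <= 1)
    out[m2] = np.cos(0.5 * math.pi * u2[m2]) ** 2
    return out


def generate_activations(config: SessionConfig,
                         com: ComState | None = None,
                         events: list | None = None) -> pd.DataFrame:
    """Ten muscle-activation series in [0, 1] on the 74.074 Hz feature grid.

    PCM: antagonist pairs phase-locked to the sway, evaluated at a lead of
    ``lead_time_s`` ahead of the kinematics (activation precedes force).
    SM: quiet-stance drive plus direction-specific bursts whose envelopes
    precede each step's wrench onset by that step's ``lead_s``.
    """
    config.validate()
    if com is None or (events is None and config.motion_type == "sm"):
        com, events = generate_kinematics(config)
    events = events or []
    t = com.t
    tau = config.lead_time_s
    k = com.eval(t + tau)  # kinematics the muscles are acting to produce
    a_ref = com.amp_ap if com.amp_ap > 0 else 1.0
    b_ref = com.amp_ml if com.amp_ml > 0 else 1.0
    s_ap = k["theta_ap"] / a_ref   # normalized lead sway, ~[-1.25, 1.25]
    s_ml = k["theta_ml"] / b_ref

    drive = {n: np.zeros_like(t) for n in MUSCLE_BY_SENSOR}
    # sagittal antagonists: plantarflexors fire on forward lean, TA on backward
    for n in (2, 5):                       # gastrocnemius
        drive[n] += 0.45 * _smooth_relu(s_ap)
    for n in (3, 6):                       # peroneus longus
        drive[n] += 0.30 * _smooth_relu(s_ap)
    for n in (1, 4):                       # tibialis anterior
        drive[n] += 0.50 * _smooth_relu(-s_ap)
    # mediolateral: evertors of the loaded side
    drive[3] += 0.30 * _smooth_relu(-s_ml)   # PL right, lean right (-y)
    drive[6] += 0.30 * _smooth_relu(s_ml)    # PL left, lean left (+y)
    # thigh muscles: weaker, mixed drive (ankle strategy dominates)
    for n in (7, 9):                       # rectus femoris
        drive[n] += 0.15 * np.abs(s_ap)
    for n in (8, 10):                      # semitendinosus
        drive[n] += 0.18 * _smooth_relu(-s_ap) + 0.05 * np.abs(s_ml)

    for ev in events:
        onset = ev.time_s - ev.lead_s      # burst precedes the wrench onset
        shape = _burst_shape(t, onset)
        for n, w in _STEP_MUSCLE_WEIGHTS[ev.direction].items():
            drive[n] += w * ev.amplitude * shape

    data = {"t": t}
    for n in sorted(MUSCLE_BY_SENSOR):
        data[f"act{n}"] = np.clip(_ACT_BASELINE + drive[n], 0.0, 1.0)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# sensor streams
# ---------------------------------------------------------------------------

def _bandlimited_carrier(rng, n: int, fs: float,
                         band=(20.0, 450.0)) -> np.ndarray:
    """Unit-RMS zero-mean Gaussian noise band-limited to the EMG band."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / np.std(y)


def _slow_drift(rng, n: int, fs: float, cutoff: float = 4.0) -> np.ndarray:
    """Unit-RMS sub-20 Hz drift emulating motion artifact."""
    x = rng.standard_normal(n)
    sos = signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    s = np.std(y)
    return y / s if s > 0 else y


def synthesize_emg(activations: pd.DataFrame, config: SessionConfig,
                   fs_emg: float = FS_EMG) -> pd.DataFrame:
    """Raw EMG: activation-modulated 20-450 Hz carrier + noise + drift.

    Each channel is ``a(t) * carrier(t) + noise.emg * white +
    artifact_amplitude * drift`` with the activation linearly interpolated
    onto the EMG time grid.
    """
    rng = np.random.default_rng([config.seed, _RNG_EMG])
    t_emg = time_grid(config.duration_s, fs_emg)
    t_act = activations["t"].to_numpy()
    out = {"t": t_emg}
    for n in sorted(MUSCLE_BY_SENSOR):
        a = np.interp(t_emg, t_act, activations[f"act{n}"].to_numpy())
        carrier = _bandlimited_carrier(rng, len(t_emg), fs_emg)
        ch = a * carrier
        if config.noise.emg > 0:
            ch = ch + config.noise.emg * rng.standard_normal(len(t_emg))
        if config.artifact_amplitude > 0:
            ch = ch + config.artifact_amplitude * _slow_drift(rng, len(t_emg), fs_emg)
        out[f"emg{n}"] = ch
    return pd.DataFrame(out)


def synthesize_imu(com: ComState, step_events: list, config: SessionConfig,
                   fs_imu: float = FS_IMU) -> pd.DataFrame:
    """Four 6-axis IMUs from segment kinematics.

    Accelerometers see the gravity projection under segment tilt plus the
    tangential acceleration at the sensor lever arm; gyros see the segment
    angular velocity. Shank sensors (1, 4) and thigh sensors (7, 9) use
    distinct tilt gains so shank-only and shank+thigh input patterns carry
    genuinely different information. Step episodes add a short damped
    oscillation on the stepping leg.
    """
    rng = np.random.default_rng([config.seed, _RNG_IMU])
    t = time_grid(config.duration_s, fs_imu)
    k = com.eval(t)
    out = {"t": t}
    for n, segment in IMU_SEGMENT.items():
        seg, side = segment.split("_")
        gain = _SEGMENT_GAIN[seg]
        lever = _SEGMENT_LEVER[seg]
        th_ap, th_ml = gain * k["theta_ap"], gain * k["theta_ml"]
        acc_x = -G * np.sin(th_ap) + lever * gain * k["alpha_ap"]
        acc_y = G * np.sin(th_ml) + lever * gain * k["alpha_ml"]
        acc_z = G * np.cos(th_ap) * np.cos(th_ml)
        gyr_x = gain * k["omega_ml"]
        gyr_y = gain * k["omega_ap"]
        gyr_z = np.zeros_like(t)
        for ev in step_events:
            moving = {"left": "L", "right": "R", "forward": "LR"}[ev.direction]
            if side not in moving:
                continue
            scale = (1.0 if seg == "shank" else 0.5) * ev.amplitude
            u = t - ev.time_s
            m = u >= 0
            ring = np.zeros_like(t)
            ring[m] = np.sin(2 * math.pi * 3.0 * u[m]) * np.exp(-u[m] / 0.15)
            acc_x = acc_x + 2.0 * scale * ring
            acc_z = acc_z - 1.0 * scale * ring
            gyr_y = gyr_y + 0.8 * scale * ring
        if config.noise.imu > 0:
            acc_x = acc_x + config.noise.imu * G * rng.standard_normal(len(t))
            acc_y = acc_y + config.noise.imu * G * rng.standard_normal(len(t))
            acc_z = acc_z + config.noise.imu * G * rng.standard_normal(len(t))
            gyr_x = gyr_x + config.noise.imu * rng.standard_normal(len(t))
            gyr_y = gyr_y + config.noise.imu * rng.standard_normal(len(t))
            gyr_z = gyr_z + config.noise.imu * rng.standard_normal(len(t))
        out[f"imu{n}_acc_x"] = acc_x
        out[f"imu{n}_acc_y"] = acc_y
        out[f"imu{n}_acc_z"] = acc_z
        out[f"imu{n}_gyro_x"] = gyr_x
        out[f"imu{n}_gyro_y"] = gyr_y
        out[f"imu{n}_gyro_z"] = gyr_z
    return pd.DataFrame(out)


# centre-of-pressure coupling constants
_COP_KIN_GAIN = 0.9       # CoP tracks the CoM projection (balance condition)
_COP_ACT_GAIN_AP = 0.05   # m of CoP per unit plantar-dorsi activation diff
_COP_ACT_GAIN_ML = 0.08
_MZ_ACT_GAIN = 4.0        # N*m per unit left-right activation asymmetry
_STEP_SHEAR_FRAC = 0.15   # shear transient amplitude as fraction of body weight
_STEP_UNLOAD_FRAC = 0.18
_STEP_COP_SHIFT = 0.05    # m


def synthesize_wrench(activations: pd.DataFrame, com: ComState,
                      step_events: list, config: SessionConfig,
                      fs_wrench: float = FS_WRENCH) -> pd.DataFrame:
    """Force-plate wrench from pendulum dynamics + activation-driven CoP.

    Fx, Fy follow the horizontal centre-of-mass acceleration; Fz is body
    weight plus a small centripetal term; Mx, My arise from centre-of-pressure
    excursion (kinematic balance term + ankle-muscle activation differences
    applied at the electromechanical delay); Mz is a small activation-driven
    torsion. SM episodes superpose a signed shear pulse in the stepped
    direction (+y left, -y right, +x forward), an unload/reload Fz sequence,
    and a CoP shift.
    """
    m, L, g = config.body_mass_kg, config.com_height_m, G
    rng = np.random.default_rng([config.seed, _RNG_WRENCH])
    t = time_grid(config.duration_s, fs_wrench)
    k = com.eval(t)
    fx = m * L * k["alpha_ap"]
    fy = m * L * k["alpha_ml"]
    fz = m * g - m * L * (k["omega_ap"] ** 2 + k["omega_ml"] ** 2) * np.ones_like(t)

    # activation acts on the plate after the electromechanical delay
    t_act = activations["t"].to_numpy()
    delayed = {n: np.interp(t - config.lead_time_s, t_act,
                            activations[f"act{n}"].to_numpy())
               for n in sorted(MUSCLE_BY_SENSOR)}
    plantar = 0.25 * (delayed[2] + delayed[3] + delayed[5] + delayed[6])
    dorsi = 0.5 * (delayed[1] + delayed[4])
    ml_diff = 0.5 * (delayed[4] + delayed[6]) - 0.5 * (delayed[1] + delayed[3])
    right_left = (sum(delayed[n] for n in (1, 2, 3, 7, 8))
                  - sum(delayed[n] for n in (4, 5, 6, 9, 10))) / 5.0

    # plantarflexor drive slightly modulates vertical load (heel unloading)
    fz = fz + 0.02 * m * g * (plantar - dorsi)

    cop_x = _COP_KIN_GAIN * L * np.sin(k["theta_ap"]) \
        + _COP_ACT_GAIN_AP * (plantar - dorsi)
    cop_y = _COP_KIN_GAIN * L * np.sin(k["theta_ml"]) \
        + _COP_ACT_GAIN_ML * ml_diff
    mz = -_MZ_ACT_GAIN * right_left

    w = _STEP_RISE_S + _STEP_FALL_S
    for ev in step_events:
        ux, uy = {"left": (0.0, 1.0), "right": (0.0, -1.0),
                  "forward": (1.0, 0.0)}[ev.direction]
        push = _burst_shape(t, ev.time_s) * ev.amplitude
        brake = _burst_shape(t, ev.time_s + w, 0.2, 0.4) * ev.amplitude
        shear = _STEP_SHEAR_FRAC * m * g * (push - 0.5 * brake)
        fx = fx + ux * shear
        fy = fy + uy * shear
        fz = fz + m * g * (-_STEP_UNLOAD_FRAC * push + 0.12 * brake)
        cop_x = cop_x + _STEP_COP_SHIFT * ux * push
        cop_y = cop_y + _STEP_COP_SHIFT * uy * push
        mz = mz + 2.0 * uy * push

    mx = cop_y * fz
    my = -cop_x * fz

    if config.noise.wrench > 0:
        s_f = config.noise.wrench * m * g
        s_m = 0.1 * s_f
        fx = fx + s_f * rng.standard_normal(len(t))
        fy = fy + s_f * rng.standard_normal(len(t))
        fz = fz + s_f * rng.standard_normal(len(t))
        mx = mx + s_m * rng.standard_normal(len(t))
        my = my + s_m * rng.standard_normal(len(t))
        mz = mz + s_m * rng.standard_normal(len(t))

    return pd.DataFrame({"t": t, "Fx": fx, "Fy": fy, "Fz": fz,
                         "Mx": mx, "My": my, "Mz": mz})


def generate_session(config: SessionConfig):
    """Full synthetic session: raw multi-rate streams + latent ground truth."""
    config.validate()
    com, events = generate_kinematics(config)
    activations = generate_activations(config, com, events)
    emg = synthesize_emg(activations, config)
    imu = synthesize_imu(com, events, config)
    wrench = synthesize_wrench(activations, com, events, config)
    rec = MultiRateRecording(
        emg=emg, imu=imu, wrench=wrench,
        rates={"emg": FS_EMG, "imu": FS_IMU, "wrench": FS_WRENCH},
        channel_map=dict(MUSCLE_BY_SENSOR),
    )
    bundle = GroundTruthBundle(activations=activations, com_state=com,
                               step_events=events)
    return rec, bundle
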