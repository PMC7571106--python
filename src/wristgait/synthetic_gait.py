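"""Synthetic wrist-worn IMU gait recordings.

Generates multi-sensor walking trials with the statistical structure a
gait-abnormality classifier relies on: quasi-periodic arm-swing harmonics
locked to a jittered stride clock, subject-level random effects, and
impairment-induced changes (slower and weaker arm swing, elevated
stride-time variability, occasional stumble-like perturbations).

The device frame convention is x = across the watch face, y = along the
strap (forearm axis), z = face normal.  Gravity projects mainly on y,
arm swing drives the largest oscillation on the x/y plane.  Each session
carries 12 channels: 3 axes for each of accelerometer (m/s^2), gyroscope
(rad/s), magnetometer (uT) and rotation-vector orientation components
(unitless).  The magnetometer sees a slowly varying heading field with a
180-degree mid-trial turn (the walker returns along the path).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CHANNELS = [
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "mag_x", "mag_y", "mag_z",
    "rot_x", "rot_y", "rot_z",
]

SENSOR_LETTERS = {"A": "acc", "G": "gyr", "M": "mag", "R": "rot"}

CONDITIONS = ("normal", "abnormal")
WRISTS = ("left", "right")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject signal parameters standing in for anthropometric variation."""

    subject_id: str
    base_stride_freq: float          # Hz, typically 0.8-1.2 (one stride = two steps)
    swing_amplitude: float           # m/s^2 scale of the arm-swing acceleration
    phase_offsets: np.ndarray        # radians, one per channel (len 12)
    noise_scale: float               # multiplies per-sensor white-noise sigma
    handedness: str = "right"

    def __post_init__(self):
        if self.base_stride_freq <= 0:
            raise ValueError("base_stride_freq must be > 0")
        if self.swing_amplitude <= 0:
            raise ValueError("swing_amplitude must be > 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass(frozen=True)
class AbnormalEffects:
    """Impairment-induced changes applied to abnormal-condition trials.

    ``stride_freq_drop`` and ``swing_reduction`` are fractional reductions;
    ``stride_time_cv_*`` are coefficients of variation of the stride
    intervals; ``perturbation_rate`` is the Poisson rate (events/s) of
    stumble-like transient bursts.
    """

    stride_freq_drop: float = 0.15
    swing_reduction: float = 0.4
    stride_time_cv_normal: float = 0.02
    stride_time_cv_abnormal: float = 0.10
    perturbation_rate: float = 0.2

    def __post_init__(self):
        if not self.stride_time_cv_abnormal > self.stride_time_cv_normal:
            raise ValueError("stride_time_cv_abnormal must exceed stride_time_cv_normal")

    @classmethod
    def none(cls) -> "AbnormalEffects":
        """Zeroed effects: abnormal trials become exchangeable with normal ones."""
        return cls(stride_freq_drop=0.0, swing_reduction=0.0,
                   stride_time_cv_normal=0.02, stride_time_cv_abnormal=0.02 + 1e-12,
                   perturbation_rate=0.0)


@dataclass(frozen=True)
class GaitSimConfig:
    n_subjects: int = 18
    trials_per_condition: int = 5
    sampling_rate: float = 100.0
    trial_duration: float | None = None          # seconds; None -> draw per trial
    duration_range: tuple[float, float] = (20.0, 40.0)
    abnormal_effects: AbnormalEffects = field(default_factory=AbnormalEffects)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        # highest simulated harmonic is 3x the stride frequency (< 4 Hz)
        if self.sampling_rate <= 2 * 4.0:
            raise ValueError("sampling_rate must exceed twice the highest harmonic")


@dataclass
class RecordingSession:
    """One labeled walking trial: a samples x channels matrix plus metadata."""

    subject_id: str
    wrist: str
    trial_index: int
    condition: str
    sampling_rate: float
    channels: list[str]
    signal: np.ndarray
    stride_intervals: np.ndarray | None = None   # realized stride clock, seconds

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.wrist not in WRISTS:
            raise ValueError(f"unknown wrist {self.wrist!r}")
        if self.signal.ndim != 2 or self.signal.shape[1] != len(self.channels):
            raise ValueError("signal shape inconsistent with channel list")
        if len(self.channels) not in (3, 6, 9, 12):
            raise ValueError("channel count must be a whole number of 3-axis sensors")
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, **kw) -> "RecordingSession":
        out = replace(self, **kw)
        return out

    def select_channels(self, names: list[str]) -> "RecordingSession":
        idx = [self.channels.index(c) for c in names]
        return self.copy_with(channels=list(names), signal=self.signal[:, idx])

    def stride_time_cv(self) -> float:
        """Coefficient of variation of the realized stride intervals."""
        iv = self.stride_intervals
        if iv is None or len(iv) < 2:
            raise ValueError("session carries no stride-interval record")
        return float(np.std(iv) / np.mean(iv))


def sensor_channels(letters: str) -> list[str]:
    """Expand a sensor-combination code such as 'AGR' into channel names."""
    out = []
    for letter in letters:
        try:
            prefix = SENSOR_LETTERS[letter]
        except KeyError:
            raise ValueError(f"unknown sensor letter {letter!r}") from None
        out += [f"{prefix}_{ax}" for ax in "xyz"]
    return out


def sample_subject_profiles(n: int, seed: int) -> list[SubjectProfile]:
    """Draw ``n`` subject profiles from the configured population ranges.

    Deterministic given ``seed``; subject ids are S01, S02, ...
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        profiles.append(SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            base_stride_freq=float(rng.uniform(0.8, 1.2)),
            swing_amplitude=float(rng.uniform(1.2, 2.5)),
            phase_offsets=rng.uniform(0.0, 2 * np.pi, size=len(CHANNELS)),
            noise_scale=float(rng.uniform(0.6, 1.4)),
            handedness="right" if rng.random() < 0.9 else "left",
        ))
    return profiles


def _stride_clock(rng, duration, stride_freq, cv):
    """Jittered stride boundaries covering [0, duration]; returns (times, intervals)."""
    mean_T = 1.0 / stride_freq
    intervals = []
    total = 0.0
    while total < duration + mean_T:
        iv = rng.normal(mean_T, cv * mean_T)
        iv = max(iv, 0.3 * mean_T)
        intervals.append(iv)
        total += iv
    intervals = np.asarray(intervals)
    times = np.concatenate([[0.0], np.cumsum(intervals)])
    return times, intervals


# per-axis weights of the arm-swing harmonics (fundamental, 2nd, 3rd)
_ACC_W = {"x": (0.55, 0.30, 0.10), "y": (1.00, 0.35, 0.12), "z": (0.30, 0.15, 0.05)}
_GYR_W = {"x": (0.50, 0.20, 0.06), "y": (0.25, 0.10, 0.03), "z": (0.90, 0.30, 0.10)}
_GRAVITY = {"x": 1.2, "y": 9.0, "z": 3.6}  # quasi-static projection, m/s^2


def simulate_session(profile: SubjectProfile, condition: str, wrist: str,
                     trial_index: int, config: GaitSimConfig, seed) -> RecordingSession:
    """Simulate one walking trial as a 12-channel IMU recording.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if wrist not in WRISTS:
        raise ValueError(f"unknown wrist {wrist!r}")
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    eff = config.abnormal_effects
    abnormal = condition == "abnormal"

    duration = (config.trial_duration if config.trial_duration is not None
                else float(rng.uniform(*config.duration_range)))
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    stride_freq = profile.base_stride_freq * (1.0 - (eff.stride_freq_drop if abnormal else 0.0))
    cv = eff.stride_time_cv_abnormal if abnormal else eff.stride_time_cv_normal
    boundaries, intervals = _stride_clock(rng, duration, stride_freq, cv)
    # instantaneous phase: 2*pi per stride, piecewise linear between boundaries
    phase = 2 * np.pi * np.interp(t, boundaries, np.arange(len(boundaries)))
    amp = profile.swing_amplitude * (1.0 - (eff.swing_reduction if abnormal else 0.0))
    wrist_shift = 0.0 if wrist == "right" else np.pi  # arms swing in antiphase

    sig = np.empty((n, len(CHANNELS)))
    off = profile.phase_offsets

    def harmonics(weights, ph0):
        y = np.zeros(n)
        for k, w in enumerate(weights, start=1):
            y += w * np.sin(k * phase + ph0 + (k - 1) * 0.7)
        return y

    # accelerometer: gravity projection + swing harmonics + white noise
    for j, ax in enumerate("xyz"):
        ph0 = off[j] + wrist_shift
        sig[:, j] = (_GRAVITY[ax]
                     + amp * harmonics(_ACC_W[ax], ph0)
                     + rng.normal(0.0, 0.25 * profile.noise_scale, n))
    # gyroscope: angular-rate harmonics, scaled from the swing amplitude
    gyr_amp = 0.6 * amp
    for j, ax in enumerate("xyz"):
        ph0 = off[3 + j] + wrist_shift
        sig[:, 3 + j] = (gyr_amp * harmonics(_GYR_W[ax], ph0 + np.pi / 2)
                         + rng.normal(0.0, 0.15 * profile.noise_scale, n))
    # magnetometer: heading field with a mid-trial 180-degree turn
    heading = np.pi / (1.0 + np.exp(-(t - duration / 2) / 0.5))  # smooth turn
    decl = off[6]
    sig[:, 6] = 25.0 * np.cos(heading + decl) + 1.5 * np.sin(phase + off[6]) \
        + rng.normal(0.0, 0.5 * profile.noise_scale, n)
    sig[:, 7] = 25.0 * np.sin(heading + decl) + 1.5 * np.sin(phase + off[7]) \
        + rng.normal(0.0, 0.5 * profile.noise_scale, n)
    sig[:, 8] = 40.0 + 1.0 * np.sin(phase + off[8]) \
        + rng.normal(0.0, 0.5 * profile.noise_scale, n)
    # rotation vector: low-frequency orientation drift + small stride ripple
    swing_tilt = 0.05 * amp / max(profile.swing_amplitude, 1e-9)
    for j, ax in enumerate("xyz"):
        ph0 = off[9 + j]
        sig[:, 9 + j] = (0.12 * np.sin(2 * np.pi * 0.06 * t + ph0)
                         + swing_tilt * np.sin(phase + ph0)
                         + rng.normal(0.0, 0.01 * profile.noise_scale, n))

    if abnormal and eff.perturbation_rate > 0:
        n_events = rng.poisson(eff.perturbation_rate * duration)
        for _ in range(n_events):
            center = rng.uniform(0.0, duration)
            width = rng.uniform(0.3, 0.8)
            envelope = np.exp(-0.5 * ((t - center) / (width / 2)) ** 2)
            burst_acc = 1.5 * amp * envelope
            for j in range(3):
                sig[:, j] += burst_acc * rng.normal(0.0, 1.0) * np.sin(
                    2 * np.pi * rng.uniform(1.0, 3.0) * t + rng.uniform(0, 2 * np.pi))
            for j in range(3, 6):
                sig[:, j] += 0.6 * burst_acc * rng.normal(0.0, 1.0) * np.sin(
                    2 * np.pi * rng.uniform(1.0, 3.0) * t + rng.uniform(0, 2 * np.pi))

    mask = boundaries[1:] <= duration
    return RecordingSession(
        subject_id=profile.subject_id, wrist=wrist, trial_index=trial_index,
        condition=condition, sampling_rate=fs, channels=list(CHANNELS),
        signal=sig, stride_intervals=intervals[mask],
    )


def _session_seed(config: GaitSimConfig, subj_idx: int, wrist: str,
                  condition: str, trial_index: int) -> np.random.SeedSequence:
    key = (subj_idx, WRISTS.index(wrist), CONDITIONS.index(condition), trial_index)
    return np.random.SeedSequence(entropy=config.rng_seed, spawn_key=key)


def simulate_dataset(config: GaitSimConfig,
                     profiles: list[SubjectProfile] | None = None) -> list[RecordingSession]:
    """Simulate the full cohort in memory.

    Session count = n_subjects x 2 wrists x 2 conditions x trials_per_condition.
    Byte-identical across runs for a fixed config (per-session seeds are derived
    from ``config.rng_seed`` and the session's coordinates).
    """
    if profiles is None:
        profiles = sample_subject_profiles(config.n_subjects, config.rng_seed)
    sessions = []
    for si, prof in enumerate(profiles):
        for wrist in WRISTS:
            for condition in CONDITIONS:
                for trial in range(config.trials_per_condition):
                    seed = _session_seed(config, si, wrist, condition, trial)
                    sessions.append(simulate_session(prof, condition, wrist,
                                                     trial, config, seed))
    return sessions


def session_filename(s: RecordingSession) -> str:
    return f"{s.subject_id}_{s.wrist}_{s.condition}_{s.trial_index:02d}.csv"


def write_session_csv(s: RecordingSession, path: Path) -> None:
    df = pd.DataFrame(s.signal, columns=s.channels)
    df.insert(0, "time_s", np.arange(s.n_samples) / s.sampling_rate)
    df.to_csv(path, index=False, float_format="%.6f")


def read_session_csv(path: Path, subject_id: str, wrist: str, trial_index: int,
                     condition: str, sampling_rate: float) -> RecordingSession:
    df = pd.read_csv(path)
    channels = [c for c in df.columns if c != "time_s"]
    return RecordingSession(subject_id=subject_id, wrist=wrist,
                            trial_index=trial_index, condition=condition,
                            sampling_rate=sampling_rate, channels=channels,
                            signal=df[channels].to_numpy())


def generate_dataset(config: GaitSimConfig, out_dir) -> list[dict]:
    """Write one CSV per session plus a JSON manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions = simulate_dataset(config)
    manifest = []
    for s in sessions:
        fname = session_filename(s)
        write_session_csv(s, out_dir / fname)
        manifest.append({
            "file": fname, "subject_id": s.subject_id, "wrist": s.wrist,
            "trial_index": s.trial_index, "condition": s.condition,
            "sampling_rate": s.sampling_rate,
        })
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_manifest(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


def load_dataset(manifest_path) -> list[RecordingSession]:
    manifest_path = Path(manifest_path)
    manifest = load_manifest(manifest_path)
    base = manifest_path.parent
    return [read_session_csv(base / e["file"], e["subject_id"], e["wrist"],
                             e["trial_index"], e["condition"], e["sampling_rate"])
            for e in manifest]


def label_permutation_pvalue(values, labels, n_perm: int = 500, seed: int = 0) -> float:
    """Two-sided permutation p-value for a difference in group means.

    Used to check that with impairment effects zeroed the two condition
    labels are exchangeable at the level of session summary statistics.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two label groups required")
    mask = labels == groups[0]
    observed = abs(values[mask].mean() - values[~mask].mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(mask)
        diff = abs(values[perm].mean() - values[~perm].mean())
        if diff >= observed - 1e-15:
            count += 1
    return (count + 1) / (n_perm + 1)
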