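"""Signal conditioning for wrist IMU recordings.

The chain, in order: downsample to the target rate, Butterworth band-pass
(zero-phase), rotation augmentation of the training data, per-channel
z-scoring, and fixed-length window segmentation.  Every step is a pure
function of (session, config, fitted scaler), so fold-wise reprocessing is
reproducible.

Windowing convention: consecutive windows share ``overlap_s`` seconds, so
the hop (stride) between window starts is ``window_s - overlap_s``; any
trailing remainder shorter than one window is discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synthetic_gait import RecordingSession


@dataclass(frozen=True)
class PreprocessConfig:
    target_rate: float = 50.0
    band_low: float = 0.5       # Hz
    band_high: float = 3.5      # Hz
    filter_order: int = 10      # overall band-pass order (lowpass prototype order 5)
    window_s: float = 8.0
    overlap_s: float = 2.0
    augment_training: bool = True

    def __post_init__(self):
        if not (0 < self.band_low < self.band_high < self.target_rate / 2):
            raise ValueError("need 0 < band_low < band_high < Nyquist")
        if not (0 <= self.overlap_s < self.window_s):
            raise ValueError("need 0 <= overlap_s < window_s")
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValueError("band-pass filter_order must be a positive even number")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.target_rate))

    @property
    def stride_samples(self) -> int:
        return int(round((self.window_s - self.overlap_s) * self.target_rate))


class UnsupportedRateError(ValueError):
    pass


class DegenerateChannelError(ValueError):
    pass


def resample_to_target(session: RecordingSession, target_rate: float) -> RecordingSession:
    """Decimate to ``target_rate`` (must divide the session rate exactly).

    An anti-alias low-pass (order-8 Chebyshev-I, via ``scipy.signal.decimate``
    with zero-phase application) precedes the sample drop.
    """
    factor = session.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise UnsupportedRateError(
            f"target rate {target_rate} does not divide session rate "
            f"{session.sampling_rate}")
    factor = int(round(factor))
    if factor == 1:
        return session.copy_with(signal=session.signal.copy())
    out = sps.decimate(session.signal, factor, axis=0, zero_phase=True)
    return session.copy_with(signal=out, sampling_rate=target_rate)


def butter_bandpass_sos(cfg: PreprocessConfig, rate: float):
    """Band-pass design in second-order sections.

    ``filter_order`` counts the order of the band-pass transfer function
    itself (twice the lowpass-prototype order), matching the convention of
    an "N-th order band-pass Butterworth".
    """
    if cfg.band_high >= rate / 2:
        raise ValueError("band_high must be below the Nyquist frequency")
    return sps.butter(cfg.filter_order // 2, [cfg.band_low, cfg.band_high],
                      btype="bandpass", fs=rate, output="sos")


def bandpass_response(cfg: PreprocessConfig, rate: float, freqs) -> np.ndarray:
    """Single-pass magnitude response of the designed filter at ``freqs`` (Hz)."""
    sos = butter_bandpass_sos(cfg, rate)
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs, float) / rate)
    return np.abs(h)


def bandpass_filter(signal: np.ndarray, rate: float, cfg: PreprocessConfig) -> np.ndarray:
    """Zero-phase (forward-backward) band-pass of each channel independently."""
    signal = np.asarray(signal)
    if not np.isfinite(signal).all():
        raise ValueError("signal must be finite")
    sos = butter_bandpass_sos(cfg, rate)
    return sps.sosfiltfilt(sos, signal, axis=0)


def bandpass_session(session: RecordingSession, cfg: PreprocessConfig) -> RecordingSession:
    return session.copy_with(signal=bandpass_filter(session.signal,
                                                    session.sampling_rate, cfg))


ROTATION_180_Z = np.diag([-1.0, -1.0, 1.0])


def rotation_augment(session: RecordingSession) -> RecordingSession:
    """180-degree rotation about the device face-normal axis.

    Emulates the watch strapped on the other way round: for every 3-axis
    sensor triplet (x, y, z) -> (-x, -y, z).  Applied to the rotation-vector
    channels with the same map as an approximation of the corresponding
    orientation conjugation.
    """
    n_ch = len(session.channels)
    if n_ch % 3:
        raise ValueError("channel count must be a multiple of 3")
    out = session.signal.copy()
    for s0 in range(0, n_ch, 3):
        out[:, s0:s0 + 3] = out[:, s0:s0 + 3] @ ROTATION_180_Z.T
    return session.copy_with(signal=out)


@dataclass(frozen=True)
class ChannelScaler:
    """Per-channel (signal-wise) z-scoring parameters.

    Uses the population (1/N) standard deviation; the convention is fixed so
    that scaled outputs are bit-stable across runs.
    """

    channels: tuple
    mean: np.ndarray
    std: np.ndarray

    def transform(self, signal: np.ndarray) -> np.ndarray:
        return (signal - self.mean) / self.std

    def transform_session(self, session: RecordingSession) -> RecordingSession:
        if tuple(session.channels) != self.channels:
            raise ValueError("session channels do not match the fitted scaler")
        return session.copy_with(signal=self.transform(session.signal))


def fit_scaler(sessions: list[RecordingSession]) -> ChannelScaler:
    """Fit per-channel mean/std over the concatenated training sessions."""
    if not sessions:
        raise ValueError("no sessions to fit on")
    channels = tuple(sessions[0].channels)
    for s in sessions:
        if tuple(s.channels) != channels:
            raise ValueError("inconsistent channel layouts")
    data = np.concatenate([s.signal for s in sessions], axis=0)
    mean = data.mean(axis=0)
    std = data.std(axis=0)  # population std
    bad = np.flatnonzero(std < 1e-12)
    if bad.size:
        raise DegenerateChannelError(
            f"zero-variance channel(s): {[channels[i] for i in bad]}")
    return ChannelScaler(channels=channels, mean=mean, std=std)


def apply_scaler(scaler: ChannelScaler, session: RecordingSession) -> RecordingSession:
    return scaler.transform_session(session)


@dataclass
class WindowSet:
    """Fixed-length labeled segments with provenance for splitting/aggregation.

    ``labels`` holds 0 for normal and 1 for abnormal gait (the positive,
    clinically costly class).  ``trial_ids`` identifies the source walking
    session (subject + wrist + trial index) for trial-level aggregation.
    """

    windows: np.ndarray            # (n, window_len, n_channels)
    labels: np.ndarray             # (n,) int, 0=normal 1=abnormal
    subject_ids: np.ndarray        # (n,) str
    trial_ids: np.ndarray          # (n,) str
    wrists: np.ndarray             # (n,) str
    augmented: np.ndarray          # (n,) bool
    channels: list[str]
    rate: float

    def __post_init__(self):
        n = len(self.windows)
        for name in ("labels", "subject_ids", "trial_ids", "wrists", "augmented"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match window count")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def window_len(self) -> int:
        return self.windows.shape[1]

    def subset(self, mask) -> "WindowSet":
        mask = np.asarray(mask)
        return WindowSet(self.windows[mask], self.labels[mask],
                         self.subject_ids[mask], self.trial_ids[mask],
                         self.wrists[mask], self.augmented[mask],
                         list(self.channels), self.rate)

    def select_channels(self, names: list[str]) -> "WindowSet":
        idx = [self.channels.index(c) for c in names]
        return WindowSet(self.windows[:, :, idx], self.labels, self.subject_ids,
                         self.trial_ids, self.wrists, self.augmented,
                         list(names), self.rate)

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            raise ValueError("nothing to concatenate")
        ref = sets[0]
        for s in sets[1:]:
            if s.channels != ref.channels or s.rate != ref.rate:
                raise ValueError("incompatible window sets")
        return WindowSet(
            np.concatenate([s.windows for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.subject_ids for s in sets]),
            np.concatenate([s.trial_ids for s in sets]),
            np.concatenate([s.wrists for s in sets]),
            np.concatenate([s.augmented for s in sets]),
            list(ref.channels), ref.rate)


LABEL_CODES = {"normal": 0, "abnormal": 1}


def trial_id(session: RecordingSession) -> str:
    """Unique walking-session key (trial indices restart per condition)."""
    return (f"{session.subject_id}/{session.wrist}/"
            f"{session.condition}/{session.trial_index}")


def window_starts(n_samples: int, window: int, stride: int) -> np.ndarray:
    """Start offsets of complete windows: 0, stride, 2*stride, ..."""
    if n_samples < window:
        return np.empty(0, dtype=int)
    n = (n_samples - window) // stride + 1
    return stride * np.arange(n)


def segment_windows(session: RecordingSession, cfg: PreprocessConfig,
                    augmented: bool = False) -> WindowSet:
    """Slice a session into labeled, provenance-tagged windows."""
    w = cfg.window_samples
    stride = cfg.stride_samples
    starts = window_starts(session.n_samples, w, stride)
    if starts.size == 0:
        warnings.warn(f"session {trial_id(session)} shorter than one window; "
                      "empty WindowSet", stacklevel=2)
    wins = np.stack([session.signal[s:s + w] for s in starts]) if starts.size \
        else np.empty((0, w, len(session.channels)))
    n = len(starts)
    return WindowSet(
        windows=wins.astype(np.float32),
        labels=np.full(n, LABEL_CODES[session.condition], dtype=np.int64),
        subject_ids=np.full(n, session.subject_id, dtype=object),
        trial_ids=np.full(n, trial_id(session), dtype=object),
        wrists=np.full(n, session.wrist, dtype=object),
        augmented=np.full(n, augmented, dtype=bool),
        channels=list(session.channels), rate=session.sampling_rate)


def condition_sessions(sessions: list[RecordingSession],
                       cfg: PreprocessConfig) -> list[RecordingSession]:
    """Resample + band-pass each session (the fold-independent prefix)."""
    return [bandpass_session(resample_to_target(s, cfg.target_rate), cfg)
            for s in sessions]


def windows_from_sessions(sessions: list[RecordingSession], cfg: PreprocessConfig,
                          scaler: ChannelScaler, augment: bool) -> WindowSet:
    """Scale and window conditioned sessions; optionally add rotated copies.

    Augmentation exactly doubles the window count: every original window is
    paired with a rotated one carrying the same label and provenance.
    """
    parts = []
    for s in sessions:
        parts.append(segment_windows(apply_scaler(scaler, s), cfg))
        if augment:
            rot = rotation_augment(s)
            parts.append(segment_windows(apply_scaler(scaler, rot), cfg,
                                         augmented=True))
    return WindowSet.concatenate(parts)


def config_hash(cfg: PreprocessConfig) -> str:
    import hashlib
    import json as _json
    from dataclasses import asdict
    payload = _json.dumps(asdict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def save_window_set(ws: WindowSet, directory, cfg: PreprocessConfig | None = None):
    """Cache a WindowSet as a columnar archive with a JSON sidecar."""
    import json as _json
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        directory / "windows.npz", windows=ws.windows, labels=ws.labels,
        subject_ids=ws.subject_ids.astype(str),
        trial_ids=ws.trial_ids.astype(str), wrists=ws.wrists.astype(str),
        augmented=ws.augmented)
    sidecar = {"channels": list(ws.channels), "rate": ws.rate,
               "n_windows": len(ws),
               "config_hash": config_hash(cfg) if cfg else None}
    with open(directory / "windows.json", "w") as fh:
        _json.dump(sidecar, fh, indent=1)


def load_window_set(directory) -> WindowSet:
    import json as _json
    from pathlib import Path
    directory = Path(directory)
    with open(directory / "windows.json") as fh:
        sidecar = _json.load(fh)
    with np.load(directory / "windows.npz", allow_pickle=False) as z:
        return WindowSet(
            windows=z["windows"], labels=z["labels"],
            subject_ids=z["subject_ids"].astype(object),
            trial_ids=z["trial_ids"].astype(object),
            wrists=z["wrists"].astype(object), augmented=z["augmented"],
            channels=list(sidecar["channels"]), rate=sidecar["rate"])
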