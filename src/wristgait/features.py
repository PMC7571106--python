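"""Hand-crafted features for the classical (RF/SVM) baselines.

Per single-channel window: nine time-domain statistics (mean, standard
deviation, median, maximum, minimum, mean absolute change, variance,
skewness, Fisher kurtosis — all population moments) and five
frequency-domain values (the three largest FFT magnitudes over positive
frequencies with DC excluded, the Shannon entropy of the
magnitude-normalized spectrum, and the total spectral energy, which by
Parseval equals the time-domain sum of squares).

Zero-variance windows get skewness and kurtosis of 0 by convention so the
feature table stays NaN-free.  Additional per-channel feature functions can
be registered through ``extra_features`` on :func:`build_feature_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import WindowSet

TIME_FEATURE_NAMES = ("mean", "std", "median", "max", "min",
                      "mean_abs_change", "variance", "skewness", "kurtosis")
FREQ_FEATURE_NAMES = ("fft_mag_1", "fft_mag_2", "fft_mag_3",
                      "fft_entropy", "fft_energy")


def extract_time_features(x) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("window must be 1-D with length >= 4")
    mu = x.mean()
    var = x.var()  # population
    std = np.sqrt(var)
    if std > 0:
        z = (x - mu) / std
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4) - 3.0)  # Fisher
    else:
        skew = kurt = 0.0
    return {
        "mean": float(mu),
        "std": float(std),
        "median": float(np.median(x)),
        "max": float(x.max()),
        "min": float(x.min()),
        "mean_abs_change": float(np.mean(np.abs(np.diff(x)))),
        "variance": float(var),
        "skewness": skew,
        "kurtosis": kurt,
    }


def extract_frequency_features(x, rate: float) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("window must be 1-D with length >= 8")
    n = len(x)
    spectrum = np.fft.fft(x)
    # energy via Parseval: sum |X_k|^2 / n == sum x^2
    energy = float(np.sum(np.abs(spectrum) ** 2) / n)
    # positive frequencies, DC excluded
    mags = np.abs(spectrum[1:n // 2 + 1])
    top = np.sort(mags)[::-1][:3]
    total = mags.sum()
    if total > 0:
        p = mags / total
        nz = p[p > 0]
        entropy = float(-(nz * np.log(nz)).sum())
    else:
        entropy = 0.0
    return {
        "fft_mag_1": float(top[0]),
        "fft_mag_2": float(top[1]) if len(top) > 1 else 0.0,
        "fft_mag_3": float(top[2]) if len(top) > 2 else 0.0,
        "fft_entropy": entropy,
        "fft_energy": energy,
    }


@dataclass
class FeatureVectorSet:
    """Window-by-feature matrix plus the provenance of each row."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    subject_ids: np.ndarray
    trial_ids: np.ndarray
    wrists: np.ndarray
    augmented: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(self.labels), len(self.feature_names)):
            raise ValueError("feature matrix shape inconsistent with metadata")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        df["subject_id"] = self.subject_ids
        df["trial_id"] = self.trial_ids
        df["wrist"] = self.wrists
        return df


def build_feature_table(ws: WindowSet, extra_features=None) -> FeatureVectorSet:
    """Extract the per-channel feature set for every window.

    Column order is channel-major: for each channel in ``ws.channels``, the
    nine time features then the five frequency features.  ``extra_features``
    is an optional mapping name -> f(window_1d, rate) appended per channel.
    """
    extra_features = extra_features or {}
    names = []
    for ch in ws.channels:
        names += [f"{ch}__{f}" for f in TIME_FEATURE_NAMES]
        names += [f"{ch}__{f}" for f in FREQ_FEATURE_NAMES]
        names += [f"{ch}__{f}" for f in extra_features]
    if len(ws) == 0:
        warnings.warn("empty WindowSet; empty feature table", stacklevel=2)
        return FeatureVectorSet(np.empty((0, len(names))), names, ws.labels,
                                ws.subject_ids, ws.trial_ids, ws.wrists,
                                ws.augmented)
    rows = np.empty((len(ws), len(names)))
    for i in range(len(ws)):
        col = 0
        for c in range(len(ws.channels)):
            x = ws.windows[i, :, c].astype(float)
            tf = extract_time_features(x)
            ff = extract_frequency_features(x, ws.rate)
            for f in TIME_FEATURE_NAMES:
                rows[i, col] = tf[f]
                col += 1
            for f in FREQ_FEATURE_NAMES:
                rows[i, col] = ff[f]
                col += 1
            for fn in extra_features.values():
                rows[i, col] = fn(x, ws.rate)
                col += 1
    return FeatureVectorSet(rows, names, ws.labels.copy(), ws.subject_ids.copy(),
                            ws.trial_ids.copy(), ws.wrists.copy(),
                            ws.augmented.copy())
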