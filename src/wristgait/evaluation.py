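"""Leave-one-subject-out evaluation of the gait classifiers.

Each fold holds out every session of one subject; the per-channel scaler is
fitted on that fold's training sessions only and rotation augmentation is
applied to training data only, so no information (statistical or identity)
leaks from the test subject.  The positive class is abnormal gait: a missed
abnormal walk is the clinically costly error, so sensitivity is the
true-positive rate on abnormal segments.

Metrics: accuracy = (TP+TN)/(TP+FP+TN+FN), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP).  Segment-level decisions use a configurable
normal-class probability threshold (a segment is called normal only when
p_normal strictly exceeds the threshold); trial labels are the majority
class of the trial's segments, ties resolved toward abnormal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_gait import RecordingSession, sensor_channels
from .preprocessing import (PreprocessConfig, WindowSet, condition_sessions,
                            fit_scaler, rotation_augment, windows_from_sessions)
from .features import build_feature_table
from .models import (ArchitectureConfig, TrainingConfig, DNN_METHODS,
                     CLASSICAL_METHODS, train_dnn, train_classical)

NORMAL, ABNORMAL = 0, 1
DEFAULT_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)


class UndefinedMetricError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; positive class = abnormal gait."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other):
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def from_predictions(y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return ConfusionCounts(
            tp=int(np.sum((y_true == ABNORMAL) & (y_pred == ABNORMAL))),
            tn=int(np.sum((y_true == NORMAL) & (y_pred == NORMAL))),
            fp=int(np.sum((y_true == NORMAL) & (y_pred == ABNORMAL))),
            fn=int(np.sum((y_true == ABNORMAL) & (y_pred == NORMAL))))


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); raises on empty denominators."""
    if c.total == 0:
        raise UndefinedMetricError("no predictions")
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("no positive (abnormal) instances")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("no negative (normal) instances")
    return ((c.tp + c.tn) / c.total,
            c.tp / (c.tp + c.fn),
            c.tn / (c.tn + c.fp))


def loso_splits(subject_ids) -> list[tuple[list, object]]:
    """One fold per subject: (training subjects, held-out subject)."""
    subjects = sorted(set(subject_ids))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 distinct subjects")
    return [([s for s in subjects if s != test], test) for test in subjects]


def apply_threshold(probs, normal_threshold: float = 0.5) -> np.ndarray:
    """Labels from (p_normal, p_abnormal) pairs.

    A segment is called normal only when its normal-class probability is
    strictly higher than the threshold; otherwise it is treated as abnormal.
    """
    if not (0 < normal_threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 2:
        raise ValueError("probs must be (n, 2) pairs")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probabilities are not normalized")
    return np.where(probs[:, NORMAL] > normal_threshold, NORMAL, ABNORMAL)


def aggregate_trial(window_labels) -> int:
    """Majority label of a trial's segments; ties go to abnormal."""
    labels = np.asarray(window_labels)
    if labels.size == 0:
        raise ValueError("empty trial")
    n_abn = int(np.sum(labels == ABNORMAL))
    return ABNORMAL if n_abn >= labels.size - n_abn else NORMAL


def trial_predictions(trial_ids, y_true, y_pred):
    """Aggregate window-level predictions to one (truth, prediction) per trial."""
    trial_ids = np.asarray(trial_ids)
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out_ids, out_true, out_pred = [], [], []
    for tid in pd.unique(trial_ids):
        mask = trial_ids == tid
        truth = np.unique(y_true[mask])
        if len(truth) != 1:
            raise ValueError(f"trial {tid} has inconsistent ground truth")
        out_ids.append(tid)
        out_true.append(int(truth[0]))
        out_pred.append(aggregate_trial(y_pred[mask]))
    return out_ids, np.asarray(out_true), np.asarray(out_pred)


class UndefinedTestError(ValueError):
    pass


def mcnemar_test(preds_a, preds_b, labels):
    """Paired comparison of two classifiers on the same instances.

    Returns ``(statistic, p_value, b, c)`` where ``b`` counts instances A
    got right and B wrong, ``c`` the reverse.  The statistic is the
    continuity-corrected chi-square (|b-c|-1)^2/(b+c); the p-value comes
    from the exact two-sided binomial(b+c, 1/2) tail when b+c < 25 and from
    the chi-square(df=1) tail otherwise.
    """
    preds_a = np.asarray(preds_a)
    preds_b = np.asarray(preds_b)
    labels = np.asarray(labels)
    if not (len(preds_a) == len(preds_b) == len(labels)):
        raise ValueError("paired predictions must have equal length")
    a_ok = preds_a == labels
    b_ok = preds_b == labels
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    n = b + c
    if n == 0:
        raise UndefinedTestError("no discordant pairs; McNemar is undefined")
    statistic = (abs(b - c) - 1) ** 2 / n
    if n < 25:
        k = min(b, c)
        p = min(1.0, 2.0 * float(stats.binom.cdf(k, n, 0.5)))
        if b == c:
            p = 1.0
    else:
        p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p, b, c


@dataclass
class FoldResult:
    test_subject: str
    window_labels: np.ndarray         # ground truth per test window
    window_probs: np.ndarray          # (n, 2) (p_normal, p_abnormal)
    trial_ids: np.ndarray             # per test window
    wrists: np.ndarray                # per test window
    n_train_windows: int = 0

    def confusion(self, threshold: float = 0.5) -> ConfusionCounts:
        pred = apply_threshold(self.window_probs, threshold)
        return ConfusionCounts.from_predictions(self.window_labels, pred)

    def trial_confusion(self, threshold: float = 0.5) -> ConfusionCounts:
        pred = apply_threshold(self.window_probs, threshold)
        _, t_true, t_pred = trial_predictions(self.trial_ids,
                                              self.window_labels, pred)
        return ConfusionCounts.from_predictions(t_true, t_pred)


@dataclass
class EvaluationReport:
    method: str
    sensors: str
    wrist_policy: tuple
    seed: int
    folds: list = field(default_factory=list)

    def pooled_confusion(self, threshold: float = 0.5,
                         level: str = "segment") -> ConfusionCounts:
        total = ConfusionCounts()
        for f in self.folds:
            total = total + (f.confusion(threshold) if level == "segment"
                             else f.trial_confusion(threshold))
        return total

    def pooled_metrics(self, threshold: float = 0.5, level: str = "segment"):
        return metrics(self.pooled_confusion(threshold, level))

    def fold_metrics(self, threshold: float = 0.5) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            try:
                acc, sens, spec = metrics(f.confusion(threshold))
            except UndefinedMetricError:
                acc = sens = spec = np.nan
            rows.append({"subject": f.test_subject, "accuracy": acc,
                         "sensitivity": sens, "specificity": spec})
        return pd.DataFrame(rows)

    def window_predictions(self, threshold: float = 0.5):
        """Pooled (labels, predictions) over all folds, in fold order."""
        labels = np.concatenate([f.window_labels for f in self.folds])
        preds = np.concatenate([apply_threshold(f.window_probs, threshold)
                                for f in self.folds])
        return labels, preds

    def to_json(self, path) -> None:
        payload = {
            "method": self.method, "sensors": self.sensors,
            "wrist_policy": list(self.wrist_policy), "seed": self.seed,
            "folds": [{
                "test_subject": f.test_subject,
                "window_labels": f.window_labels.tolist(),
                "window_probs": np.round(f.window_probs, 6).tolist(),
                "trial_ids": list(map(str, f.trial_ids)),
                "wrists": list(map(str, f.wrists)),
                "n_train_windows": f.n_train_windows,
            } for f in self.folds],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            d = json.load(fh)
        folds = [FoldResult(
            test_subject=f["test_subject"],
            window_labels=np.asarray(f["window_labels"]),
            window_probs=np.asarray(f["window_probs"]),
            trial_ids=np.asarray(f["trial_ids"], dtype=object),
            wrists=np.asarray(f["wrists"], dtype=object),
            n_train_windows=f["n_train_windows"]) for f in d["folds"]]
        return cls(method=d["method"], sensors=d["sensors"],
                   wrist_policy=tuple(d["wrist_policy"]), seed=d["seed"],
                   folds=folds)


def _select_wrist(sessions, wrists):
    if wrists == "both":
        return list(sessions)
    return [s for s in sessions if s.wrist == wrists]


def run_loso_experiment(sessions: list[RecordingSession], method: str,
                        pre_cfg: PreprocessConfig | None = None,
                        arch_cfg: ArchitectureConfig | None = None,
                        train_cfg: TrainingConfig | None = None,
                        sensors: str = "AGR",
                        wrist_policy: tuple = ("both", "both"),
                        seed: int = 0,
                        progress=None) -> EvaluationReport:
    """Run a full leave-one-subject-out evaluation of one method.

    ``wrist_policy`` is (training wrists, test wrists), each of
    'left'/'right'/'both'.  Sessions are conditioned (resampled and
    band-pass filtered) once; per fold the scaler is fitted on the training
    sessions (originals plus rotated copies when augmenting), the method is
    trained, and the held-out subject's windows are scored.
    """
    if method not in DNN_METHODS and method not in CLASSICAL_METHODS:
        raise ValueError(f"unknown method {method!r}")
    pre_cfg = pre_cfg or PreprocessConfig()
    arch_cfg = arch_cfg or ArchitectureConfig()
    train_cfg = train_cfg or TrainingConfig()
    channels = sensor_channels(sensors)
    picked = [s.select_channels(channels) for s in sessions]
    conditioned = condition_sessions(picked, pre_cfg)

    train_wrists, test_wrists = wrist_policy
    report = EvaluationReport(method=method, sensors=sensors,
                              wrist_policy=wrist_policy, seed=seed)
    for fold_i, (train_ids, test_id) in enumerate(
            loso_splits([s.subject_id for s in conditioned])):
        train_sessions = _select_wrist(
            [s for s in conditioned if s.subject_id != test_id], train_wrists)
        test_sessions = _select_wrist(
            [s for s in conditioned if s.subject_id == test_id], test_wrists)
        if not train_sessions or not test_sessions:
            raise ValueError("wrist policy selects no sessions for fold "
                             f"{test_id}")
        augment = pre_cfg.augment_training
        scaler_pool = train_sessions + ([rotation_augment(s) for s in train_sessions]
                                        if augment else [])
        scaler = fit_scaler(scaler_pool)
        train_ws = windows_from_sessions(train_sessions, pre_cfg, scaler,
                                         augment=augment)
        test_ws = windows_from_sessions(test_sessions, pre_cfg, scaler,
                                        augment=False)
        fold_seed = (seed * 100003 + fold_i * 7919) % (2 ** 31)
        fold_tc = TrainingConfig(**{**asdict(train_cfg), "seed": fold_seed})
        if method in CLASSICAL_METHODS:
            model = train_classical(method, build_feature_table(train_ws),
                                    seed=fold_seed)
            probs = model.predict_proba(build_feature_table(test_ws).values)
        else:
            model = train_dnn(method, train_ws, arch_cfg, fold_tc)
            probs = model.predict_proba(test_ws.windows)
        report.folds.append(FoldResult(
            test_subject=test_id, window_labels=test_ws.labels.copy(),
            window_probs=probs, trial_ids=test_ws.trial_ids.copy(),
            wrists=test_ws.wrists.copy(), n_train_windows=len(train_ws)))
        if progress is not None:
            progress(fold_i, test_id, report.folds[-1])
    return report


def threshold_sweep(report: EvaluationReport,
                    thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Segment- and trial-level metrics across normal-class thresholds.

    Recomputed from the stored probabilities; no retraining.
    """
    if not report.folds:
        raise ValueError("report contains no stored probabilities")
    rows = []
    for thr in thresholds:
        seg = metrics(report.pooled_confusion(thr, "segment"))
        tri = metrics(report.pooled_confusion(thr, "trial"))
        rows.append({"threshold": thr,
                     "segment_accuracy": seg[0], "segment_sensitivity": seg[1],
                     "segment_specificity": seg[2],
                     "trial_accuracy": tri[0], "trial_sensitivity": tri[1],
                     "trial_specificity": tri[2]})
    return pd.DataFrame(rows)


def compare_methods(reports: dict[str, EvaluationReport],
                    reference: str = "proposed",
                    threshold: float = 0.5) -> pd.DataFrame:
    """Method metrics plus paired McNemar p-values against a reference."""
    if len(reports) < 2:
        raise ValueError("need at least two methods to compare")
    if reference not in reports:
        raise ValueError(f"reference method {reference!r} missing")
    ref_labels, ref_preds = reports[reference].window_predictions(threshold)
    rows = []
    for name, rep in reports.items():
        acc, sens, spec = rep.pooled_metrics(threshold)
        row = {"method": name, "accuracy": acc, "sensitivity": sens,
               "specificity": spec, "mcnemar_p": np.nan,
               "discordant_b": np.nan, "discordant_c": np.nan}
        if name != reference:
            labels, preds = rep.window_predictions(threshold)
            if len(labels) != len(ref_labels):
                raise ValueError("reports score different instance sets")
            try:
                _, p, b, c = mcnemar_test(ref_preds, preds, labels)
                row.update(mcnemar_p=p, discordant_b=b, discordant_c=c)
            except UndefinedTestError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)
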