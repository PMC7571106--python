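"""Classifier construction and training.

The proposed network gives every sensor signal a dedicated branch: two
1-D convolutional blocks (conv + batch norm + ReLU, 10 filters of width 5)
followed by max pooling and flattening, in parallel with a two-layer
bidirectional LSTM (20 then 10 units) and dropout.  Each branch's spatial
and temporal features are fused in a per-signal dense layer; all branches
are then merged in a shared dense layer and a 2-way softmax (feature-level
fusion).  Variants: data-level fusion (one branch pair over the full
multivariate window), decision-level fusion (branch outputs concatenated
straight into the output layer), and CNN-only / BiLSTM-only ablations
(single path per branch, no per-branch fusion dense).

Training recipe: 2-class cross-entropy (equivalent to
binary cross-entropy for one-hot labels), Adam at learning rate 0.001,
batch size 256, re-shuffling every epoch, early stopping, and at most 30
epochs.  Classical baselines: a 100-tree gini random forest and an RBF SVM
with C=1 on hand-crafted features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import _nn
from .preprocessing import WindowSet
from .features import FeatureVectorSet

FUSION_LEVELS = ("data", "feature", "decision")
BRANCH_KINDS = ("cnn+bilstm", "cnn_only", "bilstm_only")
DNN_METHODS = {
    "proposed": ("feature", "cnn+bilstm"),
    "data": ("data", "cnn+bilstm"),
    "decision": ("decision", "cnn+bilstm"),
    "cnn": ("feature", "cnn_only"),
    "lstm": ("feature", "bilstm_only"),
}
CLASSICAL_METHODS = ("rf", "svm")


@dataclass(frozen=True)
class ConvBlockSpec:
    n_filters: int = 10
    kernel_size: int = 5

    def __post_init__(self):
        if self.n_filters < 1 or self.kernel_size < 1:
            raise ValueError("n_filters and kernel_size must be >= 1")


@dataclass(frozen=True)
class ArchitectureConfig:
    fusion_level: str = "feature"
    branch: str = "cnn+bilstm"
    sensors: str = "AGR"
    channel_mode: str = "per_axis"      # or "per_sensor"
    conv_blocks: tuple = (ConvBlockSpec(), ConvBlockSpec())
    pool_size: int = 4
    lstm_units: tuple = (20, 10)
    dropout_rate: float = 0.5
    per_channel_dense: int = 32
    shared_dense: int = 64
    n_classes: int = 2

    def __post_init__(self):
        if self.fusion_level not in FUSION_LEVELS:
            raise ValueError(f"unknown fusion level {self.fusion_level!r}")
        if self.branch not in BRANCH_KINDS:
            raise ValueError(f"unknown branch kind {self.branch!r}")
        if not self.sensors:
            raise ValueError("sensors must be non-empty")
        if self.channel_mode not in ("per_axis", "per_sensor"):
            raise ValueError("channel_mode must be per_axis or per_sensor")
        if self.n_classes != 2:
            raise ValueError("binary classifier only")


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.001
    batch_size: int = 256
    max_epochs: int = 30
    early_stopping: bool = True
    patience: int = 5
    validation_fraction: float = 0.1
    shuffle_each_epoch: bool = True
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


class DegenerateTrainingError(ValueError):
    pass


def channel_groups(cfg: ArchitectureConfig, n_channels: int) -> list[list[int]]:
    """Input-channel index groups, one per branch."""
    if cfg.fusion_level == "data":
        return [list(range(n_channels))]
    if cfg.channel_mode == "per_axis":
        return [[i] for i in range(n_channels)]
    if n_channels % 3:
        raise ValueError("per_sensor grouping needs 3-axis triplets")
    return [list(range(i, i + 3)) for i in range(0, n_channels, 3)]


def build_network(cfg: ArchitectureConfig, window_len: int, n_channels: int,
                  rng=None, dtype=np.float32) -> _nn.BranchedNet:
    """Assemble an untrained network for the given fusion/branch variant."""
    rng = rng or np.random.default_rng(0)
    groups = channel_groups(cfg, n_channels)
    P = len(groups)
    d_in = len(groups[0])
    for blk in cfg.conv_blocks:
        if blk.kernel_size > window_len:
            raise ValueError("kernel larger than the window")

    def cnn_path():
        b1, b2 = cfg.conv_blocks
        return _nn.Sequential([
            _nn.Conv1DSame(rng, P, d_in, b1.n_filters, b1.kernel_size, dtype),
            _nn.BatchNorm(P, b1.n_filters, dtype),
            _nn.ReLU(),
            _nn.Conv1DSame(rng, P, b1.n_filters, b2.n_filters, b2.kernel_size, dtype),
            _nn.BatchNorm(P, b2.n_filters, dtype),
            _nn.ReLU(),
            _nn.MaxPool1D(cfg.pool_size),
            _nn.Flatten(),
        ])

    def lstm_path():
        u1, u2 = cfg.lstm_units
        # the two layers chain in the time-major internal layout to avoid
        # transposing the full sequence tensor between them
        return _nn.Sequential([
            _nn.BiLSTM(rng, P, d_in, u1, dtype, return_sequences=True,
                       input_layout="btd", output_layout="ptdb"),
            _nn.BiLSTM(rng, P, 2 * u1, u2, dtype, return_sequences=False,
                       input_layout="ptdb"),
            _nn.Dropout(cfg.dropout_rate, rng),
        ])

    cnn_width = (window_len // cfg.pool_size) * cfg.conv_blocks[1].n_filters
    lstm_width = 2 * cfg.lstm_units[1]
    if cfg.branch == "cnn+bilstm":
        branch_layers = [_nn.Parallel([cnn_path(), lstm_path()]),
                         _nn.Dense(rng, P, cnn_width + lstm_width,
                                   cfg.per_channel_dense, dtype, relu=True),
                         _nn.Dropout(cfg.dropout_rate, rng)]
        branch_width = cfg.per_channel_dense
    elif cfg.branch == "cnn_only":
        branch_layers = [cnn_path()]
        branch_width = cnn_width
    else:
        branch_layers = [lstm_path()]
        branch_width = lstm_width
    branch = _nn.Sequential(branch_layers)

    fusion_layers = [_nn.ConcatBranches()]
    if cfg.fusion_level == "decision":
        # branch outputs feed the output layer directly (no shared dense)
        fusion_layers.append(_nn.Dense(rng, 1, P * branch_width,
                                       cfg.n_classes, dtype))
    else:
        fusion_layers += [
            _nn.Dense(rng, 1, P * branch_width, cfg.shared_dense, dtype, relu=True),
            _nn.Dropout(cfg.dropout_rate, rng),
            _nn.Dense(rng, 1, cfg.shared_dense, cfg.n_classes, dtype),
        ]
    fusion = _nn.Sequential(fusion_layers)
    return _nn.BranchedNet(branch, fusion, groups, dtype)


@dataclass
class TrainedModel:
    """A fitted classifier with a uniform probability interface.

    ``predict_proba`` returns ``(p_normal, p_abnormal)`` pairs (columns in
    label-code order 0, 1) that sum to 1.
    """

    kind: str                              # dnn method name or rf/svm
    arch: ArchitectureConfig | None
    net: object                            # BranchedNet or sklearn estimator
    history: dict = field(default_factory=dict)
    input_shape: tuple | None = None

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.kind in CLASSICAL_METHODS:
            raw = self.net.predict_proba(x)
            cols = {c: i for i, c in enumerate(self.net.classes_)}
            return np.column_stack([raw[:, cols[0]], raw[:, cols[1]]])
        x = np.asarray(x)
        if x.ndim != 3 or x.shape[1:] != self.input_shape:
            raise ValueError(f"window shape {x.shape[1:]} does not match the "
                             f"training shape {self.input_shape}")
        out = np.empty((len(x), 2))
        for s in range(0, len(x), 512):
            logits = self.net.forward(x[s:s + 512], training=False)
            out[s:s + 512] = _nn.softmax(logits.astype(np.float64))
        return out


def _validation_split(ws_labels, subject_ids, fraction, rng):
    """Subject-stratified split: hold out ``fraction`` of windows per subject."""
    n = len(ws_labels)
    val = np.zeros(n, dtype=bool)
    for sid in np.unique(subject_ids):
        idx = np.flatnonzero(subject_ids == sid)
        k = max(1, int(round(fraction * len(idx))))
        val[rng.permutation(idx)[:k]] = True
    if val.all() or not val.any():
        val[:] = False
    return ~val, val


def train_model(net: _nn.BranchedNet, ws: WindowSet,
                tc: TrainingConfig) -> TrainedModel:
    """Train a network on a labeled WindowSet (Adam, early stopping)."""
    labels = np.asarray(ws.labels)
    if len(np.unique(labels)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    rng = np.random.default_rng(tc.seed)
    x = ws.windows.astype(net.dtype)
    onehot = np.eye(2, dtype=net.dtype)[labels]

    if tc.early_stopping:
        tr_mask, val_mask = _validation_split(labels, np.asarray(ws.subject_ids),
                                              tc.validation_fraction, rng)
    else:
        tr_mask = np.ones(len(labels), dtype=bool)
        val_mask = np.zeros(len(labels), dtype=bool)
    xtr, ytr = x[tr_mask], onehot[tr_mask]
    xval, yval = x[val_mask], onehot[val_mask]
    use_val = len(xval) > 0 and tc.early_stopping

    opt = _nn.Adam(net, learning_rate=tc.learning_rate)
    history = {"loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = None
    strikes = 0
    order = np.arange(len(xtr))
    for epoch in range(tc.max_epochs):
        if tc.shuffle_each_epoch:
            rng.shuffle(order)
        losses = []
        for s in range(0, len(order), tc.batch_size):
            idx = order[s:s + tc.batch_size]
            logits = net.forward(xtr[idx], training=True)
            loss, dlogits = _nn.softmax_cross_entropy(logits, ytr[idx])
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        if use_val:
            vlosses = []
            for s in range(0, len(xval), tc.batch_size):
                logits = net.forward(xval[s:s + tc.batch_size], training=False)
                vloss, _ = _nn.softmax_cross_entropy(logits, yval[s:s + tc.batch_size])
                vlosses.append(vloss * len(logits))
            vloss = float(np.sum(vlosses) / len(xval))
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_weights = net.get_weights()
                strikes = 0
            else:
                strikes += 1
                if strikes >= tc.patience:
                    break
    if best_weights is not None:
        net.set_weights(best_weights)
    return TrainedModel(kind="dnn", arch=None, net=net, history=history,
                        input_shape=x.shape[1:])


def train_dnn(method: str, ws: WindowSet, arch: ArchitectureConfig,
              tc: TrainingConfig) -> TrainedModel:
    """Build and train one of the deep variants on a WindowSet."""
    fusion, branch = DNN_METHODS[method]
    arch = ArchitectureConfig(**{**asdict(arch), "fusion_level": fusion,
                                 "branch": branch,
                                 "conv_blocks": arch.conv_blocks})
    rng = np.random.default_rng(tc.seed)
    net = build_network(arch, ws.window_len, len(ws.channels), rng=rng,
                        dtype=np.dtype(tc.dtype).type)
    model = train_model(net, ws, tc)
    model.kind = method
    model.arch = arch
    return model


def train_classical(kind: str, fv: FeatureVectorSet, seed: int = 0) -> TrainedModel:
    """Fit a classical baseline on hand-crafted features."""
    if kind not in CLASSICAL_METHODS:
        raise ValueError(f"unknown classical method {kind!r}")
    if not np.isfinite(fv.values).all():
        raise ValueError("feature table contains non-finite values")
    labels = np.asarray(fv.labels)
    if len(np.unique(labels)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    if kind == "rf":
        est = RandomForestClassifier(n_estimators=100, criterion="gini",
                                     random_state=seed, n_jobs=1)
    else:
        est = SVC(kernel="rbf", C=1.0, probability=True, random_state=seed)
    est.fit(fv.values, labels)
    return TrainedModel(kind=kind, arch=None, net=est)


def save_model(model: TrainedModel, directory) -> None:
    """Persist a trained model: config as JSON, weights natively.

    Deep models store their weights in a NumPy archive; classical models
    go through joblib.  Training history, when present, is written as CSV.
    """
    import json
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"kind": model.kind,
            "input_shape": list(model.input_shape) if model.input_shape else None,
            "arch": asdict(model.arch) if model.arch else None}
    with open(directory / "model.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    if model.kind in CLASSICAL_METHODS:
        import joblib
        joblib.dump(model.net, directory / "model.joblib")
    else:
        weights = {f"w{i}": w for i, w in enumerate(model.net.get_weights())}
        np.savez(directory / "weights.npz", **weights)
    if model.history:
        import pandas as pd
        pd.DataFrame({k: pd.Series(v) for k, v in model.history.items()}
                     ).to_csv(directory / "history.csv", index=False)


def load_model(directory) -> TrainedModel:
    import json
    from pathlib import Path
    directory = Path(directory)
    with open(directory / "model.json") as fh:
        meta = json.load(fh)
    kind = meta["kind"]
    if kind in CLASSICAL_METHODS:
        import joblib
        return TrainedModel(kind=kind, arch=None,
                            net=joblib.load(directory / "model.joblib"))
    arch_d = dict(meta["arch"])
    arch_d["conv_blocks"] = tuple(ConvBlockSpec(**b) for b in arch_d["conv_blocks"])
    arch_d["lstm_units"] = tuple(arch_d["lstm_units"])
    arch = ArchitectureConfig(**arch_d)
    window_len, n_channels = meta["input_shape"]
    net = build_network(arch, window_len, n_channels)
    with np.load(directory / "weights.npz") as z:
        net.set_weights([z[f"w{i}"] for i in range(len(z.files))])
    history = {}
    hist_path = directory / "history.csv"
    if hist_path.exists():
        import pandas as pd
        df = pd.read_csv(hist_path)
        history = {c: df[c].dropna().tolist() for c in df.columns}
    return TrainedModel(kind=kind, arch=arch, net=net, history=history,
                        input_shape=tuple(meta["input_shape"]))
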