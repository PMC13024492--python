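"""Dataset splitting, the training loop, evaluation metrics, and the
architecture sweeps.

The evaluation vocabulary is the balanced-multiclass standard: a K x K
confusion matrix (rows = true class, columns = predicted), accuracy =
trace/total, macro-recall = unweighted mean of per-class recalls (equal to
accuracy exactly when row sums are balanced), macro-F1 = unweighted mean of
per-class F1 scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, TrainingError
from .features import dual_channel_input, frame_sequence, patchify
from .models import (CNNConfig, LSTMConfig, TransformerConfig, Classifier,
                     build_model)
from .nn.autograd import cross_entropy_logits
from .nn.optim import Adam
from .simulator import LabeledDataset

__all__ = [
    "SplitSpec", "TrainConfig", "ConfusionMatrix",
    "split_dataset", "featurize", "train", "evaluate", "metrics",
    "run_experiment", "sweep", "default_config",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (default 60/20/20), stratified."""

    fractions: tuple = (0.6, 0.2, 0.2)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ConfigurationError("fractions must be three positive numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigurationError("fractions must sum to 1")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 50
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 0:
            raise ConfigurationError("max_epochs must be >= 0")
        if self.optimizer != "adam":
            raise ConfigurationError("only the Adam optimizer is provided")


@dataclass
class ConfusionMatrix:
    """K x K integer counts; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_labels: Sequence[float]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_labels)
        if self.counts.shape != (k, k):
            raise DataError("counts must be K x K for K class labels")
        if (self.counts < 0).any():
            raise DataError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray,
                         class_labels: Sequence[float]) -> "ConfusionMatrix":
        k = len(class_labels)
        counts = np.zeros((k, k), dtype=np.int64)
        np.add.at(counts, (np.asarray(y_true), np.asarray(y_pred)), 1)
        return cls(counts, class_labels)

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.class_labels)
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def split_dataset(ds: LabeledDataset, spec: SplitSpec = SplitSpec()) -> LabeledDataset:
    """Assign each segment to train/val/test, reproducibly from the seed.

    Per-class counts for val and test are the rounded fractions; the
    remainder goes to train.  With ``stratified=False`` the same rule is
    applied to the pooled index set.
    """
    n = len(ds)
    split = np.empty(n, dtype=object)
    rng = np.random.default_rng(spec.seed)
    groups = ([np.flatnonzero(ds.labels == c) for c in ds.classes]
              if spec.stratified else [np.arange(n)])
    for idx in groups:
        idx = rng.permutation(idx)
        m = len(idx)
        n_val = int(round(spec.fractions[1] * m))
        n_test = int(round(spec.fractions[2] * m))
        if n_val + n_test > m:
            raise ConfigurationError("split fractions leave no training data")
        split[idx[:n_val]] = "val"
        split[idx[n_val:n_val + n_test]] = "test"
        split[idx[n_val + n_test:]] = "train"
    ds.split = split.astype(str)
    return ds


_FEATURIZERS: Dict[str, Callable] = {
    "cnn": lambda seg, **kw: dual_channel_input(seg),
    "lstm": lambda seg, frame=48, **kw: frame_sequence(seg, frame=frame),
    "transformer": lambda seg, T=48, stride=48, **kw: patchify(seg, T=T, stride=stride).patches,
}


def featurize(segments, arch: str, **kwargs) -> np.ndarray:
    """Stack per-segment model inputs for one architecture into a float32
    batch array: (B, N, 2) for cnn, (B, T, D) for lstm, (B, n_patches, T)
    for transformer."""
    if arch not in _FEATURIZERS:
        raise ConfigurationError(f"unknown architecture {arch!r}")
    fn = _FEATURIZERS[arch]
    return np.stack([fn(s, **kwargs) for s in segments]).astype(np.float32)


def _batch_accuracy(model: Classifier, x: np.ndarray, y: np.ndarray) -> float:
    return float((model.predict(x) == y).mean())


def _mean_loss(model: Classifier, x: np.ndarray, y: np.ndarray,
               batch_size: int) -> float:
    was = model.net.training
    model.net.eval()
    total, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        total += float(cross_entropy_logits(model.forward_logits(xb), yb).data) * len(yb)
        n += len(yb)
    model.net.train(was)
    return total / n


def train(model: Classifier, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray, y_val: np.ndarray,
          cfg: TrainConfig = TrainConfig()):
    """Cross-entropy training with Adam and validation-accuracy early stop.

    Returns ``(model, history)``; the model carries the parameters of the
    best validation epoch.  ``max_epochs=0`` returns the untouched initial
    model with an empty history.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise DataError("train and val splits must be nonempty")
    history = {"epoch": [], "train_loss": [], "train_acc": [],
               "val_loss": [], "val_acc": []}
    if cfg.max_epochs == 0:
        return model, pd.DataFrame(history)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    best_val, best_state, since_best = -np.inf, None, 0
    for epoch in range(cfg.max_epochs):
        model.train()
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            loss = cross_entropy_logits(model.forward_logits(x_train[sel]),
                                        y_train[sel])
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}", epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        val_acc = _batch_accuracy(model, x_val, y_val)
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(_batch_accuracy(model, x_train, y_train))
        history["val_loss"].append(_mean_loss(model, x_val, y_val, cfg.batch_size))
        history["val_acc"].append(val_acc)
        if val_acc > best_val:
            best_val = val_acc
            best_state = model.get_state()  # params + batch-norm buffers
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    if best_state is not None:
        model.set_state(best_state)
    model.eval()
    return model, pd.DataFrame(history)


def evaluate(model: Classifier, x_test: np.ndarray, y_test: np.ndarray,
             class_labels: Sequence[float]) -> ConfusionMatrix:
    """Confusion matrix of argmax predictions on the test split."""
    if len(x_test) == 0:
        raise DataError("test split is empty")
    return ConfusionMatrix.from_predictions(y_test, model.predict(x_test),
                                            class_labels)


def metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, macro-recall, macro-F1 and per-class recall from counts.

    Classes with an empty row (no test samples) have undefined recall; they
    are excluded from the macro averages with a warning and reported in
    ``excluded_classes``.
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise DataError("empty confusion matrix")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    diag = np.diag(counts)
    present = row > 0
    excluded = [cm.class_labels[i] for i in np.flatnonzero(~present)]
    if excluded:
        warnings.warn(f"classes with no test samples excluded from macro "
                      f"averages: {excluded}")
    recall = np.full(len(row), np.nan)
    recall[present] = diag[present] / row[present]
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.maximum(col, 1), 0.0)
        f1 = np.where((precision + recall) > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    return {
        "accuracy": float(diag.sum() / total),
        "macro_recall": float(np.mean(recall[present])),
        "macro_f1": float(np.mean(f1[present])),
        "per_class_recall": {cm.class_labels[i]: float(recall[i])
                             for i in range(len(row))},
        "misclassified": int(total - diag.sum()),
        "excluded_classes": excluded,
    }


def default_config(arch: str, sweep_value: Optional[int] = None, **overrides):
    """Architecture config with the sweep axis set to ``sweep_value``."""
    if arch == "cnn":
        kw = {} if sweep_value is None else {"n_blocks": sweep_value}
        return CNNConfig(**{**kw, **overrides})
    if arch == "lstm":
        kw = {} if sweep_value is None else {"n_units": sweep_value}
        return LSTMConfig(**{**kw, **overrides})
    if arch == "transformer":
        kw = {} if sweep_value is None else {"L": sweep_value}
        return TransformerConfig(**{**kw, **overrides})
    raise ConfigurationError(f"unknown architecture {arch!r}")


def _build_for_data(arch: str, cfg, x_train: np.ndarray, seed: int) -> Classifier:
    if arch == "cnn":
        return build_model(arch, cfg, seed=seed,
                           input_length=x_train.shape[1],
                           in_channels=x_train.shape[2])
    if arch == "lstm":
        return build_model(arch, cfg, seed=seed, input_dim=x_train.shape[2])
    return build_model(arch, cfg, seed=seed, n_tokens=x_train.shape[1])


def run_experiment(ds: LabeledDataset, arch: str, model_cfg,
                   train_cfg: TrainConfig = TrainConfig(),
                   feature_kwargs: Optional[dict] = None) -> dict:
    """Featurize a split dataset, train one model, evaluate on test.

    Returns a dict with the trained model, the per-epoch history, the test
    confusion matrix and its metrics.
    """
    if ds.split is None:
        raise DataError("dataset has no split; call split_dataset first")
    fkw = feature_kwargs or {}
    parts = {}
    labels = ds.class_index()
    for which in ("train", "val", "test"):
        idx = np.flatnonzero(ds.split == which)
        segs = [ds.segments[i] for i in idx]
        parts[which] = (featurize(segs, arch, **fkw), labels[idx])
    model = _build_for_data(arch, model_cfg, parts["train"][0], train_cfg.seed)
    model, history = train(model, *parts["train"], *parts["val"], train_cfg)
    cm = evaluate(model, *parts["test"], class_labels=list(ds.classes))
    return {"model": model, "history": history, "confusion": cm,
            "metrics": metrics(cm)}


def sweep(arch: str, sweep_values: Sequence[int], ds: LabeledDataset,
          train_cfg: TrainConfig = TrainConfig(), n_reps: int = 1,
          config_overrides: Optional[dict] = None,
          feature_kwargs: Optional[dict] = None) -> pd.DataFrame:
    """Test accuracy as a function of the architecture's sweep axis.

    One row per value; each cell aggregates ``n_reps`` independently seeded
    runs.  Failed runs are recorded in the ``n_failed`` column rather than
    silently dropped.
    """
    if len(sweep_values) == 0:
        raise ConfigurationError("sweep_values must be nonempty")
    rows = []
    for value in sweep_values:
        accs, n_failed = [], 0
        for rep in range(n_reps):
            cfg = default_config(arch, value, **(config_overrides or {}))
            tc = TrainConfig(optimizer=train_cfg.optimizer,
                             learning_rate=train_cfg.learning_rate,
                             batch_size=train_cfg.batch_size,
                             max_epochs=train_cfg.max_epochs,
                             early_stop_patience=train_cfg.early_stop_patience,
                             seed=train_cfg.seed + 1000 * rep)
            try:
                result = run_experiment(ds, arch, cfg, tc, feature_kwargs)
                accs.append(result["metrics"]["accuracy"])
            except TrainingError:
                n_failed += 1
        rows.append({"value": value,
                     "mean_accuracy": float(np.mean(accs)) if accs else np.nan,
                     "sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                     "n_reps": n_reps, "n_failed": n_failed})
    return pd.DataFrame(rows)
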