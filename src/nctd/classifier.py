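"""CNN architecture, training loop and evaluation metrics.

The network is four convolutional blocks of 64 filters (kernel 3, stride 2,
batch normalization then ReLU), chosen so a 31-pixel input follows the
15 -> 7 -> 3 -> 1 feature-map progression and any other side floor-halves
per block, followed by global average pooling to a length-64 vector, one
hidden dense layer and a softmax output. Training minimizes categorical
cross-entropy with Adam (learning rate 8e-4, batch size 64 by default) and
reports metrics at the best validation-accuracy epoch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

from .errors import ConfigurationError, InputError, TrainingError
from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Dense,
    GlobalAvgPool2d,
    ReLU,
    Sequential,
    SoftmaxCrossEntropy,
)
from .preprocess import SplitIndex

__all__ = [
    "CNNSpec",
    "TrainConfig",
    "EvalReport",
    "build_architecture",
    "build_network",
    "train",
    "evaluate_metrics",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)

N_BLOCKS = 4
N_FILTERS = 64


def _conv_padding(side: int) -> int:
    # kernel 3 / stride 2: padding 0 maps odd sides to (s-1)/2, padding 1
    # maps even sides to s/2 (and keeps a size-1 map at 1) — i.e. floor(s/2)
    # everywhere, and 31 -> 15 -> 7 -> 3 -> 1 in particular.
    return 0 if side % 2 == 1 and side >= 3 else 1


@dataclass(frozen=True)
class CNNSpec:
    """Architecture description for a square single-channel input."""

    input_side: int
    n_classes: int
    hidden_width: int = 64
    n_filters: int = N_FILTERS
    feature_map_sides: tuple[int, ...] = ()
    paddings: tuple[int, ...] = ()


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults are the published settings)."""

    learning_rate: float = 0.0008
    batch_size: int = 64
    optimizer: str = "adam"
    loss: str = "categorical_cross_entropy"
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ConfigurationError("learning rate and batch size must be positive")
        if self.epochs < 1:
            raise ConfigurationError("at least one training epoch is required")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class EvalReport:
    """Per-epoch validation accuracy plus best-epoch metrics."""

    per_epoch_val_accuracy: list[float]
    per_epoch_train_loss: list[float]
    best_epoch: int
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    class_labels: list[str]

    def to_dict(self) -> dict:
        return {
            "per_epoch_val_accuracy": [float(a) for a in self.per_epoch_val_accuracy],
            "per_epoch_train_loss": [float(l) for l in self.per_epoch_train_loss],
            "best_epoch": int(self.best_epoch),
            "accuracy": float(self.accuracy),
            "macro_precision": float(self.macro_precision),
            "macro_recall": float(self.macro_recall),
            "macro_f1": float(self.macro_f1),
            "confusion": np.asarray(self.confusion).astype(int).tolist(),
            "class_labels": list(self.class_labels),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def build_architecture(
    input_side: int, n_classes: int, hidden_width: int = 64
) -> CNNSpec:
    """Plan the four-block CNN for a given input side and class count."""
    if n_classes < 2:
        raise ConfigurationError("need at least two classes")
    if input_side < 4:
        raise ConfigurationError(
            f"input side {input_side} too small for four stride-2 blocks; "
            "use quadrant tiling (tile='quad') or pad the input"
        )
    sides, paddings = [], []
    side = input_side
    for _ in range(N_BLOCKS):
        pad = _conv_padding(side)
        side = (side + 2 * pad - 3) // 2 + 1
        sides.append(side)
        paddings.append(pad)
    return CNNSpec(
        input_side=input_side,
        n_classes=n_classes,
        hidden_width=hidden_width,
        feature_map_sides=tuple(sides),
        paddings=tuple(paddings),
    )


def build_network(spec: CNNSpec, seed: int = 0) -> Sequential:
    """Instantiate the network with seeded He initialization."""
    rng = np.random.default_rng(seed)
    layers = []
    in_ch = 1
    for pad in spec.paddings:
        layers += [
            Conv2d(in_ch, spec.n_filters, kernel=3, stride=2, padding=pad, rng=rng),
            BatchNorm2d(spec.n_filters),
            ReLU(),
        ]
        in_ch = spec.n_filters
    layers += [
        GlobalAvgPool2d(),
        Dense(spec.n_filters, spec.hidden_width, rng=rng),
        ReLU(),
        Dense(spec.hidden_width, spec.n_classes, rng=rng),
    ]
    return Sequential(layers)


def _as_stack(images: Sequence) -> np.ndarray:
    arrs = [np.asarray(getattr(img, "pixels", img), dtype=np.float32) for img in images]
    sides = {a.shape for a in arrs}
    if len(sides) != 1:
        raise InputError(f"images of mixed sizes: {sorted(sides)}")
    return np.stack(arrs)[:, None, :, :]


def train(
    images: Sequence,
    labels: Sequence,
    split: SplitIndex,
    spec: CNNSpec,
    config: TrainConfig | None = None,
) -> tuple[Sequential, EvalReport]:
    """Train the CNN on the training rows and track validation accuracy.

    Validation rows never influence the weights; accuracy is recorded after
    every epoch and the best epoch (earliest on ties) defines the reported
    metrics. The returned network carries the best-epoch weights.
    """
    config = config or TrainConfig()
    x = _as_stack(images)
    if x.shape[-1] != spec.input_side:
        raise InputError(
            f"images of side {x.shape[-1]} do not match spec input side "
            f"{spec.input_side}"
        )
    labels = np.asarray([str(c) for c in labels], dtype=object)
    classes = sorted(set(labels))
    if len(classes) != spec.n_classes:
        raise InputError(
            f"{len(classes)} classes in labels but spec expects {spec.n_classes}"
        )
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_to_idx[c] for c in labels])

    tr, va = split.train_rows, split.val_rows
    if len(va) == 0:
        raise InputError("validation split is empty; nothing to evaluate")
    missing = set(y[va]) - set(y[tr])
    if missing:
        logger.warning(
            "classes %s appear in validation but not in training",
            sorted(classes[i] for i in missing),
        )
    x_tr, y_tr = x[tr], y[tr]
    x_va, y_va = x[va], y[va]
    onehot = np.eye(spec.n_classes, dtype=np.float32)[y_tr]

    rng = np.random.default_rng(config.seed)
    net = build_network(spec, seed=int(rng.integers(2**31)))
    opt = Adam(net, lr=config.learning_rate)
    loss_fn = SoftmaxCrossEntropy()

    val_acc_history: list[float] = []
    loss_history: list[float] = []
    best = (-1.0, -1)  # (accuracy, epoch)
    best_state: dict[str, np.ndarray] = {}
    best_pred: np.ndarray | None = None

    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = net.forward(x_tr[idx], train=True)
            loss, grad = loss_fn.forward(logits, onehot[idx])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches} "
                    f"(lr={config.learning_rate}); inspect input scaling"
                )
            net.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        mean_loss = epoch_loss / max(n_batches, 1)
        probs = net.predict_proba(x_va)
        pred = probs.argmax(axis=1)
        acc = float((pred == y_va).mean()) if len(y_va) else float("nan")
        loss_history.append(mean_loss)
        val_acc_history.append(acc)
        logger.info("epoch %d train_loss %.4f val_accuracy %.4f", epoch, mean_loss, acc)
        if acc > best[0]:
            best = (acc, epoch)
            best_state = net.snapshot()
            best_pred = pred

    net.load_state_dict(best_state)
    pred_labels = [classes[i] for i in best_pred]
    true_labels = [classes[i] for i in y_va]
    accuracy, prec, rec, f1, confusion = evaluate_metrics(
        pred_labels, true_labels, labels=classes
    )
    report = EvalReport(
        per_epoch_val_accuracy=val_acc_history,
        per_epoch_train_loss=loss_history,
        best_epoch=best[1],
        accuracy=accuracy,
        macro_precision=prec,
        macro_recall=rec,
        macro_f1=f1,
        confusion=confusion,
        class_labels=classes,
    )
    return net, report


def evaluate_metrics(
    predictions: Sequence,
    truth: Sequence,
    labels: Sequence | None = None,
) -> tuple[float, float, float, float, np.ndarray]:
    """Accuracy, macro precision/recall/F1 and the confusion matrix.

    Per-class precision and recall are 0 when undefined (zero division);
    macro averages weight every class equally.
    """
    predictions = [str(c) for c in predictions]
    truth = [str(c) for c in truth]
    if len(predictions) != len(truth):
        raise InputError(
            f"length mismatch: {len(predictions)} predictions, {len(truth)} truths"
        )
    if len(truth) == 0:
        raise InputError("cannot evaluate an empty prediction set")
    if labels is None:
        labels = sorted(set(truth) | set(predictions))
    labels = [str(c) for c in labels]
    confusion = _sk_confusion(truth, predictions, labels=labels)
    accuracy = float(np.trace(confusion) / confusion.sum())
    prec, rec, f1, _ = _sk_prfs(
        truth, predictions, labels=labels, average="macro", zero_division=0
    )
    return accuracy, float(prec), float(rec), float(f1), confusion


def save_checkpoint(
    path: str | Path, net: Sequential, spec: CNNSpec, class_labels: Sequence[str]
) -> None:
    """Persist weights + architecture to an ``.npz`` checkpoint."""
    meta = json.dumps(
        {
            "input_side": spec.input_side,
            "n_classes": spec.n_classes,
            "hidden_width": spec.hidden_width,
            "class_labels": list(class_labels),
        }
    )
    np.savez(path, __meta__=np.array(meta), **net.state_dict())


def load_checkpoint(path: str | Path) -> tuple[Sequential, CNNSpec, list[str]]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    spec = build_architecture(
        meta["input_side"], meta["n_classes"], meta["hidden_width"]
    )
    net = build_network(spec, seed=0)
    net.load_state_dict(state)
    return net, spec, list(meta["class_labels"])
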