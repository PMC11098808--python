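"""Training loop with the study's regime and per-epoch history.

Defaults follow the published setup: Adam at learning rate 2e-5, batch
size 24, 200 epochs, categorical cross-entropy on the softmax output.
Shuffling and weight initialization are both seeded, so a fixed seed and
single-threaded execution give bit-identical histories across runs on the
same platform.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import engine
from .architecture import ResMiniConfig, build_model


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 2e-5
    batch_size: int = 24
    epochs: int = 200
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    seed: int = 0
    shuffle_each_epoch: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


def _one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError(
            f"labels must lie in [0, {num_classes}), got "
            f"[{labels.min()}, {labels.max()}]")
    return np.eye(num_classes, dtype=engine.DTYPE)[labels]


def evaluate_loss(model: engine.Network, x: np.ndarray, y: np.ndarray,
                  batch_size: int = 64) -> tuple[float, float]:
    """Mean cross-entropy and accuracy in inference mode."""
    onehot = _one_hot(y, model.num_classes)
    losses, correct = [], 0
    for start in range(0, len(x), batch_size):
        xb = x[start:start + batch_size]
        yb = onehot[start:start + batch_size]
        probs = model.forward(xb, training=False)
        losses.append(-np.log(np.clip((probs * yb).sum(axis=1), 1e-12, None)))
        correct += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
    return float(np.mean(np.concatenate(losses))), correct / len(x)


def train(model: engine.Network, train_set: tuple[np.ndarray, np.ndarray],
          val_set: tuple[np.ndarray, np.ndarray],
          config: TrainingConfig) -> tuple[engine.Network, History]:
    """Run exactly ``config.epochs`` epochs of mini-batch Adam.

    ``train_set``/``val_set`` are (images (N,1,H,W), integer labels) pairs.
    The logged train loss/accuracy are the running means over the epoch's
    batches (computed in training mode); validation metrics are computed in
    inference mode after each epoch.
    """
    x_train, y_train = train_set
    x_val, y_val = val_set
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    y_onehot = _one_hot(y_train, model.num_classes)
    _one_hot(y_val, model.num_classes)  # validate label range up front
    opt = engine.Adam(model, config.learning_rate, config.beta1,
                      config.beta2, config.epsilon)
    rng = np.random.default_rng(config.seed)
    history = History()
    for _ in range(config.epochs):
        order = (rng.permutation(len(x_train)) if config.shuffle_each_epoch
                 else np.arange(len(x_train)))
        losses, accs = [], []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if idx.size == 0:
                raise ValueError("empty batch")
            loss, acc = model.train_step(x_train[idx], y_onehot[idx])
            opt.step()
            losses.append(loss)
            accs.append(acc)
        val_loss, val_acc = evaluate_loss(model, x_val, y_val)
        history.train_loss.append(float(np.mean(losses)))
        history.train_accuracy.append(float(np.mean(accs)))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
    return model, history


def save_history(history: History, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "train_loss", "train_accuracy",
                         "val_loss", "val_accuracy"])
        for i in range(len(history)):
            writer.writerow([i + 1, history.train_loss[i],
                             history.train_accuracy[i], history.val_loss[i],
                             history.val_accuracy[i]])


def load_history(path: str | Path) -> History:
    history = History()
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            history.train_loss.append(float(row["train_loss"]))
            history.train_accuracy.append(float(row["train_accuracy"]))
            history.val_loss.append(float(row["val_loss"]))
            history.val_accuracy.append(float(row["val_accuracy"]))
    return history


def save_model(model: engine.Network, config: ResMiniConfig,
               path: str | Path) -> None:
    """Weights + architecture config in one .npz archive."""
    state = model.state_dict()
    cfg = asdict(config)
    cfg["shortcut_policy"] = config.shortcut_policy.value
    cfg["module_strides"] = list(config.module_strides)
    np.savez(Path(path), __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **state)


def load_model(path: str | Path) -> tuple[engine.Network, ResMiniConfig]:
    """Restore a saved model; predictions are bit-identical to pre-save."""
    from .architecture import ShortcutPolicy

    with np.load(Path(path)) as data:
        cfg_raw = json.loads(bytes(data["__config__"].tobytes()).decode())
        cfg_raw["shortcut_policy"] = ShortcutPolicy(cfg_raw["shortcut_policy"])
        cfg_raw["module_strides"] = tuple(cfg_raw["module_strides"])
        config = ResMiniConfig(**cfg_raw)
        model = build_model(config, seed=0)
        model.load_state_dict({k: data[k] for k in data.files
                               if k != "__config__"})
    return model, config
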