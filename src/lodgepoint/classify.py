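"""Image dataset construction and CNN training/evaluation for lodging degree.

Canopy-height rasters rendered to RGB are the classifier inputs.  The
dataset workflow mirrors the field study: offline augmentation by seeded
rotations/flips up to a target size, a stratified 16:4:5
train/validation/test split, CNN training with Adam at learning rate 0.001,
batch size 4, up to 400 epochs with early stopping after 30 epochs without
validation improvement, and evaluation by one-vs-rest TP/FP/TN/FN with
accuracy, precision, recall and F1 (macro-averaged across classes).

Augmentation before the split means augmented copies can share a source
plot with training images; ``split_by_plot`` groups by source plot first
and is the recommended leakage-free protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .lodging import LodgingClass
from .models import MODEL_NAMES, build_model, count_parameters
from .nn import Adam, Network, cross_entropy, softmax_probs

logger = logging.getLogger("lodgepoint")

__all__ = [
    "ImageSample",
    "TrainConfig",
    "EvalReport",
    "SoftmaxOutput",
    "augment_dataset",
    "split_dataset",
    "split_by_plot",
    "softmax",
    "build_model",
    "count_parameters",
    "train_model",
    "evaluate_model",
    "metrics_from_confusion",
    "write_manifest",
]

_AUG_OPS = ("rot90", "rot270", "hflip", "vflip")


@dataclass
class ImageSample:
    """One classifier input: an RGB image with its lodging-degree label."""

    image: np.ndarray          # (H, W, 3) float in [0, 1] or uint8
    label: int                 # LodgingClass value
    source_plot: int = -1
    augmented: bool = False


def _apply_op(img: np.ndarray, op: str) -> np.ndarray:
    if op == "rot90":
        return np.rot90(img, 1, axes=(0, 1)).copy()
    if op == "rot270":
        return np.rot90(img, 3, axes=(0, 1)).copy()
    if op == "hflip":
        return img[:, ::-1].copy()
    if op == "vflip":
        return img[::-1, :].copy()
    raise ValueError(f"unknown augmentation op {op!r}")


def augment_dataset(
    images: Sequence[ImageSample], target_total: int, seed: int = 0
) -> list[ImageSample]:
    """Grow a dataset to ``target_total`` by seeded rotations and flips.

    Originals are kept; each augmented copy applies one randomly chosen op
    (rot90 / rot270 / horizontal flip / vertical mirror) to a randomly
    chosen source image and inherits its label and source plot.
    """
    if not images:
        raise ValueError("cannot augment an empty dataset")
    if target_total < len(images):
        raise ValueError("target_total must be >= the number of originals")
    rng = np.random.default_rng(seed)
    out = list(images)
    while len(out) < target_total:
        src = images[int(rng.integers(len(images)))]
        op = _AUG_OPS[int(rng.integers(len(_AUG_OPS)))]
        out.append(
            ImageSample(
                image=_apply_op(np.asarray(src.image), op),
                label=src.label,
                source_plot=src.source_plot,
                augmented=True,
            )
        )
    return out


def _largest_remainder(count: int, ratio: tuple[int, ...]) -> list[int]:
    total = sum(ratio)
    exact = [count * r / total for r in ratio]
    base = [int(np.floor(e)) for e in exact]
    rem = count - sum(base)
    order = np.argsort([b - e for b, e in zip(base, exact)], kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base


def split_dataset(
    samples: Sequence[ImageSample],
    ratio: tuple[int, int, int] = (16, 4, 5),
    seed: int = 0,
) -> tuple[list[ImageSample], list[ImageSample], list[ImageSample]]:
    """Seeded stratified split into train/validation/test.

    Within each class the samples are shuffled and allotted to the three
    splits by largest-remainder rounding of the ratio, so per-class
    proportions stay within one sample of 16:4:5 and the splits partition
    the input.
    """
    if len(samples) < sum(ratio):
        raise ValueError(f"need at least {sum(ratio)} samples to split {ratio}")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[ImageSample]] = {}
    for s in samples:
        by_class.setdefault(int(s.label), []).append(s)
    total = sum(ratio)
    targets = _largest_remainder(len(samples), ratio)
    # per-class largest remainder keeps each class within 1 of the ratio;
    # a repair pass then moves single samples between parts until the
    # global sizes hit the largest-remainder targets as well
    alloc = {lab: _largest_remainder(len(g), ratio) for lab, g in by_class.items()}
    exact = {lab: [len(g) * r / total for r in ratio] for lab, g in by_class.items()}
    for _ in range(len(samples)):
        sizes = [sum(alloc[lab][p] for lab in by_class) for p in range(len(ratio))]
        if sizes == targets:
            break
        p_over = next(p for p, (s, t) in enumerate(zip(sizes, targets)) if s > t)
        p_under = next(p for p, (s, t) in enumerate(zip(sizes, targets)) if s < t)
        lab = max(
            by_class,
            key=lambda L: (alloc[L][p_over] - exact[L][p_over])
            + (exact[L][p_under] - alloc[L][p_under]),
        )
        alloc[lab][p_over] -= 1
        alloc[lab][p_under] += 1
    parts: tuple[list, list, list] = ([], [], [])
    for label in sorted(by_class):
        group = by_class[label]
        idx = rng.permutation(len(group))
        start = 0
        for part, size in zip(parts, alloc[label]):
            part.extend(group[i] for i in idx[start : start + size])
            start += size
    return parts


def split_by_plot(
    samples: Sequence[ImageSample],
    ratio: tuple[int, int, int] = (16, 4, 5),
    seed: int = 0,
) -> tuple[list[ImageSample], list[ImageSample], list[ImageSample]]:
    """Leakage-free variant: source plots (not images) are split, and every
    image follows its plot, so no augmented copy crosses a split boundary."""
    plots: dict[int, list[ImageSample]] = {}
    for s in samples:
        plots.setdefault(int(s.source_plot), []).append(s)
    plot_label = {p: int(group[0].label) for p, group in plots.items()}
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {}
    for p, lab in plot_label.items():
        by_class.setdefault(lab, []).append(p)
    parts: tuple[list, list, list] = ([], [], [])
    for label in sorted(by_class):
        ps = sorted(by_class[label])
        idx = rng.permutation(len(ps))
        sizes = _largest_remainder(len(ps), ratio)
        start = 0
        for part, size in zip(parts, sizes):
            for i in idx[start : start + size]:
                part.extend(plots[ps[i]])
            start += size
    return parts


@dataclass
class SoftmaxOutput:
    probabilities: np.ndarray
    logits: np.ndarray


def softmax(logits: Sequence[float]) -> SoftmaxOutput:
    """Stable softmax over C >= 2 class logits; probabilities sum to 1."""
    z = np.asarray(logits, dtype=float)
    if z.ndim != 1 or z.size < 2:
        raise ValueError("softmax expects a vector of at least 2 logits")
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax logits must be finite")
    return SoftmaxOutput(probabilities=softmax_probs(z), logits=z)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (field-study defaults).

    ``input_size`` and ``width_mult`` allow the scaled-down CPU variant;
    224 / 1.0 reproduce the full-size networks.
    """

    model_name: str = "mobilenetv2"
    learning_rate: float = 0.001
    batch_size: int = 4
    max_epochs: int = 400
    patience: int = 30
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int = 0
    num_classes: int = 4
    input_size: int = 224
    width_mult: float = 1.0

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_NAMES:
            raise ValueError(f"model_name must be one of {MODEL_NAMES}")
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) < 0:
            raise ValueError("hyperparameters must be non-negative")
        if self.optimizer != "adam" or self.loss != "cross_entropy":
            raise ValueError("only adam + cross_entropy are supported")


def _prepare(samples: Sequence[ImageSample], size: int) -> tuple[np.ndarray, np.ndarray]:
    """Resize to size x size (bilinear), scale to [0,1], standardise, NCHW."""
    xs = np.empty((len(samples), 3, size, size), dtype=np.float32)
    ys = np.empty(len(samples), dtype=np.int64)
    for i, s in enumerate(samples):
        img = np.asarray(s.image)
        if img.dtype != np.uint8:
            img = (np.clip(img, 0, 1) * 255).astype(np.uint8)
        if img.shape[:2] != (size, size):
            img = np.asarray(Image.fromarray(img).resize((size, size), Image.BILINEAR))
        arr = ((img.astype(np.float32) / 255.0) - 0.5) / 0.5
        xs[i] = arr.transpose(2, 0, 1)
        ys[i] = int(s.label)
    return xs, ys


def _epoch_eval(model: Network, x: np.ndarray, y: np.ndarray, batch: int = 64):
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        logits = model.forward(x[i : i + batch], train=False)
        loss, _ = cross_entropy(logits, y[i : i + batch])
        losses.append(loss * len(y[i : i + batch]))
        correct += int((logits.argmax(axis=1) == y[i : i + batch]).sum())
    return sum(losses) / len(y), correct / len(y)


def train_model(
    train: Sequence[ImageSample],
    validation: Sequence[ImageSample],
    cfg: TrainConfig = TrainConfig(),
) -> tuple[Network, dict]:
    """Train a CNN with early stopping on validation accuracy.

    Stops after ``patience`` consecutive epochs without strict improvement
    (ties keep the earlier epoch) and restores the best-validation weights.
    Fully deterministic for a fixed config and seed.
    """
    if not train or not validation:
        raise ValueError("train and validation sets must be non-empty")
    model = build_model(cfg.model_name, cfg.num_classes, seed=cfg.seed,
                        width_mult=cfg.width_mult)
    for j, d in enumerate(model.dropout_layers()):
        d.rng = np.random.default_rng((cfg.seed, 1, j))
    xtr, ytr = _prepare(train, cfg.input_size)
    xva, yva = _prepare(validation, cfg.input_size)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng((cfg.seed, 2))
    history: dict[str, list[float]] = {
        "train_loss": [], "train_accuracy": [], "val_loss": [], "val_accuracy": [],
    }
    best_acc = -np.inf
    best_state = model.get_state()
    best_epoch = 0
    since_improve = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(xtr))
        losses, correct = [], 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(xtr[idx], train=True)
            loss, grad = cross_entropy(logits, ytr[idx])
            model.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == ytr[idx]).sum())
        val_loss, val_acc = _epoch_eval(model, xva, yva)
        history["train_loss"].append(sum(losses) / len(xtr))
        history["train_accuracy"].append(correct / len(xtr))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_state, best_epoch = val_acc, model.get_state(), epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                break
    model.set_state(best_state)
    history["best_epoch"] = best_epoch
    history["epochs_run"] = len(history["train_loss"])
    return model, history


@dataclass
class EvalReport:
    """One-vs-rest counts and metrics per class, macro averages, confusion."""

    confusion: np.ndarray                   # (C, C), rows = true, cols = predicted
    per_class: dict[int, dict[str, float]]  # tp/fp/tn/fn/accuracy/precision/recall/f1
    accuracy: float                         # overall, trace / total
    macro_precision: float
    macro_recall: float
    macro_f1: float


def metrics_from_confusion(confusion: np.ndarray) -> EvalReport:
    """Per-class one-vs-rest TP/FP/TN/FN and derived metrics.

    accuracy_c = (TP+TN)/(TP+TN+FP+FN), precision = TP/(TP+FP),
    recall = TP/(TP+FN), F1 = 2PR/(P+R).  Classes absent from the test set
    get NaN metrics and are excluded from the macro averages.
    """
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    per_class: dict[int, dict[str, float]] = {}
    precisions, recalls, f1s = [], [], []
    for c in range(cm.shape[0]):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        entry = {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
                 "accuracy": (tp + tn) / total if total else float("nan")}
        if cm[c].sum() == 0:
            logger.info("class %d absent from the test set; metrics undefined", c)
            entry.update(precision=float("nan"), recall=float("nan"), f1=float("nan"))
        else:
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            entry.update(precision=prec, recall=rec, f1=f1)
            precisions.append(prec)
            recalls.append(rec)
            f1s.append(f1)
        per_class[c] = entry
    return EvalReport(
        confusion=cm.astype(int),
        per_class=per_class,
        accuracy=float(np.trace(cm) / total) if total else float("nan"),
        macro_precision=float(np.mean(precisions)) if precisions else float("nan"),
        macro_recall=float(np.mean(recalls)) if recalls else float("nan"),
        macro_f1=float(np.mean(f1s)) if f1s else float("nan"),
    )


def evaluate_model(
    model: Network,
    test: Sequence[ImageSample],
    input_size: int | None = None,
    num_classes: int = 4,
    batch: int = 64,
) -> EvalReport:
    """Predict the test set and score it with the one-vs-rest metrics."""
    from sklearn.metrics import confusion_matrix

    if not test:
        raise ValueError("test set must be non-empty")
    if input_size is None:
        img = np.asarray(test[0].image)
        input_size = img.shape[0] if img.shape[0] == img.shape[1] else 224
    x, y = _prepare(test, input_size)
    preds = []
    for i in range(0, len(x), batch):
        logits = model.forward(x[i : i + batch], train=False)
        preds.append(logits.argmax(axis=1))
    yhat = np.concatenate(preds)
    cm = confusion_matrix(y, yhat, labels=list(range(num_classes)))
    return metrics_from_confusion(cm)


def write_manifest(samples: Sequence[ImageSample], splits: Sequence[str],
                   paths: Sequence[str], out: str | Path) -> Path:
    """Dataset manifest CSV: path, label, source_plot, augmented, split."""
    df = pd.DataFrame({
        "path": list(paths),
        "label": [int(s.label) for s in samples],
        "source_plot": [s.source_plot for s in samples],
        "augmented": [s.augmented for s in samples],
        "split": list(splits),
    })
    df.to_csv(out, index=False)
    return Path(out)
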