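"""Training harness, hyperparameter sweeps, and pixel-wise evaluation.

Training minimizes mean binary cross-entropy between the network's per-pixel
glomerulus probabilities and the ground-truth masks, with one of four
optimizers (Adam, SGD, Adadelta, RMSprop) at its standard default learning
rate unless overridden. Each epoch records training loss, validation loss
and validation pixel accuracy; the weights of the best validation-loss epoch
are retained and restored at the end of training.

Evaluation is confusion-matrix based: per-pixel TP/FP/FN/TN between a
predicted and a ground-truth mask, from which accuracy, precision, recall
and F1 derive (F1 is algebraically the Dice coefficient of the two masks).
Percentages follow the field's reporting convention; losses are reported in
natural units with an optional x100 view. Aggregate reports compute metrics
per image and then average them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from ._nn import OPTIMIZERS, binary_cross_entropy, make_optimizer
from .model import ModifiedUNet
from .rle_codec import validate_binary
from .tiling import TileSet

logger = logging.getLogger("glomseg")

SWEEP_COLUMNS = ["optimizer", "batch_size", "epochs", "val_loss", "val_accuracy"]


@dataclass(frozen=True)
class TrainConfig:
    """A single training run's hyperparameters.

    ``learning_rate=None`` uses the optimizer's standard default (SGD 0.01,
    Adam 1e-3, RMSprop 1e-3, Adadelta 1.0). The grid explored in the
    reference sweeps is batch sizes {8, 16, 24} and epochs {10..50}.
    """

    optimizer: str = "adam"
    batch_size: int = 8
    epochs: int = 10
    learning_rate: float | None = None
    loss: str = "binary_cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer.lower() not in OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer {self.optimizer!r}; "
                f"expected one of {sorted(OPTIMIZERS)}"
            )
        if self.loss != "binary_cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_accuracy: float  # percent


@dataclass
class TrainHistory:
    """Per-epoch loss/accuracy records plus the best-epoch index."""

    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self, loss_times_100: bool = False) -> pd.DataFrame:
        """History as a table; ``loss_times_100`` adds the x100 loss view
        used in some reports."""
        df = pd.DataFrame(
            [{"epoch": r.epoch, "train_loss": r.train_loss,
              "val_loss": r.val_loss, "val_accuracy": r.val_accuracy}
             for r in self.records]
        )
        if loss_times_100 and len(df):
            df["val_loss_x100"] = 100.0 * df["val_loss"]
        return df

    @property
    def final(self) -> EpochRecord:
        return self.records[-1]


def _tiles_to_arrays(tiles: TileSet | Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Stack tiles into (images, masks) float32 batches, images in [0,1]."""
    imgs = np.stack([t.image for t in tiles]).astype(np.float32) / 255.0
    masks = np.stack([t.mask for t in tiles]).astype(np.float32)[..., None]
    return imgs, masks


def train(
    net: ModifiedUNet,
    train_tiles: TileSet,
    val_tiles: TileSet,
    config: TrainConfig | None = None,
) -> TrainHistory:
    """Train the network on tile batches; returns the per-epoch history.

    Deterministic under a fixed ``config.seed`` on fixed hardware/thread
    settings. The epoch with the lowest validation loss is retained and its
    weights restored into ``net`` before returning.
    """
    config = config or TrainConfig()
    if len(train_tiles) == 0:
        raise ValueError("empty training set")
    T = net.spec.tile_size
    for t in train_tiles:
        if t.size != T:
            raise ValueError(
                f"training tile of size {t.size} does not match the "
                f"network tile size {T}"
            )
    logger.info("training: %s, %d train / %d val tiles, seed %d",
                config, len(train_tiles), len(val_tiles), config.seed)
    x_train, y_train = _tiles_to_arrays(train_tiles)
    x_val, y_val = _tiles_to_arrays(val_tiles) if len(val_tiles) else (None, None)
    rng = np.random.default_rng(config.seed)
    opt = make_optimizer(config.optimizer, net.parameters(), config.learning_rate)
    history = TrainHistory()
    best_loss, best_weights = np.inf, None
    n = len(x_train)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            probs = net.forward(xb, training=True)
            loss, grad = binary_cross_entropy(probs, yb)
            opt.zero_grad()
            net.backward(grad)
            opt.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        if x_val is not None:
            val_loss, val_acc = _validate(net, x_val, y_val, config.batch_size)
        else:
            val_loss, val_acc = float("nan"), float("nan")
        history.records.append(
            EpochRecord(epoch, train_loss, val_loss, val_acc)
        )
        logger.info("epoch %d: train loss %.4f, val loss %.4f, val acc %.2f%%",
                    epoch, train_loss, val_loss, val_acc)
        ref = val_loss if x_val is not None else train_loss
        if ref < best_loss:
            best_loss = ref
            best_weights = net.get_weights()
            history.best_epoch = epoch
    if best_weights is not None:
        net.set_weights(best_weights)
    return history


def _validate(net: ModifiedUNet, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> tuple[float, float]:
    """Validation BCE (natural units) and pixel accuracy (percent)."""
    losses, correct, total = [], 0, 0
    for start in range(0, len(x), batch_size):
        xb, yb = x[start : start + batch_size], y[start : start + batch_size]
        probs = net.forward(xb, training=False)
        loss, _ = binary_cross_entropy(probs, yb)
        losses.append(loss * xb.shape[0])
        correct += int(((probs >= 0.5) == (yb >= 0.5)).sum())
        total += yb.size
    return float(np.sum(losses) / len(x)), 100.0 * correct / total


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PixelConfusion:
    """Pixel-wise confusion counts between predicted and true masks."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "PixelConfusion") -> "PixelConfusion":
        return PixelConfusion(self.tp + other.tp, self.fp + other.fp,
                              self.fn + other.fn, self.tn + other.tn)


def confusion(pred: np.ndarray, truth: np.ndarray) -> PixelConfusion:
    """Pixel-wise confusion matrix of a predicted mask against ground truth."""
    p = validate_binary(pred).astype(bool)
    t = validate_binary(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return PixelConfusion(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
        tn=int((~p & ~t).sum()),
    )


@dataclass(frozen=True)
class MetricReport:
    """Accuracy/precision/recall/F1 in percent."""

    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(
            f"{name} has a zero denominator; reporting 0", RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    return num / den


def metrics(cm: PixelConfusion) -> MetricReport:
    """Accuracy, precision, recall and F1 (percent) from a confusion matrix.

    F1 is the harmonic mean of precision and recall, which for binary masks
    equals the Dice coefficient ``2|P∩T| / (|P| + |T|)``. Zero-denominator
    cases report 0 with a warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix (zero pixels)")
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall")
    f1 = _ratio(2 * precision * recall, precision + recall, "f1")
    return MetricReport(100 * accuracy, 100 * precision, 100 * recall, 100 * f1)


def evaluate(
    net: ModifiedUNet,
    tiles: TileSet,
    threshold: float = 0.5,
    batch_size: int = 8,
) -> tuple[pd.DataFrame, MetricReport]:
    """Per-image metric table plus the averaged aggregate report.

    Each tile gets its own confusion matrix and metric row (columns
    image_id, accuracy, precision, recall, f1); the aggregate is the mean of
    the per-image metrics, matching per-image reporting followed by an
    average performance score.
    """
    if len(tiles) == 0:
        raise ValueError("no tiles to evaluate")
    x, y = _tiles_to_arrays(tiles)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for start in range(0, len(x), batch_size):
            probs = net.forward(x[start : start + batch_size], training=False)
            preds = (probs[..., 0] >= threshold).astype(np.uint8)
            for i, pred in enumerate(preds):
                tile = tiles[start + i]
                rep = metrics(confusion(pred, tile.mask))
                rows.append(
                    {"image_id": f"{tile.parent_id}_{tile.origin[0]}_{tile.origin[1]}",
                     **rep.as_dict()}
                )
    table = pd.DataFrame(rows)
    agg = MetricReport(*(float(table[c].mean())
                         for c in ("accuracy", "precision", "recall", "f1")))
    return table, agg


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice coefficient ``2|P∩T| / (|P| + |T|)`` of two binary masks.

    Independent overlap measure; numerically identical to F1/100 on the same
    pair. Returns 0 for two empty masks.
    """
    p = validate_binary(pred).astype(bool)
    t = validate_binary(truth).astype(bool)
    denom = p.sum() + t.sum()
    return 2.0 * (p & t).sum() / denom if denom else 0.0


# ---------------------------------------------------------------------------
# Hyperparameter sweep
# ---------------------------------------------------------------------------

def sweep(
    grid: Sequence[TrainConfig],
    train_tiles: TileSet,
    val_tiles: TileSet,
    net_factory: Callable[[], ModifiedUNet],
) -> pd.DataFrame:
    """Train one fresh network per configuration; tabulate final metrics.

    Returns a table with columns exactly ``optimizer, batch_size, epochs,
    val_loss, val_accuracy`` (one row per configuration), mirroring the
    structure of an optimizer/batch-size/epoch comparison.
    """
    if not grid:
        raise ValueError("empty sweep grid")
    rows = []
    for config in grid:
        net = net_factory()
        history = train(net, train_tiles, val_tiles, config)
        rows.append({
            "optimizer": config.optimizer,
            "batch_size": config.batch_size,
            "epochs": config.epochs,
            "val_loss": history.final.val_loss,
            "val_accuracy": history.final.val_accuracy,
        })
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
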