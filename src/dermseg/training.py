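"""Adam training loop with best-epoch checkpointing, plus evaluation/reporting.

Training follows the protocol of the underlying study: Adam at learning
rate 1e-4 (default moment parameters), batch size 2, combined
(1-alpha)*BCE + alpha*Dice loss on sigmoid probabilities, and per-epoch
validation curves.  "Early stopping" is realised retrospectively: every
epoch's validation metrics are recorded and the returned checkpoint is the
weights at the epoch optimising ``checkpoint_metric`` (min val_loss or max
val_dice) — the practice of saving the best epoch's weights and testing
with them, rather than halting the loop.

The whole loop is deterministic for a fixed seed on one device: data
shuffling, augmentation draws, dropout masks and validation-crop draws all
derive from ``TrainingConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import DermoscopySample
from .errors import ConfigError, DivergenceError, UndefinedMetricError, ValidationError
from .losses import LossWeights, combined_loss_t
from .metrics import accuracy, binarize, confusion_counts, dice_score, iou_score
from .models import SegmentationModel
from .nn.optim import Adam
from .nn.tensor import Tensor
from .preprocess import AugmentPolicy, augment_sample, gray_world_normalize, normalize_for_network

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "EpochRecord",
    "TrainResult",
    "train",
    "evaluate",
    "report",
    "write_history",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-4
    batch_size: int = 2
    epochs: int = 100
    loss_weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    checkpoint_metric: str = "val_loss"
    threshold: float = 0.5
    device: str = "cpu"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigError("batch_size and epochs must be >= 1")
        if self.checkpoint_metric not in ("val_loss", "val_dice"):
            raise ConfigError(
                f"checkpoint_metric must be 'val_loss' or 'val_dice', "
                f"got {self.checkpoint_metric!r}"
            )
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.device != "cpu":
            raise ConfigError("only device='cpu' is supported")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_dice: float
    val_iou: float
    val_accuracy: float


@dataclass
class TrainResult:
    history: list[EpochRecord]
    best_state: dict[str, np.ndarray]
    best_epoch: int
    batch_log: list[dict] = field(default_factory=list)


def _to_batch(samples: list[DermoscopySample]) -> tuple[np.ndarray, np.ndarray]:
    """Normalise and stack samples into (N, 3, H, W) inputs + (N, 1, H, W) targets."""
    shapes = {s.shape for s in samples}
    if len(shapes) != 1:
        raise ValidationError(f"batch mixes image sizes: {sorted(shapes)}")
    xs, ys = [], []
    for s in samples:
        img = normalize_for_network(gray_world_normalize(s.image))
        xs.append(img.transpose(2, 0, 1))
        ys.append(s.mask[None].astype(np.float32))
    return np.stack(xs).astype(np.float32), np.stack(ys)


def _augmented(samples, policy, rng):
    return [augment_sample(s, policy, rng) for s in samples]


def _validation_metrics(model, val_set, policy, cfg, epoch):
    """Eval-mode loss + unweighted-mean metrics on the validation set."""
    val_rng = np.random.default_rng([cfg.seed, 1000 + epoch])  # fixed per-epoch crop
    val_policy = policy.for_validation()
    model.eval()
    losses, dices, ious, accs = [], [], [], []
    for s in val_set:
        s = augment_sample(s, val_policy, val_rng)
        x, y = _to_batch([s])
        probs = model.predict_proba(x)
        losses.append(
            float(combined_loss_t(Tensor(probs), y, cfg.loss_weights).item())
        )
        pred = binarize(probs[0, 0], cfg.threshold)
        try:
            c = confusion_counts(pred, s.mask)
            dices.append(dice_score(c))
            ious.append(iou_score(c))
            accs.append(accuracy(c))
        except UndefinedMetricError:
            logger.warning("skipping %s: both masks empty", s.sample_id)
    model.train()
    return (
        float(np.mean(losses)),
        float(np.mean(dices)) if dices else float("nan"),
        float(np.mean(ious)) if ious else float("nan"),
        float(np.mean(accs)) if accs else float("nan"),
    )


def train(
    model: SegmentationModel,
    train_set: list[DermoscopySample],
    val_set: list[DermoscopySample],
    config: TrainingConfig,
    augment_policy: AugmentPolicy | None = None,
    log_batches: bool = False,
) -> TrainResult:
    """Run the full training loop and return history + best checkpoint."""
    if not train_set or not val_set:
        raise ValidationError("train and validation sets must be non-empty")
    policy = augment_policy if augment_policy is not None else AugmentPolicy()
    rng = np.random.default_rng([config.seed, 7])
    model.set_rng(rng)
    model.train()
    opt = Adam(model.parameters(), lr=config.learning_rate)
    weights = config.loss_weights
    history: list[EpochRecord] = []
    batch_log: list[dict] = []
    best_key = None
    best_state = None
    best_epoch = -1

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_set))
        epoch_loss, n_seen = 0.0, 0
        for b0 in range(0, len(order), config.batch_size):
            idx = order[b0 : b0 + config.batch_size]
            batch = _augmented([train_set[i] for i in idx], policy, rng)
            x, y = _to_batch(batch)
            heads = model.forward_heads(Tensor(x))
            losses = [combined_loss_t(h.sigmoid(), y, weights) for h in heads]
            loss = losses[0]
            for extra in losses[1:]:
                loss = loss + extra
            if len(losses) > 1:
                loss = loss * (1.0 / len(losses))
            lval = loss.item()
            if not np.isfinite(lval):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, batch {b0 // config.batch_size}"
                )
            if log_batches:
                probs = 1.0 / (1.0 + np.exp(-heads[-1].data))
                batch_log.append(
                    {
                        "epoch": epoch,
                        "batch": b0 // config.batch_size,
                        "loss": lval,
                        "n_heads": len(losses),
                        "probs": probs,
                        "targets": y,
                    }
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += lval * len(idx)
            n_seen += len(idx)

        val_loss, val_dice, val_iou, val_acc = _validation_metrics(
            model, val_set, policy, config, epoch
        )
        rec = EpochRecord(
            epoch, epoch_loss / n_seen, val_loss, val_dice, val_iou, val_acc
        )
        history.append(rec)
        logger.info(
            "epoch %d: train_loss=%.4f val_loss=%.4f val_dice=%.4f",
            epoch, rec.train_loss, rec.val_loss, rec.val_dice,
        )
        key = -val_loss if config.checkpoint_metric == "val_loss" else val_dice
        if best_key is None or key > best_key:
            best_key = key
            best_epoch = epoch
            best_state = model.state_dict()

    return TrainResult(history, best_state, best_epoch, batch_log)


def evaluate(
    model: SegmentationModel,
    test_set: list[DermoscopySample],
    threshold: float = 0.5,
    pooled: bool = False,
) -> dict:
    """Per-image Dice/IoU/accuracy and a dataset summary.

    The summary is the unweighted mean of per-image metrics; ``pooled=True``
    instead pools confusion counts over the whole set before computing the
    metrics.  Images where prediction and reference are both empty are
    skipped with a warning.
    """
    if not test_set:
        raise ValidationError("test set is empty")
    h, w = test_set[0].shape
    if h % 32 or w % 32:
        raise ValidationError(
            f"test images are {h}x{w}; resize to multiples of 32 "
            f"(resize_pair) before evaluation"
        )
    rows = []
    pooled_counts = None
    for s in test_set:
        x, _ = _to_batch([s])
        probs = model.predict_proba(x)[0, 0]
        pred = binarize(probs, threshold)
        try:
            c = confusion_counts(pred, s.mask)
            row = {
                "sample_id": s.sample_id,
                "dice": dice_score(c),
                "iou": iou_score(c),
                "accuracy": accuracy(c),
            }
        except UndefinedMetricError:
            logger.warning("skipping %s: both masks empty", s.sample_id)
            continue
        rows.append(row)
        pooled_counts = c if pooled_counts is None else pooled_counts + c
    if not rows:
        raise UndefinedMetricError("no scorable image in the test set")
    if pooled:
        summary = {
            "dice": dice_score(pooled_counts),
            "iou": iou_score(pooled_counts),
            "accuracy": accuracy(pooled_counts),
        }
    else:
        summary = {
            m: float(np.mean([r[m] for r in rows]))
            for m in ("dice", "iou", "accuracy")
        }
    return {"per_image": rows, "summary": summary, "n": len(rows)}


def report(results: dict[str, dict]) -> str:
    """Comparison table: rows = models, columns Dice | Accuracy | IoU.

    The best value in each column is starred; ties are all marked.
    """
    if not results:
        raise ValidationError("report needs at least one evaluation summary")
    cols = ("dice", "accuracy", "iou")
    best = {c: max(r["summary"][c] for r in results.values()) for c in cols}
    name_w = max(len("Method"), *(len(n) for n in results))
    lines = [f"{'Method':<{name_w}}  {'Dice':>9}  {'Accuracy':>9}  {'IoU':>9}"]
    for name, res in results.items():
        cells = []
        for c in cols:
            v = res["summary"][c]
            mark = "*" if v == best[c] else " "
            cells.append(f"{v:.4f}{mark}".rjust(9))
        lines.append(f"{name:<{name_w}}  " + "  ".join(cells))
    return "\n".join(lines)


def write_history(history: list[EpochRecord], path: str | Path) -> None:
    """Per-epoch curves (the loss/Dice trend data) as delimited text."""
    with Path(path).open("w") as fh:
        fh.write("epoch\ttrain_loss\tval_loss\tval_dice\tval_iou\tval_accuracy\n")
        for r in history:
            fh.write(
                f"{r.epoch}\t{r.train_loss:.6f}\t{r.val_loss:.6f}"
                f"\t{r.val_dice:.6f}\t{r.val_iou:.6f}\t{r.val_accuracy:.6f}\n"
            )


def save_checkpoint(result: TrainResult, path: str | Path) -> None:
    np.savez(
        Path(path),
        __best_epoch__=np.array(result.best_epoch),
        **result.best_state,
    )


def load_checkpoint(model: SegmentationModel, path: str | Path) -> int:
    """Load a saved best-epoch state into ``model``; returns the epoch index."""
    with np.load(Path(path)) as data:
        state = {k: data[k] for k in data.files if k != "__best_epoch__"}
        model.load_state_dict(state)
        return int(data["__best_epoch__"])
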