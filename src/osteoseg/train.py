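"""Loss, training loop and evaluation.

The loss combines three terms,

    L = l_dice * soft-Dice(mask) + l_bce * BCE(mask) + l_edge * BCE(edge),

with default weights (1, 1, 0.5): the Dice term directly optimizes the
overlap score the method is judged by, binary cross-entropy stabilizes the
early phase when predictions are diffuse, and the edge term supervises the
gated shape stream with the morphological boundary of the reference mask.

Training uses Adam (learning rate 1e-4, 200 epochs at full scale by
default), keeps a per-epoch history of loss and validation metrics, and
retains the parameters of the epoch with the best validation mean DSC.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .metrics import metrics_from_masks, metrics_table
from .model import SegmentationNet
from .nn import Adam, bce_with_logits, sigmoid
from .shape_stream import boundary_target

__all__ = ["TrainConfig", "segmentation_loss", "train_model",
           "evaluate_model", "soft_dice_loss"]

logger = logging.getLogger("osteoseg.train")


@dataclass
class TrainConfig:
    """Optimization settings.

    ``max_steps`` caps the total number of optimizer steps (``None`` trains
    the full ``epochs``); useful for desk-scale runs.
    """

    lr: float = 1e-4
    epochs: int = 200
    batch_size: int = 8
    seed: int = 0
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 0.5)
    optimizer: str = "adam"
    max_steps: int | None = None
    eval_every: int = 1          # epochs between validation passes

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer: {self.optimizer!r}")


def soft_dice_loss(mask_logits, target) -> nn.Tensor:
    """1 - soft Dice between sigmoid probabilities and a binary target."""
    p = sigmoid(mask_logits)
    t = np.asarray(target, dtype=p.data.dtype)
    inter = (p * t).sum()
    denom = p.sum() + float(t.sum())
    eps = 1.0
    return 1.0 - (inter * 2.0 + eps) / (denom + eps)


def segmentation_loss(output, mask, edge_target=None,
                      weights=(1.0, 1.0, 0.5)) -> nn.Tensor:
    """Weighted Dice + BCE + edge-BCE loss for one batch.

    ``output`` is a :class:`~osteoseg.model.SegOutput`; ``mask`` and
    ``edge_target`` are binary arrays shaped like its logits.
    """
    l_dice, l_bce, l_edge = weights
    mask = np.asarray(mask)
    if mask.ndim == 3:
        mask = mask[..., None]
    if mask.shape != tuple(output.mask_logits.shape):
        raise ValueError(
            f"mask shape {mask.shape} does not match logits "
            f"{tuple(output.mask_logits.shape)}")
    loss = nn.Tensor(np.zeros(()))
    if l_dice:
        loss = loss + soft_dice_loss(output.mask_logits, mask) * l_dice
    if l_bce:
        loss = loss + bce_with_logits(output.mask_logits, mask).mean() * l_bce
    if l_edge and output.edge_logits is not None:
        if edge_target is None:
            raise ValueError("edge supervision requested but no edge target given")
        et = np.asarray(edge_target)
        if et.ndim == 3:
            et = et[..., None]
        loss = loss + bce_with_logits(output.edge_logits, et).mean() * l_edge
    return loss


def _stack(samples):
    images = np.stack([np.asarray(s.image, dtype=np.float32) for s in samples])
    masks = np.stack([np.asarray(s.mask, dtype=np.float32) for s in samples])
    return images, masks


def train_model(model: SegmentationNet, train_samples, val_samples,
                config: TrainConfig | None = None):
    """Train ``model``; returns ``(model, history)``.

    ``train_samples`` / ``val_samples`` are sequences of objects with
    ``.image`` and ``.mask`` array attributes (e.g.
    :class:`~osteoseg.phantom.Sample`).  The model is left holding the
    parameters of the epoch with the best validation mean DSC.
    """
    cfg = config if config is not None else TrainConfig()
    if len(train_samples) == 0:
        raise ValueError("empty training partition")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    weights = cfg.loss_weights
    needs_edges = model.config.shape_flow_enabled and weights[2] != 0

    history: list[dict] = []
    best_dsc = -1.0
    best_state = model.state_dict()
    step = 0
    n = len(train_samples)
    done = False
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            batch = [train_samples[i] for i in order[start:start + cfg.batch_size]]
            images, masks = _stack(batch)
            edges = boundary_target(masks) if needs_edges else None
            out = model(images)
            loss = segmentation_loss(out, masks, edges, weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                done = True
                break
        record = {"epoch": epoch + 1, "step": step,
                  "train_loss": float(np.mean(epoch_losses))}
        if len(val_samples) and ((epoch + 1) % cfg.eval_every == 0 or done
                                 or epoch + 1 == cfg.epochs):
            val_dsc = _mean_dsc(model, val_samples)
            record["val_dsc"] = val_dsc
            if val_dsc >= best_dsc:
                best_dsc = val_dsc
                best_state = model.state_dict()
        history.append(record)
        logger.info("epoch %d step %d loss %.4f val_dsc %s",
                    epoch + 1, step, record["train_loss"],
                    record.get("val_dsc"))
        if done:
            break
    if len(val_samples):
        model.load_state_dict(best_state)
    return model, pd.DataFrame.from_records(history)


def _mean_dsc(model: SegmentationNet, samples, batch_size: int = 4) -> float:
    images, masks = _stack(samples)
    preds = model.predict(images, batch_size=batch_size)
    scores = [metrics_from_masks(p, m).dsc for p, m in zip(preds, masks)]
    return float(np.mean(scores))


def evaluate_model(model: SegmentationNet, samples,
                   batch_size: int = 4) -> pd.DataFrame:
    """Per-sample metric table (with mean and pooled footers)."""
    images, masks = _stack(samples)
    preds = model.predict(images, batch_size=batch_size)
    names = [getattr(s, "slice_id", str(i)) for i, s in enumerate(samples)]
    rows = [(name, metrics_from_masks(p, m))
            for name, p, m in zip(names, preds, masks)]
    return metrics_table(rows)


def setup_logging(logfile=None) -> None:
    """Log per-epoch progress to stderr and optionally a file."""
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=logging.INFO, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(message)s")
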