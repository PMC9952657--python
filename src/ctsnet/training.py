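"""Training loop, polynomial learning-rate schedule, and k-fold protocol.

The optimiser is SGD (momentum 0.9, weight decay 1e-4) under the
polynomial decay

    lr(it) = lr0 * (1 - it / it_max) ** power      (lr0 = 0.05, power = 0.95)

with it_max = epochs * iterations-per-epoch.  Batches default to 4 tiles
(the four squares of one pre-processed scan).  Cross-validation splits
the training set into k disjoint folds, trains one model per fold on the
remainder, and evaluates every model on the same fixed test set.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .boundaries import SGFilterSpec, mask_to_boundaries, smooth_boundaries
from .geometry import augment as _augment
from .losses import LossSpec, combined_loss, one_hot
from .metrics import MetricsReport, evaluate
from .network import CTSNet, NetworkSpec, predict_mask
from .nn import SGD
from .tensor import softmax

log = logging.getLogger(__name__)

__all__ = ["TrainSpec", "lr_schedule", "train", "kfold_split", "cross_validate"]


@dataclass
class TrainSpec:
    epochs: int = 150
    batch: int = 4
    lr0: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-4
    power: float = 0.95
    seed: int = 0
    loss: LossSpec = field(default_factory=LossSpec)
    train_n: int = 80
    test_n: int = 20
    folds: int = 5
    augment: bool = False
    max_rotation: float = 10.0
    aux_weight: float = 0.4

    def __post_init__(self):
        for name in ("epochs", "batch", "lr0", "momentum", "power"):
            if getattr(self, name) <= 0 and name not in ("momentum",):
                raise ValueError(f"{name} must be positive")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")


def lr_schedule(it: int, it_max: int, lr0: float = 0.05, power: float = 0.95) -> float:
    """Polynomial decay from lr0 at it=0 to 0 at it=it_max."""
    if it_max <= 0:
        raise ValueError(f"it_max must be positive, got {it_max}")
    if not 0 <= it <= it_max:
        raise ValueError(f"iteration {it} outside [0, {it_max}]")
    return lr0 * (1.0 - it / it_max) ** power


def train(data: list[tuple[np.ndarray, np.ndarray]], spec: TrainSpec,
          net: CTSNet | NetworkSpec | None = None,
          max_iterations: int | None = None,
          log_path: str | Path | None = None) -> tuple[CTSNet, list[dict]]:
    """Optimise the combined Dice + BADice objective with scheduled SGD.

    ``data`` is a list of (image, mask) pairs of network-ready square
    rasters.  Returns the trained model and a per-iteration history of
    loss and learning rate; ``max_iterations`` (if given) caps it_max and
    stops there, which the desk-scale experiments use.  Fully
    deterministic for a fixed spec seed.
    """
    if not data:
        raise ValueError("empty training dataset")
    if isinstance(net, CTSNet):
        model = net
    else:
        model = CTSNet(net if isinstance(net, NetworkSpec) else NetworkSpec(),
                       seed=spec.seed)
    n_classes = model.spec.n_classes
    rng = np.random.default_rng(spec.seed)
    per_epoch = math.ceil(len(data) / spec.batch)
    it_max = spec.epochs * per_epoch
    if max_iterations is not None:
        it_max = min(it_max, max_iterations)
    opt = SGD(model.parameters(), lr=spec.lr0, momentum=spec.momentum,
              weight_decay=spec.weight_decay)
    history: list[dict] = []
    it = 0
    writer = open(log_path, "w") if log_path is not None else None
    try:
        for epoch in range(spec.epochs):
            order = rng.permutation(len(data))
            for start in range(0, len(data), spec.batch):
                if it >= it_max:
                    return model, history
                idx = order[start:start + spec.batch]
                imgs, masks = [], []
                for i in idx:
                    img, msk = data[i]
                    if spec.augment:
                        img, msk = _augment(img, msk, rng, spec.max_rotation)
                    imgs.append(img)
                    masks.append(msk)
                batch_x = np.stack(imgs)
                batch_g = one_hot(np.stack(masks), n_classes)
                maps = model(batch_x)
                probs = softmax(maps.logits, axis=1)
                loss = combined_loss(probs, batch_g, spec.loss)
                if model.spec.aux_supervision and spec.aux_weight > 0:
                    # deep supervision: the same objective against the
                    # nearest-subsampled truth at each auxiliary scale
                    full = batch_g.shape[-1]
                    for aux in maps.aux:
                        step = full // aux.shape[-1]
                        aux_g = batch_g[..., ::step, ::step]
                        aux_p = softmax(aux, axis=1)
                        loss = loss + spec.aux_weight * combined_loss(aux_p, aux_g, spec.loss)
                value = loss.item()
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"non-finite loss {value} at iteration {it} (epoch {epoch}); "
                        "lower lr0 or inspect the input scaling"
                    )
                opt.zero_grad()
                loss.backward()
                opt.lr = lr_schedule(it, it_max, spec.lr0, spec.power)
                opt.step()
                record = {"it": it, "epoch": epoch, "lr": opt.lr, "loss": value}
                history.append(record)
                if writer is not None:
                    writer.write(json.dumps(record) + "\n")
                it += 1
        return model, history
    finally:
        if writer is not None:
            writer.close()


def kfold_split(n: int, k: int, fold: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint near-equal validation folds covering range(n) exactly once.

    Returns (train_indices, val_indices) for the given fold; across the k
    folds the validation sets partition the dataset.
    """
    if k > n:
        raise ValueError(f"cannot split {n} items into {k} folds")
    if not 0 <= fold < k:
        raise ValueError(f"fold {fold} outside [0, {k})")
    perm = np.random.default_rng(seed).permutation(n)
    chunks = np.array_split(perm, k)
    val = np.sort(chunks[fold])
    train_idx = np.sort(np.concatenate([c for i, c in enumerate(chunks) if i != fold]))
    return train_idx, val


def _boundaries_from_mask(mask: np.ndarray, sg: SGFilterSpec | None):
    bset = mask_to_boundaries(mask, repair=True)
    return smooth_boundaries(bset, sg) if sg is not None else bset


def cross_validate(train_data: list[tuple[np.ndarray, np.ndarray]],
                   test_data: list[tuple[np.ndarray, np.ndarray]],
                   spec: TrainSpec,
                   net_spec: NetworkSpec | None = None,
                   k: int | None = None,
                   max_iterations: int | None = None,
                   sg: SGFilterSpec | None = None
                   ) -> tuple[list[MetricsReport], pd.DataFrame]:
    """k-fold cross-validation with a fixed test set.

    For each fold, a fresh model is trained on the non-validation part of
    the training set and evaluated on ``test_data``; returns the per-fold
    reports plus a summary table with the mean and the max-min range of
    the Overall MAD / RMSE / DSC across folds.
    """
    k = k or spec.folds
    net_spec = net_spec or NetworkSpec()
    gts = [(mask, _boundaries_from_mask(mask, None)) for _, mask in test_data]
    reports = []
    for fold in range(k):
        tr_idx, _val_idx = kfold_split(len(train_data), k, fold, spec.seed)
        subset = [train_data[i] for i in tr_idx]
        model, _ = train(subset, spec, net_spec, max_iterations=max_iterations)
        preds = []
        for img, _ in test_data:
            mask = predict_mask(model(img[None]))[0]
            preds.append((mask, _boundaries_from_mask(mask, sg)))
        reports.append(evaluate(preds, gts))
        log.info("fold %d/%d: overall MAD %.3f px, DSC %.2f%%",
                 fold + 1, k, reports[-1].overall_mad, reports[-1].overall_dsc)
    rows = {
        "overall_mad": [r.overall_mad for r in reports],
        "overall_rmse": [r.overall_rmse for r in reports],
        "overall_dsc": [r.overall_dsc for r in reports],
    }
    summary = pd.DataFrame(
        {name: {"mean": float(np.mean(v)), "range": float(np.max(v) - np.min(v))}
         for name, v in rows.items()}
    ).T
    return reports, summary
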