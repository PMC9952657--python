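"""Boundary-distance and overlap metrics.

Per boundary: mean absolute distance (MAD) and root-mean-square error
(RMSE) between predicted and true per-column row positions, in pixels.
Per layer: Dice-similarity coefficient (DSC) in percent on the three
annotated layer classes (RNFL, GCIPL, CL).  ``evaluate`` aggregates a
test set into mean(Std) tables with an Overall row (mean of the
constituent rows; Std is the population standard deviation across
images).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .boundaries import BOUNDARY_NAMES, BoundarySet
from .geometry import LAYER_CLASSES

__all__ = ["mad", "rmse", "dsc", "evaluate", "MetricsReport"]


def _check_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError(f"trace length mismatch: {pred.shape} vs {gt.shape}")
    return pred, gt


def mad(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean absolute columnwise distance between two boundary traces."""
    pred, gt = _check_pair(pred, gt)
    return float(np.mean(np.abs(pred - gt)))


def rmse(pred: np.ndarray, gt: np.ndarray) -> float:
    """Root-mean-square columnwise distance between two boundary traces."""
    pred, gt = _check_pair(pred, gt)
    return float(np.sqrt(np.mean((pred - gt) ** 2)))


def dsc(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice-similarity coefficient of two binary rasters, in percent.

    Two empty rasters are in perfect agreement (100%)."""
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    denom = pred.sum() + gt.sum()
    if denom == 0:
        return 100.0
    return float(200.0 * np.logical_and(pred, gt).sum() / denom)


@dataclass
class MetricsReport:
    """Aggregated test metrics.

    ``boundary_table``: rows = boundaries + Overall, columns = mad_mean,
    mad_std, rmse_mean, rmse_std (pixels).  ``layer_table``: rows =
    layers + Overall, columns = dsc_mean, dsc_std (percent).
    """

    boundary_table: pd.DataFrame
    layer_table: pd.DataFrame
    n_images: int

    @property
    def overall_mad(self) -> float:
        return float(self.boundary_table.loc["Overall", "mad_mean"])

    @property
    def overall_rmse(self) -> float:
        return float(self.boundary_table.loc["Overall", "rmse_mean"])

    @property
    def overall_dsc(self) -> float:
        return float(self.layer_table.loc["Overall", "dsc_mean"])

    def to_csv(self, path: str | Path) -> None:
        combined = pd.concat(
            [self.boundary_table.assign(kind="boundary"),
             self.layer_table.assign(kind="layer")]
        )
        combined.index.name = "name"
        combined.to_csv(path)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "n_images": self.n_images,
            "boundaries": self.boundary_table.to_dict(orient="index"),
            "layers": self.layer_table.to_dict(orient="index"),
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def evaluate(preds: list[tuple[np.ndarray, BoundarySet]],
             gts: list[tuple[np.ndarray, BoundarySet]],
             layers: dict[str, int] | None = None) -> MetricsReport:
    """Aggregate per-image metrics over a paired test set.

    ``preds`` and ``gts`` are equal-length lists of (class mask,
    boundary set).  Per image and boundary, MAD and RMSE are computed
    columnwise; per image and layer class, DSC.  Means and population
    standard deviations are taken across images, and the Overall row is
    the mean of the per-boundary (per-layer) rows.
    """
    if len(preds) != len(gts):
        raise ValueError(f"unpaired inputs: {len(preds)} predictions vs {len(gts)} truths")
    if not preds:
        raise ValueError("nothing to evaluate")
    layers = layers if layers is not None else LAYER_CLASSES

    mad_per = {b: [] for b in BOUNDARY_NAMES}
    rmse_per = {b: [] for b in BOUNDARY_NAMES}
    dsc_per = {l: [] for l in layers}
    for (pmask, pbound), (gmask, gbound) in zip(preds, gts):
        for b in BOUNDARY_NAMES:
            mad_per[b].append(mad(pbound.traces[b], gbound.traces[b]))
            rmse_per[b].append(rmse(pbound.traces[b], gbound.traces[b]))
        for lname, cls in layers.items():
            dsc_per[lname].append(dsc(np.asarray(pmask) == cls, np.asarray(gmask) == cls))

    brows = {}
    for b in BOUNDARY_NAMES:
        brows[b] = {
            "mad_mean": float(np.mean(mad_per[b])),
            "mad_std": float(np.std(mad_per[b])),
            "rmse_mean": float(np.mean(rmse_per[b])),
            "rmse_std": float(np.std(rmse_per[b])),
        }
    btable = pd.DataFrame.from_dict(brows, orient="index")
    btable.loc["Overall"] = btable.mean()

    lrows = {
        lname: {"dsc_mean": float(np.mean(vals)), "dsc_std": float(np.std(vals))}
        for lname, vals in dsc_per.items()
    }
    ltable = pd.DataFrame.from_dict(lrows, orient="index")
    ltable.loc["Overall"] = ltable.mean()

    return MetricsReport(boundary_table=btable, layer_table=ltable, n_images=len(preds))
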