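"""Stage implementations behind the command-line interface.

Each stage reads the previous stage's directory layout:

    synth       -> DATA/images/*.png, DATA/masks/*.png, DATA/boundaries/*.csv
    preprocess  -> network-ready square tiles in the same layout
    train       -> OUT/checkpoint.npz, OUT/history.jsonl
    predict     -> OUT/pred_masks/*.png, OUT/pred_probs/*.tiff,
                   OUT/pred_boundaries/*.csv
    evaluate    -> OUT/report.csv / report.json
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io
from .boundaries import BoundarySet, SGFilterSpec, mask_to_boundaries, smooth_boundaries
from .config import RunConfig
from .geometry import crop_and_resize, restore_geometry, stitch, tile
from .losses import one_hot  # noqa: F401  (re-exported for scripting convenience)
from .metrics import MetricsReport, evaluate
from .network import CTSNet, predict_mask
from .phantoms import PhantomSpec, generate_dataset, raw_scan_spec
from .tensor import softmax
from .training import cross_validate, train

log = logging.getLogger(__name__)


def _pairs(data_dir: Path) -> list[str]:
    stems = sorted(p.stem for p in (data_dir / "images").glob("*.png"))
    if not stems:
        raise FileNotFoundError(f"no images under {data_dir / 'images'}")
    return stems


def run_synth(n: int, seed: int, out: Path, spec: PhantomSpec | None = None,
              raw: bool = False) -> list[str]:
    spec = spec or (raw_scan_spec() if raw else PhantomSpec())
    samples = generate_dataset(n, spec, seed)
    for sub in ("images", "masks", "boundaries"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    names = []
    for i, s in enumerate(samples):
        name = f"phantom_{i:04d}"
        io.write_image(out / "images" / f"{name}.png", s.image)
        io.write_mask(out / "masks" / f"{name}.png", s.mask)
        s.boundaries.to_csv(out / "boundaries" / f"{name}.csv")
        names.append(name)
    return names


def run_preprocess(cfg: RunConfig, in_dir: Path, out: Path) -> list[str]:
    geom = cfg.geometry
    for sub in ("images", "masks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    written = []
    for stem in _pairs(in_dir):
        img = crop_and_resize(io.read_image(in_dir / "images" / f"{stem}.png"), geom, order=1)
        msk = crop_and_resize(io.read_mask(in_dir / "masks" / f"{stem}.png"), geom, order=0)
        for k, (ti, tm) in enumerate(zip(tile(img, geom), tile(msk, geom))):
            name = f"{stem}_t{k}"
            io.write_image(out / "images" / f"{name}.png", ti)
            io.write_mask(out / "masks" / f"{name}.png", tm)
            written.append(name)
    return written


def _load_pairs(data_dir: Path) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(io.read_image(data_dir / "images" / f"{s}.png"),
             io.read_mask(data_dir / "masks" / f"{s}.png"))
            for s in _pairs(data_dir)]


def run_train(cfg: RunConfig, data_dir: Path, out: Path,
              max_iterations: int | None = None) -> Path:
    out.mkdir(parents=True, exist_ok=True)
    data = _load_pairs(data_dir)
    model, _ = train(data, cfg.train, cfg.net, max_iterations=max_iterations,
                     log_path=out / "history.jsonl")
    ckpt = out / "checkpoint.npz"
    model.save(ckpt)
    return ckpt


def run_predict(ckpt: Path, data_dir: Path, out: Path,
                sg: SGFilterSpec | None = None) -> list[str]:
    model = CTSNet.load(ckpt)
    for sub in ("pred_masks", "pred_probs", "pred_boundaries"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    names = []
    for stem in _pairs(data_dir):
        img = io.read_image(data_dir / "images" / f"{stem}.png")
        maps = model(img[None])
        probs = softmax(maps.logits, axis=1).data[0]
        mask = predict_mask(maps)[0]
        io.write_mask(out / "pred_masks" / f"{stem}.png", mask)
        io.write_probability_maps(out / "pred_probs" / f"{stem}.tiff", probs)
        bset = smooth_boundaries(mask_to_boundaries(mask, repair=True), sg)
        bset.to_csv(out / "pred_boundaries" / f"{stem}.csv")
        names.append(stem)
    return names


def run_evaluate(pred_dir: Path, gt_dir: Path, out: Path) -> MetricsReport:
    stems = sorted(p.stem for p in (pred_dir / "pred_masks").glob("*.png"))
    if not stems:
        raise FileNotFoundError(f"no predictions under {pred_dir / 'pred_masks'}")
    preds, gts = [], []
    for stem in stems:
        preds.append((io.read_mask(pred_dir / "pred_masks" / f"{stem}.png"),
                      BoundarySet.from_csv(pred_dir / "pred_boundaries" / f"{stem}.csv")))
        gts.append((io.read_mask(gt_dir / "masks" / f"{stem}.png"),
                    BoundarySet.from_csv(gt_dir / "boundaries" / f"{stem}.csv")))
    report = evaluate(preds, gts)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "report.csv")
    report.to_json(out / "report.json")
    return report


def run_crossval(cfg: RunConfig, data_dir: Path, out: Path, k: int | None = None,
                 max_iterations: int | None = None):
    data = _load_pairs(data_dir)
    n_test = min(cfg.train.test_n, max(1, len(data) // 5))
    test_data, train_data = data[:n_test], data[n_test:]
    reports, summary = cross_validate(train_data, test_data, cfg.train, cfg.net,
                                      k=k, max_iterations=max_iterations)
    out.mkdir(parents=True, exist_ok=True)
    for i, r in enumerate(reports):
        r.to_csv(out / f"fold_{i}.csv")
    summary.to_csv(out / "crossval_summary.csv")
    return reports, summary
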