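"""YAML run configuration with a strict schema.

Every section maps onto one of the package's spec dataclasses; unknown
keys raise immediately so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import GeometrySpec
from .losses import LossSpec
from .network import NetworkSpec
from .phantoms import PhantomSpec
from .training import TrainSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class Paths:
    data_dir: str = "data"
    out_dir: str = "runs"


@dataclass
class RunConfig:
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    net: NetworkSpec = field(default_factory=NetworkSpec)
    loss: LossSpec = field(default_factory=LossSpec)
    train: TrainSpec = field(default_factory=TrainSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    paths: Paths = field(default_factory=Paths)
    seed: int = 0

    def __post_init__(self):
        # single seed propagated to every stage unless a stage overrides it
        self.train.seed = self.train.seed or self.seed
        self.train.loss = self.loss


_TUPLE_FIELDS = {"depths", "dec_depths", "heads", "stripe_widths",
                 "mean_depths", "layer_intensities"}


def _build(cls, payload: dict, where: str):
    if not isinstance(payload, dict):
        raise ValueError(f"config section '{where}' must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown keys in config section '{where}': {sorted(unknown)}")
    kwargs = {k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
              for k, v in payload.items()}
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    payload: dict = {}
    if path is not None:
        payload = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        payload.update(overrides)
    sections = {
        "geometry": GeometrySpec,
        "net": NetworkSpec,
        "loss": LossSpec,
        "train": TrainSpec,
        "phantom": PhantomSpec,
        "paths": Paths,
    }
    unknown = set(payload) - set(sections) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in sections.items():
        if name in payload:
            sub = dict(payload[name] or {})
            if name == "train" and "loss" in sub:
                sub["loss"] = _build(LossSpec, sub["loss"], "train.loss")
            kwargs[name] = _build(cls, sub, name)
    if "seed" in payload:
        kwargs["seed"] = int(payload["seed"])
    return RunConfig(**kwargs)
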