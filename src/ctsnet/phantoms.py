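"""Synthetic layered B-scan phantoms with known boundary ground truth.

Each phantom has five smooth, strictly ordered boundary curves (ILM,
RNFL-GCIPL, GCIPL-INL, BM, CS), a 6-class mask rasterised from them, and
an intensity image built from per-class mean grey levels under
multiplicative speckle-like noise.  A ``thinning`` factor < 1 shrinks the
RNFL (the glaucoma signature) by moving the RNFL-GCIPL boundary toward
the ILM.

Default geometry is the post-preprocessing 256 x 1024 raster; a "raw"
800 x 1000 spec (boundaries inside the standard crop band) exercises the
crop/resize path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .boundaries import BOUNDARY_NAMES, BoundarySet
from .geometry import labels_to_classes

__all__ = ["PhantomSpec", "PhantomSample", "generate_phantom", "generate_dataset",
           "raw_scan_spec"]

#: mean grey levels per class: vitreous, RNFL, GCIPL, remaining retina,
#: choroid, sclera — bright nerve-fibre and choroid bands over a dark
#: background, as in a typical B-scan.
_DEFAULT_INTENSITIES = (0.05, 0.60, 0.30, 0.45, 0.65, 0.15)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic B-scan.

    mean_depths: mean row of each of the five boundaries (strictly
    increasing); amplitude: peak boundary undulation in pixels;
    smoothness: Gaussian smoothing scale (columns) of the underlying
    noise, i.e. the low-frequency cutoff of the curves; layer_intensities:
    six per-class mean grey levels in [0, 1]; speckle_sigma: relative
    standard deviation of the multiplicative noise; thinning: RNFL
    thickness scale in (0, 1]; seed: RNG seed.
    """

    h: int = 256
    w: int = 1024
    mean_depths: tuple = (56, 108, 148, 196, 228)
    amplitude: float = 8.0
    smoothness: float = 40.0
    layer_intensities: tuple = _DEFAULT_INTENSITIES
    speckle_sigma: float = 0.12
    thinning: float = 1.0
    seed: int = 0

    def __post_init__(self):
        depths = np.asarray(self.mean_depths, float)
        if len(depths) != 5 or not np.all(np.diff(depths) > 0):
            raise ValueError(f"mean_depths must be 5 strictly increasing rows, got {self.mean_depths}")
        if not (0.0 < self.thinning <= 1.0):
            raise ValueError(f"thinning must be in (0, 1], got {self.thinning}")
        if len(self.layer_intensities) != 6:
            raise ValueError("layer_intensities must list 6 grey levels")


@dataclass
class PhantomSample:
    image: np.ndarray
    boundaries: BoundarySet
    mask: np.ndarray
    thinning: float = 1.0


def raw_scan_spec(**overrides) -> PhantomSpec:
    """An 800x1000 'raw scan' spec with boundaries inside the crop band."""
    defaults = dict(h=800, w=1000, mean_depths=(180, 290, 370, 470, 540), amplitude=16.0)
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def _smooth_curve(rng: np.random.Generator, w: int, smoothness: float,
                  amplitude: float) -> np.ndarray:
    """Band-limited random undulation: cumulative sum of smoothed noise,
    centred and scaled to peak ``amplitude`` pixels."""
    if amplitude == 0:
        return np.zeros(w)
    walk = np.cumsum(gaussian_filter1d(rng.standard_normal(w), smoothness, mode="reflect"))
    walk -= walk.mean()
    peak = np.abs(walk).max()
    if peak > 0:
        walk *= amplitude / peak
    return walk


def generate_phantom(spec: PhantomSpec, seed: int | None = None
                     ) -> tuple[np.ndarray, BoundarySet, np.ndarray]:
    """Generate one phantom: (image, boundaries, mask), deterministic per seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    depths = np.asarray(spec.mean_depths, float)
    traces = np.stack([
        depths[j] + _smooth_curve(rng, spec.w, spec.smoothness, spec.amplitude)
        for j in range(5)
    ])
    # glaucoma mode: shrink the RNFL band toward the ILM
    traces[1] = traces[0] + spec.thinning * (traces[1] - traces[0])
    # enforce ordering and the raster bounds without reordering layers
    traces = np.maximum.accumulate(traces, axis=0)
    traces = np.clip(traces, 0, spec.h - 1)
    traces = np.maximum.accumulate(traces, axis=0)
    bset = BoundarySet.from_array(traces)
    mask = labels_to_classes(bset, spec.h, spec.w)
    levels = np.asarray(spec.layer_intensities, float)
    image = levels[mask]
    if spec.speckle_sigma > 0:
        image = image * (1.0 + spec.speckle_sigma * rng.standard_normal(image.shape))
    return np.clip(image, 0.0, 1.0), bset, mask


def generate_dataset(n: int, spec: PhantomSpec | None = None, seed: int = 0,
                     glaucoma_fraction: float = 0.5,
                     glaucoma_thinning: float = 0.6) -> list[PhantomSample]:
    """Generate ``n`` independent phantoms with reproducible per-item seeds.

    The last ``glaucoma_fraction`` of the items are generated with the
    RNFL thinned by ``glaucoma_thinning`` (a glaucoma-like cohort); the
    rest use the spec's own thinning (default 1.0, healthy).
    """
    spec = spec or PhantomSpec()
    children = np.random.SeedSequence(seed).spawn(n)
    samples = []
    n_healthy = n - int(round(n * glaucoma_fraction))
    for i in range(n):
        item_spec = spec if i < n_healthy else replace(spec, thinning=glaucoma_thinning)
        img, bset, mask = generate_phantom(item_spec, seed=children[i])
        samples.append(PhantomSample(img, bset, mask,
                                     thinning=item_spec.thinning))
    return samples
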