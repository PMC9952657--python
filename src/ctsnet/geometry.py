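"""Geometric pre/post-processing of B-scans.

The raw scans are tall rasters (rows = axial depth, columns = lateral
position).  Training geometry: crop the axial band containing the retina
(rows [crop_start, crop_stop), default [63, 613) — 550 rows), resample to
``target_h x target_w`` (default 256 x 1024), and cut into square tiles
(default four 256 x 256 tiles).  ``restore_geometry`` inverts the crop and
resample so predictions come back in original-image pixel coordinates.

Intensity rasters are plain 2-D float arrays; label masks are 2-D integer
arrays over six classes ordered top-to-bottom: 0 above the ILM, 1 RNFL,
2 GCIPL, 3 remaining retina (GCIPL-INL to BM), 4 choroid (CL), 5 below
the choroid–sclera interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .boundaries import BOUNDARY_NAMES, N_BOUNDARIES, BoundarySet

N_CLASSES = 6
#: classes carrying a named retinal layer, as annotated in the source data
LAYER_CLASSES = {"RNFL": 1, "GCIPL": 2, "CL": 4}


class GeometryError(ValueError):
    """Raised when an image does not fit the requested crop/tiling."""


@dataclass
class GeometrySpec:
    """Axial crop window and target raster geometry.

    Defaults follow the 800x1000 circumpapillary-scan layout: the crop
    keeps rows [63, 613) (550 rows covering all retinal layers), resampled
    to 256 rows; the width is resampled to 1024 and tiled into 256-wide
    squares.
    """

    crop_start: int = 63
    crop_stop: int = 613
    target_h: int = 256
    target_w: int = 1024
    tile: int = 256

    def __post_init__(self):
        if self.crop_stop <= self.crop_start:
            raise ValueError("crop_stop must exceed crop_start")
        if self.target_w % self.tile != 0:
            raise ValueError(f"target_w ({self.target_w}) must be divisible by tile ({self.tile})")
        if self.target_h != self.tile:
            raise ValueError(f"target_h ({self.target_h}) must equal tile ({self.tile})")

    @property
    def n_tiles(self) -> int:
        return self.target_w // self.tile


def _resize(img: np.ndarray, shape: tuple[int, int], order: int) -> np.ndarray:
    """Separable resample with half-pixel centre alignment and edge clamp."""
    if img.shape == shape:
        return img.astype(float if order else img.dtype, copy=True)
    out = _sk_resize(img.astype(float), shape, order=order, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    if order == 0:
        return np.rint(out).astype(img.dtype)
    return out


def crop_and_resize(img: np.ndarray, spec: GeometrySpec, order: int = 1) -> np.ndarray:
    """Crop rows [crop_start, crop_stop) then resample to target size.

    ``order=1`` (bilinear) for intensity rasters, ``order=0`` (nearest)
    for label masks.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise GeometryError(f"expected a 2-D raster, got shape {img.shape}")
    if img.shape[0] < spec.crop_stop:
        raise GeometryError(
            f"image has {img.shape[0]} rows; crop window needs at least {spec.crop_stop}"
        )
    band = img[spec.crop_start:spec.crop_stop]
    return _resize(band, (spec.target_h, spec.target_w), order)


def tile(img: np.ndarray, spec: GeometrySpec) -> list[np.ndarray]:
    """Cut a target_h x target_w raster into square tiles, left to right."""
    img = np.asarray(img)
    if img.shape != (spec.target_h, spec.target_w):
        raise GeometryError(
            f"expected {spec.target_h}x{spec.target_w} raster, got {img.shape}"
        )
    return [img[:, k * spec.tile:(k + 1) * spec.tile].copy() for k in range(spec.n_tiles)]


def stitch(tiles: list[np.ndarray]) -> np.ndarray:
    """Horizontally concatenate equal-height square tiles (inverse of tile)."""
    if not tiles:
        raise GeometryError("no tiles to stitch")
    shapes = {t.shape for t in map(np.asarray, tiles)}
    if len(shapes) != 1:
        raise GeometryError(f"tile shapes differ: {shapes}")
    return np.concatenate([np.asarray(t) for t in tiles], axis=1)


def restore_geometry(map_small: np.ndarray, spec: GeometrySpec,
                     orig_h: int, orig_w: int, order: int = 0) -> np.ndarray:
    """Invert crop_and_resize: resample back and re-embed in the original canvas.

    Rows are resampled to the crop-band height and placed at
    [crop_start, crop_stop); rows outside the band are filled with the
    background class 0 (or intensity 0).  Class rasters use nearest-
    neighbour resampling (``order=0``).
    """
    map_small = np.asarray(map_small)
    if map_small.shape != (spec.target_h, spec.target_w):
        raise GeometryError(
            f"expected {spec.target_h}x{spec.target_w} raster, got {map_small.shape}"
        )
    band_h = spec.crop_stop - spec.crop_start
    band = _resize(map_small, (band_h, orig_w), order)
    canvas = np.zeros((orig_h, orig_w), dtype=band.dtype)
    canvas[spec.crop_start:spec.crop_stop] = band
    return canvas


def labels_to_classes(boundaries: BoundarySet | np.ndarray, h: int, w: int) -> np.ndarray:
    """Rasterise five ordered boundary traces into a 6-class mask.

    Per column, a pixel's class is the number of boundaries at or above
    it, so class ``j`` occupies rows [boundary_j, boundary_{j+1}) with
    half-open intervals (class 0 above the ILM, class 5 from the CS down).
    """
    arr = boundaries.as_array() if isinstance(boundaries, BoundarySet) else np.asarray(boundaries, float)
    if arr.shape != (N_BOUNDARIES, w):
        raise ValueError(f"expected boundary array of shape ({N_BOUNDARIES}, {w}), got {arr.shape}")
    diffs = np.diff(arr, axis=0)
    if (diffs < 0).any():
        j, col = np.argwhere(diffs < 0)[0]
        raise ValueError(
            f"boundary order violated at column {col}: "
            f"{BOUNDARY_NAMES[j]} ({arr[j, col]:.2f}) > {BOUNDARY_NAMES[j + 1]} ({arr[j + 1, col]:.2f})"
        )
    rows = np.arange(h)[:, None, None]          # (h, 1, 1)
    crossed = rows >= arr.T[None, :, :]          # (h, w, 5)
    return crossed.sum(axis=2).astype(np.int64)


def augment(img: np.ndarray, mask: np.ndarray, seed: int | np.random.Generator,
            max_rotation: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Random small rotation and horizontal flip, applied jointly.

    Rotation angle is uniform in [-max_rotation, +max_rotation] degrees
    with reflection padding; the flip is lateral only (a vertical flip
    would invert the anatomical layer order).  Deterministic for a fixed
    seed or generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask)
    angle = rng.uniform(-max_rotation, max_rotation)
    flip = rng.random() < 0.5
    if abs(angle) > 1e-12:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="reflect")
        mask = ndimage.rotate(mask, angle, reshape=False, order=0, mode="reflect")
    else:
        img, mask = img.copy(), mask.copy()
    if flip:
        img = img[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
    return img, mask
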