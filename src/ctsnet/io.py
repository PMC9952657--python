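"""Reading and writing the pipeline's on-disk artefacts.

Images and class masks travel as 8-bit PNG (intensities scaled to 0-255,
class indices stored verbatim); per-class probability maps as float32
TIFF stacks; boundaries as CSV via :class:`~ctsnet.boundaries.BoundarySet`.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image", "read_mask", "write_mask",
           "write_probability_maps"]


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale raster scaled to [0, 1] floats."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr /= 255.0
    return arr


def write_image(path: str | Path, img: np.ndarray) -> None:
    img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (img * 255).round().astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.int64)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > 255:
        raise ValueError("class mask does not fit in 8 bits")
    iio.imwrite(path, mask.astype(np.uint8))


def write_probability_maps(path: str | Path, probs: np.ndarray) -> None:
    """Store an (N, H, W) probability stack as multi-page float32 TIFF."""
    iio.imwrite(path, np.asarray(probs, dtype=np.float32), extension=".tiff")
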