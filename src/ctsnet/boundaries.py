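"""Layer-boundary extraction and smoothing.

A segmented B-scan is summarised by five named boundary traces (row
position per image column, top to bottom): ILM, RNFL-GCIPL, GCIPL-INL,
BM and CS.  This module converts 6-class layer masks into such traces,
smooths them with a Savitzky–Golay filter, and runs the full
post-processing chain (stitch tiles, restore original geometry, extract,
smooth) on network predictions.

The normative boundary localisation is a deterministic per-column scan
for the class transition; a Canny-based extractor is provided as a
cross-check and agrees with the scan to within one row on clean masks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter
from skimage.feature import canny

log = logging.getLogger(__name__)

BOUNDARY_NAMES = ("ILM", "RNFL-GCIPL", "GCIPL-INL", "BM", "CS")
N_BOUNDARIES = len(BOUNDARY_NAMES)

__all__ = [
    "BOUNDARY_NAMES",
    "BoundarySet",
    "SGFilterSpec",
    "mask_to_boundaries",
    "canny_boundaries",
    "savitzky_golay",
    "predict_boundaries",
]


@dataclass
class SGFilterSpec:
    """Savitzky–Golay smoothing settings.

    window: odd number of samples per fit (default 33); order: polynomial
    degree (default 3).  For traces shorter than the window, the window is
    shrunk to the largest valid odd length.
    """

    window: int = 33
    order: int = 3

    def __post_init__(self):
        if self.window % 2 == 0:
            raise ValueError(f"window must be odd, got {self.window}")
        if self.window <= self.order:
            raise ValueError(f"window ({self.window}) must exceed order ({self.order})")


@dataclass
class BoundarySet:
    """Five per-column boundary row traces, ordered top to bottom."""

    traces: dict[str, np.ndarray]

    def __post_init__(self):
        if set(self.traces) != set(BOUNDARY_NAMES):
            raise ValueError(f"expected traces for {BOUNDARY_NAMES}, got {sorted(self.traces)}")
        widths = {len(np.asarray(t)) for t in self.traces.values()}
        if len(widths) != 1:
            raise ValueError(f"trace lengths differ: {widths}")
        self.traces = {k: np.asarray(v, dtype=float) for k, v in self.traces.items()}

    @property
    def width(self) -> int:
        return len(self.traces[BOUNDARY_NAMES[0]])

    def as_array(self) -> np.ndarray:
        """Stack traces into a (5, width) array in anatomical order."""
        return np.stack([self.traces[n] for n in BOUNDARY_NAMES])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "BoundarySet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] != N_BOUNDARIES:
            raise ValueError(f"expected {N_BOUNDARIES} rows, got {arr.shape[0]}")
        return cls({n: arr[i] for i, n in enumerate(BOUNDARY_NAMES)})

    def is_ordered(self, tol: float = 0.0) -> bool:
        arr = self.as_array()
        return bool(np.all(np.diff(arr, axis=0) >= -tol))

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        lines = ["boundary_name,column_index,row_position"]
        for name in BOUNDARY_NAMES:
            for j, r in enumerate(self.traces[name]):
                lines.append(f"{name},{j},{r:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "BoundarySet":
        rows: dict[str, list[tuple[int, float]]] = {n: [] for n in BOUNDARY_NAMES}
        for line in Path(path).read_text().strip().splitlines()[1:]:
            name, col, row = line.split(",")
            rows[name].append((int(col), float(row)))
        traces = {}
        for name, entries in rows.items():
            entries.sort()
            traces[name] = np.array([r for _, r in entries])
        return cls(traces)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({n: self.traces[n].tolist() for n in BOUNDARY_NAMES}))

    @classmethod
    def from_json(cls, path: str | Path) -> "BoundarySet":
        return cls({k: np.asarray(v, float) for k, v in json.loads(Path(path).read_text()).items()})


def _interpolate_missing(trace: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill columns without a crossing from their valid neighbours."""
    if valid.all():
        return trace
    if not valid.any():
        return np.zeros_like(trace)
    cols = np.arange(len(trace))
    filled = trace.copy()
    filled[~valid] = np.interp(cols[~valid], cols[valid], trace[valid])
    return filled


def mask_to_boundaries(mask: np.ndarray, repair: bool = False) -> BoundarySet:
    """Extract the five boundary traces from a 6-class layer mask.

    Boundary ``j`` (1-based over the anatomical order) is located per
    column at the first row whose class index reaches ``j``; for an
    integer-trace mask built by :func:`ctsnet.geometry.labels_to_classes`
    this inverts that construction exactly.  Columns where a class is
    absent are interpolated from neighbouring columns; a trace absent from
    the whole mask is set to row 0.

    With ``repair=False`` a mask violating the top-to-bottom class order
    raises ``ValueError`` naming the offending column; with
    ``repair=True`` the per-column first-crossing scan is applied as-is
    and the resulting traces are re-sorted into anatomical order.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    monotone = np.diff(mask, axis=0) >= 0
    if not monotone.all() and not repair:
        bad = np.argwhere(~monotone)[0]
        raise ValueError(
            f"mask violates layer order at column {bad[1]}, rows {bad[0]}->{bad[0] + 1}"
        )
    h, w = mask.shape
    traces = np.empty((N_BOUNDARIES, w))
    for j in range(1, N_BOUNDARIES + 1):
        below = mask >= j
        valid = below.any(axis=0)
        first = below.argmax(axis=0).astype(float)
        traces[j - 1] = _interpolate_missing(first, valid)
    if repair:
        traces = np.maximum.accumulate(traces, axis=0)
    return BoundarySet.from_array(traces)


def canny_boundaries(mask: np.ndarray, sigma: float = 1.0,
                     low: float = 0.1, high: float = 0.2) -> BoundarySet:
    """Boundary traces via Canny edges on the per-transition binary maps.

    Cross-check for :func:`mask_to_boundaries`; thresholds apply to the
    normalised binary maps.
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    traces = np.empty((N_BOUNDARIES, w))
    for j in range(1, N_BOUNDARIES + 1):
        binary = (mask >= j).astype(float)
        edges = canny(binary, sigma=sigma, low_threshold=low, high_threshold=high)
        valid = edges.any(axis=0)
        first = edges.argmax(axis=0).astype(float)
        traces[j - 1] = _interpolate_missing(first, valid)
    return BoundarySet.from_array(traces)


def savitzky_golay(series: np.ndarray, spec: SGFilterSpec | None = None) -> np.ndarray:
    """Least-squares polynomial smoothing of a 1-D trace.

    Each sample is replaced by the centre value of the polynomial of
    ``spec.order`` fitted over ``spec.window`` samples; trace ends are
    mirror-padded.  Output length equals input length.
    """
    spec = spec or SGFilterSpec()
    series = np.asarray(series, dtype=float)
    window, order = spec.window, spec.order
    n = len(series)
    if n < window:
        window = n if n % 2 == 1 else n - 1
        if window < 3:
            return series.copy()
        order = min(order, window - 1)
    return savgol_filter(series, window_length=window, polyorder=order, mode="mirror")


def smooth_boundaries(bset: BoundarySet, spec: SGFilterSpec | None = None) -> BoundarySet:
    return BoundarySet({n: savitzky_golay(t, spec) for n, t in bset.traces.items()})


def predict_boundaries(maps, geom, orig_shape: tuple[int, int],
                       sg: SGFilterSpec | None = None) -> BoundarySet:
    """Full post-processing: tiles -> mask -> original geometry -> traces.

    ``maps`` is a :class:`~ctsnet.network.PredictionMaps` holding the
    logits for the tiles of one image (or an already-stitched class mask).
    The stitched argmax mask is restored to ``orig_shape``, boundary
    traces are scanned out, smoothed, and finally guarded against
    anatomical-order violations (re-sorted; violations are logged).
    """
    from . import geometry  # deferred: geometry imports BoundarySet from here

    if hasattr(maps, "logits"):
        from .network import predict_mask

        masks = predict_mask(maps)
        mask = geometry.stitch(list(masks))
    else:
        mask = np.asarray(maps)
    orig_h, orig_w = orig_shape
    restored = geometry.restore_geometry(mask, geom, orig_h, orig_w, order=0)
    bset = mask_to_boundaries(restored, repair=True)
    bset = smooth_boundaries(bset, sg)
    arr = bset.as_array()
    resorted = np.maximum.accumulate(arr, axis=0)
    if not np.allclose(arr, resorted):
        log.warning("boundary order violated after smoothing in %d columns; re-sorted",
                    int((arr != resorted).any(axis=0).sum()))
    resorted = np.clip(resorted, 0, orig_h - 1)
    return BoundarySet.from_array(resorted)
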