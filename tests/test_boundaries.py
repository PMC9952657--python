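"""Boundary extraction, Savitzky-Golay smoothing, post-processing chain."""

import numpy as np
import pytest

from ctsnet.boundaries import (BoundarySet, SGFilterSpec, canny_boundaries,
                               mask_to_boundaries, savitzky_golay,
                               smooth_boundaries)
from ctsnet.geometry import GeometrySpec, crop_and_resize, labels_to_classes, tile
from ctsnet.network import PredictionMaps
from ctsnet.phantoms import generate_phantom, raw_scan_spec
from ctsnet.tensor import Tensor


class TestMaskToBoundaries:
    def test_single_class_mask_degenerates_to_row_zero(self):
        assert (mask_to_boundaries(np.full((8, 8), 5)).as_array() == 0).all()

    def test_background_only_mask_degenerates_to_row_zero(self):
        assert (mask_to_boundaries(np.zeros((8, 8), int)).as_array() == 0).all()

    def test_order_violation_raises_unless_repaired(self):
        mask = np.zeros((8, 4), int)
        mask[2:] = 1
        mask[5, 1] = 0  # class decreases down the column
        with pytest.raises(ValueError, match="column 1"):
            mask_to_boundaries(mask)
        out = mask_to_boundaries(mask, repair=True)
        assert out.is_ordered()

    def test_noisy_mask_matches_per_column_scan_oracle(self, rng):
        b = np.sort(rng.integers(4, 60, size=(5, 12)), axis=0).astype(float)
        noisy = labels_to_classes(b, 64, 12)
        for _ in range(10):  # sprinkle label noise, then repair-extract
            noisy[rng.integers(0, 64), rng.integers(0, 12)] = rng.integers(0, 6)
        traces = mask_to_boundaries(noisy, repair=True).as_array()
        # independent scalar-loop oracle: first crossing, then running max
        oracle = np.zeros((5, 12))
        for j in range(1, 6):
            firsts, valid_cols = [], []
            for col in range(12):
                rows = [r for r in range(64) if noisy[r, col] >= j]
                if rows:
                    firsts.append(rows[0])
                    valid_cols.append(col)
            cols = np.arange(12)
            oracle[j - 1] = np.interp(cols, valid_cols, firsts) if valid_cols else 0.0
        for j in range(1, 5):
            oracle[j] = np.maximum(oracle[j], oracle[j - 1])
        assert np.array_equal(traces, oracle)

    def test_agrees_with_canny_extractor_on_clean_masks(self, smoke_phantom_spec):
        _, _, mask = generate_phantom(smoke_phantom_spec, seed=2)
        scan = mask_to_boundaries(mask).as_array()
        edge = canny_boundaries(mask).as_array()
        assert np.abs(scan - edge).max() <= 1.0


class TestSavitzkyGolay:
    def test_constant_series_unchanged(self):
        x = np.full(100, 3.7)
        assert np.allclose(savitzky_golay(x), x)

    def test_reproduces_cubic_exactly_vs_least_squares_oracle(self):
        t = np.arange(120, dtype=float)
        y = 1.0 - 0.5 * t + 0.02 * t ** 2 - 1e-4 * t ** 3
        spec = SGFilterSpec(window=33, order=3)
        out = savitzky_golay(y, spec)
        # independent per-window polynomial fit at each interior point
        w = spec.window // 2
        for k in (40, 60, 75):
            idx = np.arange(k - w, k + w + 1)
            coeffs = np.polyfit(idx - k, y[idx], spec.order)
            assert abs(out[k] - np.polyval(coeffs, 0.0)) <= 1e-9
        assert np.abs(out[w:-w] - y[w:-w]).max() <= 1e-9

    def test_default_window_is_33(self):
        assert SGFilterSpec().window == 33

    def test_linearity(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        spec = SGFilterSpec(window=11, order=2)
        assert np.allclose(savitzky_golay(2.0 * x + 3.0 * y, spec),
                           2.0 * savitzky_golay(x, spec) + 3.0 * savitzky_golay(y, spec))

    def test_short_series_shrinks_window(self, rng):
        x = rng.normal(size=9)
        out = savitzky_golay(x, SGFilterSpec(window=33, order=3))
        assert out.shape == x.shape

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SGFilterSpec(window=10)
        with pytest.raises(ValueError, match="exceed"):
            SGFilterSpec(window=3, order=3)


class TestPredictBoundaries:
    def test_oracle_logits_recover_traces_within_resampling_bound(self):
        """A perfect class map pushed through tile -> stitch -> restore
        recovers the phantom's boundaries to the crop/resize bound."""
        from ctsnet.boundaries import predict_boundaries

        spec = raw_scan_spec(speckle_sigma=0.0, amplitude=8.0)
        _, bset, mask = generate_phantom(spec, seed=4)
        geom = GeometrySpec()
        small = crop_and_resize(mask, geom, order=0)
        tiles = tile(small, geom)
        logits = np.stack([np.eye(6)[t].transpose(2, 0, 1) for t in tiles])
        maps = PredictionMaps(logits=Tensor(logits))
        out = predict_boundaries(maps, geom, (800, 1000), sg=SGFilterSpec())
        err = np.abs(out.as_array() - bset.as_array())
        assert err.mean() < 2.0
        assert err.max() < 8.0  # resampling quantisation + smoothing at ends
        assert out.is_ordered()

    def test_constant_row_boundaries_survive_smoothing(self):
        b = np.tile(np.array([10.0, 20, 30, 40, 50])[:, None], (1, 64))
        bset = BoundarySet.from_array(b)
        sm = smooth_boundaries(bset, SGFilterSpec())
        assert np.allclose(sm.as_array(), b)


class TestBoundarySetIO:
    def test_csv_roundtrip(self, tmp_path, rng):
        b = BoundarySet.from_array(np.sort(rng.uniform(0, 60, (5, 10)), axis=0))
        path = tmp_path / "b.csv"
        b.to_csv(path)
        back = BoundarySet.from_csv(path)
        assert np.allclose(back.as_array(), b.as_array(), atol=1e-4)

    def test_json_roundtrip(self, tmp_path, rng):
        b = BoundarySet.from_array(np.sort(rng.uniform(0, 60, (5, 10)), axis=0))
        path = tmp_path / "b.json"
        b.to_json(path)
        assert np.allclose(BoundarySet.from_json(path).as_array(), b.as_array())

    def test_wrong_names_rejected(self):
        with pytest.raises(ValueError):
            BoundarySet({"a": np.zeros(4)})
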