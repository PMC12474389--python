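"""Manifest validation, cropping arithmetic, splitting, preprocessing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tailbcs.data import (
    IMAGENET_MEAN,
    IMAGENET_SD,
    crop_tail,
    preprocess,
    read_manifest,
    split_dataset,
)


def _write_manifest(path, rows):
    pd.DataFrame(rows, columns=["path", "x0", "y0", "x1", "y1", "bcs"]).to_csv(
        path, index=False
    )
    return path


class TestReadManifest:
    def test_reads_valid_rows(self, tmp_path):
        p = _write_manifest(tmp_path / "m.csv", [
            ("a.png", 0, 0, 10, 10, 3.25),
            ("b.png", 5, 5, 20, 30, 4.25),
        ])
        records = read_manifest(p, validate_bounds=False)
        assert len(records) == 2
        assert records[1].bbox == (5, 5, 20, 30)
        assert records[0].label_index == 0

    def test_illegal_bcs_named_row(self, tmp_path):
        p = _write_manifest(tmp_path / "m.csv", [("a.png", 0, 0, 5, 5, 3.30)])
        with pytest.raises(ValueError, match="row 0"):
            read_manifest(p, validate_bounds=False)

    def test_inverted_bbox_rejected(self, tmp_path):
        p = _write_manifest(tmp_path / "m.csv", [("a.png", 10, 0, 10, 5, 3.25)])
        with pytest.raises(ValueError, match="bbox"):
            read_manifest(p, validate_bounds=False)

    def test_missing_column(self, tmp_path):
        p = tmp_path / "m.csv"
        pd.DataFrame({"path": ["a.png"], "x0": [0]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_manifest(p)

    def test_duplicate_path(self, tmp_path):
        p = _write_manifest(tmp_path / "m.csv", [
            ("a.png", 0, 0, 5, 5, 3.25),
            ("a.png", 0, 0, 5, 5, 3.50),
        ])
        with pytest.raises(ValueError, match="duplicate"):
            read_manifest(p, validate_bounds=False)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_manifest(tmp_path / "nope.csv")


class TestCropTail:
    def test_full_extent_is_identity(self, rng):
        img = rng.integers(0, 255, (20, 30, 3), dtype=np.uint8)
        np.testing.assert_array_equal(crop_tail(img, (0, 0, 30, 20)), img)

    def test_half_open_dimensions(self, rng):
        img = rng.integers(0, 255, (100, 100, 3), dtype=np.uint8)
        crop = crop_tail(img, (10, 20, 30, 60))
        assert crop.shape[:2] == (40, 20)
        np.testing.assert_array_equal(crop, img[20:60, 10:30])

    def test_empty_width_rejected(self, rng):
        img = rng.integers(0, 255, (20, 20, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="bbox"):
            crop_tail(img, (0, 0, 0, 10))

    def test_out_of_bounds_rejected(self, rng):
        img = rng.integers(0, 255, (20, 20, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="bbox"):
            crop_tail(img, (0, 0, 21, 10))

    def test_idempotent_under_full_extent(self, rng):
        img = rng.integers(0, 255, (20, 20, 3), dtype=np.uint8)
        once = crop_tail(img, (2, 3, 12, 15))
        h, w = once.shape[:2]
        np.testing.assert_array_equal(crop_tail(once, (0, 0, w, h)), once)


class TestSplitDataset:
    def test_published_corpus_size(self):
        """The floor-remainder rule on 53,566 items gives 37,496/10,713/5,357."""
        split = split_dataset(53_566, seed=0)
        assert split.sizes() == (37_496, 10_713, 5_357)

    @pytest.mark.parametrize("n,expected", [(10, (7, 2, 1)), (11, (7, 2, 2))])
    def test_small_n_floor_remainder(self, n, expected):
        assert split_dataset(n, seed=3).sizes() == expected

    def test_too_few_items(self):
        with pytest.raises(ValueError, match="at least 3"):
            split_dataset(2)

    def test_bad_ratios(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(10, ratios=(0.5, 0.2, 0.1))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(3, 5000), st.integers(0, 2**31 - 1))
    def test_partition_property(self, n, seed):
        split = split_dataset(n, seed=seed)
        combined = np.concatenate([split.train, split.val, split.test])
        assert len(combined) == n
        assert len(np.unique(combined)) == n

    def test_sizes_depend_only_on_n(self):
        assert split_dataset(100, seed=1).sizes() == split_dataset(100, seed=2).sizes()

    def test_membership_depends_on_seed(self):
        a = split_dataset(100, seed=1)
        b = split_dataset(100, seed=2)
        assert not np.array_equal(a.train, b.train)

    def test_same_seed_reproduces(self):
        a, b = split_dataset(100, seed=5), split_dataset(100, seed=5)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)


class TestPreprocess:
    def test_output_shape(self, rng):
        img = rng.integers(0, 255, (100, 80, 3), dtype=np.uint8)
        out = preprocess(img, input_size=224)
        assert out.shape == (3, 224, 224)
        assert out.dtype == np.float32

    def test_all_zero_image(self):
        out = preprocess(np.zeros((10, 10, 3), np.uint8), input_size=8)
        for c in range(3):
            np.testing.assert_allclose(
                out[c], -IMAGENET_MEAN[c] / IMAGENET_SD[c], atol=1e-6
            )

    def test_uniform_gray_hand_value(self):
        """Gray 128: channel value (128/255 - mean_c) / sd_c."""
        out = preprocess(np.full((16, 16, 3), 128, np.uint8), input_size=8)
        for c in range(3):
            expected = (128 / 255 - IMAGENET_MEAN[c]) / IMAGENET_SD[c]
            np.testing.assert_allclose(out[c], expected, atol=1e-6)

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError, match="RGB"):
            preprocess(np.zeros((10, 10), np.uint8))
        with pytest.raises(ValueError, match="empty"):
            preprocess(np.zeros((0, 10, 3), np.uint8))
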