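"""Dataset I/O round-trips, mask binarisation, and split contracts."""

import numpy as np
import pytest
from PIL import Image

from dermseg.data import (
    DatasetSplit,
    DermoscopySample,
    kfold_split,
    read_isic_pair,
    read_manifest,
    read_ph2_case,
    split_dataset,
    write_manifest,
    write_sample,
)
from dermseg.errors import ValidationError


def _write_png(path, arr):
    Image.fromarray(arr).save(path)


class TestSampleInvariants:
    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValidationError, match="mismatch"):
            DermoscopySample("x", np.zeros((64, 64, 3)), np.zeros((64, 32)))

    def test_rejects_non_binary_mask(self):
        mask = np.zeros((64, 64), np.uint8)
        mask[0, 0] = 7
        with pytest.raises(ValidationError, match="0 or 1"):
            DermoscopySample("x", np.zeros((64, 64, 3)), mask)

    def test_rejects_tiny_images(self):
        with pytest.raises(ValidationError, match="at least 32"):
            DermoscopySample("x", np.zeros((16, 64, 3)), np.zeros((16, 64)))


class TestIsicReader:
    def test_binary_mask_preserved_and_id_extracted(self, tmp_path, rng):
        img = rng.integers(0, 256, (64, 64, 3)).astype(np.uint8)
        mask255 = (rng.random((64, 64)) > 0.5).astype(np.uint8) * 255
        _write_png(tmp_path / "ISIC_0001.png", img)
        _write_png(tmp_path / "ISIC_0001_segmentation.png", mask255)
        s = read_isic_pair(
            tmp_path / "ISIC_0001.png", tmp_path / "ISIC_0001_segmentation.png"
        )
        assert s.sample_id == "ISIC_0001"
        assert s.source == "isic"
        np.testing.assert_array_equal(s.mask, mask255 // 255)

    def test_anti_aliased_pixel_128_maps_to_one_127_to_zero(self, tmp_path):
        img = np.zeros((64, 64, 3), np.uint8)
        mask = np.zeros((64, 64), np.uint8)
        mask[0, 0], mask[0, 1] = 128, 127
        _write_png(tmp_path / "a.png", img)
        _write_png(tmp_path / "a_segmentation.png", mask)
        s = read_isic_pair(tmp_path / "a.png", tmp_path / "a_segmentation.png")
        assert s.mask[0, 0] == 1 and s.mask[0, 1] == 0

    def test_shape_mismatch_reports_both_shapes(self, tmp_path):
        _write_png(tmp_path / "b.png", np.zeros((64, 64, 3), np.uint8))
        _write_png(tmp_path / "b_segmentation.png", np.zeros((32, 64), np.uint8))
        with pytest.raises(ValidationError, match=r"64.*32"):
            read_isic_pair(tmp_path / "b.png", tmp_path / "b_segmentation.png")

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.png"):
            read_isic_pair(tmp_path / "nope.png", tmp_path / "nope_segmentation.png")


class TestPh2Reader:
    def test_roundtrip_via_write_sample(self, tmp_path, one_sample):
        write_sample(one_sample, tmp_path, layout="ph2")
        back = read_ph2_case(tmp_path / one_sample.sample_id)
        assert back.sample_id == one_sample.sample_id
        assert back.source == "ph2"
        np.testing.assert_array_equal(back.mask, one_sample.mask)
        np.testing.assert_array_equal(
            back.image, np.clip(np.rint(one_sample.image), 0, 255)
        )

    def test_empty_directory_is_ambiguous(self, tmp_path):
        (tmp_path / "case").mkdir()
        with pytest.raises(ValidationError, match="ambiguous"):
            read_ph2_case(tmp_path / "case")

    def test_three_channel_mask_with_identical_channels_collapses(self, tmp_path):
        case = tmp_path / "IMD1"
        case.mkdir()
        _write_png(case / "IMD1.png", np.zeros((64, 64, 3), np.uint8))
        m = (np.random.default_rng(0).random((64, 64)) > 0.5).astype(np.uint8) * 255
        _write_png(case / "IMD1_lesion.png", np.repeat(m[:, :, None], 3, axis=2))
        s = read_ph2_case(case)
        np.testing.assert_array_equal(s.mask, m // 255)

    def test_two_masks_is_ambiguous(self, tmp_path):
        case = tmp_path / "IMD2"
        case.mkdir()
        _write_png(case / "IMD2.png", np.zeros((64, 64, 3), np.uint8))
        _write_png(case / "IMD2_lesion.png", np.zeros((64, 64), np.uint8))
        _write_png(case / "IMD2b_lesion.png", np.zeros((64, 64), np.uint8))
        with pytest.raises(ValidationError, match="ambiguous"):
            read_ph2_case(case)


class TestIsicRoundtrip:
    def test_write_then_read_is_bit_identical(self, tmp_path, one_sample):
        write_sample(one_sample, tmp_path, layout="isic")
        s = read_isic_pair(
            tmp_path / f"{one_sample.sample_id}.png",
            tmp_path / f"{one_sample.sample_id}_segmentation.png",
        )
        np.testing.assert_array_equal(s.mask, one_sample.mask)
        assert s.image.shape == one_sample.image.shape


class TestSplits:
    def test_paper_style_160_40_split(self):
        ids = [f"s{i}" for i in range(200)]
        split = split_dataset(ids, (0.8, 0.0, 0.2), seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (160, 0, 40)

    def test_rounding_remainder_goes_to_train(self):
        ids = [f"s{i}" for i in range(10)]
        split = split_dataset(ids, (0.5, 0.2, 0.3), seed=5)
        assert (len(split.train), len(split.validation), len(split.test)) == (5, 2, 3)
        assert split.all_ids == set(ids)

    def test_deterministic_for_fixed_seed(self):
        ids = [f"s{i}" for i in range(37)]
        a = split_dataset(ids, (0.7, 0.15, 0.15), seed=42)
        b = split_dataset(ids, (0.7, 0.15, 0.15), seed=42)
        assert a.train == b.train and a.validation == b.validation and a.test == b.test
        c = split_dataset(ids, (0.7, 0.15, 0.15), seed=43)
        assert a.train != c.train  # different seed shuffles differently

    def test_split_errors(self):
        with pytest.raises(ValidationError):
            split_dataset(["a", "b"], (0.5, 0.25, 0.25), seed=0)
        with pytest.raises(ValidationError):
            split_dataset(list("abcd"), (0.5, 0.2, 0.2), seed=0)  # sums to 0.9
        with pytest.raises(ValidationError):
            DatasetSplit(train=["a"], validation=["a"], test=[])

    def test_kfold_partition_properties(self):
        ids = [f"s{i}" for i in range(10)]
        pairs = kfold_split(ids, k=5, seed=3)
        assert len(pairs) == 5
        val_all = [v for _, val in pairs for v in val]
        assert sorted(val_all) == sorted(ids)  # each id in exactly one fold
        for train, val in pairs:
            assert len(val) == 2
            assert set(train) | set(val) == set(ids)
            assert not set(train) & set(val)

    def test_kfold_unbalanced_sizes(self):
        sizes = sorted(len(v) for _, v in kfold_split(list("abcdefg"), 5, seed=0))
        assert sizes == [1, 1, 1, 2, 2]

    def test_kfold_errors(self):
        with pytest.raises(ValidationError):
            kfold_split(list("abc"), k=5, seed=0)
        with pytest.raises(ValidationError):
            kfold_split(list("abc"), k=1, seed=0)

    def test_manifest_roundtrip(self, tmp_path):
        split = split_dataset([f"s{i}" for i in range(20)], (0.6, 0.2, 0.2), seed=1)
        write_manifest(split, tmp_path / "split.tsv")
        back = read_manifest(tmp_path / "split.tsv")
        assert back.train == split.train
        assert back.validation == split.validation
        assert back.test == split.test
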