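"""Preprocessing: mask binarization, NLM denoising, the x4 augmentation and
patient-level splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoseg.phantom import Sample
from osteoseg.preprocess import (ChannelInconsistencyError, DatasetSplit,
                                 ImageSlice, MaskSlice, augment_quadruple,
                                 denoise_nlm, mask_to_binary, split_dataset,
                                 write_split_manifest)


# -- mask_to_binary -------------------------------------------------------

def test_all_zero_rgb_raster_gives_empty_mask():
    out = mask_to_binary(np.zeros((16, 16, 3), dtype=np.uint8))
    np.testing.assert_array_equal(out.pixels, 0)


def test_single_saturated_pixel_maps_to_single_one():
    raw = np.zeros((16, 16, 3), dtype=np.uint8)
    raw[5, 7] = (255, 255, 255)
    out = mask_to_binary(raw)
    assert out.pixels.sum() == 1
    assert out.pixels[5, 7] == 1


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_grayscale_popcount_matches_nonzero_count(seed):
    rng = np.random.default_rng(seed)
    raw = rng.choice([0, 128, 255], size=(12, 12)).astype(np.uint8)
    out = mask_to_binary(raw)
    assert out.pixels.sum() == np.count_nonzero(raw)
    assert set(np.unique(out.pixels)) <= {0, 1}


def test_disagreeing_rgb_channels_rejected():
    raw = np.zeros((8, 8, 3), dtype=np.uint8)
    raw[2, 2, 0] = 255  # red-only pixel: channels disagree
    with pytest.raises(ChannelInconsistencyError):
        mask_to_binary(raw)


# -- denoise_nlm ----------------------------------------------------------

def test_denoise_strength_zero_returns_input_unchanged(rng):
    img = ImageSlice(rng.random((32, 32)))
    assert denoise_nlm(img, strength=0) is img


def test_denoise_constant_image_stays_constant():
    img = ImageSlice(np.full((32, 32), 0.5))
    out = denoise_nlm(img, strength=0.1)
    np.testing.assert_allclose(out.pixels, 0.5, atol=1e-6)


def test_denoise_reduces_noise_standard_deviation(rng):
    noisy = np.clip(0.5 + rng.normal(0, 0.1, (64, 64)), 0, 1)
    img = ImageSlice(noisy)
    out = denoise_nlm(img)
    assert out.pixels.std() < noisy.std()
    assert out.pixels.shape == noisy.shape
    assert out.pixels.min() >= 0 and out.pixels.max() <= 1


def test_denoise_rejects_invalid_pixels():
    with pytest.raises(ValueError):
        ImageSlice(np.full((16, 16), np.nan))


# -- augment_quadruple ----------------------------------------------------

def _disk_pair(h=64):
    yy, xx = np.mgrid[0:h, 0:h]
    c = (h - 1) / 2  # the rotation center used by the augmentation
    mask = ((yy - c) ** 2 + (xx - c) ** 2 <= (h / 4) ** 2).astype(np.uint8)
    img = np.clip(0.2 + 0.5 * mask, 0, 1)
    return ImageSlice(img, "p0", "s0"), MaskSlice(mask)


def test_augmentation_quadruples_and_keeps_masks_binary(rng):
    img, mask = _disk_pair()
    pairs = augment_quadruple(img, mask)
    assert len(pairs) == 4
    for im, mk in pairs:
        assert im.pixels.shape == img.pixels.shape
        assert set(np.unique(mk.pixels)) <= {0, 1}


def test_flip_and_transpose_are_involutions(rng):
    img = ImageSlice(rng.random((32, 32)), "p", "s")
    mask = MaskSlice((rng.random((32, 32)) > 0.5).astype(np.uint8))
    pairs = augment_quadruple(img, mask)
    _, _, (t_img, t_mask), (f_img, f_mask) = pairs
    np.testing.assert_array_equal(t_img.pixels.T, img.pixels)
    np.testing.assert_array_equal(t_mask.pixels.T, mask.pixels)
    np.testing.assert_array_equal(np.fliplr(f_img.pixels), img.pixels)
    np.testing.assert_array_equal(np.fliplr(f_mask.pixels), mask.pixels)


def test_rotated_centered_disk_overlaps_original():
    img, mask = _disk_pair()
    rot_mask = augment_quadruple(img, mask)[1][1].pixels
    inter = np.logical_and(rot_mask, mask.pixels).sum()
    union = np.logical_or(rot_mask, mask.pixels).sum()
    assert inter / union >= 0.95  # a centered disk is nearly rotation-invariant


def test_augmentation_rejects_shape_mismatch(rng):
    img = ImageSlice(rng.random((32, 32)))
    mask = MaskSlice(np.zeros((16, 16), dtype=np.uint8))
    with pytest.raises(ValueError, match="shape"):
        augment_quadruple(img, mask)


# -- split_dataset --------------------------------------------------------

def _patients(n_patients, slices_each=3):
    return [Sample(image=np.zeros((8, 8)), mask=np.zeros((8, 8), dtype=np.uint8),
                   patient_id=f"p{i:03d}", slice_id=f"p{i:03d}_s{j}")
            for i in range(n_patients) for j in range(slices_each)]


def test_ten_patients_split_seven_two_one():
    split = split_dataset(_patients(10), seed=0)
    sizes = {part: len({s.patient_id for s in items})
             for part, items in split.partitions().items()}
    assert sizes == {"train": 7, "val": 2, "test": 1}


def test_split_is_deterministic_for_fixed_seed():
    a = split_dataset(_patients(10), seed=42)
    b = split_dataset(_patients(10), seed=42)
    for part in ("train", "val", "test"):
        assert [s.slice_id for s in getattr(a, part)] == \
               [s.slice_id for s in getattr(b, part)]


def test_no_slice_or_patient_leaks_across_partitions():
    split = split_dataset(_patients(100, slices_each=1), seed=1)
    parts = split.partitions()
    slice_sets = {k: {s.slice_id for s in v} for k, v in parts.items()}
    patient_sets = {k: {s.patient_id for s in v} for k, v in parts.items()}
    for a in parts:
        for b in parts:
            if a < b:
                assert not slice_sets[a] & slice_sets[b]
                assert not patient_sets[a] & patient_sets[b]
    total = set.union(*slice_sets.values())
    assert len(total) == 100


def test_patients_with_many_slices_stay_together():
    split = split_dataset(_patients(12, slices_each=5), seed=3)
    for part, items in split.partitions().items():
        for s in items:
            owner = [p for p, its in split.partitions().items()
                     if any(t.patient_id == s.patient_id for t in its)]
            assert owner == [part]


def test_split_rejects_fewer_than_three_patients():
    with pytest.raises(ValueError, match="3 patients"):
        split_dataset(_patients(2))


def test_split_manifest_written_with_partitions(tmp_path):
    split = split_dataset(_patients(5), seed=0)
    path = tmp_path / "split.csv"
    write_split_manifest(split, path)
    import pandas as pd

    df = pd.read_csv(path)
    assert set(df.columns) == {"patient_id", "slice_id", "partition"}
    assert set(df.partition) == {"train", "val", "test"}
    assert len(df) == 15
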