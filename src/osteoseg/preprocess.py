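"""Data preprocessing: mask normalization, denoising, augmentation, splits.

Annotation masks often arrive as saturated RGB overlays; they are collapsed
to single-channel binary rasters (any positive luminance is foreground).
Images are denoised with the non-local-means (NLM) algorithm before
segmentation, since Gaussian acquisition noise is the dominant artifact in
the MRI slices this pipeline targets.  The dataset is quadrupled by three
deterministic transforms — 45° clockwise rotation, transposition and
horizontal flip — and split 7:2:1 into train/validation/test at the
*patient* level so no patient's slices leak across partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.restoration import denoise_nl_means, estimate_sigma
from skimage.transform import rotate

__all__ = ["ImageSlice", "MaskSlice", "DatasetSplit", "ChannelInconsistencyError",
           "mask_to_binary", "denoise_nlm", "augment_quadruple", "split_dataset",
           "load_slice_image", "load_mask_image", "nifti_slices",
           "read_manifest", "write_split_manifest"]


class ChannelInconsistencyError(ValueError):
    """Raised when a 3-channel mask's channels disagree on the label."""


@dataclass
class ImageSlice:
    """A grayscale 2-D slice with intensities in [0, 1]."""

    pixels: np.ndarray
    patient_id: str = ""
    slice_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image slice must be 2-D")
        h, w = self.pixels.shape
        if h < 8 or w < 8:
            raise ValueError(f"slice must be at least 8x8, got {h}x{w}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]")


@dataclass
class MaskSlice:
    """A binary 2-D mask paired with an image slice of the same shape."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.all(np.isin(np.unique(self.pixels), (0, 1))):
            raise ValueError("mask values must be strictly binary")
        self.pixels = self.pixels.astype(np.uint8)


def mask_to_binary(raw_mask: np.ndarray) -> MaskSlice:
    """Collapse a raw mask raster to a binary single-channel mask.

    Accepts single-channel rasters or 3-channel RGB whose channels carry
    identical label information (saturated overlays); any strictly positive
    luminance maps to foreground.
    """
    raw = np.asarray(raw_mask)
    if raw.ndim == 3:
        if raw.shape[2] not in (3, 4):
            raise ValueError(f"expected 3 or 4 channels, got {raw.shape[2]}")
        rgb = raw[..., :3]
        binarized = rgb > 0
        if not (np.array_equal(binarized[..., 0], binarized[..., 1])
                and np.array_equal(binarized[..., 0], binarized[..., 2])):
            raise ChannelInconsistencyError(
                "mask channels disagree on the foreground label")
        raw = rgb[..., 0]
    elif raw.ndim != 2:
        raise ValueError(f"mask raster must be 2-D or 3-D, got rank {raw.ndim}")
    return MaskSlice((raw > 0).astype(np.uint8))


def denoise_nlm(img: ImageSlice, patch_size: int = 5, search_window: int = 11,
                strength: float | None = None) -> ImageSlice:
    """Non-local-means denoising of one slice.

    ``strength`` is the NLM filtering parameter ``h``; ``None`` uses
    0.8x the estimated noise standard deviation, and 0 returns the input
    unchanged.
    """
    if strength is not None and strength < 0:
        raise ValueError("strength must be >= 0")
    if strength == 0:
        return img
    pixels = img.pixels
    if strength is None:
        strength = 0.8 * float(estimate_sigma(pixels))
        if strength == 0:
            return img
    out = denoise_nl_means(pixels, patch_size=patch_size,
                           patch_distance=search_window // 2,
                           h=strength, fast_mode=True)
    return ImageSlice(np.clip(out, 0.0, 1.0), img.patient_id, img.slice_id)


def _rotate45(image: np.ndarray, is_mask: bool) -> np.ndarray:
    # clockwise => negative angle; canvas kept, exposed corners filled with 0
    order = 0 if is_mask else 1
    out = rotate(image.astype(float), -45.0, resize=False, order=order,
                 mode="constant", cval=0.0)
    if is_mask:
        return (out > 0.5).astype(np.uint8)
    return np.clip(out, 0.0, 1.0)


def augment_quadruple(img: ImageSlice, mask: MaskSlice) -> list[tuple[ImageSlice, MaskSlice]]:
    """[original, rotated 45° clockwise, transposed, flipped] pairs.

    The same transform is applied to image and mask; masks are re-binarized
    after the rotation's interpolation.
    """
    if img.pixels.shape != mask.pixels.shape:
        raise ValueError(
            f"image {img.pixels.shape} and mask {mask.pixels.shape} differ in shape")

    def pair(suffix: str, ip: np.ndarray, mp: np.ndarray):
        return (ImageSlice(ip, img.patient_id, f"{img.slice_id}{suffix}"),
                MaskSlice(mp))

    return [
        pair("", img.pixels.copy(), mask.pixels.copy()),
        pair("_rot45", _rotate45(img.pixels, False), _rotate45(mask.pixels, True)),
        pair("_transpose", img.pixels.T.copy(), mask.pixels.T.copy()),
        pair("_flip", np.fliplr(img.pixels).copy(), np.fliplr(mask.pixels).copy()),
    ]


@dataclass
class DatasetSplit:
    """Patient-disjoint train/validation/test partition of sample references."""

    train: list
    val: list
    test: list
    ratio: tuple[float, float, float]
    seed: int

    def partitions(self) -> dict:
        return {"train": self.train, "val": self.val, "test": self.test}


def _patient_of(sample) -> str:
    if hasattr(sample, "patient_id"):
        return sample.patient_id
    if isinstance(sample, dict) and "patient_id" in sample:
        return sample["patient_id"]
    raise ValueError("every sample must carry a patient_id")


def split_dataset(samples, ratio=(0.7, 0.2, 0.1), seed: int = 0) -> DatasetSplit:
    """Split samples 7:2:1 (by default) at the patient level.

    All slices of one patient land in the same partition; the partition of
    each patient is a deterministic function of ``seed``.  Patient counts
    follow largest-remainder rounding of ``ratio`` with every partition
    guaranteed at least one patient.
    """
    if len(ratio) != 3 or not np.isclose(sum(ratio), 1.0):
        raise ValueError("ratio must be three fractions summing to 1")
    patients = sorted({_patient_of(s) for s in samples})
    if len(patients) < 3:
        raise ValueError(f"need at least 3 patients to split, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]

    n = len(patients)
    exact = [r * n for r in ratio]
    counts = [int(np.floor(e)) for e in exact]
    # largest-remainder distribution, then top up empty partitions
    remainders = np.argsort([c - e for c, e in zip(counts, exact)])
    for i in range(n - sum(counts)):
        counts[remainders[i % 3]] += 1
    for i in range(3):
        while counts[i] == 0:
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[i] += 1

    bounds = np.cumsum(counts)
    assignment = {}
    for idx, patient in enumerate(order):
        part = int(np.searchsorted(bounds, idx, side="right"))
        assignment[patient] = ("train", "val", "test")[part]
    parts = {"train": [], "val": [], "test": []}
    for s in samples:
        parts[assignment[_patient_of(s)]].append(s)
    return DatasetSplit(train=parts["train"], val=parts["val"],
                        test=parts["test"], ratio=tuple(ratio), seed=seed)


# -- file I/O ------------------------------------------------------------


def load_slice_image(path, patient_id: str = "", slice_id: str = "") -> ImageSlice:
    """Read a PNG/TIFF slice as a [0, 1] grayscale ImageSlice."""
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        raw = raw[..., :3].mean(axis=-1)
    info = np.iinfo(raw.dtype) if np.issubdtype(raw.dtype, np.integer) else None
    pixels = raw.astype(float) / (info.max if info else 1.0)
    return ImageSlice(np.clip(pixels, 0.0, 1.0), patient_id,
                      slice_id or Path(path).stem)


def load_mask_image(path) -> MaskSlice:
    """Read a PNG/TIFF mask raster and collapse it to binary."""
    import imageio.v3 as iio

    return mask_to_binary(np.asarray(iio.imread(path)))


def nifti_slices(path, patient_id: str = "") -> list[ImageSlice]:
    """Slice a NIfTI volume along its last axis into normalized 2-D slices."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got rank {vol.ndim}")
    lo, hi = vol.min(), vol.max()
    span = hi - lo if hi > lo else 1.0
    pid = patient_id or Path(path).name.split(".")[0]
    return [ImageSlice((vol[:, :, k] - lo) / span, pid, f"{pid}_z{k:04d}")
            for k in range(vol.shape[2])]


def read_manifest(data_dir) -> pd.DataFrame:
    """Read a dataset manifest (patient_id, slice_id, image, mask paths)."""
    data_dir = Path(data_dir)
    manifest = data_dir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv under {data_dir}")
    df = pd.read_csv(manifest)
    required = {"patient_id", "slice_id", "image"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return df


def write_split_manifest(split: DatasetSplit, path) -> None:
    """Persist a split as (patient_id, slice_id, partition) rows."""
    rows = []
    for part, items in split.partitions().items():
        for s in items:
            rows.append({"patient_id": _patient_of(s),
                         "slice_id": getattr(s, "slice_id", ""),
                         "partition": part})
    pd.DataFrame.from_records(rows).to_csv(path, index=False)
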