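"""Synthetic MRI-like phantoms with known tumor geometry.

The clinical images the method targets cannot be redistributed, so testing
and desk-scale experiments run on phantoms that emulate their salient
features: a smooth low-frequency anatomy background crossed by bright
elliptical "bone" bands, one or more tumor blobs whose boundaries are
irregular (an ellipse with a random low-order Fourier perturbation of its
radius), and additive Gaussian noise of the kind MRI acquisition
introduces.  The mask is the exact noiseless union of the tumor regions;
noise only ever touches the image.

Every sample is a pure function of ``(spec, index)``, so datasets are fully
reproducible and never need to be stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["PhantomSpec", "Sample", "generate_phantom", "generate_dataset",
           "write_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of the phantom family.

    ``tumor_radius_frac`` is the base-ellipse radius as a fraction of
    ``min(H, W)``; ``boundary_irregularity`` scales the Fourier radius
    perturbation (0 gives exact ellipses); ``contrast`` is the intensity
    offset of tumor over background; ``noise_sigma`` the Gaussian noise
    level.  Defaults give clearly present tumors with noisy, ambiguous
    boundaries (contrast-to-noise about 7).
    """

    size: tuple[int, int] = (64, 64)
    n_tumors: tuple[int, int] = (1, 2)
    tumor_radius_frac: tuple[float, float] = (0.10, 0.25)
    boundary_irregularity: float = 0.3
    contrast: float = 0.35
    noise_sigma: float = 0.05
    bone_structures: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")
        lo, hi = self.tumor_radius_frac
        if not 0 < lo <= hi:
            raise ValueError("tumor_radius_frac range must be positive and ordered")
        if hi * min(self.size) < 2:
            raise ValueError("largest tumor radius is below 2 pixels")
        if hi >= 0.5:
            raise ValueError("tumor radius exceeds the canvas")
        if self.n_tumors[0] > self.n_tumors[1] or self.n_tumors[0] < 0:
            raise ValueError("n_tumors range must be nonempty")


@dataclass
class Sample:
    """One image/mask pair with its provenance identifiers."""

    image: np.ndarray
    mask: np.ndarray
    patient_id: str
    slice_id: str


def _background(rng: np.random.Generator, h: int, w: int,
                n_bones: int) -> np.ndarray:
    """Smooth low-frequency field plus elliptical bone bands, range <= 0.7."""
    field = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=min(h, w) / 8)
    lo, hi = field.min(), field.max()
    span = hi - lo if hi > lo else 1.0
    bg = 0.15 + 0.3 * (field - lo) / span
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_bones):
        cy, cx = rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w
        a = rng.uniform(0.25, 0.45) * min(h, w)
        b = a * rng.uniform(0.5, 0.9)
        phi = rng.uniform(0, np.pi)
        yr = (yy - cy) * np.cos(phi) + (xx - cx) * np.sin(phi)
        xr = -(yy - cy) * np.sin(phi) + (xx - cx) * np.cos(phi)
        rho = np.sqrt((yr / a) ** 2 + (xr / b) ** 2)
        thickness = rng.uniform(0.06, 0.12)
        bg += 0.22 * np.exp(-((rho - 1.0) / thickness) ** 2)
    return np.clip(bg, 0.0, 0.7)


def _tumor_mask(rng: np.random.Generator, h: int, w: int,
                spec: PhantomSpec) -> np.ndarray:
    """Rasterize one irregular tumor blob as a boolean mask."""
    lo, hi = spec.tumor_radius_frac
    r0 = rng.uniform(lo, hi) * min(h, w)
    margin = r0 * 1.3
    cy = rng.uniform(margin, h - margin) if h > 2 * margin else h / 2
    cx = rng.uniform(margin, w - margin) if w > 2 * margin else w / 2
    ecc = rng.uniform(0.6, 1.0)
    phi = rng.uniform(0, np.pi)
    # low-order Fourier perturbation of the boundary radius
    orders = np.arange(2, 6)
    amp_cos = rng.normal(size=orders.size) / orders
    amp_sin = rng.normal(size=orders.size) / orders
    yy, xx = np.mgrid[0:h, 0:w]
    yr = (yy - cy) * np.cos(phi) + (xx - cx) * np.sin(phi)
    xr = -(yy - cy) * np.sin(phi) + (xx - cx) * np.cos(phi)
    rho = np.sqrt((yr / r0) ** 2 + (xr / (r0 * ecc)) ** 2)
    theta = np.arctan2(xr, yr)
    wobble = sum(ac * np.cos(k * theta) + as_ * np.sin(k * theta)
                 for k, ac, as_ in zip(orders, amp_cos, amp_sin))
    boundary = np.clip(1.0 + spec.boundary_irregularity * wobble, 0.3, None)
    return rho <= boundary


def generate_phantom(spec: PhantomSpec, index: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministically generate phantom ``index``: ``(image, mask)``.

    The image is ``background + contrast * mask + N(0, noise_sigma)``
    clipped to [0, 1]; the mask is the exact noiseless tumor geometry.
    """
    h, w = spec.size
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, int(index)]))
    bg = _background(rng, h, w, spec.bone_structures)
    n_tumors = int(rng.integers(spec.n_tumors[0], spec.n_tumors[1] + 1))
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_tumors):
        mask |= _tumor_mask(rng, h, w, spec)
    image = bg + spec.contrast * mask
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    return np.clip(image, 0.0, 1.0), mask.astype(np.uint8)


def generate_dataset(spec: PhantomSpec, n: int,
                     slices_per_patient: int = 5) -> list[Sample]:
    """Generate ``n`` samples grouped into synthetic patients.

    Slices are assigned to patients in consecutive groups (default 5 per
    patient) so patient-level splitting is exercised realistically.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    samples = []
    for i in range(n):
        image, mask = generate_phantom(spec, i)
        samples.append(Sample(
            image=image, mask=mask,
            patient_id=f"patient{i // slices_per_patient:04d}",
            slice_id=f"slice{i:05d}",
        ))
    return samples


def write_dataset(samples: list[Sample], out_dir) -> Path:
    """Write PNG image/mask pairs and a manifest CSV; returns the manifest path."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        img_path = out_dir / "images" / f"{s.slice_id}.png"
        mask_path = out_dir / "masks" / f"{s.slice_id}.png"
        iio.imwrite(img_path, (np.clip(s.image, 0, 1) * 255).astype(np.uint8))
        iio.imwrite(mask_path, (s.mask.astype(np.uint8) * 255))
        rows.append({"patient_id": s.patient_id, "slice_id": s.slice_id,
                     "image": str(img_path.relative_to(out_dir)),
                     "mask": str(mask_path.relative_to(out_dir))})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame.from_records(rows).to_csv(manifest, index=False)
    return manifest
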