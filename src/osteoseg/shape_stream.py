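"""Gated shape stream: an auxiliary boundary-prediction path.

Tumor boundaries in MRI are often ambiguous where the lesion fuses with
bone or soft tissue.  The shape stream keeps a full-resolution feature map
``S`` focused on boundary evidence.  At each step a single-channel
attention map

    alpha = sigmoid( Conv1x1( [S, D] ) )

is computed from ``S`` and the deep semantic feature ``D`` (bilinearly
resampled so spatial dims match), and the stream is updated by gating then
a residual block: ``S <- F(S * alpha)``.  Encoder taps are injected into
the stream step by step so boundary evidence from all depths contributes.
Finally ``S`` is concatenated with the Sobel gradient magnitude of the raw
image and projected to single-channel edge logits at input resolution; the
stream's features are also returned for fusion with the segmentation path.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .blocks import FBlock
from .nn import Conv2d, Module, bilinear_resize, concat, sigmoid
from .nn.tensor import Tensor, as_tensor

__all__ = ["GateUnit", "shape_flow_step", "image_gradient", "GatedShapeStream",
           "boundary_target"]


def image_gradient(img: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude, min-max normalized to [0, 1].

    Accepts a single slice ``(H, W)`` or a batch ``(N, H, W)``; a constant
    image maps to an all-zero gradient map.
    """
    img = np.asarray(img, dtype=float)
    single = img.ndim == 2
    batch = img[None] if single else img
    out = np.empty_like(batch)
    for i, sl in enumerate(batch):
        gx = ndimage.sobel(sl, axis=1, mode="reflect")
        gy = ndimage.sobel(sl, axis=0, mode="reflect")
        mag = np.hypot(gx, gy)
        peak = mag.max()
        out[i] = mag / peak if peak > 0 else 0.0
    return out[0] if single else out


def boundary_target(mask: np.ndarray) -> np.ndarray:
    """Morphological gradient of a binary mask: 1-pixel boundary raster.

    Dilation minus erosion with a 3x3 structuring element — the standard
    edge-supervision target when only region masks are annotated.
    """
    mask = np.asarray(mask) > 0
    if mask.ndim == 2:
        mask = mask[None]
        squeeze = True
    else:
        squeeze = False
    struct = np.ones((3, 3), dtype=bool)
    out = np.empty(mask.shape, dtype=float)
    for i, m in enumerate(mask):
        dil = ndimage.binary_dilation(m, structure=struct)
        ero = ndimage.binary_erosion(m, structure=struct)
        out[i] = (dil & ~ero).astype(float)
    return out[0] if squeeze else out


class GateUnit(Module):
    """Attention map ``alpha = sigmoid(Conv1x1([S, resize(D)]))`` in (0,1)."""

    def __init__(self, s_channels: int, d_channels: int,
                 rng: np.random.Generator | None = None,
                 negative_slope: float = 0.01):
        super().__init__()
        self.conv = Conv2d(s_channels + d_channels, 1, 1, rng=rng,
                           negative_slope=negative_slope)

    def forward(self, s, d):
        s, d = as_tensor(s), as_tensor(d)
        d_resized = bilinear_resize(d, s.shape[1:3])
        return sigmoid(self.conv(concat([s, d_resized], axis=-1)))


def shape_flow_step(s, alpha, residual_block: FBlock):
    """One gated update of the shape stream: ``F(S * alpha)``."""
    return residual_block(as_tensor(s) * as_tensor(alpha))


class GatedShapeStream(Module):
    """Full-resolution boundary stream over the encoder taps."""

    def __init__(self, tap_channels, d_channels: int, width: int = 16,
                 rng: np.random.Generator | None = None,
                 negative_slope: float = 0.01):
        super().__init__()
        if len(tap_channels) < 1:
            raise ValueError("at least one encoder tap is required")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.width = width
        self.proj0 = Conv2d(tap_channels[0], width, 1, rng=rng,
                            negative_slope=negative_slope)
        self.tap_projs = [Conv2d(c, width, 1, rng=rng, negative_slope=negative_slope)
                          for c in tap_channels[1:]]
        self.gates = [GateUnit(width, d_channels, rng=rng,
                               negative_slope=negative_slope)
                      for _ in tap_channels[1:]]
        self.residuals = [FBlock(width, rng=rng, negative_slope=negative_slope)
                          for _ in tap_channels[1:]]
        self.edge_head = Conv2d(width + 1, 1, 1, rng=rng,
                                negative_slope=negative_slope)

    def forward(self, taps, d, image):
        """Run the stream.

        Parameters
        ----------
        taps:
            Encoder feature maps ordered fine to coarse; the first defines
            the stream's (full) resolution.
        d:
            Deep semantic feature driving the gates (any resolution).
        image:
            Raw input batch ``(N, H, W)`` or ``(N, H, W, 1)`` as an array;
            only its Sobel gradient enters the stream.

        Returns
        -------
        (shape_features, edge_logits):
            Stream features ``(N, H, W, width)`` and single-channel edge
            logits at input resolution.
        """
        if len(taps) == 0:
            raise ValueError("empty encoder tap list")
        img = np.asarray(image.data if isinstance(image, Tensor) else image)
        if img.ndim == 4:
            img = img[..., 0]

        s = self.proj0(as_tensor(taps[0]))
        grad = Tensor(image_gradient(img)[..., None].astype(s.data.dtype))
        hw = s.shape[1:3]
        for tap, proj, gate, res in zip(taps[1:], self.tap_projs,
                                        self.gates, self.residuals):
            s = s + proj(bilinear_resize(as_tensor(tap), hw))
            alpha = gate(s, d)
            s = shape_flow_step(s, alpha, res)
        edge_logits = self.edge_head(concat([s, grad], axis=-1))
        return s, edge_logits
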