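"""Full segmentation network: encoders, multiscale fusion, gated shape
stream and attention decoders.

Data flow for an input batch ``(N, H, W, 1)`` with ``H, W`` divisible by 16:

1. Four encoders (two ``H`` convolutions + squeeze-excitation, dropout
   p=0.2 in training, 2x max pooling between stages) produce taps at
   scales 1, 1/2, 1/4 and 1/8 with widths ``base * {1, 2, 4, 8}``.
2. The multiscale fusion subnetwork exchanges features across all four
   scales (six pairwise exchange blocks per layer, four layers, first-layer
   residual).
3. A stride-2 ``C`` block on the fused coarsest scale forms the 1/16
   bottleneck that seeds the decoder chain; each fused scale passes an
   ``F`` block and serves as the skip input of one of four decoder blocks,
   which restore full resolution (x2 per block).
4. The gated shape stream runs over the encoder taps, driven by the fused
   coarsest scale, and produces single-channel edge logits; its features
   are fused (``F`` on the concatenation) with the last decoder output
   before the 1x1 mask head.

Outputs are logits; apply a sigmoid and threshold at 0.5 for masks.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .blocks import CBlock, FBlock, HBlock, SEBlock
from .exchange import ExchangeConfig
from .fusion import FusionConfig, MultiscaleFusion
from .nn import Conv2d, Module, concat, dropout, max_pool2, sigmoid
from .nn.tensor import Tensor
from .shape_stream import GatedShapeStream

__all__ = ["ModelConfig", "SegOutput", "SegmentationNet", "small_config",
           "count_parameters", "save_checkpoint", "load_checkpoint",
           "pad_to_multiple"]


@dataclass
class ModelConfig:
    """Hyperparameters of the full network."""

    base_channels: int = 32
    input_size: tuple[int, int] = (512, 512)
    dropout_p: float = 0.2
    negative_slope: float = 0.01
    se_reduction: int = 8
    shape_flow_enabled: bool = True
    shape_width: int = 16
    fusion: FusionConfig = field(default_factory=FusionConfig)
    seed: int = 0

    def __post_init__(self):
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ValueError(f"input size must be divisible by 16, got {h}x{w}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "fusion" in d and isinstance(d["fusion"], dict):
            fd = dict(d["fusion"])
            if "exchange" in fd and isinstance(fd["exchange"], dict):
                fd["exchange"] = ExchangeConfig(**fd["exchange"])
            d["fusion"] = FusionConfig(**fd)
        if "input_size" in d:
            d["input_size"] = tuple(d["input_size"])
        return cls(**d)


def small_config(seed: int = 0) -> ModelConfig:
    """Desk-scale preset: 64x64 inputs, narrow widths, light fusion graph."""
    return ModelConfig(
        base_channels=8,
        input_size=(64, 64),
        fusion=FusionConfig(n_layers=2, pairing="adjacent"),
        seed=seed,
    )


@dataclass
class SegOutput:
    """Network output: mask logits and (optionally) edge logits."""

    mask_logits: Tensor
    edge_logits: Tensor | None


class Encoder(Module):
    """Two ``H`` convolutions followed by squeeze-and-excitation."""

    def __init__(self, in_channels: int, out_channels: int, se_reduction: int,
                 rng: np.random.Generator, negative_slope: float):
        super().__init__()
        self.h1 = HBlock(in_channels, out_channels, rng=rng,
                         negative_slope=negative_slope)
        self.h2 = HBlock(out_channels, out_channels, rng=rng,
                         negative_slope=negative_slope)
        self.se = SEBlock(out_channels, reduction=se_reduction, rng=rng,
                          negative_slope=negative_slope)

    def forward(self, x):
        return self.se(self.h2(self.h1(x)))


class SegmentationNet(Module):
    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        cfg = config if config is not None else ModelConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng((cfg.seed, 1))
        b = cfg.base_channels
        ns = cfg.negative_slope
        widths = [b, 2 * b, 4 * b, 8 * b]
        self.widths = widths

        self.encoders = [
            Encoder(1 if r == 0 else widths[r - 1], widths[r],
                    cfg.se_reduction, rng, ns)
            for r in range(4)
        ]
        self.fusion = MultiscaleFusion(widths, cfg.fusion, rng=rng)
        self.skip_blocks = [FBlock(w, rng=rng, negative_slope=ns) for w in widths]
        self.bottleneck = CBlock(8 * b, 16 * b, rng=rng, negative_slope=ns)

        from .decoder import DecoderBlock  # local import avoids a cycle in docs builds

        self.decoders = [
            DecoderBlock(widths[3], 16 * b, widths[3], cfg.se_reduction, rng, ns),
            DecoderBlock(widths[2], widths[3], widths[2], cfg.se_reduction, rng, ns),
            DecoderBlock(widths[1], widths[2], widths[1], cfg.se_reduction, rng, ns),
            DecoderBlock(widths[0], widths[1], widths[0], cfg.se_reduction, rng, ns),
        ]
        if cfg.shape_flow_enabled:
            self.shape_stream = GatedShapeStream(widths, widths[3],
                                                 width=cfg.shape_width,
                                                 rng=rng, negative_slope=ns)
            self.fuse = FBlock(cfg.shape_width + b, rng=rng, negative_slope=ns)
            self.head = Conv2d(cfg.shape_width + b, 1, 1, rng=rng,
                               negative_slope=ns)
        else:
            self.head = Conv2d(b, 1, 1, rng=rng, negative_slope=ns)

    # -- pieces ----------------------------------------------------------
    @staticmethod
    def _as_batch(x) -> Tensor:
        if isinstance(x, Tensor):
            return x
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        if x.ndim != 4 or x.shape[-1] != 1:
            raise ValueError("expected a batch of single-channel slices "
                             "(N, H, W) or (N, H, W, 1)")
        return Tensor(x)

    def encode(self, x) -> list:
        """Encoder taps at scales 1, 1/2, 1/4, 1/8 (widths ``base*2^r``)."""
        x = self._as_batch(x)
        _, h, w, _ = x.shape
        if h % 16 or w % 16:
            raise ValueError(f"input spatial dims must be divisible by 16, got {h}x{w}")
        taps = []
        t = x
        for i, enc in enumerate(self.encoders):
            y = enc(t)
            y = dropout(y, self.config.dropout_p, self._dropout_rng,
                        training=self.training)
            taps.append(y)
            if i < 3:
                t = max_pool2(y)
        return taps

    def forward(self, x) -> SegOutput:
        x = self._as_batch(x)
        taps = self.encode(x)
        fused = self.fusion(taps)
        skips = [blk(f) for blk, f in zip(self.skip_blocks, fused)]
        p = self.bottleneck(fused[3])
        for dec, skip in zip(self.decoders, reversed(skips)):
            p = dec(skip, p)
        if self.config.shape_flow_enabled:
            shape_feat, edge_logits = self.shape_stream(taps, fused[3], x)
            mask_logits = self.head(self.fuse(concat([shape_feat, p], axis=-1)))
        else:
            edge_logits = None
            mask_logits = self.head(p)
        return SegOutput(mask_logits=mask_logits, edge_logits=edge_logits)

    # -- inference helpers -----------------------------------------------
    def predict_proba(self, images, batch_size: int = 8) -> np.ndarray:
        """Tumor probabilities for ``(N, H, W)`` inputs of any size.

        Inputs whose spatial dims are not divisible by 16 are reflect-padded
        and the output is cropped back.
        """
        images = np.asarray(images, dtype=float)
        if images.ndim == 2:
            images = images[None]
        was_training = self.training
        self.eval()
        try:
            padded, crop = pad_to_multiple(images, 16)
            probs = []
            for start in range(0, len(padded), batch_size):
                chunk = padded[start:start + batch_size]
                out = self.forward(chunk)
                probs.append(sigmoid(out.mask_logits).data[..., 0])
            full = np.concatenate(probs, axis=0)
        finally:
            self.train(was_training)
        return full[:, crop[0]:crop[1], crop[2]:crop[3]]

    def predict(self, images, batch_size: int = 8,
                threshold: float = 0.5) -> np.ndarray:
        """Binary tumor masks (sigmoid then threshold, default 0.5)."""
        return (self.predict_proba(images, batch_size) >= threshold).astype(np.uint8)


def pad_to_multiple(images: np.ndarray, multiple: int):
    """Reflect-pad ``(N, H, W)`` so H and W divide ``multiple``.

    Returns the padded batch and the crop window ``(h0, h1, w0, w1)`` that
    recovers the original extent.
    """
    n, h, w = images.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    padded = np.pad(images, ((0, 0), (0, ph), (0, pw)), mode="reflect") \
        if (ph or pw) else images
    return padded, (0, h, 0, w)


def count_parameters(config_or_model) -> int:
    """Exact count of trainable scalars for a config or a built network."""
    if isinstance(config_or_model, Module):
        return config_or_model.n_parameters()
    return SegmentationNet(config_or_model).n_parameters()


def save_checkpoint(model: SegmentationNet, path) -> None:
    """Single-file checkpoint (.npz) with the config embedded as YAML.

    A sidecar ``<path>.yaml`` with the same config is written so the
    checkpoint is self-describing as plain text too.
    """
    path = Path(path)
    cfg_yaml = yaml.safe_dump(model.config.to_dict())
    state = model.state_dict()
    np.savez(path, __config__=np.frombuffer(cfg_yaml.encode(), dtype=np.uint8),
             **state)
    Path(str(path) + ".yaml").write_text(cfg_yaml)


def load_checkpoint(path) -> SegmentationNet:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as data:
        cfg_yaml = bytes(data["__config__"]).decode()
        state = {k: data[k] for k in data.files if k != "__config__"}
    cfg = ModelConfig.from_dict(yaml.safe_load(cfg_yaml))
    model = SegmentationNet(cfg)
    model.load_state_dict(state)
    return model
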