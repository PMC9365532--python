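"""Layer containers for the autodiff engine.

:class:`Module` discovers parameters and submodules by attribute walking (as
the major frameworks do), supports recursive ``state_dict`` round trips and a
train/eval mode flag. Convolutions are initialized He-style with the
LeakyReLU gain; biases start at zero.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, conv_transpose2d, matmul

__all__ = ["Module", "Parameter", "Conv2d", "ConvTranspose2d", "Linear",
           "DEFAULT_DTYPE"]

# Single precision by default: ample for segmentation and twice the
# throughput of float64 on the NumPy backend. Assign float64 arrays to
# ``Parameter.data`` directly when exact arithmetic is wanted.
DEFAULT_DTYPE = np.float32


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DEFAULT_DTYPE), requires_grad=True)


class Module:
    """Base class: parameter discovery, state dicts, train/eval mode."""

    def __init__(self):
        self.training = True

    # -- traversal --------------------------------------------------------
    def _children(self):
        for name in sorted(vars(self)):
            value = getattr(self, name)
            if isinstance(value, (Parameter, Module)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, (Parameter, Module)):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, child in self._children():
            full = f"{prefix}{name}"
            if isinstance(child, Parameter):
                yield full, child
            else:
                yield from child.named_parameters(prefix=full + ".")

    def parameters(self) -> list:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, child in self._children():
            if isinstance(child, Module):
                yield from child.modules()

    # -- state ------------------------------------------------------------
    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def zero_init(self) -> None:
        """Set every parameter to zero (useful for identity-map probes)."""
        for p in self.parameters():
            p.data = np.zeros_like(p.data)

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict is missing parameters: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype, copy=True)

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_std(fan_in: int, negative_slope: float) -> float:
    gain2 = 2.0 / (1.0 + negative_slope**2)
    return float(np.sqrt(gain2 / max(fan_in, 1)))


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, rng: np.random.Generator | None = None,
                 negative_slope: float = 0.01):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        k = kernel_size
        std = _he_std(k * k * in_channels, negative_slope)
        self.weight = Parameter(rng.normal(0.0, std, (k, k, in_channels, out_channels)))
        self.bias = Parameter(np.zeros(out_channels))
        self.stride = stride

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride)


class ConvTranspose2d(Module):
    """Stride-2 transposed convolution doubling the spatial size."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None,
                 negative_slope: float = 0.01):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        k = kernel_size
        std = _he_std(k * k * in_channels, negative_slope)
        self.weight = Parameter(rng.normal(0.0, std, (k, k, in_channels, out_channels)))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None,
                 negative_slope: float = 0.01):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        std = _he_std(in_features, negative_slope)
        self.weight = Parameter(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x):
        return matmul(x, self.weight) + self.bias
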