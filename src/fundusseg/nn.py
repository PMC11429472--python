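"""Neural-network layers built on :mod:`fundusseg.autograd`.

Convolutions are expressed as compositions of autodiff primitives:

* 1x1 convolutions are batched matrix products over the channel axis;
* k x k depthwise convolutions are shift-and-add sums over kernel offsets;
* strided k x k convolutions loop over kernel offsets with strided slices;
* transposed convolutions zero-interleave the input and then correlate with
  the spatially flipped kernel, with the output size asserted exactly.

Every layer takes a ``numpy.random.Generator`` at construction so that model
initialisation is a pure function of the seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor, concatenate

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Linear",
    "Conv1x1",
    "DepthwiseConv2d",
    "Conv2d",
    "ConvTranspose2d",
    "LayerNorm",
    "softmax",
    "trunc_normal",
]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) samples clipped at two standard deviations."""
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2.0 * std, 2.0 * std).astype(np.float32)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal parameter container with recursive discovery."""

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    @staticmethod
    def _walk(value, path: str):
        if isinstance(value, Parameter):
            yield path, value
        elif isinstance(value, Module):
            yield from value.named_parameters(prefix=path + ".")
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                yield from Module._walk(item, f"{path}.{i}")

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            yield from Module._walk(value, f"{prefix}{name}")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = sorted(set(own) - set(state))
        unexpected = sorted(set(state) - set(own))
        if missing or unexpected:
            raise KeyError(f"state mismatch; missing={missing[:5]}, unexpected={unexpected[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data = np.asarray(state[name], dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, std: float = 0.02):
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features), std))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = as_tensor(x) @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv1x1(Module):
    """Pointwise convolution on NCHW tensors."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 bias: bool = True):
        std = float(np.sqrt(2.0 / in_channels))
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        n, c, h, w = x.shape
        y = self.weight @ x.reshape(n, c, h * w)
        if self.bias is not None:
            y = y + self.bias.reshape(1, -1, 1)
        return y.reshape(n, -1, h, w)


class DepthwiseConv2d(Module):
    """k x k depthwise convolution, stride 1, 'same' zero padding."""

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator):
        k = kernel_size
        std = float(np.sqrt(2.0 / (k * k)))
        self.kernel_size = k
        self.weight = Parameter(rng.normal(0.0, std, (channels, k, k)).astype(np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        n, c, h, w = x.shape
        k = self.kernel_size
        p = k // 2
        xp = x.pad(((0, 0), (0, 0), (p, p), (p, p)))
        out = None
        for u in range(k):
            for v in range(k):
                term = xp[:, :, u:u + h, v:v + w] * self.weight[:, u, v].reshape(1, c, 1, 1)
                out = term if out is None else out + term
        return out + self.bias.reshape(1, c, 1, 1)


class Conv2d(Module):
    """General strided convolution (used by the ResNet-style fallback branch)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        k = kernel_size
        std = float(np.sqrt(2.0 / (in_channels * k * k)))
        self.kernel_size, self.stride, self.padding = k, stride, padding
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, k, k)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        n, c, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = x.pad(((0, 0), (0, 0), (p, p), (p, p))) if p else x
        out = None
        for u in range(k):
            for v in range(k):
                sl = xp[:, :, u:u + (ho - 1) * s + 1:s, v:v + (wo - 1) * s + 1:s]
                term = self.weight[:, :, u, v] @ sl.reshape(n, c, ho * wo)
                out = term if out is None else out + term
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1)
        return out.reshape(n, -1, ho, wo)


def _zero_interleave(x: Tensor, stride: int) -> Tensor:
    """Insert ``stride - 1`` zeros between spatial elements (transposed-conv core)."""
    n, c, h, w = x.shape
    hs, ws = (h - 1) * stride + 1, (w - 1) * stride + 1
    data = np.zeros((n, c, hs, ws), dtype=x.data.dtype)
    data[:, :, ::stride, ::stride] = x.data

    def bwd(g, a=x, s=stride):
        a._accumulate(g[:, :, ::s, ::s])

    return Tensor._make(data, (x,), bwd)


class ConvTranspose2d(Module):
    """Transposed convolution; output size is asserted, never silently cropped."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 output_padding: int = 0):
        k = kernel_size
        std = float(np.sqrt(2.0 / (in_channels * k * k)))
        self.kernel_size, self.stride = k, stride
        self.padding, self.output_padding = padding, output_padding
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, k, k)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))

    def output_size(self, h: int) -> int:
        return (h - 1) * self.stride - 2 * self.padding + self.kernel_size + self.output_padding

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        n, c, h, w = x.shape
        k, s, p, op = self.kernel_size, self.stride, self.padding, self.output_padding
        ho, wo = self.output_size(h), self.output_size(w)
        if ho <= 0 or wo <= 0:
            raise ValueError(f"transposed conv produces empty output for input {h}x{w} "
                             f"(k={k}, stride={s}, padding={p})")
        xi = _zero_interleave(x, s) if s > 1 else x
        lo = k - 1 - p
        hi_h = ho - ((h - 1) * s + 1) - lo + (k - 1)
        hi_w = wo - ((w - 1) * s + 1) - lo + (k - 1)
        if lo < 0 or hi_h < 0 or hi_w < 0:
            raise ValueError(f"invalid transposed-conv geometry (k={k}, stride={s}, padding={p}, "
                             f"output_padding={op})")
        xp = xi.pad(((0, 0), (0, 0), (lo, hi_h), (lo, hi_w)))
        out = None
        for u in range(k):
            for v in range(k):
                sl = xp[:, :, u:u + ho, v:v + wo]
                # correlate with the flipped kernel
                term = self.weight[:, :, k - 1 - u, k - 1 - v] @ sl.reshape(n, c, ho * wo)
                out = term if out is None else out + term
        out = out + self.bias.reshape(1, -1, 1)
        out = out.reshape(n, -1, ho, wo)
        assert out.shape[2] == ho and out.shape[3] == wo
        return out


class LayerNorm(Module):
    """Layer normalisation over one axis (last for tokens, 1 for NCHW maps)."""

    def __init__(self, dim: int, axis: int = -1, eps: float = 1e-6):
        self.dim, self.axis, self.eps = dim, axis, eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        ax = self.axis if self.axis >= 0 else x.ndim + self.axis
        mu = x.mean(axis=ax, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=ax, keepdims=True)
        inv = (var + self.eps) ** -0.5
        shape = [1] * x.ndim
        shape[ax] = self.dim
        return xc * inv * self.weight.reshape(shape) + self.bias.reshape(shape)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def cat(tensors, axis: int = 0) -> Tensor:
    return concatenate(tensors, axis=axis)
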