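"""Neural-network layers built on the autodiff engine.

Channels-first layout ``(N, C, *spatial)`` throughout; 2D and 3D share
the same n-dimensional convolution primitives. Weight init is a
fan-in-scaled normal drawn from an explicit ``numpy`` generator, so every
model is reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    def __init__(self):
        self._params: list[Tensor] = []
        self._modules: list[Module] = []

    def register(self, *tensors: Tensor) -> None:
        self._params.extend(tensors)

    def add_module(self, module: "Module") -> "Module":
        self._modules.append(module)
        return module

    def parameters(self) -> list[Tensor]:
        out = list(self._params)
        for m in self._modules:
            out.extend(m.parameters())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"state has {len(arrays)} arrays, model has {len(params)} parameters")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(p.data.dtype, copy=True)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def _he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv(Module):
    """n-D convolution, kernel size k, optional stride and same/valid padding."""

    def __init__(self, nd, in_ch, out_ch, kernel, stride=1, pad=None, rng=None,
                 dtype=np.float32, zero_init=False, init_scale=1.0):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        kshape = (kernel,) * nd
        fan_in = in_ch * kernel**nd
        w = np.zeros((out_ch, in_ch) + kshape, dtype=dtype) if zero_init else (
            init_scale * _he_normal(rng, (out_ch, in_ch) + kshape, fan_in, dtype)
        )
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        self.register(self.w, self.b)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_nd(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ConvTranspose(Module):
    """n-D transposed convolution with kernel = stride (exact upscaling)."""

    def __init__(self, nd, in_ch, out_ch, stride=2, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        kshape = (stride,) * nd
        self.w = Tensor(_he_normal(rng, (in_ch, out_ch) + kshape, in_ch, dtype), requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.register(self.w, self.b)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose_nd(x, self.w, self.b, stride=self.stride)


class GroupNorm(Module):
    """Group normalization over channel groups; batch-size independent."""

    def __init__(self, channels, groups, eps=1e-5, dtype=np.float32):
        super().__init__()
        if channels % groups != 0:
            raise ValueError(f"groups={groups} does not divide channels={channels}")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.register(self.gamma, self.beta)

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        spatial = x.shape[2:]
        g = self.groups
        xg = x.reshape(n, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        centered = xg - mu
        var = (centered * centered).mean(axis=2, keepdims=True)
        xhat = centered / ag.sqrt(var + self.eps)
        xhat = xhat.reshape((n, self.channels) + spatial)
        shape = (1, self.channels) + (1,) * len(spatial)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class InstanceNorm(GroupNorm):
    """Per-channel, per-sample normalization (group size 1); no affine by default."""

    def __init__(self, channels, eps=1e-5, dtype=np.float32, affine=False):
        super().__init__(channels, groups=channels, eps=eps, dtype=dtype)
        if not affine:
            self._params = []  # gamma/beta stay fixed at identity
            self.gamma.requires_grad = False
            self.beta.requires_grad = False


class LeakyReLU(Module):
    def __init__(self, slope=0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return ag.leaky_relu(x, self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.tanh(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        for m in modules:
            self.add_module(m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self._modules:
            x = m(x)
        return x
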