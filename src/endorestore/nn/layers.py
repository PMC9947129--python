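"""Trainable layers built on the autodiff tensor."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d"]

_DTYPE = np.float32


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _submodules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._submodules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        """All persistent arrays (parameters then buffers), in a stable order."""
        arrays = [p.data for p in self.parameters()]
        arrays.extend(self.buffers())
        return arrays

    def buffers(self) -> list[np.ndarray]:
        bufs: list[np.ndarray] = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                bufs.extend(v.buffers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        bufs.extend(item.buffers())
        bufs.extend(getattr(self, "_buffers", []))
        return bufs


class Conv2d(Module):
    """3x3 (or 1x1) convolution with 'same' zero padding by default.

    He-normal initialization, seeded through the generator passed in.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, padding: int | None = None):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.padding = padding
        std = np.sqrt(2.0 / (in_ch * kernel * kernel))
        w = rng.standard_normal((out_ch, in_ch, kernel, kernel)) * std
        self.weight = Tensor(w.astype(_DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=_DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=1, padding=self.padding)


class ConvTranspose2d(Module):
    """2x2 stride-2 up-convolution (doubles H and W)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 stride: int = 2):
        super().__init__()
        self.stride = stride
        std = np.sqrt(2.0 / (in_ch * stride * stride))
        w = rng.standard_normal((in_ch, out_ch, stride, stride)) * std
        self.weight = Tensor(w.astype(_DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=_DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, num_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(num_ch, dtype=_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(num_ch, dtype=_DTYPE), requires_grad=True)
        self.running_mean = np.zeros(num_ch, dtype=_DTYPE)
        self.running_var = np.ones(num_ch, dtype=_DTYPE)
        self._buffers = [self.running_mean, self.running_var]

    def __call__(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training,
                              self.momentum, self.eps)
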