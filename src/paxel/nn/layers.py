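"""Layer modules and the Adam optimizer for the numpy autodiff engine."""

from __future__ import annotations

import numpy as np

from paxel.nn.autograd import (
    Tensor,
    batchnorm,
    conv2d,
    conv_transpose2x2,
    relu,
)

__all__ = ["Module", "Conv2d", "ConvTranspose2x2", "BatchNorm2d", "Adam"]


class Module:
    """Base class: parameter discovery by attribute walk."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in vars(self).values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def train(self) -> None:
        self._set_mode(True)

    def eval(self) -> None:
        self._set_mode(False)

    def _set_mode(self, mode: bool) -> None:
        self.training = mode
        for v in vars(self).values():
            for m in _collect_modules(v):
                m._set_mode(mode)

    def state_arrays(self) -> list[np.ndarray]:
        """All learned arrays (parameters plus batch-norm running stats)."""
        arrays = [p.data for p in self.parameters()]
        for v in vars(self).values():
            for m in _collect_modules(v):
                if isinstance(m, BatchNorm2d):
                    arrays.extend([m.running["mean"], m.running["var"]])
        return arrays


def _collect(v) -> list[Tensor]:
    if isinstance(v, Tensor) and v.requires_grad:
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _collect_modules(v) -> list["Module"]:
    if isinstance(v, Module):
        return [v]
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect_modules(item))
        return out
    return []


class Conv2d(Module):
    """Stride-1 same-padding convolution with He-normal initialization."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        fan_in = in_ch * k * k
        if zero_init:
            w = np.zeros((out_ch, in_ch, k, k), dtype=np.float32)
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(out_ch, in_ch, k, k)).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class ConvTranspose2x2(Module):
    """2 x 2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        fan_in = in_ch * 4
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(in_ch, out_ch, 2, 2)).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running = {"mean": np.zeros(channels, dtype=np.float32),
                        "var": np.ones(channels, dtype=np.float32)}
        self.momentum = momentum

    def __call__(self, x: Tensor) -> Tensor:
        return batchnorm(x, self.gamma, self.beta, self.running,
                         training=self.training, momentum=self.momentum)


def bn_relu_conv(bn: BatchNorm2d, conv: Conv2d, x: Tensor) -> Tensor:
    return conv(relu(bn(x)))


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
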