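"""Neural-network building blocks on top of the autodiff engine.

Provides the convolutional layer, batch normalisation and the Adam optimiser
used by the learned regularisers.  Everything operates on float64 numpy
arrays for bit-reproducibility under a fixed seed.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Conv", "BatchNorm", "Parameter", "Module", "Adam", "he_init"]


def Parameter(data) -> Tensor:
    """A trainable leaf tensor."""
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def he_init(rng: np.random.Generator, out_ch: int, in_ch: int, kshape: tuple) -> np.ndarray:
    fan_in = in_ch * int(np.prod(kshape))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch) + tuple(kshape))


class Module:
    """Base class with parameter traversal and state (de)serialisation."""

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                out[prefix + k] = v.data.copy()
            elif isinstance(v, np.ndarray):
                out[prefix + k] = v.copy()
            elif isinstance(v, Module):
                out.update(v.state_dict(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_dict(f"{prefix}{k}.{i}."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor):
                v.data = np.array(state[prefix + k], dtype=np.float64)
            elif isinstance(v, np.ndarray):
                self.__dict__[k] = np.array(state[prefix + k])
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix + k + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{prefix}{k}.{i}.")


class Conv(Module):
    """Stride-1, zero-padded ('same') convolution for 2D or 3D images."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple,
                 rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((out_ch, in_ch) + tuple(kernel))
        else:
            w = he_init(rng, out_ch, in_ch, tuple(kernel))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch))

    def __call__(self, x):
        return ad.conv_nd(x, self.weight, self.bias)


class BatchNorm(Module):
    """Per-channel batch normalisation.

    Batch statistics during training (with a batch of one this degenerates to
    per-instance normalisation), exponential running averages at evaluation.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(n_ch))
        self.beta = Parameter(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self._eps = eps
        self._momentum = momentum

    def __call__(self, x, training: bool):
        xd = x.data if isinstance(x, Tensor) else x
        d = xd.ndim - 2
        bshape = (1, -1) + (1,) * d
        axes = (0,) + tuple(range(2, 2 + d))
        if training:
            n = xd.shape[0] * int(np.prod(xd.shape[2:]))
            mu = ad.mul(ad.sum_(x, axis=axes, keepdims=True), 1.0 / n)
            xc = ad.add(x, ad.mul(mu, -1.0))
            var = ad.mul(ad.sum_(ad.mul(xc, xc), axis=axes, keepdims=True), 1.0 / n)
            m = self._momentum
            self.running_mean = (1 - m) * self.running_mean + m * (
                mu.data if isinstance(mu, Tensor) else mu).reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * (
                var.data if isinstance(var, Tensor) else var).reshape(-1)
            inv = ad.div(1.0, ad.sqrt(ad.add(var, self._eps)))
            xhat = ad.mul(xc, inv)
        else:
            mu = self.running_mean.reshape(bshape)
            inv = 1.0 / np.sqrt(self.running_var + self._eps)
            xhat = ad.mul(ad.add(x, -mu), inv.reshape(bshape))
        g = ad.reshape(self.gamma, bshape)
        b = ad.reshape(self.beta, bshape)
        return ad.add(ad.mul(xhat, g), b)


def calibrate_batchnorm(module: Module):
    """Context-free helper: set every BatchNorm momentum to 1 so the next
    training-mode forward overwrites the running averages with the exact
    statistics of that pass; restore afterwards via the returned callable."""
    bns = [m for m in _walk(module) if isinstance(m, BatchNorm)]
    saved = [(bn, bn._momentum) for bn in bns]
    for bn in bns:
        bn._momentum = 1.0

    def restore():
        for bn, m in saved:
            bn._momentum = m

    return restore


def _walk(module: Module):
    yield module
    for v in module.__dict__.values():
        if isinstance(v, Module):
            yield from _walk(v)
        elif isinstance(v, (list, tuple)):
            for item in v:
                if isinstance(item, Module):
                    yield from _walk(item)


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
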