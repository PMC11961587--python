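"""Layers, parameter management and optimizers on top of the autodiff engine.

Deliberately small: just the pieces the encoder/decoder need.  Every layer
draws its initial weights from an explicit ``numpy.random.Generator`` so
that model construction is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (DTYPE, Tensor, as_tensor, conv2d, depthwise_conv2d)

__all__ = [
    "Module", "Parameter", "Sequential", "Identity", "Linear", "Conv2d",
    "DepthwiseConv2d", "BatchNorm2d", "ChannelLayerNorm", "SqueezeExcite",
    "SGD", "Adam",
]


def Parameter(array) -> Tensor:
    return Tensor(np.asarray(array, dtype=DTYPE), requires_grad=True)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Module:
    """Base class with recursive parameter/submodule traversal."""

    def __init__(self):
        self.training = True

    # traversal is over __dict__ insertion order -> deterministic
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def _submodules(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
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

    # ---- (de)serialization ------------------------------------------
    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_buffers(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def state_dict(self) -> dict:
        state = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        for k, p in self.named_parameters():
            p.data = np.asarray(state[f"param:{k}"], dtype=DTYPE).copy()
        buffers = dict(self.named_buffers())
        for k, v in buffers.items():
            v[...] = state[f"buffer:{k}"]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x):
        return as_tensor(x)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    """Affine map applied to the trailing axis."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (in_features, out_features),
                                         in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = as_tensor(x) @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int | None = None, bias: bool = True,
                 pad_mode: str = "zero"):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.stride, self.padding, self.pad_mode = stride, padding, pad_mode
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kernel, kernel),
                                         in_ch * kernel * kernel))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, pad_mode=self.pad_mode)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None,
                 bias: bool = True, pad_mode: str = "zero"):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.stride, self.padding, self.pad_mode = stride, padding, pad_mode
        self.weight = Parameter(_kaiming(rng, (channels, kernel, kernel),
                                         kernel * kernel))
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x):
        return depthwise_conv2d(x, self.weight, self.bias, stride=self.stride,
                                padding=self.padding, pad_mode=self.pad_mode)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x):
        x = as_tensor(x)
        C = x.shape[1]
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean[...] = ((1 - m) * self.running_mean
                                      + m * mean.data.reshape(C))
            self.running_var[...] = ((1 - m) * self.running_var
                                     + m * var.data.reshape(C))
            inv = (var + self.eps) ** -0.5
            normed = centered * inv
        else:
            mean = Tensor(self.running_mean.reshape(1, C, 1, 1))
            inv = Tensor(((self.running_var + self.eps) ** -0.5)
                         .reshape(1, C, 1, 1))
            normed = (x - mean) * inv
        w = self.weight.reshape(1, C, 1, 1)
        b = self.bias.reshape(1, C, 1, 1)
        return normed * w + b


class ChannelLayerNorm(Module):
    """Layer normalization over the channel axis of a [B,C,H,W] map."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x):
        x = as_tensor(x)
        C = x.shape[1]
        mean = x.mean(axis=1, keepdims=True)
        centered = x - mean
        var = (centered * centered).mean(axis=1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.weight.reshape(1, C, 1, 1) \
            + self.bias.reshape(1, C, 1, 1)


class SqueezeExcite(Module):
    """Global pool -> bottleneck MLP -> sigmoid channel gate."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 4):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, x):
        x = as_tensor(x)
        B, C = x.shape[:2]
        pooled = x.mean(axis=(2, 3))                      # B, C
        gate = self.fc2(self.fc1(pooled).relu()).sigmoid()
        return x * gate.reshape(B, C, 1, 1)


# ---------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------

class SGD:
    def __init__(self, params, lr: float = 0.05, momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
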