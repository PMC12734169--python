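"""Attention blocks: EMA (efficient multi-scale attention) and ECA
(efficient channel attention).

EMA splits the channels into ``g`` subgroups and runs a three-branch layout
per group: a 1x1 branch built from directional (height-wise and width-wise)
average pooling, a 3x3 local branch, and a cross-spatial aggregation that
forms two attention maps by matrix products between each branch's globally
pooled, softmax-normalised descriptor and the other branch's spatial map.
The input is rescaled by the sigmoid of the summed maps, so channel count
and spatial size are preserved and no channel reduction ever happens.

ECA rescales channels with a sigmoid gate produced by a 1-D convolution
sliding across the globally pooled channel descriptor; its kernel size is
either fixed (odd) or derived from the channel count by the adaptive rule
k = nearest odd to |log2(C) + 1| / 2.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, as_tensor, concat, matmul, sigmoid, softmax, sqrt
from .nn.functional import conv1d_circularless, conv2d
from .nn.layers import Module, Profile


class InvalidInputError(ValueError):
    pass


class ConfigError(ValueError):
    pass


@dataclass
class EmaConfig:
    channels: int
    groups: int = 8

    def __post_init__(self):
        if self.groups < 1 or self.channels % self.groups:
            raise ConfigError(
                f"groups ({self.groups}) must divide channels ({self.channels})"
            )


@dataclass
class EcaConfig:
    kernel: int | str = "adaptive"
    gamma: int = 2
    b: int = 1

    def kernel_for(self, channels: int) -> int:
        if self.kernel == "adaptive":
            t = int(abs(math.log2(channels) + self.b) / self.gamma)
            return t if t % 2 else t + 1
        k = int(self.kernel)
        if k < 1 or k % 2 == 0:
            raise ConfigError(f"ECA kernel must be odd and positive, got {k}")
        return k


def _check(x):
    x = as_tensor(x)
    if x.ndim != 4:
        raise InvalidInputError(f"expected (b,c,h,w), got shape {x.shape}")
    b, c, h, w = x.shape
    if c < 1 or h < 1 or w < 1:
        raise InvalidInputError(f"empty channel/spatial dimension in shape {x.shape}")
    return x


def directional_pool_h(x) -> Tensor:
    """Average pool along the width: (b,c,h,w) -> (b,c,h,1)."""
    x = _check(x)
    return x.mean(axis=3, keepdims=True)


def directional_pool_w(x) -> Tensor:
    """Average pool along the height: (b,c,h,w) -> (b,c,1,w)."""
    x = _check(x)
    return x.mean(axis=2, keepdims=True)


class EMA(Module):
    def __init__(self, channels: int, groups: int = 8, rng=None):
        super().__init__()
        cfg = EmaConfig(channels, groups)
        rng = rng or np.random.default_rng(0)
        self.c, self.g = channels, cfg.groups
        cg = channels // cfg.groups
        self.cg = cg
        self.register("gn_gamma", np.ones(cg))
        self.register("gn_beta", np.zeros(cg))
        self.register("w1", rng.normal(0, np.sqrt(2.0 / cg), (cg, cg, 1, 1)))
        self.register("b1", np.zeros(cg))
        self.register("w3", rng.normal(0, np.sqrt(2.0 / (9 * cg)), (cg, cg, 3, 3)))
        self.register("b3", np.zeros(cg))

    def _group_norm(self, x):
        # one normalisation group per channel, over the spatial extent
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xhat = xc / sqrt(var + 1e-5)
        return xhat * self.gn_gamma.reshape(1, self.cg, 1, 1) + self.gn_beta.reshape(
            1, self.cg, 1, 1
        )

    def forward(self, x):
        x = _check(x)
        b, c, h, w = x.shape
        if c != self.c:
            raise ConfigError(f"expected {self.c} channels, got {c}")
        g, cg = self.g, self.cg
        xg = x.reshape(b * g, cg, h, w)
        xh = directional_pool_h(xg)                       # (bg, cg, h, 1)
        xw = directional_pool_w(xg).transpose(0, 1, 3, 2)  # (bg, cg, w, 1)
        hw = conv2d(concat([xh, xw], axis=2), self.w1, self.b1)
        xh2 = hw[:, :, :h, :]
        xw2 = hw[:, :, h:, :].transpose(0, 1, 3, 2)
        x1 = self._group_norm(xg * sigmoid(xh2) * sigmoid(xw2))
        x2 = conv2d(xg, self.w3, self.b3, padding=1)
        a1 = softmax(x1.mean(axis=(2, 3)).reshape(b * g, 1, cg), axis=-1)
        a2 = softmax(x2.mean(axis=(2, 3)).reshape(b * g, 1, cg), axis=-1)
        m1 = matmul(a1, x2.reshape(b * g, cg, h * w))
        m2 = matmul(a2, x1.reshape(b * g, cg, h * w))
        wts = sigmoid((m1 + m2).reshape(b * g, 1, h, w))
        return (xg * wts).reshape(b, c, h, w)

    def profile(self, h, w):
        g, cg = self.g, self.cg
        pr = Profile()
        pr.params = 2 * cg + cg * cg + cg + 9 * cg * cg + cg
        pr.macs = g * (cg * cg * (h + w) + 9 * cg * cg * h * w + 2 * cg * h * w)
        pr.act_elems = 2 * self.c * h * w + self.c * (h + w)
        return pr, (h, w)


class ECA(Module):
    def __init__(self, channels: int, cfg: EcaConfig | None = None, rng=None):
        super().__init__()
        cfg = cfg or EcaConfig()
        rng = rng or np.random.default_rng(0)
        self.c = channels
        self.k = cfg.kernel_for(channels)
        self.register("weight", rng.normal(0, np.sqrt(1.0 / self.k), (self.k,)))

    def forward(self, x):
        x = _check(x)
        b, c, h, w = x.shape
        y = x.mean(axis=(2, 3)).reshape(b, 1, c)
        y = conv1d_circularless(y, self.weight, padding=self.k // 2)
        gate = sigmoid(y).reshape(b, c, 1, 1)
        return x * gate

    def profile(self, h, w):
        pr = Profile()
        pr.params = self.k
        pr.macs = self.k * self.c + self.c
        pr.act_elems = self.c * h * w
        return pr, (h, w)


def ema_forward(x, cfg: EmaConfig, rng=None) -> Tensor:
    """Functional entry point building a seeded EMA block and applying it."""
    block = EMA(cfg.channels, cfg.groups, rng=rng)
    return block(x)


def eca_forward(x, cfg: EcaConfig | None = None, rng=None) -> Tensor:
    x = _check(x)
    block = ECA(x.shape[1], cfg, rng=rng)
    return block(x)
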