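"""Adaptive residual block (ARBlock) and the C3k2-B container.

ARBlock is the lightweight multi-receptive-field extractor: a 3x3
depthwise-separable stem (depthwise then pointwise, batch norm, SiLU)
feeds three parallel depthwise 3x3 branches at dilations 1, 3 and 5 —
receptive fields of 3, 7 and 11 pixels at identical parameter cost —
whose concatenation is batch-normalised, channel-reweighted by ECA,
projected back to the block width, and finally blended with the block
input through an adaptive sigmoid gate:

    x_out = gate(x_res) * x_conv + (1 - gate(x_res)) * x_res

so the gate (a 1x1 convolution + sigmoid computed from the residual
stream) decides pointwise between the transformed and the raw feature.

C3k2-B keeps the split-transform-concat skeleton of the block it
replaces: a 1x1 transition, a channel split, a 1x1 convolution on each
half, ``n`` ARBlocks on the right half, concatenation and a 1x1 fusion
to the output width.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention import ECA, EcaConfig
from .nn.autograd import concat, sigmoid
from .nn.layers import BatchNorm2d, Conv, DWConv, Module, Profile


class ConfigError(ValueError):
    pass


@dataclass
class ARBlockSpec:
    channels: int
    dilations: tuple[int, ...] = (1, 3, 5)

    def __post_init__(self):
        if any(d < 1 for d in self.dilations):
            raise ConfigError(f"dilations must be positive, got {self.dilations}")


@dataclass
class C3k2BSpec:
    c1: int
    c2: int
    n: int = 1
    e: float = 0.5

    def __post_init__(self):
        if self.n < 0:
            raise ConfigError(f"n must be >= 0, got {self.n}")


class ARBlock(Module):
    def __init__(self, spec: ARBlockSpec | int, rng=None):
        super().__init__()
        if isinstance(spec, int):
            spec = ARBlockSpec(spec)
        c = spec.channels
        self.spec = spec
        self.c = c
        self.stem_dw = DWConv(c, 3, act="none", bn=False, bias=False, rng=rng)
        self.stem_pw = Conv(c, c, 1, rng=rng)  # carries the BN + SiLU
        self.branches = self.add_children(
            [DWConv(c, 3, d=d, act="none", bn=False, bias=False, rng=rng)
             for d in spec.dilations]
        )
        nb = len(spec.dilations)
        self.post_bn = BatchNorm2d(nb * c)
        self.eca = ECA(nb * c, rng=rng)
        self.proj = Conv(nb * c, c, 1, act="none", bn=False, rng=rng)
        self.gate = Conv(c, c, 1, act="none", bn=False, rng=rng)

    def forward(self, x, gate_override=None):
        if x.shape[1] != self.c:
            raise ConfigError(f"expected {self.c} channels, got {x.shape[1]}")
        y = self.stem_pw(self.stem_dw(x))
        y = concat([br(y) for br in self.branches], axis=1)
        y = self.proj(self.eca(self.post_bn(y)))
        g = sigmoid(self.gate(x)) if gate_override is None else gate_override
        return g * y + (1.0 - g) * x

    def profile(self, h, w):
        c, nb = self.c, len(self.spec.dilations)
        pr = Profile()
        pr.params = 9 * c  # depthwise stem
        pr.macs = 9 * c * h * w
        p, _ = self.stem_pw.profile(h, w)
        pr += p
        pr.params += nb * 9 * c
        pr.macs += nb * 9 * c * h * w
        p, _ = self.post_bn.profile(h, w)
        pr += p
        p, _ = self.eca.profile(h, w)
        pr += p
        pr.params += nb * c * c + c          # projection (bias, no BN)
        pr.macs += nb * c * c * h * w
        pr.params += c * c + c               # gate conv
        pr.macs += c * c * h * w
        pr.act_elems += c * h * w            # gate sigmoid
        pr.act_elems += 2 * c * h * w        # blend
        return pr, (h, w)


class C3k2B(Module):
    def __init__(self, spec: C3k2BSpec, rng=None):
        super().__init__()
        self.spec = spec
        c = int(spec.c2 * spec.e)
        self.c = c
        self.transition = Conv(spec.c1, 2 * c, 1, rng=rng)
        self.left = Conv(c, c, 1, rng=rng)
        self.right = Conv(c, c, 1, rng=rng)
        self.blocks = self.add_children(
            [ARBlock(ARBlockSpec(c), rng=rng) for _ in range(spec.n)]
        )
        self.fuse = Conv(2 * c, spec.c2, 1, rng=rng)

    def forward(self, x):
        if x.shape[1] != self.spec.c1:
            raise ConfigError(
                f"expected {self.spec.c1} channels, got {x.shape[1]}"
            )
        t = self.transition(x)
        l = self.left(t[:, : self.c])
        r = self.right(t[:, self.c:])
        for blk in self.blocks:
            r = blk(r)
        return self.fuse(concat([l, r], axis=1))

    def profile(self, h, w):
        pr = Profile()
        for mod in (self.transition, self.left, self.right, *self.blocks, self.fuse):
            p, _ = mod.profile(h, w)
            pr += p
        return pr, (h, w)


def arblock_forward(x, spec: ARBlockSpec, rng=None, gate_override=None):
    return ARBlock(spec, rng=rng)(x, gate_override=gate_override)


def c3k2b_forward(x, spec: C3k2BSpec, rng=None):
    return C3k2B(spec, rng=rng)(x)
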