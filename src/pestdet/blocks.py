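"""Baseline building blocks of the nano-scale detector family.

These follow the established single-stage layout: ``Conv`` stem blocks,
split-transform-concat ``C3k2`` feature blocks, the area-attention
``A2C2f`` stage, and an anchor-free decoupled detect head with
distribution-focal box regression (``reg_max`` bins per box side).
"""
from __future__ import annotations

import math

import numpy as np

from .nn.autograd import Tensor, concat, matmul, softmax
from .nn.functional import conv2d
from .nn.layers import Conv, DWConv, Module, Profile, Sequential

REG_MAX = 16


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, k=(3, 3), e=0.5, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, k[0], rng=rng)
        self.cv2 = Conv(c_, c2, k[1], rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    def profile(self, h, w):
        pr, _ = self.cv1.profile(h, w)
        p2, _ = self.cv2.profile(h, w)
        pr += p2
        return pr, (h, w)


class C3k(Module):
    def __init__(self, c1, c2, n=2, shortcut=True, e=0.5, k=3, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1, rng=rng)
        self.cv2 = Conv(c1, c_, 1, rng=rng)
        self.cv3 = Conv(2 * c_, c2, 1, rng=rng)
        self.m = self.add_children(
            [Bottleneck(c_, c_, shortcut, k=(k, k), e=1.0, rng=rng) for _ in range(n)]
        )

    def forward(self, x):
        a = self.cv1(x)
        for blk in self.m:
            a = blk(a)
        return self.cv3(concat([a, self.cv2(x)], axis=1))

    def profile(self, h, w):
        pr = Profile()
        for mod in (self.cv1, self.cv2, self.cv3, *self.m):
            p, _ = mod.profile(h, w)
            pr += p
        return pr, (h, w)


class C3k2(Module):
    """C2f-style block: 1x1 expand, split, n inner blocks, concat, 1x1 fuse."""

    def __init__(self, c1, c2, n=1, c3k=False, e=0.5, shortcut=True, rng=None):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1, rng=rng)
        self.cv2 = Conv((2 + n) * self.c, c2, 1, rng=rng)
        self.m = self.add_children(
            [
                C3k(self.c, self.c, 2, shortcut, rng=rng)
                if c3k
                else Bottleneck(self.c, self.c, shortcut, rng=rng)
                for _ in range(n)
            ]
        )

    def forward(self, x):
        y = self.cv1(x)
        ys = [y[:, : self.c], y[:, self.c:]]
        for blk in self.m:
            ys.append(blk(ys[-1]))
        return self.cv2(concat(ys, axis=1))

    def profile(self, h, w):
        pr = Profile()
        for mod in (self.cv1, self.cv2, *self.m):
            p, _ = mod.profile(h, w)
            pr += p
        return pr, (h, w)


class AAttn(Module):
    """Area attention: multi-head self-attention inside horizontal strips.

    ``area`` splits the flattened spatial extent into equal chunks so the
    quadratic term stays linear in image size; a depthwise 5x5 convolution
    on the value path restores positional structure.
    """

    def __init__(self, dim, num_heads, area=1, rng=None):
        super().__init__()
        self.dim, self.nh, self.area = dim, num_heads, area
        self.hd = dim // num_heads
        self.qkv = Conv(dim, dim * 3, 1, act="none", rng=rng)
        self.proj = Conv(dim, dim, 1, act="none", rng=rng)
        self.pe = Conv(dim, dim, 5, g=dim, act="none", rng=rng)

    def forward(self, x):
        b, c, h, w = x.shape
        n = h * w
        area = self.area if n % self.area == 0 else 1
        na = n // area
        qkv = self.qkv(x).reshape(b, 3, self.nh, self.hd, n)
        qkv = qkv.transpose(1, 0, 2, 3, 4).reshape(3 * b * self.nh, self.hd, n)
        # fold area chunks into the batch axis
        qkv = qkv.reshape(3 * b * self.nh, self.hd, area, na).transpose(0, 2, 1, 3)
        qkv = qkv.reshape(3, b * self.nh * area, self.hd, na)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = softmax(matmul(q.transpose(0, 2, 1), k) * (self.hd ** -0.5), axis=-1)
        out = matmul(v, attn.transpose(0, 2, 1))
        out = out.reshape(b * self.nh, area, self.hd, na).transpose(0, 2, 1, 3)
        out = out.reshape(b, c, h, w)
        vsp = v.reshape(b * self.nh, area, self.hd, na).transpose(0, 2, 1, 3)
        vsp = vsp.reshape(b, c, h, w)
        return self.proj(out + self.pe(vsp))

    def profile(self, h, w):
        pr = Profile()
        for mod in (self.qkv, self.proj, self.pe):
            p, _ = mod.profile(h, w)
            pr += p
        return pr, (h, w)


class ABlock(Module):
    def __init__(self, dim, num_heads, mlp_ratio=2.0, area=1, rng=None):
        super().__init__()
        self.attn = AAttn(dim, num_heads, area, rng=rng)
        mh = int(dim * mlp_ratio)
        self.mlp1 = Conv(dim, mh, 1, rng=rng)
        self.mlp2 = Conv(mh, dim, 1, act="none", rng=rng)

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.mlp2(self.mlp1(x))

    def profile(self, h, w):
        pr = Profile()
        for mod in (self.attn, self.mlp1, self.mlp2):
            p, _ = mod.profile(h, w)
            pr += p
        return pr, (h, w)


class A2C2f(Module):
    """Attention-augmented C2f stage: 1x1 reduce, n branches (each a pair of
    ABlocks, or a C3k when attention is disabled), concat, 1x1 fuse."""

    def __init__(self, c1, c2, n=1, a2=True, area=1, rng=None):
        super().__init__()
        c_ = int(c2 * 0.5)
        if a2 and c_ % 32:
            raise ValueError("attention width must be a multiple of 32")
        self.cv1 = Conv(c1, c_, 1, rng=rng)
        self.cv2 = Conv((1 + n) * c_, c2, 1, rng=rng)
        mods = []
        for _ in range(n):
            if a2:
                mods.append(
                    Sequential(
                        ABlock(c_, c_ // 32, area=area, rng=rng),
                        ABlock(c_, c_ // 32, area=area, rng=rng),
                    )
                )
            else:
                mods.append(C3k(c_, c_, 2, rng=rng))
        self.m = self.add_children(mods)

    def forward(self, x):
        ys = [self.cv1(x)]
        for blk in self.m:
            ys.append(blk(ys[-1]))
        return self.cv2(concat(ys, axis=1))

    def profile(self, h, w):
        pr = Profile()
        for mod in (self.cv1, self.cv2, *self.m):
            p, _ = mod.profile(h, w)
            pr += p
        return pr, (h, w)


class Detect(Module):
    """Anchor-free decoupled head over three scales.

    Box branch regresses ``4 * REG_MAX`` distribution-focal logits; the
    class branch is the depthwise-separable variant of the family.  Raw
    per-scale maps are returned; decoding lives in :mod:`pestdet.netgraph`.
    """

    def __init__(self, nc, ch, strides=(8, 16, 32), rng=None):
        super().__init__()
        self.nc = nc
        self.ch = tuple(ch)
        self.strides = tuple(strides)
        c2 = max(16, ch[0] // 4, REG_MAX * 4)
        c3 = max(ch[0], min(nc, 100))
        self.box_branches = self.add_children(
            [
                Sequential(
                    Conv(c, c2, 3, rng=rng),
                    Conv(c2, c2, 3, rng=rng),
                    Conv(c2, 4 * REG_MAX, 1, act="none", bn=False, rng=rng),
                )
                for c in ch
            ]
        )
        self.cls_branches = self.add_children(
            [
                Sequential(
                    DWConv(c, 3, rng=rng),
                    Conv(c, c3, 1, rng=rng),
                    DWConv(c3, 3, rng=rng),
                    Conv(c3, c3, 1, rng=rng),
                    Conv(c3, nc, 1, act="none", bn=False, rng=rng),
                )
                for c in ch
            ]
        )
        for br, s in zip(self.box_branches, self.strides):
            br.mods[-1].bias.data[:] = 1.0
        for br, s in zip(self.cls_branches, self.strides):
            br.mods[-1].bias.data[:] = math.log(5.0 / nc / (640.0 / s) ** 2)

    def forward(self, feats):
        outs = []
        for f, bb, cb in zip(feats, self.box_branches, self.cls_branches):
            outs.append(concat([bb(f), cb(f)], axis=1))
        return outs

    def profile(self, h, w):
        pr = Profile()
        for s, bb, cb in zip(self.strides, self.box_branches, self.cls_branches):
            hs, ws = h * 8 // s, w * 8 // s
            for mod in (bb, cb):
                p, _ = mod.profile(hs, ws)
                pr += p
        return pr, (h, w)


def dfl_expectation(box_logits: Tensor) -> Tensor:
    """Distribution-focal decode: softmax over REG_MAX bins -> expected
    distance, for logits shaped (..., 4, REG_MAX)."""
    probs = softmax(box_logits, axis=-1)
    proj = Tensor(np.arange(REG_MAX, dtype=np.float32))
    return (probs * proj.reshape(*([1] * (box_logits.ndim - 1)), REG_MAX)).sum(axis=-1)
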