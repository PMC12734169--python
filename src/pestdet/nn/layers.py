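"""Module system: parameter containers with forward, backward (via the tape),
and per-layer compute accounting.

Every module exposes ``profile(h, w)`` returning a :class:`Profile` with the
trainable-parameter count, convolution multiply-accumulates, and the
elementwise batch-norm / activation tallies used by the FLOP report, plus the
output spatial size.  Keeping the accounting next to the compute guarantees
the profiler and the executed network can never drift apart.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import functional as F
from .autograd import Tensor, concat, sigmoid, silu


@dataclass
class Profile:
    params: int = 0
    macs: int = 0
    bn_elems: int = 0
    act_elems: int = 0

    def __iadd__(self, other: "Profile"):
        self.params += other.params
        self.macs += other.macs
        self.bn_elems += other.bn_elems
        self.act_elems += other.act_elems
        return self

    def flops(self, mac_cost: float = 2.0, bn_cost: float = 0.0,
              act_cost: float = 9.0) -> float:
        return mac_cost * self.macs + bn_cost * self.bn_elems + act_cost * self.act_elems


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, arr: np.ndarray) -> Tensor:
        t = Tensor(arr.astype(np.float32), requires_grad=True)
        self._params[name] = t
        setattr(self, name, t)
        return t

    def add_children(self, mods):
        """Track a list of sub-modules (list attributes bypass __setattr__)."""
        for i, m in enumerate(mods):
            self._children[f"{id(mods)}_{i}"] = m
        return mods

    def modules(self):
        yield self
        for c in self._children.values():
            yield from c.modules()

    def parameters(self):
        for m in self.modules():
            yield from m._params.values()

    def named_parameters(self, prefix=""):
        for n, p in self._params.items():
            yield f"{prefix}{n}", p
        for cn, c in self._children.items():
            yield from c.named_parameters(f"{prefix}{cn}.")

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array map of parameters and buffers, for (de)serialisation."""
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"p{i}"] = p.data
        for i, (m, bname, buf) in enumerate(self._iter_buffers()):
            out[f"b{i}"] = buf
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]):
        for i, p in enumerate(self.parameters()):
            p.data = arrays[f"p{i}"].astype(np.float32).reshape(p.data.shape)
        for i, (m, bname, buf) in enumerate(self._iter_buffers()):
            src = arrays[f"b{i}"].astype(np.float32).reshape(buf.shape)
            buf[...] = src

    def _iter_buffers(self):
        for m in self.modules():
            for bname in ("running_mean", "running_var"):
                buf = m.__dict__.get(bname)
                if isinstance(buf, np.ndarray):
                    yield m, bname, buf

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)

    def profile(self, h: int, w: int) -> tuple[Profile, tuple[int, int]]:
        raise NotImplementedError


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Conv(Module):
    """Conv2d + optional BatchNorm + activation (the family's basic block).

    Bias is disabled whenever batch norm follows, enabled otherwise.
    """

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, d=1, act="silu",
                 bn=True, bias=None, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c1, self.c2, self.k, self.s, self.g, self.d = c1, c2, k, s, g, d
        self.p = (d * (k - 1)) // 2 if p is None else p
        self.act = act
        self.bn = bn
        self.has_bias = (not bn) if bias is None else bias
        fan_in = c1 // g * k * k
        self.register("weight", _he(rng, (c2, c1 // g, k, k), fan_in))
        if bn:
            self.register("gamma", np.ones(c2))
            self.register("beta", np.zeros(c2))
            self.running_mean = np.zeros(c2, dtype=np.float32)
            self.running_var = np.ones(c2, dtype=np.float32)
        if self.has_bias:
            self.register("bias", np.zeros(c2))

    def forward(self, x):
        y = F.conv2d(x, self.weight, self.bias if self.has_bias else None,
                     stride=self.s, padding=self.p, dilation=self.d, groups=self.g)
        if self.bn:
            y = F.batch_norm(y, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training)
        if self.act == "silu":
            y = silu(y)
        elif self.act == "sigmoid":
            y = sigmoid(y)
        return y

    def profile(self, h, w):
        oh = (h + 2 * self.p - self.d * (self.k - 1) - 1) // self.s + 1
        ow = (w + 2 * self.p - self.d * (self.k - 1) - 1) // self.s + 1
        pr = Profile()
        pr.params = self.k * self.k * self.c1 * self.c2 // self.g
        if self.bn:
            pr.params += 2 * self.c2
        if self.has_bias:
            pr.params += self.c2
        pr.macs = self.k * self.k * self.c1 * self.c2 // self.g * oh * ow
        if self.bn:
            pr.bn_elems = self.c2 * oh * ow
        if self.act in ("silu", "sigmoid"):
            pr.act_elems = self.c2 * oh * ow
        return pr, (oh, ow)


class DWConv(Conv):
    def __init__(self, c, k=3, s=1, d=1, act="silu", bn=True, bias=None, rng=None):
        super().__init__(c, c, k, s, g=c, d=d, act=act, bn=bn, bias=bias, rng=rng)


class BatchNorm2d(Module):
    def __init__(self, c):
        super().__init__()
        self.c = c
        self.register("gamma", np.ones(c))
        self.register("beta", np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training)

    def profile(self, h, w):
        return Profile(params=2 * self.c, bn_elems=self.c * h * w), (h, w)


class Upsample(Module):
    def __init__(self, scale=2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return F.upsample_nearest(x, self.scale)

    def profile(self, h, w):
        return Profile(), (h * self.scale, w * self.scale)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = self.add_children(list(mods))

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def profile(self, h, w):
        pr = Profile()
        for m in self.mods:
            p, (h, w) = m.profile(h, w)
            pr += p
        return pr, (h, w)
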