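"""Structured NN ops (convolution, batch norm, upsampling) on the autodiff tape.

Convolutions are evaluated by lowering to GEMM: a zero-copy strided window
view gathers receptive fields, a single matrix multiply applies the kernel.
The backward pass reuses the cached window view for the weight gradient and
scatters the column gradient back with one vectorised strided addition per
kernel tap.  Depthwise convolutions take an einsum fast path instead of
looping channels.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .autograd import Tensor, _make, as_tensor, pad2d


def _windows(xp: np.ndarray, kh: int, kw: int, stride: int, dil: int):
    """Strided view (b, c, oh, ow, kh, kw) of the padded input."""
    b, c, H, W = xp.shape
    oh = (H - dil * (kh - 1) - 1) // stride + 1
    ow = (W - dil * (kw - 1) - 1) // stride + 1
    sb, sc, sh, sw = xp.strides
    return as_strided(
        xp,
        shape=(b, c, oh, ow, kh, kw),
        strides=(sb, sc, sh * stride, sw * stride, sh * dil, sw * dil),
        writeable=False,
    )


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0,
           dilation: int = 1, groups: int = 1):
    """2-D cross-correlation.  weight: (cout, cin/groups, kh, kw)."""
    x = as_tensor(x)
    weight = as_tensor(weight)
    xe = pad2d(x, padding, padding) if padding else x
    xp = xe.data
    cout, cing, kh, kw = weight.data.shape
    b, c, H, W = xp.shape
    if groups == c and cout == c and cing == 1:
        out = _dwconv(xe, weight, stride, dilation)
    elif groups == 1:
        out = _conv_full(xe, weight, stride, dilation)
    else:
        cg, cog = c // groups, cout // groups
        parts = []
        for gi in range(groups):
            xg = xe[:, gi * cg:(gi + 1) * cg]
            wg = weight[gi * cog:(gi + 1) * cog]
            parts.append(_conv_full(xg, wg, stride, dilation))
        from .autograd import concat
        out = concat(parts, axis=1)
    if bias is not None:
        bias = as_tensor(bias)
        out = out + bias.reshape(1, cout, 1, 1)
    return out


def _conv_full(xe: Tensor, weight: Tensor, stride: int, dil: int) -> Tensor:
    xp = xe.data
    cout, cin, kh, kw = weight.data.shape
    b = xp.shape[0]
    win = _windows(xp, kh, kw, stride, dil)
    oh, ow = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        b * oh * ow, cin * kh * kw
    )
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out_data = (cols @ wmat.T).reshape(b, oh, ow, cout).transpose(0, 3, 1, 2)

    def back(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(b * oh * ow, cout)
        weight._accum((g2.T @ cols).reshape(weight.data.shape))
        gcols = (g2 @ wmat).reshape(b, oh, ow, cin, kh, kw)
        gxp = np.zeros_like(xp)
        span_h, span_w = stride * oh, stride * ow
        for ki in range(kh):
            for kj in range(kw):
                gxp[:, :, ki * dil:ki * dil + span_h:stride,
                    kj * dil:kj * dil + span_w:stride] += gcols[..., ki, kj].transpose(0, 3, 1, 2)
        xe._accum(gxp)

    return _make(np.ascontiguousarray(out_data), (xe, weight), back)


def _dwconv(xe: Tensor, weight: Tensor, stride: int, dil: int) -> Tensor:
    xp = xe.data
    c, _, kh, kw = weight.data.shape
    win = _windows(xp, kh, kw, stride, dil)
    oh, ow = win.shape[2], win.shape[3]
    w = weight.data.reshape(c, kh, kw)
    out_data = np.einsum("bcijkl,ckl->bcij", win, w, optimize=True)

    def back(g):
        gw = np.einsum("bcij,bcijkl->ckl", g, win, optimize=True)
        weight._accum(gw.reshape(weight.data.shape))
        gxp = np.zeros_like(xp)
        span_h, span_w = stride * oh, stride * ow
        for ki in range(kh):
            for kj in range(kw):
                gxp[:, :, ki * dil:ki * dil + span_h:stride,
                    kj * dil:kj * dil + span_w:stride] += g * w[None, :, ki, kj, None, None]
        xe._accum(gxp)

    return _make(np.ascontiguousarray(out_data), (xe, weight), back)


def batch_norm(x, gamma, beta, running_mean, running_var,
               training: bool, momentum: float = 0.03, eps: float = 1e-3):
    """Batch normalisation over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain ndarrays updated in place
    during training (outside the gradient path).
    """
    x = as_tensor(x)
    gamma = as_tensor(gamma)
    beta = as_tensor(beta)
    xd = x.data
    n = xd.shape[0] * xd.shape[2] * xd.shape[3]
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) * invstd[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    if training:
        def back(g):
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            beta._accum(g.sum(axis=(0, 2, 3)))
            gxhat = g * gamma.data[None, :, None, None]
            gsum = gxhat.sum(axis=(0, 2, 3), keepdims=True)
            gdot = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (gxhat - gsum / n - xhat * gdot / n) * invstd[None, :, None, None]
            x._accum(gx.astype(np.float32))
    else:
        def back(g):
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            beta._accum(g.sum(axis=(0, 2, 3)))
            x._accum(g * (gamma.data * invstd)[None, :, None, None])

    return _make(out_data.astype(np.float32), (x, gamma, beta), back)


def upsample_nearest(x, scale: int):
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    out_data = np.broadcast_to(
        x.data[:, :, :, None, :, None], (b, c, h, scale, w, scale)
    ).reshape(b, c, h * scale, w * scale)

    def back(g):
        x._accum(
            g.reshape(b, c, h, scale, w, scale).sum(axis=(3, 5))
        )

    return _make(np.ascontiguousarray(out_data), (x,), back)


def conv1d_circularless(x, weight, padding: int):
    """1-D convolution across the channel axis for a (b, 1, c) signal.

    Used by ECA: the kernel slides over channels with zero padding.
    weight: (k,).
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    k = weight.data.shape[0]
    b, one, c = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    win = as_strided(
        xp, shape=(b, c, k),
        strides=(xp.strides[0], xp.strides[2], xp.strides[2]),
        writeable=False,
    )
    out_data = np.einsum("bck,k->bc", win, weight.data).reshape(b, 1, c)

    def back(g):
        g2 = g.reshape(b, c)
        weight._accum(np.einsum("bc,bck->k", g2, win))
        gxp = np.zeros_like(xp)
        for ki in range(k):
            gxp[:, 0, ki:ki + c] += g2 * weight.data[ki]
        x._accum(gxp[:, :, padding:padding + c])

    return _make(out_data.astype(np.float32), (x, weight), back)
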