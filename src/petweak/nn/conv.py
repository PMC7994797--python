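"""Strided 3D convolution with ceil-mode "same" padding.

The output length along every axis is ``ceil(in / stride)``; because
``ceil(ceil(n/a)/b) == ceil(n/(a*b))``, stacked layers compose into a single
declared per-axis reduction factor, which is the shape contract the scan
encoders expose.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor

__all__ = ["conv3d", "same_ceil_pad"]


def same_ceil_pad(n: int, kernel: int, stride: int) -> tuple[int, int]:
    """(before, after) zero padding so that out = ceil(n / stride)."""
    out = -(-n // stride)
    total = max((out - 1) * stride + kernel - n, 0)
    before = total // 2
    return before, total - before


def _im2col(x: np.ndarray, kernel: tuple, stride: tuple):
    """x: (N, C, H, W, L) padded -> cols (N, P, C*kh*kw*kl), out spatial dims."""
    n, c, h, w, l = x.shape
    kh, kw, kl = kernel
    sh, sw, sl = stride
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    ol = (l - kl) // sl + 1
    sn, sc, s0, s1, s2 = x.strides
    windows = as_strided(
        x,
        shape=(n, oh, ow, ol, c, kh, kw, kl),
        strides=(sn, s0 * sh, s1 * sw, s2 * sl, sc, s0, s1, s2),
        writeable=False,
    )
    cols = windows.reshape(n, oh * ow * ol, c * kh * kw * kl)
    return np.ascontiguousarray(cols), (oh, ow, ol)


def _col_indices(padded_shape: tuple, kernel: tuple, stride: tuple) -> np.ndarray:
    """Flat indices into (C, Hp, Wp, Lp) for every (position, column) pair."""
    c, h, w, l = padded_shape
    kh, kw, kl = kernel
    sh, sw, sl = stride
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    ol = (l - kl) // sl + 1
    ih = (np.arange(oh) * sh)[:, None] + np.arange(kh)[None, :]  # (oh, kh)
    iw = (np.arange(ow) * sw)[:, None] + np.arange(kw)[None, :]
    il = (np.arange(ol) * sl)[:, None] + np.arange(kl)[None, :]
    # broadcast to (oh, ow, ol, c, kh, kw, kl)
    idx = (
        np.arange(c)[None, None, None, :, None, None, None] * (h * w * l)
        + ih[:, None, None, None, :, None, None] * (w * l)
        + iw[None, :, None, None, None, :, None] * l
        + il[None, None, :, None, None, None, :]
    )
    return idx.reshape(oh * ow * ol, c * kh * kw * kl)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor, stride: tuple) -> Tensor:
    """3D convolution of x (N, C, H, W, L) with weight (Cout, C, kh, kw, kl).

    Output: (N, Cout, ceil(H/sh), ceil(W/sw), ceil(L/sl)).
    """
    n, c, h, w, l = x.shape
    cout, cin, kh, kw, kl = weight.shape
    if cin != c:
        raise ValueError(f"channel mismatch: input has {c}, weight expects {cin}")
    kernel = (kh, kw, kl)
    pads = [same_ceil_pad(dim, k, s) for dim, k, s in zip((h, w, l), kernel, stride)]
    xp = np.pad(x.data, ((0, 0), (0, 0), *pads))
    cols, (oh, ow, ol) = _im2col(xp, kernel, stride)
    wmat = weight.data.reshape(cout, -1)
    out_data = cols @ wmat.T + bias.data  # (N, P, Cout)
    out_data = out_data.transpose(0, 2, 1).reshape(n, cout, oh, ow, ol)

    padded_shape = xp.shape[1:]

    def backward(out):
        g = out.grad.reshape(n, cout, -1).transpose(0, 2, 1)  # (N, P, Cout)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = np.einsum("npo,npk->ok", g, cols)
            weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            dcols = np.matmul(g, wmat)  # (N, P, C*k)
            idx = _col_indices(padded_shape, kernel, stride).ravel()
            size = int(np.prod(padded_shape))
            gx = np.empty((n, *padded_shape))
            for i in range(n):
                gx[i] = np.bincount(idx, weights=dcols[i].ravel(), minlength=size).reshape(
                    padded_shape
                )
            (pb_h, _), (pb_w, _), (pb_l, _) = pads
            x._accumulate(gx[:, :, pb_h : pb_h + h, pb_w : pb_w + w, pb_l : pb_l + l])

    return Tensor._make(out_data, (x, weight, bias), backward)
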