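"""CNN kernels with hand-written backward passes.

Convolution is im2col + one BLAS matmul; its input gradient is re-assembled
with a small kernel-offset loop rather than a scatter, which keeps the
backward pass vectorised.  All functions take and return
:class:`~dermseg.nn.tensor.Tensor` and participate in the autodiff tape.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv_transpose2x",
    "batch_norm2d",
    "max_pool2x",
    "global_avg_pool",
    "upsample_bilinear2x",
    "concat_channels",
    "dropout2d",
    "relu",
    "prelu",
    "gelu",
    "swish",
    "mish",
]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    # (N, C*kh*kw, ho*wo) — copy happens here, once
    return view.reshape(n, c * kh * kw, ho * wo), ho, wo, hp, wp


def _col2im(dcols: np.ndarray, x_shape, kh, kw, stride, pad, ho, wo, hp, wp):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    d6 = dcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        hi = i + stride * ho
        for j in range(kw):
            wj = j + stride * wo
            dxp[:, :, i:hi:stride, j:wj:stride] += d6[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad or None, pad:-pad or None]
    return dxp


def _conv1x1(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int) -> Tensor:
    """Pointwise convolution: a channel matmul (with optional subsampling)."""
    n, c, h, w = x.shape
    o = weight.shape[0]
    xs = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
    ho, wo = xs.shape[2], xs.shape[3]
    xf = np.ascontiguousarray(xs).reshape(n, c, ho * wo)
    wm = weight.data.reshape(o, c)
    out = np.matmul(wm, xf).reshape(n, o, ho, wo)
    if bias is not None:
        out += bias.data.reshape(1, o, 1, 1)

    def bw(g):
        gf = g.reshape(n, o, ho * wo)
        if bias is not None and (bias.requires_grad or bias._parents):
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad or weight._parents:
            dw = np.einsum("nol,ncl->oc", gf, xf, optimize=True)
            weight._accum(dw.reshape(weight.shape))
        if x.requires_grad or x._parents:
            dxs = np.matmul(wm.T, gf).reshape(n, c, ho, wo)
            if stride > 1:
                dx = np.zeros_like(x.data)
                dx[:, :, ::stride, ::stride] = dxs
            else:
                dx = dxs
            x._accum(dx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, _parents=parents, _backward=bw)


def _conv_depthwise(
    x: Tensor, weight: Tensor, bias: Tensor | None, stride: int, padding: int
) -> Tensor:
    """Depthwise convolution via kernel-offset accumulation (no im2col copy)."""
    n, c, h, w = x.shape
    _, _, kh, kw = weight.shape
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1
    out = np.zeros((n, c, ho, wo), dtype=x.data.dtype)
    wd = weight.data[:, 0]  # (C, kh, kw)
    for i in range(kh):
        hi = i + stride * ho
        for j in range(kw):
            wj = j + stride * wo
            out += xp[:, :, i:hi:stride, j:wj:stride] * wd[:, i, j][None, :, None, None]
    if bias is not None:
        out += bias.data.reshape(1, c, 1, 1)

    def bw(g):
        if bias is not None and (bias.requires_grad or bias._parents):
            bias._accum(g.sum(axis=(0, 2, 3)))
        need_dx = x.requires_grad or x._parents
        dxp = np.zeros_like(xp) if need_dx else None
        if weight.requires_grad or weight._parents:
            dw = np.empty_like(weight.data)
        else:
            dw = None
        for i in range(kh):
            hi = i + stride * ho
            for j in range(kw):
                wj = j + stride * wo
                sl = (slice(None), slice(None), slice(i, hi, stride), slice(j, wj, stride))
                if dw is not None:
                    dw[:, 0, i, j] = np.einsum(
                        "nchw,nchw->c", g, xp[sl], optimize=True
                    )
                if need_dx:
                    dxp[sl] += g * wd[:, i, j][None, :, None, None]
        if dw is not None:
            weight._accum(dw)
        if need_dx:
            dx = (
                dxp[:, :, padding:-padding or None, padding:-padding or None]
                if padding
                else dxp
            )
            x._accum(dx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, _parents=parents, _backward=bw)


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation.  weight: (O, C//groups, kh, kw)."""
    n, c, h, w = x.shape
    o, cg, kh, kw = weight.shape
    if c != cg * groups or o % groups:
        raise ValueError(
            f"channel/group mismatch: input {c}, weight {weight.shape}, groups {groups}"
        )
    if kh == kw == 1 and groups == 1 and padding == 0:
        return _conv1x1(x, weight, bias, stride)
    if groups == c and cg == 1 and o == c:
        return _conv_depthwise(x, weight, bias, stride, padding)
    cols, ho, wo, hp, wp = _im2col(x.data, kh, kw, stride, padding)
    if groups == 1:
        wm = weight.data.reshape(o, cg * kh * kw)
        out = np.matmul(wm, cols)  # (N, O, L)
    else:
        og = o // groups
        colg = cols.reshape(n, groups, cg * kh * kw, ho * wo)
        wg = weight.data.reshape(groups, og, cg * kh * kw)
        out = np.einsum("gok,ngkl->ngol", wg, colg, optimize=True).reshape(
            n, o, ho * wo
        )
    out = out.reshape(n, o, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, o, 1, 1)

    def bw(g):
        gf = g.reshape(n, o, ho * wo)
        if bias is not None and (bias.requires_grad or bias._parents):
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad or weight._parents:
            if groups == 1:
                dw = np.einsum("nol,nkl->ok", gf, cols, optimize=True)
            else:
                og = o // groups
                colg = cols.reshape(n, groups, cg * kh * kw, ho * wo)
                gg = gf.reshape(n, groups, og, ho * wo)
                dw = np.einsum("ngol,ngkl->gok", gg, colg, optimize=True)
            weight._accum(dw.reshape(weight.shape))
        if x.requires_grad or x._parents:
            if groups == 1:
                wm = weight.data.reshape(o, cg * kh * kw)
                dcols = np.matmul(wm.T, gf)  # (N, Ckk, L)
            else:
                og = o // groups
                wg = weight.data.reshape(groups, og, cg * kh * kw)
                gg = gf.reshape(n, groups, og, ho * wo)
                dcols = np.einsum("gok,ngol->ngkl", wg, gg, optimize=True).reshape(
                    n, c * kh * kw, ho * wo
                )
            x._accum(
                _col2im(dcols, x.shape, kh, kw, stride, padding, ho, wo, hp, wp)
            )

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, _parents=parents, _backward=bw)


def conv_transpose2x(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2 stride 2 (the classic U-Net up step).

    weight: (C_in, C_out, 2, 2).  Output positions are disjoint so the map is
    a per-offset matmul.
    """
    n, c, h, w = x.shape
    ci, co, kh, kw = weight.shape
    if ci != c or (kh, kw) != (2, 2):
        raise ValueError(f"expected weight (C_in, C_out, 2, 2), got {weight.shape}")
    out = np.empty((n, co, 2 * h, 2 * w), dtype=x.data.dtype)
    for i in range(2):
        for j in range(2):
            out[:, :, i::2, j::2] = np.einsum(
                "nchw,co->nohw", x.data, weight.data[:, :, i, j], optimize=True
            )
    if bias is not None:
        out += bias.data.reshape(1, co, 1, 1)

    def bw(g):
        if bias is not None and (bias.requires_grad or bias._parents):
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad or weight._parents:
            dw = np.empty_like(weight.data)
            for i in range(2):
                for j in range(2):
                    dw[:, :, i, j] = np.einsum(
                        "nchw,nohw->co", x.data, g[:, :, i::2, j::2], optimize=True
                    )
            weight._accum(dw)
        if x.requires_grad or x._parents:
            dx = np.zeros_like(x.data)
            for i in range(2):
                for j in range(2):
                    dx += np.einsum(
                        "nohw,co->nchw", g[:, :, i::2, j::2], weight.data[:, :, i, j],
                        optimize=True,
                    )
            x._accum(dx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, _parents=parents, _backward=bw)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    c = x.shape[1]
    xd = x.data
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def bw(g):
        if beta.requires_grad or beta._parents:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad or gamma._parents:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gi = g * gamma.data.reshape(1, c, 1, 1)
            if training:
                m = xd.shape[0] * xd.shape[2] * xd.shape[3]
                sum_gi = gi.sum(axis=(0, 2, 3), keepdims=True)
                sum_gix = (gi * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (
                    inv.reshape(1, c, 1, 1)
                    * (gi - sum_gi / m - xhat * sum_gix / m)
                )
            else:
                dx = gi * inv.reshape(1, c, 1, 1)
            x._accum(dx.astype(xd.dtype))

    return Tensor(out.astype(xd.dtype), _parents=(x, gamma, beta), _backward=bw)


def max_pool2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x requires even spatial dims, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = (
            dxr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accum(dx)

    return Tensor(out, _parents=(x,), _backward=bw)


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out = x.data.mean(axis=(2, 3), keepdims=True)

    def bw(g):
        x._accum(np.broadcast_to(g / (h * w), x.shape).astype(g.dtype))

    return Tensor(out, _parents=(x,), _backward=bw)


def _bilinear_axis_idx(n_out: int, n_in: int, dtype):
    """Half-pixel-centre sampling positions for a 2x upscale."""
    centres = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    i0 = np.floor(centres).astype(np.int64)
    frac = (centres - i0).astype(dtype)
    i0c = np.clip(i0, 0, n_in - 1)
    i1c = np.clip(i0 + 1, 0, n_in - 1)
    return i0c, i1c, frac


def upsample_bilinear2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    h0, h1, fh = _bilinear_axis_idx(2 * h, h, x.data.dtype)
    w0, w1, fw = _bilinear_axis_idx(2 * w, w, x.data.dtype)
    rows = x.data[:, :, h0, :] * (1 - fh)[None, None, :, None] + x.data[
        :, :, h1, :
    ] * fh[None, None, :, None]
    out = rows[:, :, :, w0] * (1 - fw) + rows[:, :, :, w1] * fw

    def bw(g):
        drows = np.zeros((n, c, 2 * h, w), dtype=g.dtype)
        np.add.at(drows, (slice(None), slice(None), slice(None), w0), g * (1 - fw))
        np.add.at(drows, (slice(None), slice(None), slice(None), w1), g * fw)
        dx = np.zeros((n, c, h, w), dtype=g.dtype)
        np.add.at(
            dx,
            (slice(None), slice(None), h0, slice(None)),
            drows * (1 - fh)[None, None, :, None],
        )
        np.add.at(
            dx,
            (slice(None), slice(None), h1, slice(None)),
            drows * fh[None, None, :, None],
        )
        x._accum(dx)

    return Tensor(out, _parents=(x,), _backward=bw)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=1)
    splits = np.cumsum([d.shape[1] for d in datas])[:-1]

    def bw(g):
        for t, gs in zip(tensors, np.split(g, splits, axis=1)):
            if t.requires_grad or t._parents:
                t._accum(gs)

    return Tensor(out, _parents=tuple(tensors), _backward=bw)


def dropout2d(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    n, c = x.shape[:2]
    keep = (rng.random((n, c, 1, 1)) >= p).astype(x.data.dtype) / (1.0 - p)

    def bw(g):
        x._accum(g * keep)

    return Tensor(x.data * keep, _parents=(x,), _backward=bw)


# -- activations ----------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accum(g * mask)

    return Tensor(x.data * mask, _parents=(x,), _backward=bw)


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    neg = x.data < 0
    out = np.where(neg, slope.data * x.data, x.data)

    def bw(g):
        if slope.requires_grad or slope._parents:
            slope._accum(np.array([(g * x.data * neg).sum()], dtype=slope.data.dtype))
        if x.requires_grad or x._parents:
            x._accum(g * np.where(neg, slope.data, 1.0).astype(g.dtype))

    return Tensor(out.astype(x.data.dtype), _parents=(x, slope), _backward=bw)


_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: Tensor) -> Tensor:
    xd = x.data
    cdf = 0.5 * (1.0 + erf(xd / _SQRT2))
    out = xd * cdf

    def bw(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * xd * xd)
        x._accum(g * (cdf + xd * pdf).astype(g.dtype))

    return Tensor(out.astype(xd.dtype), _parents=(x,), _backward=bw)


def swish(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = x.data * s

    def bw(g):
        x._accum(g * (s + x.data * s * (1.0 - s)))

    return Tensor(out, _parents=(x,), _backward=bw)


def mish(x: Tensor) -> Tensor:
    xd = x.data
    sp = np.logaddexp(0.0, xd)  # softplus, overflow-safe
    tsp = np.tanh(sp)
    out = xd * tsp

    def bw(g):
        sig = 1.0 / (1.0 + np.exp(-xd))
        x._accum(g * (tsp + xd * sig * (1.0 - tsp * tsp)).astype(g.dtype))

    return Tensor(out.astype(xd.dtype), _parents=(x,), _backward=bw)
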