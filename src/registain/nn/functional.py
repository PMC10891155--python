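"""Structured differentiable operations on (..., H, W) arrays.

Convolution uses an im2col/col2im pair; window sums use integral images; the
bilinear displacement sampler implements the differentiable spatial
transformation used to warp histology targets by a displacement field.  Each
operation has a numpy forward helper shared by the non-training code paths.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _kernels
from .tensor import _acc, _make, as_tensor


# ---------------------------------------------------------------- conv / pool
def conv2d(x, w, b=None, stride: int = 1, pad: int = 0):
    """2-D convolution (cross-correlation), zero padding, NCHW layout.

    x: (B, C, H, W); w: (O, C, kh, kw); b: (O,) or None.
    """
    xt, wt = as_tensor(x), as_tensor(w)
    bt = None if b is None else as_tensor(b)
    B, C, H, W = xt.data.shape
    O, _, kh, kw = wt.data.shape
    if pad:
        xp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=xt.data.dtype)
        xp[:, :, pad:-pad, pad:-pad] = xt.data
    else:
        xp = np.ascontiguousarray(xt.data)
    oh = (xp.shape[2] - kh) // stride + 1
    ow = (xp.shape[3] - kw) // stride + 1

    if _kernels.HAVE_NUMBA:
        wd = np.ascontiguousarray(wt.data)
        out = np.zeros((B, O, oh, ow), dtype=xp.dtype)
        _kernels.conv_fwd(xp, wd, stride, out)
        if bt is not None:
            out += bt.data[:, None, None]

        def backward(g):
            g = np.ascontiguousarray(g)
            if wt.requires_grad:
                dw = np.zeros_like(wd)
                _kernels.conv_bwd_w(xp, g, stride, dw)
                _acc(wt, dw)
            if bt is not None:
                _acc(bt, g.sum(axis=(0, 2, 3)))
            if xt.requires_grad:
                gxp = np.zeros_like(xp)
                _kernels.conv_bwd_x(wd, g, stride, gxp)
                _acc(xt, gxp[:, :, pad : pad + H, pad : pad + W] if pad else gxp)

        parents = (xt, wt) if bt is None else (xt, wt, bt)
        return _make(out, parents, backward)

    # BLAS/im2col fallback: (B, C*kh*kw, oh*ow) layout keeps the gather cache-friendly
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        B, C * kh * kw, oh * ow
    )
    wf = wt.data.reshape(O, -1)
    out = np.matmul(wf, cols).reshape(B, O, oh, ow)
    if bt is not None:
        out = out + bt.data[:, None, None]

    def backward(g):
        gf = np.ascontiguousarray(g).reshape(B, O, oh * ow)
        _acc(wt, np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0).reshape(wt.data.shape))
        if bt is not None:
            _acc(bt, gf.sum(axis=(0, 2)))
        if xt.requires_grad:
            dcols = np.matmul(wf.T, gf).reshape(B, C, kh, kw, oh, ow)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[
                        :, :, i, j
                    ]
            _acc(xt, gxp[:, :, pad : pad + H, pad : pad + W] if pad else gxp)

    parents = (xt, wt) if bt is None else (xt, wt, bt)
    return _make(out, parents, backward)


def avg_pool2(x):
    """2x2 average pooling; spatial dims must be even."""
    xt = as_tensor(x)
    B, C, H, W = xt.data.shape
    out_data = xt.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        _acc(xt, gx)

    return _make(out_data, (xt,), backward)


def upsample_nearest2(x):
    xt = as_tensor(x)
    out_data = np.repeat(np.repeat(xt.data, 2, axis=2), 2, axis=3)

    def backward(g):
        B, C, H2, W2 = g.shape
        _acc(xt, g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

    return _make(out_data, (xt,), backward)


# ------------------------------------------------------------------- padding
def _replicate_mats(H: int, W: int, p: int, dtype):
    ri = np.clip(np.arange(-p, H + p), 0, H - 1)
    ci = np.clip(np.arange(-p, W + p), 0, W - 1)
    R = np.zeros((H + 2 * p, H), dtype=dtype)
    R[np.arange(H + 2 * p), ri] = 1.0
    Cm = np.zeros((W + 2 * p, W), dtype=dtype)
    Cm[np.arange(W + 2 * p), ci] = 1.0
    return R, Cm


def pad_replicate(x, p: int):
    """Edge-replicating pad of the last two axes by ``p`` pixels."""
    xt = as_tensor(x)
    H, W = xt.data.shape[-2:]
    R, Cm = _replicate_mats(H, W, p, xt.data.dtype)
    out_data = R @ xt.data @ Cm.T

    def backward(g):
        _acc(xt, R.T @ g @ Cm)

    return _make(out_data, (xt,), backward)


def pad_replicate_np(x: np.ndarray, p: int) -> np.ndarray:
    widths = [(0, 0)] * (x.ndim - 2) + [(p, p), (p, p)]
    return np.pad(x, widths, mode="edge")


# --------------------------------------------------------------- window sums
def window_sum_np(x: np.ndarray, k: int, stride: int = 1) -> np.ndarray:
    """Sums over all k x k windows of the last two axes (integral image)."""
    H, W = x.shape[-2:]
    if H < k or W < k:
        raise ValueError(f"image ({H}x{W}) smaller than window k={k}")
    S = np.zeros(x.shape[:-2] + (H + 1, W + 1), dtype=np.result_type(x, np.float64))
    S[..., 1:, 1:] = x.cumsum(axis=-2).cumsum(axis=-1)
    oh = (H - k) // stride + 1
    ow = (W - k) // stride + 1
    i0 = np.arange(oh) * stride
    j0 = np.arange(ow) * stride
    a = S[..., i0[:, None] + k, j0[None, :] + k]
    b = S[..., i0[:, None], j0[None, :] + k]
    c = S[..., i0[:, None] + k, j0[None, :]]
    d = S[..., i0[:, None], j0[None, :]]
    return (a - b - c + d).astype(np.result_type(x, np.float32))


def window_sum(x, k: int, stride: int = 1):
    """Differentiable k x k sliding-window sum over the last two axes."""
    xt = as_tensor(x)
    out_data = window_sum_np(xt.data, k, stride)
    H, W = xt.data.shape[-2:]
    oh, ow = out_data.shape[-2:]

    def backward(g):
        gx = np.zeros_like(xt.data)
        for di in range(k):
            for dj in range(k):
                gx[..., di : di + stride * oh : stride, dj : dj + stride * ow : stride] += g
        _acc(xt, gx)

    return _make(out_data, (xt,), backward)


# ----------------------------------------------------- bilinear displacement
def _bilinear_pieces(img_bhwc: np.ndarray, dx: np.ndarray, dy: np.ndarray):
    """Gather the four neighbours and weights for sampling at p + (dx, dy).

    img_bhwc: (B, H, W, C); dx, dy: (B, H, W) displacements in pixels
    (dx = horizontal/column, dy = vertical/row).  Out-of-bounds sample
    positions are clamped to the border (replication).
    """
    B, H, W, _ = img_bhwc.shape
    gy, gx = np.meshgrid(
        np.arange(H, dtype=img_bhwc.dtype), np.arange(W, dtype=img_bhwc.dtype), indexing="ij"
    )
    xs = gx[None] + dx
    ys = gy[None] + dy
    in_x = (xs >= 0.0) & (xs <= W - 1.0)
    in_y = (ys >= 0.0) & (ys <= H - 1.0)
    xs = np.clip(xs, 0.0, W - 1.0)
    ys = np.clip(ys, 0.0, H - 1.0)
    x0 = np.minimum(np.floor(xs).astype(np.int64), max(W - 2, 0))
    y0 = np.minimum(np.floor(ys).astype(np.int64), max(H - 2, 0))
    wx = (xs - x0)[..., None]
    wy = (ys - y0)[..., None]
    bi = np.arange(B)[:, None, None]
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    I00 = img_bhwc[bi, y0, x0]
    I01 = img_bhwc[bi, y0, x1]
    I10 = img_bhwc[bi, y1, x0]
    I11 = img_bhwc[bi, y1, x1]
    return (I00, I01, I10, I11, wx, wy, x0, x1, y0, y1, bi, in_x, in_y)


def bilinear_warp_np(img: np.ndarray, dvf: np.ndarray) -> np.ndarray:
    """Numpy forward: img (B, C, H, W), dvf (B, 2, H, W) -> warped (B, C, H, W).

    Output(p) samples img at p + dvf(p); dvf plane 0 is the horizontal
    (column) shift, plane 1 the vertical (row) shift.
    """
    img_bhwc = np.ascontiguousarray(img.transpose(0, 2, 3, 1))
    I00, I01, I10, I11, wx, wy, *_ = _bilinear_pieces(img_bhwc, dvf[:, 0], dvf[:, 1])
    out = (
        I00 * (1 - wy) * (1 - wx)
        + I01 * (1 - wy) * wx
        + I10 * wy * (1 - wx)
        + I11 * wy * wx
    )
    return out.transpose(0, 3, 1, 2)


def grid_sample_disp(img, dvf):
    """Differentiable bilinear sampling of ``img`` at p + dvf(p).

    img: (B, C, H, W); dvf: (B, 2, H, W) (plane 0 horizontal, plane 1
    vertical, units of pixels).  Differentiable with respect to both the
    image and the displacement field; border samples replicate the edge and
    contribute zero displacement gradient where the position is clamped.
    """
    it, dt = as_tensor(img), as_tensor(dvf)
    B, C, H, W = it.data.shape
    if dt.data.shape != (B, 2, H, W):
        raise ValueError(f"dvf shape {dt.data.shape} != {(B, 2, H, W)}")
    img_bhwc = np.ascontiguousarray(it.data.transpose(0, 2, 3, 1))
    (I00, I01, I10, I11, wx, wy, x0, x1, y0, y1, bi, in_x, in_y) = _bilinear_pieces(
        img_bhwc, dt.data[:, 0], dt.data[:, 1]
    )
    out_bhwc = (
        I00 * (1 - wy) * (1 - wx)
        + I01 * (1 - wy) * wx
        + I10 * wy * (1 - wx)
        + I11 * wy * wx
    )

    def backward(g):
        gb = g.transpose(0, 2, 3, 1)  # (B, H, W, C)
        if it.requires_grad:
            gimg = np.zeros_like(img_bhwc)
            np.add.at(gimg, (bi, y0, x0), gb * (1 - wy) * (1 - wx))
            np.add.at(gimg, (bi, y0, x1), gb * (1 - wy) * wx)
            np.add.at(gimg, (bi, y1, x0), gb * wy * (1 - wx))
            np.add.at(gimg, (bi, y1, x1), gb * wy * wx)
            _acc(it, gimg.transpose(0, 3, 1, 2))
        if dt.requires_grad:
            dout_dx = (I01 - I00) * (1 - wy) + (I11 - I10) * wy
            dout_dy = (I10 - I00) * (1 - wx) + (I11 - I01) * wx
            gdx = (gb * dout_dx).sum(axis=-1) * in_x
            gdy = (gb * dout_dy).sum(axis=-1) * in_y
            _acc(dt, np.stack([gdx, gdy], axis=1))

    return _make(out_bhwc.transpose(0, 3, 1, 2), (it, dt), backward)
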