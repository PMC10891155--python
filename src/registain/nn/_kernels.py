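"""Numba-jitted convolution kernels (optional fast path).

The loops are written dtype-generically; numba specialises per signature.
If numba is unavailable the caller falls back to a BLAS/im2col path.
"""

from __future__ import annotations

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # noqa: D103
        def deco(f):
            return f

        return deco


@njit(cache=True, fastmath=True)
def _conv_fwd_s1(xp, w, out):  # pragma: no cover - jitted
    B, C, Hp, Wp = xp.shape
    O, _, kh, kw = w.shape
    H, W = out.shape[2], out.shape[3]
    for b in range(B):
        for o in range(O):
            for c in range(C):
                for i in range(kh):
                    for j in range(kw):
                        wv = w[o, c, i, j]
                        for y in range(H):
                            for x in range(W):
                                out[b, o, y, x] += wv * xp[b, c, y + i, x + j]


@njit(cache=True, fastmath=True)
def _conv_bwd_w_s1(xp, g, dw):  # pragma: no cover - jitted
    B, C, Hp, Wp = xp.shape
    O, _, kh, kw = dw.shape
    H, W = g.shape[2], g.shape[3]
    for b in range(B):
        for o in range(O):
            for c in range(C):
                for i in range(kh):
                    for j in range(kw):
                        acc = dw[o, c, i, j]
                        for y in range(H):
                            for x in range(W):
                                acc += g[b, o, y, x] * xp[b, c, y + i, x + j]
                        dw[o, c, i, j] = acc


@njit(cache=True, fastmath=True)
def _conv_bwd_x_s1(w, g, gxp):  # pragma: no cover - jitted
    B, C, Hp, Wp = gxp.shape
    O, _, kh, kw = w.shape
    H, W = g.shape[2], g.shape[3]
    for b in range(B):
        for o in range(O):
            for c in range(C):
                for i in range(kh):
                    for j in range(kw):
                        wv = w[o, c, i, j]
                        for y in range(H):
                            for x in range(W):
                                gxp[b, c, y + i, x + j] += wv * g[b, o, y, x]


@njit(cache=True, fastmath=True)
def _conv_fwd_gen(xp, w, stride, out):  # pragma: no cover - jitted
    B, C, Hp, Wp = xp.shape
    O, _, kh, kw = w.shape
    H, W = out.shape[2], out.shape[3]
    for b in range(B):
        for o in range(O):
            for c in range(C):
                for i in range(kh):
                    for j in range(kw):
                        wv = w[o, c, i, j]
                        for y in range(H):
                            yy = y * stride + i
                            for x in range(W):
                                out[b, o, y, x] += wv * xp[b, c, yy, x * stride + j]


@njit(cache=True, fastmath=True)
def _conv_bwd_w_gen(xp, g, stride, dw):  # pragma: no cover - jitted
    B, C, Hp, Wp = xp.shape
    O, _, kh, kw = dw.shape
    H, W = g.shape[2], g.shape[3]
    for b in range(B):
        for o in range(O):
            for c in range(C):
                for i in range(kh):
                    for j in range(kw):
                        acc = dw[o, c, i, j]
                        for y in range(H):
                            yy = y * stride + i
                            for x in range(W):
                                acc += g[b, o, y, x] * xp[b, c, yy, x * stride + j]
                        dw[o, c, i, j] = acc


@njit(cache=True, fastmath=True)
def _conv_bwd_x_gen(w, g, stride, gxp):  # pragma: no cover - jitted
    B, C, Hp, Wp = gxp.shape
    O, _, kh, kw = w.shape
    H, W = g.shape[2], g.shape[3]
    for b in range(B):
        for o in range(O):
            for c in range(C):
                for i in range(kh):
                    for j in range(kw):
                        wv = w[o, c, i, j]
                        for y in range(H):
                            yy = y * stride + i
                            for x in range(W):
                                gxp[b, c, yy, x * stride + j] += wv * g[b, o, y, x]


def conv_fwd(xp, w, stride, out):
    if stride == 1:
        _conv_fwd_s1(xp, w, out)
    else:
        _conv_fwd_gen(xp, w, stride, out)


def conv_bwd_w(xp, g, stride, dw):
    if stride == 1:
        _conv_bwd_w_s1(xp, g, dw)
    else:
        _conv_bwd_w_gen(xp, g, stride, dw)


def conv_bwd_x(w, g, stride, gxp):
    if stride == 1:
        _conv_bwd_x_s1(w, g, gxp)
    else:
        _conv_bwd_x_gen(w, g, stride, gxp)
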