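"""Displacement-field post-processing and differentiable sub-pixel warping.

A raw displacement vector field (DVF) predicted by the registration network
is conditioned in three fixed steps before use: (1) smoothing with a 3x3
Gaussian kernel (separable [1,2,1]/4 weights, replicate borders), (2) an
adaptive clip of outliers beyond three standard deviations from the mean of
each plane, and (3) an absolute clip to [-30, 30] pixels.  The warp itself is
bilinear sampling at ``p + dvf(p)`` with border replication, differentiable
with respect to both the image and the field.

Every function accepts either plain numpy arrays or autodiff ``Tensor``s; the
same arithmetic runs in both cases.

Field layout: plane 0 horizontal (column) shift, plane 1 vertical (row)
shift, units of pixels; arrays are ``(2, H, W)`` or batched ``(B, 2, H, W)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import functional as F
from .nn import tensor as T
from .nn.tensor import Tensor


@dataclass
class DvfPostConfig:
    adaptive_clip_sd: float = 3.0
    abs_clip: float = 30.0

    def __post_init__(self):
        if self.adaptive_clip_sd <= 0 or self.abs_clip <= 0:
            raise ValueError("adaptive_clip_sd and abs_clip must be positive")


def _data(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _where(cond, a, b):
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        return T.where(cond, a, b)
    return np.where(cond, a, b)


def smooth3(x):
    """3x3 Gaussian smoothing ([1,2,1]/4 separable) with replicate borders."""
    if isinstance(x, Tensor):
        xp = F.pad_replicate(x, 1)
    else:
        xp = F.pad_replicate_np(np.asarray(x), 1)
    t = (xp[..., 0:-2, :] + 2.0 * xp[..., 1:-1, :] + xp[..., 2:, :]) * 0.25
    return (t[..., :, 0:-2] + 2.0 * t[..., :, 1:-1] + t[..., :, 2:]) * 0.25


def _clip(x, lo, hi):
    d = _data(x)
    return _where(d < lo, lo, _where(d > hi, hi, x))


def postprocess_dvf(raw, cfg: DvfPostConfig | None = None):
    """Smooth, adaptively clip (mean +- 3 SD per plane), then clip to [-30, 30].

    ``raw``: (2, H, W) or (B, 2, H, W) displacement field.  The adaptive-clip
    statistics are computed per plane per image on the smoothed field and
    treated as constants for differentiation.
    """
    cfg = cfg or DvfPostConfig()
    d = _data(raw)
    if d.ndim not in (3, 4) or d.shape[-3] != 2:
        raise ValueError(f"expected (..., 2, H, W) displacement field, got {d.shape}")
    if not np.all(np.isfinite(d)):
        raise ValueError("displacement field contains NaN or Inf")
    sm = smooth3(raw)
    smd = _data(sm)
    mean = smd.mean(axis=(-2, -1), keepdims=True)
    sd = smd.std(axis=(-2, -1), keepdims=True)
    lo = mean - cfg.adaptive_clip_sd * sd
    hi = mean + cfg.adaptive_clip_sd * sd
    out = _clip(sm, lo, hi)
    return _clip(out, -cfg.abs_clip, cfg.abs_clip)


def warp_image(img, dvf):
    """Bilinear sample ``img`` at ``p + dvf(p)`` with border replication.

    ``img``: (H, W), (C, H, W) or (B, C, H, W); ``dvf``: (2, H, W) or
    (B, 2, H, W) matching the image spatial dims.  Returns the same layout
    as the input image.
    """
    def expand(x, target_ndim):
        """Prepend singleton axes up to target_ndim (graph-aware for Tensors)."""
        while _data(x).ndim < target_ndim:
            if isinstance(x, Tensor):
                x = x.reshape((1,) + x.data.shape)
            else:
                x = np.asarray(x)[None]
        return x

    squeeze_ch = _data(img).ndim == 2
    squeeze_batch = _data(img).ndim <= 3
    img_b = expand(img, 4)
    dvf_b = expand(dvf, 4)
    di, dd = _data(img_b), _data(dvf_b)
    if dd.shape[-3] != 2:
        raise ValueError("dvf must have two planes (horizontal, vertical)")
    if di.shape[-2:] != dd.shape[-2:]:
        raise ValueError(f"image spatial dims {di.shape[-2:]} != dvf dims {dd.shape[-2:]}")
    if isinstance(img, Tensor) or isinstance(dvf, Tensor):
        out = F.grid_sample_disp(T.as_tensor(img_b), T.as_tensor(dvf_b))
    else:
        out = F.bilinear_warp_np(
            di.astype(np.float64),
            np.broadcast_to(dd, (di.shape[0],) + dd.shape[-3:]).astype(np.float64),
        )
    if squeeze_batch:
        out = out[0]
    if squeeze_ch:
        out = out[0]
    return out


def align_target(he_raw, dvf, cfg: DvfPostConfig | None = None):
    """Warp the ORIGINAL raw histology target by a post-processed DVF.

    Always called with the raw (never previously warped) target so repeated
    alignment cannot accumulate resampling blur.
    """
    return warp_image(he_raw, postprocess_dvf(dvf, cfg))
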