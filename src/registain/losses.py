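"""Training losses: BerHu, total variation, windowed NCC and composites.

All functions accept either plain numpy arrays (returning floats, used by the
oracle tests and evaluation code) or autodiff ``Tensor``s (returning scalar
Tensors, used by the trainer); a single arithmetic path serves both.

Image layout is channel-first: ``(H, W)``, ``(C, H, W)`` or ``(B, C, H, W)``,
with the last two axes spatial.  Multi-channel convention: BerHu and TV sum
over channels; NCC averages the per-window correlation over channels (and
batch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import functional as F
from .nn import tensor as T
from .nn.tensor import Tensor


@dataclass
class LossConfig:
    """Weights and window settings for the generator/registration losses.

    alpha: total-variation weight in the generator loss (0.02).
    beta: adversarial weight in the generator loss (50).
    delta_frac: BerHu delta as a fraction of the target's SD (0.2).
    ncc_window: sliding-window size k for NCC (20 pixels).
    ncc_stride: window stride; 1 evaluates every window placement.
    ncc_eps: stabiliser added to the window SD product.
    """

    alpha: float = 0.02
    beta: float = 50.0
    delta_frac: float = 0.2
    ncc_window: int = 20
    ncc_stride: int = 1
    ncc_eps: float = 1e-6
    reg_tv_reduction: str = "mean"  # TV term of the registration loss: "sum" | "mean"

    def __post_init__(self):
        for name in ("alpha", "beta", "delta_frac", "ncc_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _data(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _where(cond, a, b):
    if _is_tensor(a, b):
        return T.where(cond, a, b)
    return np.where(cond, a, b)


def _abs(x):
    return x.abs() if isinstance(x, Tensor) else np.abs(x)


def _sqrt(x):
    return T.tsqrt(x) if isinstance(x, Tensor) else np.sqrt(x)


def _sum_all(x):
    return x.sum() if isinstance(x, Tensor) else float(np.sum(x))


def _mean_all(x):
    return x.mean() if isinstance(x, Tensor) else float(np.mean(x))


def _check_shapes(a, b):
    if _data(a).shape != _data(b).shape:
        raise ValueError(f"shape mismatch: {_data(a).shape} vs {_data(b).shape}")


# ----------------------------------------------------------------- primitives
def berhu(a, b, delta: float):
    """Reverse Huber loss: |d| up to delta, (d^2 + delta^2)/(2 delta) beyond.

    Summed over all pixels and channels; continuous at |d| = delta.
    """
    _check_shapes(a, b)
    if not np.isfinite(delta) or delta <= 0:
        raise ValueError("delta must be a positive finite number")
    d = a - b
    ad = _abs(d)
    quad = (ad ** 2 + delta ** 2) * (0.5 / delta)
    return _sum_all(_where(_data(ad) <= delta, ad, quad))


def tv(a):
    """Anisotropic total variation: interior first differences, summed.

    Sum over valid index pairs of |a(m+1,n)-a(m,n)| + |a(m,n+1)-a(m,n)|,
    accumulated over channels (and batch).
    """
    if _data(a).size == 0:
        raise ValueError("empty image")
    dv = _abs(a[..., 1:, :] - a[..., :-1, :])
    dh = _abs(a[..., :, 1:] - a[..., :, :-1])
    return _sum_all(dv) + _sum_all(dh)


def ncc(a, b, k: int = 20, stride: int = 1, eps: float = 1e-6):
    """Mean windowed normalized cross-correlation in [-1, 1].

    Every k x k window placement (at the given stride) contributes the
    Pearson correlation of the window contents, with ``eps`` added to the
    product of the window standard deviations; the result is the mean over
    window placements, channels and batch.  Constant windows contribute 0.
    """
    _check_shapes(a, b)
    H, W = _data(a).shape[-2:]
    if H < k or W < k:
        raise ValueError(f"image ({H}x{W}) smaller than NCC window k={k}")

    def ws(x):
        return F.window_sum(x, k, stride) if isinstance(x, Tensor) else F.window_sum_np(np.asarray(x, dtype=np.float64), k, stride)

    inv_k2 = 1.0 / (k * k)
    mu_a = ws(a) * inv_k2
    mu_b = ws(b) * inv_k2
    cov = ws(a * b) * inv_k2 - mu_a * mu_b
    var_a = ws(a * a) * inv_k2 - mu_a ** 2
    var_b = ws(b * b) * inv_k2 - mu_b ** 2
    var_a = _where(_data(var_a) < 0, 0.0, var_a)
    var_b = _where(_data(var_b) < 0, 0.0, var_b)
    if _is_tensor(a, b):
        # tiny floor keeps the sqrt gradient finite on constant windows
        sigma = _sqrt(var_a * var_b + 1e-12)
    else:
        sigma = _sqrt(var_a * var_b)
    return _mean_all(cov / (sigma + eps))


# ----------------------------------------------------------------- composites
def generator_loss(i_vs, i_hs_reg, d_of_vs, cfg: LossConfig | None = None):
    """BerHu + alpha*TV + beta*(1 - D(I_VS))^2, with per-target adaptive delta.

    delta is ``delta_frac`` times the standard deviation of the registered
    target (a constant for differentiation).  Returns (total, components).
    """
    cfg = cfg or LossConfig()
    delta = max(cfg.delta_frac * float(_data(i_hs_reg).std()), 1e-8)
    l_berhu = berhu(i_vs, i_hs_reg, delta)
    l_tv = tv(i_vs)
    l_adv = (1.0 - d_of_vs) ** 2 * cfg.beta
    total = l_berhu + cfg.alpha * l_tv + l_adv
    components = {
        "berhu": float(_data(l_berhu)),
        "tv": float(_data(l_tv)),
        "adv": float(_data(l_adv)),
        "delta": delta,
    }
    return total, components


def discriminator_loss(d_of_vs, d_of_real):
    """D(I_VS)^2 + (1 - D(I_HS,raw))^2; the raw target serves as the real image."""
    for name, v in (("d_of_vs", d_of_vs), ("d_of_real", d_of_real)):
        val = float(np.max(_data(v))), float(np.min(_data(v)))
        if val[0] > 1.0 + 1e-9 or val[1] < -1e-9:
            raise ValueError(f"{name} must be a probability in [0, 1], got {val}")
    return d_of_vs ** 2 + (1.0 - d_of_real) ** 2


def registration_loss(i_vs, i_hs_reg, dvf, cfg: LossConfig | None = None,
                      tv_reduction: str = "sum"):
    """1 - NCC(I_VS, I_HS,reg) + TV(DVF); TV covers both displacement planes.

    ``tv_reduction="sum"`` is the plain summed form; ``"mean"`` divides the
    TV term by the number of field elements, which balances it against the
    bounded NCC term (the trainer uses the mean form — a summed TV over a
    pixel-unit field is several orders of magnitude stiffer than the
    registration signal and pins the field at a constant).
    """
    cfg = cfg or LossConfig()
    tv_term = tv(dvf)
    if tv_reduction == "mean":
        tv_term = tv_term * (1.0 / _data(dvf).size)
    elif tv_reduction != "sum":
        raise ValueError("tv_reduction must be 'sum' or 'mean'")
    return 1.0 - ncc(i_vs, i_hs_reg, k=cfg.ncc_window, stride=cfg.ncc_stride, eps=cfg.ncc_eps) + tv_term
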