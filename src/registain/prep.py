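"""Training-data preparation: coarse registration, tiling and pair screening.

The two-step workflow mirrors slide-scale practice: (1) rigid registration of
the whole histology image to the autofluorescence image by maximising the
cross-correlation over a grid of candidate rotation angles; (2) per-tile
multi-modal affine refinement, followed by centre-cropping each tile to drop
edge artifacts, and (3) screening of candidate training pairs by PSNR/SSIM
thresholds (reject below PSNR 15 or SSIM 0.6).

Conventions: 0-based (row, col), top-left origin; shifts stored as
``(dx, dy)`` = (column shift, row shift).  A positive shift means the moving
image content must move right/down to align with the fixed image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage, signal

from .evalqc import psnr, ssim
from .image import PairedSample

try:  # SimpleITK backs the multi-modal affine refinement
    import SimpleITK as sitk
except ImportError:  # pragma: no cover
    sitk = None

DEFAULT_ANGLE_GRID = (0.0, 90.0, 180.0, -90.0)


@dataclass
class RigidTransform:
    """Estimated pose of the moving image relative to the fixed image.

    ``angle`` and ``shift`` report the rotation/translation that the moving
    image exhibits w.r.t. the fixed one; ``apply`` undoes both.
    """

    angle: float  # degrees, in (-180, 180]
    shift: Tuple[float, float]  # (dx, dy) pixels

    def apply(self, img: np.ndarray) -> np.ndarray:
        """Undo the estimated rotation and shift (zero fill), aligning to fixed."""
        out = _rotate(img, self.angle)
        dx, dy = self.shift
        return ndimage.shift(out, _shift_vector(out.ndim, -dy, -dx), order=1, cval=0.0)


@dataclass
class AffineTransform:
    matrix: np.ndarray  # 2x3, maps moving (x, y, 1) -> fixed (x, y)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("linear part is singular")

    def apply(self, moving: np.ndarray) -> np.ndarray:
        """Resample the moving image onto the fixed grid."""
        A = np.vstack([self.matrix, [0.0, 0.0, 1.0]])
        inv = np.linalg.inv(A)  # fixed -> moving, (x, y) convention
        # scipy affine_transform works in (row, col) = (y, x) order
        lin = inv[:2, :2][::-1, ::-1]
        off = inv[:2, 2][::-1]
        if moving.ndim == 2:
            return ndimage.affine_transform(moving, lin, offset=off, order=1, cval=0.0)
        out = np.empty_like(moving, dtype=np.float64)
        for c in range(moving.shape[2]):
            out[..., c] = ndimage.affine_transform(
                moving[..., c].astype(np.float64), lin, offset=off, order=1, cval=0.0
            )
        return out


@dataclass
class ScreenConfig:
    psnr_min: float = 15.0
    ssim_min: float = 0.6

    def __post_init__(self):
        if self.psnr_min <= 0:
            raise ValueError("psnr_min must be > 0")
        if not 0.0 < self.ssim_min <= 1.0:
            raise ValueError("ssim_min must be in (0, 1]")


def _luminance(img: np.ndarray) -> np.ndarray:
    """Mean over channels, cast to float (the documented luminance reduction)."""
    arr = np.asarray(img, dtype=np.float64)
    return arr.mean(axis=2) if arr.ndim == 3 else arr


def _rotate(img: np.ndarray, angle: float) -> np.ndarray:
    """Rotate by -angle (undoing a relative rotation); exact for multiples of 90."""
    if angle % 90.0 == 0.0:
        k = int(angle // 90) % 4
        return np.rot90(img, k=-k, axes=(0, 1))
    return ndimage.rotate(img, -angle, axes=(1, 0), reshape=False, order=1, cval=0.0)


def _shift_vector(ndim: int, dy: float, dx: float):
    return (dy, dx) if ndim == 2 else (dy, dx) + (0.0,) * (ndim - 2)


def rigid_register_wsi(
    moving, fixed, angle_grid: Sequence[float] = DEFAULT_ANGLE_GRID
) -> RigidTransform:
    """Grid-search rotation + FFT cross-correlation shift of moving vs fixed.

    Returns the angle from the grid and the integer (dx, dy) shift maximising
    the normalised cross-correlation of the mean-subtracted luminances
    (luminance = channel mean); ties break toward the smallest |shift|, then
    smallest |angle|.  Cross-modality callers should pass the brightfield
    side inverted (e.g. ``1 - luminance``) so tissue correlates positively
    with fluorescence signal — the CLI's prep command does this.
    """
    fl = _luminance(fixed)
    ml = _luminance(moving)
    if fl.size == 0 or ml.size == 0:
        raise ValueError("empty image")
    fl = fl - fl.mean()
    if np.ptp(fl) == 0 or np.ptp(ml) == 0:
        raise ValueError("constant image: cross-correlation undefined")
    candidates = []
    for angle in angle_grid:
        rot = _rotate(ml, angle)  # hypothesise the relative rotation, undo it
        rot = rot - rot.mean()
        denom = np.linalg.norm(fl) * np.linalg.norm(rot)
        if denom == 0:
            continue
        corr = signal.fftconvolve(fl, rot[::-1, ::-1], mode="full") / denom
        idx = np.unravel_index(np.argmax(corr), corr.shape)
        peak = corr[idx]
        # argmax gives the corrective shift; report the exhibited displacement
        dy = -(idx[0] - (rot.shape[0] - 1))
        dx = -(idx[1] - (rot.shape[1] - 1))
        candidates.append((peak, float(np.hypot(dx, dy)), abs(angle), angle, (int(dx), int(dy))))
    best_peak = max(c[0] for c in candidates)
    viable = [c for c in candidates if c[0] >= best_peak - 1e-9]
    viable.sort(key=lambda c: (c[1], c[2]))
    _, _, _, angle, shift = viable[0]
    angle = ((angle + 180.0) % 360.0) - 180.0
    if angle == -180.0:
        angle = 180.0
    return RigidTransform(angle=angle, shift=shift)


def affine_register_patch(
    moving, fixed, criterion: str = "mattes", iterations: int = 200
) -> Tuple[AffineTransform, dict]:
    """Multi-modal affine registration of a patch pair via SimpleITK.

    ``criterion`` selects Mattes mutual information (default) or correlation.
    Returns (transform mapping moving -> fixed coordinates, info dict with
    the final metric value).  Raises RuntimeError with diagnostics if the
    optimisation fails; callers may fall back to identity.
    """
    if sitk is None:  # pragma: no cover
        raise RuntimeError("SimpleITK is required for affine registration")
    fl = _luminance(fixed).astype(np.float32)
    ml = _luminance(moving).astype(np.float32)
    if fl.shape != ml.shape:
        raise ValueError("patches must have equal size")
    f_img = sitk.GetImageFromArray(fl)
    m_img = sitk.GetImageFromArray(ml)
    reg = sitk.ImageRegistrationMethod()
    if criterion == "mattes":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    elif criterion == "correlation":
        reg.SetMetricAsCorrelation()
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-7, numberOfIterations=iterations,
        relaxationFactor=0.5, gradientMagnitudeTolerance=1e-10,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    levels = [4, 2, 1] if min(fl.shape) >= 64 else [1]
    reg.SetShrinkFactorsPerLevel(levels)
    reg.SetSmoothingSigmasPerLevel([max(l - 1, 0) for l in levels])
    init = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.AffineTransform(2),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(init, inPlace=False)
    try:
        init_metric = float(reg.MetricEvaluate(f_img, m_img))
        final = reg.Execute(f_img, m_img)
    except RuntimeError as exc:  # optimisation failure with diagnostics
        raise RuntimeError(f"affine registration failed: {exc}") from exc
    metric = float(reg.GetMetricValue())
    if init_metric <= metric:  # guard: never return worse than the initialization
        final, metric = init, init_metric
    # Flatten (possibly composite) result to a single affine in pixel coords.
    affine = _flatten_to_affine(final)
    A = np.array(affine.GetMatrix(), dtype=np.float64).reshape(2, 2)
    t = np.array(affine.GetTranslation(), dtype=np.float64)
    center = np.array(affine.GetCenter(), dtype=np.float64)
    # sitk maps fixed physical points to moving: m = A (f - c) + c + t
    full_t = center + t - A @ center
    fixed_to_moving = np.hstack([A, full_t[:, None]])
    M = np.vstack([fixed_to_moving, [0, 0, 1]])
    moving_to_fixed = np.linalg.inv(M)[:2, :]
    info = {"metric": metric, "criterion": criterion,
            "stop": reg.GetOptimizerStopConditionDescription()}
    return AffineTransform(moving_to_fixed), info


def _flatten_to_affine(transform) -> "sitk.AffineTransform":
    if transform.GetName() == "CompositeTransform":
        comp = sitk.CompositeTransform(transform)
        if comp.GetNumberOfTransforms() != 1:
            raise RuntimeError("unexpected composite transform from registration")
        transform = comp.GetNthTransform(0)
    return sitk.AffineTransform(transform)


def tile_paired_wsi(
    af_wsi: np.ndarray,
    he_wsi_registered: np.ndarray,
    tile: int = 3248,
    crop: int = 2048,
    tissue_min: float = 0.05,
    refine_affine: bool = True,
    background_threshold: float = 235.0 / 255.0,
) -> List[PairedSample]:
    """Non-overlapping tiling with per-tile affine refinement and centre crop.

    Each ``tile``-sized histology tile is affine-registered to its
    autofluorescence counterpart, then both are centre-cropped by
    ``(tile - crop) / 2`` per side; tiles with less than ``tissue_min``
    tissue are discarded.
    """
    af = np.asarray(af_wsi)
    he = np.asarray(he_wsi_registered)
    if af.shape[:2] != he.shape[:2]:
        raise ValueError("WSIs must have equal spatial dims after coarse registration")
    H, W = af.shape[:2]
    if H < tile or W < tile:
        raise ValueError(f"WSI ({H}x{W}) smaller than one {tile}x{tile} tile")
    if (tile - crop) % 2:
        raise ValueError("tile - crop must be even for a symmetric centre crop")
    margin = (tile - crop) // 2
    he01 = he.astype(np.float64) / 255.0 if he.dtype == np.uint8 else he.astype(np.float64)
    out: List[PairedSample] = []
    for i in range(H // tile):
        for j in range(W // tile):
            y, x = i * tile, j * tile
            af_t = af[y : y + tile, x : x + tile]
            he_t = he01[y : y + tile, x : x + tile]
            info = {}
            if refine_affine:
                try:
                    tf, info = affine_register_patch(he_t, af_t)
                    he_t = tf.apply(he_t)
                except RuntimeError as exc:
                    info = {"affine_error": str(exc)}  # identity fallback
            af_c = af_t[margin : margin + crop, margin : margin + crop]
            he_c = he_t[margin : margin + crop, margin : margin + crop]
            lum = he_c.mean(axis=2) if he_c.ndim == 3 else he_c
            tissue_frac = float((lum < background_threshold).mean())
            if tissue_frac < tissue_min:
                continue
            out.append(
                PairedSample(
                    af=af_c,
                    he_raw=np.clip(he_c, 0.0, 1.0),
                    meta={"offset": (y + margin, x + margin),
                          "tissue_fraction": tissue_frac, **info},
                )
            )
    return out


def screen_training_pair(pre_vs, he, cfg: ScreenConfig | None = None):
    """Keep a candidate pair iff PSNR >= psnr_min AND SSIM >= ssim_min.

    ``pre_vs`` is the output of a preliminary staining model for the pair's
    input; boundary values are kept.  Returns (keep, {"psnr": ..., "ssim": ...}).
    """
    cfg = cfg or ScreenConfig()
    a, b = np.asarray(pre_vs), np.asarray(he)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    p = psnr(pre_vs, he)
    s = ssim(pre_vs, he)
    keep = (p >= cfg.psnr_min) and (s >= cfg.ssim_min)
    return keep, {"psnr": p, "ssim": s}
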