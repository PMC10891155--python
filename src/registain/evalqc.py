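"""Quantitative staining evaluation and slide quality control.

Implements the global SSIM/PSNR image-quality statistics, Beer-Lambert stain
unmixing into hematoxylin/eosin concentration channels, Otsu-based nuclei
segmentation with morphological cleanup, connected-component nuclei
quantification, the paired two-tailed t-test used to compare nuclei
statistics, and the FOV-level staining-artifact screening workflow (nuclei
area fraction and mean eosin intensity against thresholds 0.01 / 0.07).

SSIM here is the single-window whole-image statistic (means, variances and
covariance over the full image), not the conventional 11x11 locally windowed
variant; a windowed option exists behind a flag for exploration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .phantom import DEFAULT_STAIN_VECTORS

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class MetricConfig:
    c1: float = 1e-4
    c2: float = 9e-4

    def __post_init__(self):
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("SSIM stabilizers must be positive")


@dataclass
class QCConfig:
    fov: int = 8000
    nuclei_area_threshold: float = 0.01
    eosin_intensity_threshold: float = 0.07
    background_threshold: float = 235.0 / 255.0  # tissue = mean RGB below this
    eosin_od_ref: float = 1.0  # eosin concentration mapped to [0,1] against this OD
    stain_vectors: np.ndarray = field(default_factory=lambda: DEFAULT_STAIN_VECTORS.copy())

    def __post_init__(self):
        if self.fov <= 0:
            raise ValueError("fov must be positive")
        if self.nuclei_area_threshold <= 0 or self.eosin_intensity_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class FovRecord:
    row: int
    col: int
    nuclei_area_fraction: Optional[float]
    eosin_mean_intensity: Optional[float]
    label: str  # "well" | "poor" | "skipped"
    reason: str = ""


@dataclass
class QualityReport:
    fovs: List[FovRecord]

    @property
    def n_well(self) -> int:
        return sum(1 for f in self.fovs if f.label == "well")

    @property
    def n_poor(self) -> int:
        return sum(1 for f in self.fovs if f.label == "poor")

    def to_records(self):
        return [vars(f).copy() for f in self.fovs]


def _as_float01(img: np.ndarray) -> np.ndarray:
    """Coerce an RGB image to float in [0, 1] (uint8 inputs divided by 255)."""
    arr = np.asarray(img)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    return arr.astype(np.float64)


# ----------------------------------------------------------------- metrics
def ssim(a, b, cfg: MetricConfig | None = None, windowed: bool = False, window: int = 11) -> float:
    """Whole-image structural similarity, averaged over channels.

    Intensities are expected on the [0, 1] scale.  With ``windowed=True`` a
    conventional sliding-window mean of the same statistic is returned
    instead (never used by the screening defaults).
    """
    cfg = cfg or MetricConfig()
    A, B = _as_float01(a), _as_float01(b)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if A.ndim == 2:
        A, B = A[..., None], B[..., None]
    vals = []
    for c in range(A.shape[2]):
        x, y = A[..., c], B[..., c]
        if windowed:
            vals.append(_ssim_windowed(x, y, cfg, window))
            continue
        mu_x, mu_y = x.mean(), y.mean()
        var_x, var_y = x.var(), y.var()
        cov = ((x - mu_x) * (y - mu_y)).mean()
        vals.append(
            ((2 * mu_x * mu_y + cfg.c1) * (2 * cov + cfg.c2))
            / ((mu_x ** 2 + mu_y ** 2 + cfg.c1) * (var_x + var_y + cfg.c2))
        )
    return float(np.mean(vals))


def _ssim_windowed(x, y, cfg, k):
    from .nn.functional import window_sum_np

    n = k * k
    mx = window_sum_np(x, k) / n
    my = window_sum_np(y, k) / n
    vx = np.maximum(window_sum_np(x * x, k) / n - mx ** 2, 0.0)
    vy = np.maximum(window_sum_np(y * y, k) / n - my ** 2, 0.0)
    cov = window_sum_np(x * y, k) / n - mx * my
    s = ((2 * mx * my + cfg.c1) * (2 * cov + cfg.c2)) / (
        (mx ** 2 + my ** 2 + cfg.c1) * (vx + vy + cfg.c2)
    )
    return float(s.mean())


def psnr(i_vs, i_hs) -> float:
    """10 log10(max(reference)^2 / MSE); +inf for identical images.

    The peak is the maximum intensity of the *reference* image, not a fixed
    dynamic range; MSE averages over pixels and channels.
    """
    a, b = _as_float01(i_vs), _as_float01(i_hs)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    peak = float(b.max())
    return float(10.0 * np.log10(peak ** 2 / mse))


# ------------------------------------------------------------- stain unmixing
def stain_unmix(rgb, stain_vectors: np.ndarray | None = None) -> Tuple[np.ndarray, np.ndarray]:
    """Beer-Lambert unmixing into (hematoxylin, eosin) concentration maps.

    Per pixel OD = -log(clip(rgb, 1, 255) / 255) componentwise — the exact
    inverse of the Beer-Lambert renderer before quantization (uint8 or
    0..255 floats accepted; [0,1] floats are rescaled) — projected onto the
    two unit stain vectors by least squares; negative concentrations clip
    to 0.
    """
    v = DEFAULT_STAIN_VECTORS if stain_vectors is None else np.asarray(stain_vectors, dtype=np.float64)
    if v.shape != (2, 3):
        raise ValueError("stain_vectors must be (2, 3)")
    gram = v @ v.T
    if abs(np.linalg.det(gram)) < 1e-8:
        raise ValueError("degenerate stain vector pair")
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got {arr.shape}")
    if arr.max() <= 1.0:
        arr = arr * 255.0
    od = -np.log(np.clip(arr, 1.0, 255.0) / 255.0)
    conc = od @ v.T @ np.linalg.inv(gram)  # least-squares coefficients
    conc = np.clip(conc, 0.0, None)
    return conc[..., 0], conc[..., 1]


# ------------------------------------------------------- nuclei quantification
def segment_nuclei(hema_od: np.ndarray, opening_radius: int = 1, min_od: float = 0.15) -> np.ndarray:
    """Nuclei mask: Otsu threshold on the hematoxylin channel + binary opening.

    The effective threshold is max(Otsu, ``min_od``): nuclei are
    hematoxylin-dense, and the floor keeps unmixing/quantization noise in
    stain-free images from being segmented.  Opening uses a disk of radius
    ``opening_radius`` (erosion then dilation).
    """
    od = np.asarray(hema_od, dtype=np.float64)
    if np.any(od < 0):
        raise ValueError("hematoxylin OD must be non-negative")
    if od.size == 0 or od.max() == od.min():
        return np.zeros(od.shape, dtype=bool)
    mask = od > max(float(threshold_otsu(od)), min_od)
    if not mask.any():
        return mask
    return ndimage.binary_opening(mask, structure=disk(opening_radius))


def nuclei_stats(mask: np.ndarray) -> Tuple[int, float]:
    """(count, mean area in pixels) of 8-connected components; empty -> (0, nan)."""
    arr = np.asarray(mask)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary")
        arr = arr.astype(bool)
    labels, count = ndimage.label(arr, structure=EIGHT_CONNECTED)
    if count == 0:
        return 0, float("nan")
    areas = np.bincount(labels.ravel())[1:]
    return int(count), float(areas.mean())


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Classical two-tailed paired t-test on d = x - y; returns (t, P)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------------- FOV screening
def fov_quality_metrics(he_fov, cfg: QCConfig | None = None) -> Tuple[float, float]:
    """(nuclei area fraction of tissue, mean eosin intensity over tissue).

    Tissue is everything below the background threshold (mean RGB).  The
    eosin concentration channel is mapped to [0, 1] against a reference OD
    of ``eosin_od_ref`` before averaging.  Raises on zero tissue area.
    """
    cfg = cfg or QCConfig()
    rgb01 = _as_float01(he_fov)
    tissue = rgb01.mean(axis=2) < cfg.background_threshold
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("zero tissue area in FOV")
    hema, eosin = stain_unmix(rgb01 * 255.0, cfg.stain_vectors)
    nuclei = segment_nuclei(hema)
    metric1 = float((nuclei & tissue).sum()) / n_tissue
    eosin01 = np.clip(eosin / cfg.eosin_od_ref, 0.0, 1.0)
    metric2 = float(eosin01[tissue].mean())
    return metric1, metric2


def classify_fovs(wsi, cfg: QCConfig | None = None) -> QualityReport:
    """Split a WSI into FOVs and label each well/poor by the two metrics.

    A FOV is well-stained iff BOTH metrics strictly exceed their thresholds
    (equality counts as poor); FOVs with no tissue are skipped with a reason.
    """
    cfg = cfg or QCConfig()
    arr = np.asarray(wsi)
    H, W = arr.shape[:2]
    f = cfg.fov
    if H < f or W < f:
        raise ValueError(f"WSI ({H}x{W}) smaller than one {f}x{f} FOV")
    records: List[FovRecord] = []
    for i in range(H // f):
        for j in range(W // f):
            fov = arr[i * f : (i + 1) * f, j * f : (j + 1) * f]
            try:
                m1, m2 = fov_quality_metrics(fov, cfg)
            except ValueError as exc:
                records.append(FovRecord(i, j, None, None, "skipped", str(exc)))
                continue
            well = m1 > cfg.nuclei_area_threshold and m2 > cfg.eosin_intensity_threshold
            records.append(FovRecord(i, j, m1, m2, "well" if well else "poor"))
    return QualityReport(records)


# --------------------------------------------------------- paired evaluation
def evaluate_staining(
    vs_images: Sequence, he_images: Sequence, cfg: QCConfig | None = None
) -> dict:
    """SSIM/PSNR per pair plus nuclei-count/size distributions and paired t-tests."""
    cfg = cfg or QCConfig()
    if len(vs_images) != len(he_images):
        raise ValueError("need equally many virtual and histochemical images")
    out = {"ssim": [], "psnr": [], "vs_counts": [], "he_counts": [], "vs_areas": [], "he_areas": []}
    for vs, he in zip(vs_images, he_images):
        out["ssim"].append(ssim(vs, he))
        out["psnr"].append(psnr(vs, he))
        for key_img, prefix in ((vs, "vs"), (he, "he")):
            hema, _ = stain_unmix(_as_float01(key_img) * 255.0, cfg.stain_vectors)
            count, area = nuclei_stats(segment_nuclei(hema))
            out[f"{prefix}_counts"].append(count)
            out[f"{prefix}_areas"].append(area if np.isfinite(area) else 0.0)
    if len(vs_images) >= 2:
        out["ttest_counts"] = paired_ttest(out["vs_counts"], out["he_counts"])
        out["ttest_areas"] = paired_ttest(out["vs_areas"], out["he_areas"])
    out["mean_ssim"] = float(np.mean(out["ssim"]))
    finite = [p for p in out["psnr"] if np.isfinite(p)]
    out["mean_psnr"] = float(np.mean(finite)) if finite else float("inf")
    return out
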