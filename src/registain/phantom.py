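"""Synthetic paired autofluorescence / H&E phantoms with known ground truth.

The phantom emulates the three properties the training framework must cope
with: (a) a fixed, invertible texture-to-colour mapping between the
autofluorescence channels and the stain optical densities, (b) smooth elastic
misalignment between the two modalities, and (c) under-staining artifacts
(faded hematoxylin and/or eosin).  Nuclei are drawn as ellipses carrying
hematoxylin optical density (OD), cytoplasm as a smooth eosin OD texture,
and the RGB H&E image is rendered through Beer-Lambert composition with the
classical hematoxylin/eosin stain colour vectors.

All randomness flows from the single seed in the spec via a named
``numpy.random.Generator``; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .image import MultiChannelImage, PairedSample
from .warp import warp_image

#: Classical H&E optical-density colour vectors (rows), L2-normalised.
DEFAULT_STAIN_VECTORS = np.array(
    [[0.650, 0.704, 0.286], [0.072, 0.990, 0.105]], dtype=np.float64
)
DEFAULT_STAIN_VECTORS /= np.linalg.norm(DEFAULT_STAIN_VECTORS, axis=1, keepdims=True)

#: Saturation rates of the documented invertible OD -> autofluorescence mapping.
AF_GAIN_DAPI = 2.0
AF_GAIN_TXRED = 1.5


@dataclass
class PhantomSpec:
    height: int = 256
    width: int = 256
    n_nuclei: int = 60
    nucleus_radius_range: Tuple[float, float] = (4.0, 8.0)
    nucleus_overlap_allowed: bool = False
    cytoplasm_texture_scale: float = 8.0
    background_fraction: float = 0.25
    hematoxylin_od_nucleus: float = 0.9
    eosin_od_cytoplasm: float = 0.55
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError("height and width must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        lo, hi = self.nucleus_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("nucleus radii must be positive with lo <= hi")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")


@dataclass
class ArtifactSpec:
    """Under-staining artifact: fade fractions in [0, 1] per stain."""

    hema_fade: float = 0.0
    eosin_fade: float = 0.0
    region_mask: Optional[np.ndarray] = None  # None means the whole image

    def __post_init__(self):
        if not (0.0 <= self.hema_fade <= 1.0 and 0.0 <= self.eosin_fade <= 1.0):
            raise ValueError("fades must be in [0, 1]")


@dataclass
class MisalignmentSpec:
    """Cross-modality misalignment: constant translation or smooth random field."""

    mode: str = "smooth_random"
    amplitude: float = 4.0
    smoothness_scale: float = 16.0
    seed: int = 0
    translation: Optional[Tuple[float, float]] = None  # (dx, dy); translation mode

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class PhantomSample:
    af: MultiChannelImage  # (H, W, 2) float32 in [0, 1]: DAPI-role, TxRed-role
    he_ideal: MultiChannelImage  # (H, W, 3) uint8 RGB
    nuclei_mask: np.ndarray  # (H, W) bool
    nuclei_count: int
    od_maps: np.ndarray  # (H, W, 2) float32: hematoxylin, eosin OD
    tissue_mask: np.ndarray = None  # (H, W) bool
    true_dvf: Optional[np.ndarray] = None  # (2, H, W); aligns he_raw to the AF frame
    spec: Optional[PhantomSpec] = None


def render_he(od_maps: np.ndarray, stain_vectors: np.ndarray | None = None) -> MultiChannelImage:
    """Beer-Lambert rendering: RGB = round(255 * exp(-(c_h v_h + c_e v_e))).

    ``od_maps``: (H, W, 2) non-negative stain concentrations (OD units);
    ``stain_vectors``: two unit RGB-OD vectors as rows (defaults to the
    classical hematoxylin/eosin pair).
    """
    od = np.asarray(od_maps, dtype=np.float64)
    if od.ndim != 3 or od.shape[2] != 2:
        raise ValueError(f"od_maps must be (H, W, 2), got {od.shape}")
    if np.any(od < 0):
        raise ValueError("optical densities must be non-negative")
    v = DEFAULT_STAIN_VECTORS if stain_vectors is None else np.asarray(stain_vectors, dtype=np.float64)
    _check_stain_vectors(v)
    absorbance = od @ v  # (H, W, 3)
    rgb = np.round(255.0 * np.exp(-absorbance))
    return MultiChannelImage(rgb.astype(np.uint8), ("R", "G", "B"))


def _check_stain_vectors(v: np.ndarray) -> None:
    if v.shape != (2, 3):
        raise ValueError("stain_vectors must be (2, 3)")
    norms = np.linalg.norm(v, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("stain vectors must be unit-norm")
    if np.linalg.matrix_rank(v, tol=1e-8) < 2:
        raise ValueError("stain vectors must be linearly independent")


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom sample; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width

    # Tissue support: smooth random field thresholded at the background quantile.
    base = ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma=max(H, W) / 8.0)
    if spec.background_fraction <= 0.0:
        tissue = np.ones((H, W), dtype=bool)
    elif spec.background_fraction >= 1.0:
        tissue = np.zeros((H, W), dtype=bool)
    else:
        tissue = base >= np.quantile(base, spec.background_fraction)

    nuclei_mask = np.zeros((H, W), dtype=bool)
    od_h = np.zeros((H, W), dtype=np.float64)
    placed = 0
    r_hi = spec.nucleus_radius_range[1]
    for _ in range(spec.n_nuclei):
        ok = False
        for _attempt in range(200):
            ry = rng.uniform(*spec.nucleus_radius_range)
            rx = rng.uniform(*spec.nucleus_radius_range)
            theta = rng.uniform(0.0, np.pi)
            margin = r_hi + 1
            if H <= 2 * margin or W <= 2 * margin:
                raise RuntimeError(
                    "phantom too small to place nuclei of the requested radius"
                )
            cy = rng.uniform(margin, H - margin)
            cx = rng.uniform(margin, W - margin)
            if tissue.any() and not tissue[int(cy), int(cx)]:
                continue
            ell = _ellipse_patch(cy, cx, ry, rx, theta, H, W)
            if ell is None:
                continue
            ys, xs = ell
            if not spec.nucleus_overlap_allowed:
                # require a 2-px separation: keeps 8-connected components
                # distinct and prevents the optical blur from bridging
                # adjacent nuclei above the segmentation threshold
                box = np.zeros((H, W), dtype=bool)
                box[ys, xs] = True
                grown = ndimage.binary_dilation(box, structure=np.ones((3, 3)), iterations=2)
                if np.any(nuclei_mask & grown):
                    continue
            nuclei_mask[ys, xs] = True
            od_h[ys, xs] = spec.hematoxylin_od_nucleus * rng.uniform(0.85, 1.15)
            placed += 1
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place nucleus {placed + 1}/{spec.n_nuclei} without overlap "
                "after 200 retries; reduce n_nuclei, radii, or allow overlap"
            )

    # Cytoplasm: smooth eosin texture on tissue, faint nonspecific hematoxylin.
    cyto = ndimage.gaussian_filter(rng.random((H, W)), sigma=spec.cytoplasm_texture_scale)
    lo, hi = cyto.min(), cyto.max()
    # floor at half the nominal OD keeps all tissue clearly below the
    # brightfield background threshold used by the QC tissue mask
    cyto = 0.5 + 0.5 * ((cyto - lo) / (hi - lo) if hi > lo else np.zeros_like(cyto))
    od_e = spec.eosin_od_cytoplasm * cyto * tissue
    od_h = od_h + 0.06 * cyto * tissue * ~nuclei_mask

    # slight optical blur: soft structure edges, as a microscope would record
    od_h = ndimage.gaussian_filter(od_h, sigma=0.6)
    od_e = ndimage.gaussian_filter(od_e, sigma=0.6)
    od_maps = np.stack([od_h, od_e], axis=-1).astype(np.float32)
    he_ideal = render_he(od_maps)

    # Fixed invertible OD -> AF mapping (saturation curves) plus sensor noise.
    dapi = 1.0 - np.exp(-AF_GAIN_DAPI * od_h)
    txred = 1.0 - np.exp(-AF_GAIN_TXRED * od_e)
    af = np.stack([dapi, txred], axis=-1)
    af = np.clip(af + rng.normal(0.0, spec.noise_sd, af.shape), 0.0, 1.0)

    return PhantomSample(
        af=MultiChannelImage(af.astype(np.float32), ("DAPI", "TxRed")),
        he_ideal=he_ideal,
        nuclei_mask=nuclei_mask,
        nuclei_count=placed,
        od_maps=od_maps,
        tissue_mask=tissue,
        spec=spec,
    )


def _ellipse_patch(cy, cx, ry, rx, theta, H, W):
    """Pixel index arrays of a rotated ellipse, or None if empty."""
    r = int(np.ceil(max(ry, rx))) + 1
    y0, y1 = int(cy) - r, int(cy) + r + 1
    x0, x1 = int(cx) - r, int(cx) + r + 1
    if y0 < 0 or x0 < 0 or y1 > H or x1 > W:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    if not inside.any():
        return None
    ys, xs = np.nonzero(inside)
    return ys + y0, xs + x0


def degrade_staining(sample: PhantomSample, art: ArtifactSpec) -> MultiChannelImage:
    """Scale hematoxylin/eosin OD by (1 - fade) inside the region, re-render."""
    od = sample.od_maps.astype(np.float64).copy()
    if art.region_mask is None:
        region = np.ones(od.shape[:2], dtype=bool)
    else:
        region = np.asarray(art.region_mask, dtype=bool)
        if region.shape != od.shape[:2]:
            raise ValueError(
                f"region_mask shape {region.shape} != image shape {od.shape[:2]}"
            )
    od[..., 0] = np.where(region, od[..., 0] * (1.0 - art.hema_fade), od[..., 0])
    od[..., 1] = np.where(region, od[..., 1] * (1.0 - art.eosin_fade), od[..., 1])
    return render_he(od)


def generate_misalignment(mis: MisalignmentSpec, height: int, width: int) -> np.ndarray:
    """Displacement field (2, H, W): plane 0 horizontal dx, plane 1 vertical dy.

    ``translation`` mode: constant field.  ``smooth_random``: Gaussian-filtered
    white noise rescaled so the maximum displacement norm equals ``amplitude``.
    """
    if mis.mode == "translation":
        dx, dy = mis.translation if mis.translation is not None else (mis.amplitude, 0.0)
        field = np.empty((2, height, width), dtype=np.float32)
        field[0] = dx
        field[1] = dy
        return field
    if mis.mode == "smooth_random":
        if mis.amplitude == 0.0:
            return np.zeros((2, height, width), dtype=np.float32)
        rng = np.random.default_rng(mis.seed)
        noise = rng.standard_normal((2, height, width))
        field = ndimage.gaussian_filter(
            noise, sigma=(0.0, mis.smoothness_scale, mis.smoothness_scale)
        )
        norm = np.sqrt(field[0] ** 2 + field[1] ** 2)
        peak = norm.max()
        if peak > 0:
            field *= mis.amplitude / peak
        return field.astype(np.float32)
    raise ValueError(f"unknown misalignment mode: {mis.mode!r}")


def to_paired(
    sample: PhantomSample,
    mis: MisalignmentSpec | None = None,
    artifact: ArtifactSpec | None = None,
) -> PairedSample:
    """Build a training pair from a phantom; optionally misalign/degrade the target.

    ``true_dvf`` (stored on the sample and in ``meta``) is the field that
    aligns ``he_raw`` back to the AF frame: warp(he_raw, true_dvf) ~ he_ideal.
    The raw target is produced by warping the ideal rendering with the
    negated field.
    """
    he = sample.he_ideal if artifact is None else degrade_staining(sample, artifact)
    he_float = he.chw / 255.0  # (3, H, W) in [0, 1]
    H, W = he_float.shape[1:]
    if mis is None:
        true_dvf = None
        he_raw = he_float
    else:
        true_dvf = generate_misalignment(mis, H, W)
        he_raw = warp_image(he_float, -true_dvf).astype(np.float32)
        sample.true_dvf = true_dvf
    return PairedSample(
        af=sample.af.data,
        he_raw=np.ascontiguousarray(he_raw.transpose(1, 2, 0)),
        meta={"true_dvf": true_dvf, "nuclei_count": sample.nuclei_count},
    )
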