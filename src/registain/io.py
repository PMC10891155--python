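"""Image and displacement-field file I/O (TIFF/PNG round-trips).

Displacement fields are stored as two-plane 32-bit float TIFFs: plane 0 the
horizontal (column) displacement, plane 1 the vertical (row) displacement,
in pixels.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .image import MultiChannelImage

_SUPPORTED_DTYPES = ("uint8", "uint16", "float32", "float64", "bool")


def read_image(path) -> MultiChannelImage:
    """Read a TIFF or PNG into a (H, W, C) container; channels-first TIFF pages
    with few planes are transposed to channel-last."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] <= 4 < arr.shape[2]:
        arr = arr.transpose(1, 2, 0)  # pages-as-channels layout
    if str(arr.dtype) not in _SUPPORTED_DTYPES:
        raise IOError(f"unsupported dtype {arr.dtype} in {path}")
    return MultiChannelImage(arr)


def write_image(img, path) -> None:
    """Write a MultiChannelImage or array losslessly (TIFF) or as PNG."""
    path = Path(path)
    arr = img.data if isinstance(img, MultiChannelImage) else np.asarray(img)
    if str(arr.dtype) not in _SUPPORTED_DTYPES:
        raise IOError(f"unsupported dtype {arr.dtype} for {path}")
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        if arr.dtype == bool:
            arr = arr.astype(np.uint8) * 255
        iio.imwrite(path, arr)


def write_dvf(dvf: np.ndarray, path) -> None:
    """Write a (2, H, W) displacement field as a two-plane float32 TIFF."""
    arr = np.asarray(dvf, dtype=np.float32)
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError(f"expected (2, H, W) displacement field, got {arr.shape}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, arr)


def read_dvf(path) -> np.ndarray:
    try:
        arr = np.asarray(tifffile.imread(path), dtype=np.float32)
    except Exception as exc:
        raise IOError(f"could not read displacement field {path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise IOError(f"not a two-plane displacement field: shape {arr.shape}")
    return arr
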