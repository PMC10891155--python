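"""In-memory containers for multi-channel images and paired training samples.

Coordinate convention used across the package: 0-based ``(row, col)`` with the
origin at the top-left.  Displacement fields store two planes, plane 0 the
horizontal (column, ``dx``) shift and plane 1 the vertical (row, ``dy``)
shift, in units of pixels.  Images are stored channel-last ``(H, W, C)`` for
I/O friendliness; network code works channel-first and converts at the edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np


@dataclass
class MultiChannelImage:
    """A 2-D pixel grid with C channels plus dtype/range metadata."""

    data: np.ndarray  # (H, W, C)
    channel_names: Tuple[str, ...] = ()

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if self.data.ndim != 3:
            raise ValueError(f"expected (H, W, C) array, got shape {self.data.shape}")
        if self.channel_names and len(self.channel_names) != self.data.shape[2]:
            raise ValueError("channel_names length does not match channel count")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def chw(self) -> np.ndarray:
        """Channel-first float view for network/loss code."""
        return np.ascontiguousarray(self.data.transpose(2, 0, 1)).astype(np.float32)


def as_hwc(img) -> np.ndarray:
    """Coerce a MultiChannelImage or array to a (H, W, C) float array."""
    if isinstance(img, MultiChannelImage):
        return img.data
    arr = np.asarray(img)
    return arr[:, :, None] if arr.ndim == 2 else arr


@dataclass
class PairedSample:
    """One autofluorescence input with its (possibly misaligned) histology target.

    ``af``: (H, W, 2) float, DAPI-role then TxRed-role channel.
    ``he_raw``: (H, W, 3) float in [0, 1], coarsely registered target.
    ``he_reg``/``vs``: optional warped target / generator output.
    """

    af: np.ndarray
    he_raw: np.ndarray
    he_reg: Optional[np.ndarray] = None
    vs: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.af = np.asarray(self.af, dtype=np.float32)
        self.he_raw = np.asarray(self.he_raw, dtype=np.float32)
        if self.af.shape[:2] != self.he_raw.shape[:2]:
            raise ValueError("af and he_raw spatial dims differ")
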