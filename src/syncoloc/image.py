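"""Single-plane channel images with physical pixel calibration.

All analysis in this package operates on 2D grayscale images, one per
immunolabel, with a known pixel size in nanometers.  Coordinates follow
the image convention: origin at the top-left pixel center, ``x`` along
columns, ``y`` along rows; physical positions are ``x = col * pixel_size``,
``y = row * pixel_size`` in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ChannelImage"]

DEFAULT_PIXEL_SIZE_NM = 27.0


@dataclass
class ChannelImage:
    """A 2D non-negative intensity grid with pixel-size metadata.

    Parameters
    ----------
    pixels
        2D array of intensities. Stored as float64 internally.
    pixel_size_nm
        Physical size of one pixel in nanometers (default 27 nm,
        a 60x objective with a 4x optical-reassignment disk).
    channel_label
        Free-text label, e.g. ``"bassoon"`` or ``"homer"``.
    """

    pixels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("ChannelImage requires a 2D array, got "
                             f"ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ChannelImage intensities must be finite")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def fov_size_nm(self) -> tuple[float, float]:
        """Physical FOV extent (height, width) in nm."""
        return (self.shape[0] * self.pixel_size_nm,
                self.shape[1] * self.pixel_size_nm)

    def copy_with(self, pixels: np.ndarray) -> "ChannelImage":
        return ChannelImage(pixels, self.pixel_size_nm, self.channel_label)

    @classmethod
    def from_tiff(cls, path, pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
                  channel_label: str = "") -> "ChannelImage":
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single-plane grayscale "
                             f"TIFF, got shape {arr.shape}")
        return cls(arr.astype(np.float64), pixel_size_nm, channel_label)

    def to_tiff(self, path) -> None:
        """Write as 16-bit grayscale TIFF (values clipped to uint16 range)."""
        arr = np.clip(np.round(self.pixels), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, arr)
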