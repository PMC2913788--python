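"""Grey-level image container and raster I/O.

Fundus photographs are handled as 8-bit grey rasters together with a binary
field-of-view (FOV) mask marking the elliptical retina region.  All statistics
computed downstream (means, standard deviations, histograms) are restricted to
the FOV.  RGB inputs are reduced to the green channel, the standard choice for
fundus vessel work because vessel/background contrast is highest there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np


@dataclass
class GreyImage:
    """A 2D grey-level raster with an attached field-of-view mask.

    Parameters
    ----------
    pixels : ndarray of float, shape (H, W)
        Grey levels, nominally in [0, 255].  Stored as float64 so that
        intermediate results (smoothing, illumination correction) keep full
        precision; values are clipped back to [0, 255] only where an
        operation's contract says so.
    fov_mask : ndarray of bool, shape (H, W)
        True inside the field of view.  Defaults to the full frame.
    """

    pixels: np.ndarray
    fov_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected 2D raster, got shape {self.pixels.shape}")
        if self.pixels.size == 0:
            raise ValueError("zero-area image")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.fov_mask is None:
            self.fov_mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
            if self.fov_mask.shape != self.pixels.shape:
                raise ValueError("fov_mask shape must match pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy(self) -> "GreyImage":
        return GreyImage(self.pixels.copy(), self.fov_mask.copy())

    def fov_values(self) -> np.ndarray:
        """Grey levels inside the FOV, as a flat array."""
        return self.pixels[self.fov_mask]

    def to_uint8(self) -> np.ndarray:
        """Rounded 8-bit view of the raster (for SGLD statistics and export)."""
        return np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)


def load_image(path: str | Path, channel: str = "green") -> GreyImage:
    """Read a PNG/TIFF/PPM image as an 8-bit grey raster.

    RGB(A) inputs are reduced to a single channel (``green`` by default;
    ``red``, ``blue`` or ``luma`` are accepted).
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        if channel == "luma":
            arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
        else:
            idx = {"red": 0, "green": 1, "blue": 2}[channel]
            arr = arr[..., idx]
    return GreyImage(arr.astype(np.float64))


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary raster as a 0/255 PNG."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def save_image(path: str | Path, img: GreyImage) -> None:
    iio.imwrite(path, img.to_uint8())


def load_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG as a boolean raster (any nonzero pixel is True)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0
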