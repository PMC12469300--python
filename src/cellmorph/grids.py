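"""Core raster container.

A :class:`ImageGrid` is a 2-D scalar field (fluorescence intensity or AFM
height) together with its physical pixel size.  Coordinates are row-major and
0-based; pixel centers sit at integer coordinates.  Masks are plain boolean
arrays — a pixel is in or out, there is no sub-pixel membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid"]


@dataclass
class ImageGrid:
    """A 2-D scalar image with physical calibration.

    Parameters
    ----------
    data
        2-D float array of intensities or heights.
    pixel_size
        Physical edge length of one pixel. Units are the caller's
        (µm/pixel for fluorescence, can be nm or µm for AFM height maps).
    units
        Free-text unit label for ``pixel_size`` (default ``"um"``).
    source
        Optional provenance string (file path or generator tag).
    """

    data: np.ndarray
    pixel_size: float = 1.0
    units: str = "um"
    source: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"ImageGrid requires a 2-D array, got ndim={self.data.ndim}")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def pixel_area(self) -> float:
        """Physical area of one pixel (pixel_size squared)."""
        return float(self.pixel_size) ** 2

    def astype(self, dtype) -> "ImageGrid":
        return ImageGrid(self.data.astype(dtype), self.pixel_size, self.units, self.source)
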