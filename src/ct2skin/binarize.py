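"""In-range Hounsfield-unit thresholding of CT slices.

Soft tissue (including the skin layer) occupies roughly the -200..+220 HU
band: air is far below it and cortical bone far above.  A slice is converted
to a binary mask by marking every pixel whose HU falls inside a closed
interval as foreground (255) and everything else as background (0).  No
morphology or smoothing is applied at any point, so the mask boundary stays
faithful to the raw image data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import PlanarSlice

__all__ = ["HURange", "BinaryMask", "binarize_slice", "DEFAULT_HU_RANGE"]

FOREGROUND: int = 255
BACKGROUND: int = 0


@dataclass(frozen=True)
class HURange:
    """Closed HU interval ``[hu_min, hu_max]`` defining the tissue band."""

    hu_min: float
    hu_max: float

    def __post_init__(self) -> None:
        if self.hu_min > self.hu_max:
            raise ValueError(f"hu_min ({self.hu_min}) must be <= hu_max ({self.hu_max})")

    def contains(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values)
        return (v >= self.hu_min) & (v <= self.hu_max)


#: Default soft-tissue band used for skin isolation.
DEFAULT_HU_RANGE = HURange(-200.0, 220.0)


@dataclass(frozen=True)
class BinaryMask:
    """A binary image of {0, 255} with provenance to its source slice."""

    pixels: np.ndarray
    orientation: str
    index: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.uint8)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {px.shape}")
        if not np.isin(px, (BACKGROUND, FOREGROUND)).all():
            raise ValueError("mask may contain only values 0 and 255")
        object.__setattr__(self, "pixels", px)

    @property
    def foreground(self) -> np.ndarray:
        """Boolean view of the foreground."""
        return self.pixels == FOREGROUND

    def with_pixels(self, pixels: np.ndarray) -> "BinaryMask":
        return BinaryMask(pixels=pixels, orientation=self.orientation, index=self.index)


def binarize_slice(sl: PlanarSlice, hu_range: HURange = DEFAULT_HU_RANGE) -> BinaryMask:
    """Threshold one HU slice into a :class:`BinaryMask`.

    A pixel becomes foreground iff ``hu_min <= value <= hu_max`` (both
    endpoints included).  Total function: any slice yields a valid mask.
    """
    fg = hu_range.contains(sl.pixels)
    pixels = np.where(fg, FOREGROUND, BACKGROUND).astype(np.uint8)
    return BinaryMask(pixels=pixels, orientation=sl.orientation, index=sl.index)
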