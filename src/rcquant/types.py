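"""Core in-memory containers shared by every pipeline stage.

All images live on a single row-major, 0-based pixel grid with pixel-center
coordinates; a section and its masks always share that grid, so areas can be
compared pixel-for-pixel without resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The four rotator cuff muscles: supraspinatus, subscapularis,
#: infraspinatus, teres minor.
MUSCLE_LABELS = ("SS", "SC", "IS", "TM")

HU_MIN = -1024
HU_MAX = 3071


@dataclass
class CTSection:
    """A 2D sagittal-oblique CT section in calibrated Hounsfield units.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        HU values (water = 0, air ≈ −1000).
    pixel_size_mm : (float, float)
        Physical spacing (row, col) in millimetres.
    origin_id : str
        Free-text provenance (file path, phantom case id, ...).
    """

    pixels: np.ndarray
    pixel_size_mm: tuple[float, float]
    origin_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("CTSection.pixels must be 2D")
        r, c = self.pixel_size_mm
        if not (r > 0 and c > 0):
            raise ValueError("pixel_size_mm must be positive in both axes")
        if self.pixels.size and (
            self.pixels.min() < HU_MIN or self.pixels.max() > HU_MAX
        ):
            raise ValueError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: "
                f"range [{self.pixels.min()}, {self.pixels.max()}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_size_mm[0] * self.pixel_size_mm[1])


@dataclass
class PremorbidMask:
    """Binary mask of one muscle's premorbid (pre-degeneration) cross-section.

    ``pixels`` holds exactly {0, 1} (uint8) and matches the shape of the
    paired :class:`CTSection`.
    """

    pixels: np.ndarray
    muscle_label: str = "SS"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("PremorbidMask.pixels must be 2D")
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be exactly {0, 1}")
        self.pixels = arr.astype(np.uint8)
        if self.muscle_label not in MUSCLE_LABELS:
            raise ValueError(
                f"muscle_label must be one of {MUSCLE_LABELS}, got {self.muscle_label!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def as_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)


def require_same_grid(section: CTSection, mask: PremorbidMask) -> None:
    if section.shape != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match section shape {section.shape}"
        )
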