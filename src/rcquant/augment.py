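"""Training-set augmentation: joint random scaling and rotation.

Each augmented example draws one scale factor (uniform in 1 + scale_range,
default ±20%) and one angle (uniform, default ±90°) and applies them
identically to the image and every mask, so image/mask alignment is exact
by construction.  Expansion is tenfold by default, counting the original:
the identity transform is kept as one of the ten, and nine random draws
are added.  Augmented items are lazy — they carry provenance (source case,
rater, scale, angle) and materialize on demand — so bookkeeping (fold
assignment, leakage control) never touches pixel data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import CTSection, PremorbidMask, require_same_grid

BACKGROUND_HU = -1000.0


@dataclass(frozen=True)
class AugmentParams:
    scale_range: tuple[float, float] = (-0.20, 0.20)
    rotation_range_deg: tuple[float, float] = (-90.0, 90.0)
    expansion_factor: int = 10
    seed: int = 0

    def __post_init__(self):
        if 1 + self.scale_range[0] <= 0:
            raise ValueError("scale factor 1+s must stay positive")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be ≥ 1")


def apply_transform(section: CTSection, masks: list[PremorbidMask],
                    scale: float, angle_deg: float
                    ) -> tuple[CTSection, list[PremorbidMask]]:
    """Rotate by ``angle_deg`` and scale by ``1+scale`` about the image center.

    The image is interpolated linearly with out-of-frame fill at background
    HU; masks use nearest-neighbor and stay binary.
    """
    for m in masks:
        require_same_grid(section, m)
    h, w = section.shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    s = 1.0 + scale
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    # inverse map: output coordinate → input coordinate
    inv = rot.T / s
    offset = c - inv @ c
    img = ndimage.affine_transform(section.pixels, inv, offset=offset, order=1,
                                   cval=BACKGROUND_HU, mode="constant")
    img = np.clip(img, -1024, 3071)
    out_sec = CTSection(img, section.pixel_size_mm,
                        origin_id=f"{section.origin_id}|s={scale:+.3f},a={angle_deg:+.1f}")
    out_masks = []
    for m in masks:
        mm = ndimage.affine_transform(m.pixels, inv, offset=offset, order=0,
                                      cval=0, mode="constant")
        out_masks.append(PremorbidMask(mm.astype(np.uint8), m.muscle_label))
    return out_sec, out_masks


def random_transform(section: CTSection, masks: list[PremorbidMask],
                     params: AugmentParams, rng: np.random.Generator
                     ) -> tuple[CTSection, list[PremorbidMask]]:
    """Draw one (scale, angle) pair and apply it jointly to image and masks."""
    scale = rng.uniform(*params.scale_range)
    angle = rng.uniform(*params.rotation_range_deg)
    return apply_transform(section, masks, scale, angle)


@dataclass
class SegItem:
    """One training example: a section plus its masks for one delineation."""

    case_id: str
    rater_id: int
    section: CTSection
    masks: list[PremorbidMask]


@dataclass
class AugmentedItem:
    """Lazy augmented copy of a :class:`SegItem` with full provenance."""

    source: SegItem
    scale: float
    angle_deg: float
    is_identity: bool
    _cache: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def case_id(self) -> str:
        return self.source.case_id

    @property
    def rater_id(self) -> int:
        return self.source.rater_id

    def materialize(self) -> tuple[CTSection, list[PremorbidMask]]:
        if self.is_identity:
            return self.source.section, self.source.masks
        if self._cache is None:
            self._cache = apply_transform(self.source.section, self.source.masks,
                                          self.scale, self.angle_deg)
        return self._cache


def augment_dataset(items: list[SegItem],
                    params: AugmentParams = AugmentParams()
                    ) -> list[AugmentedItem]:
    """Expand a dataset ``expansion_factor``-fold (identity + random draws).

    Output order groups all copies of one source item together, so fold
    assignment by ``case_id`` automatically confines augmented copies to
    their source's fold.
    """
    if not items:
        raise ValueError("items must be non-empty")
    rng = np.random.default_rng(params.seed)
    out: list[AugmentedItem] = []
    for item in items:
        out.append(AugmentedItem(item, 0.0, 0.0, is_identity=True))
        for _ in range(params.expansion_factor - 1):
            scale = rng.uniform(*params.scale_range)
            angle = rng.uniform(*params.rotation_range_deg)
            out.append(AugmentedItem(item, scale, angle, is_identity=False))
    return out


def provenance_frame(augmented: list[AugmentedItem]) -> pd.DataFrame:
    """Tabular provenance of an augmented set (one row per item)."""
    return pd.DataFrame(
        {
            "case_id": [a.case_id for a in augmented],
            "rater_id": [a.rater_id for a in augmented],
            "scale": [a.scale for a in augmented],
            "angle_deg": [a.angle_deg for a in augmented],
            "is_identity": [a.is_identity for a in augmented],
        }
    )
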