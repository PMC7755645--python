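"""Threshold-based quantification of muscle degeneration.

Within a muscle's premorbid cross-section S, pixels are classified by
Hounsfield value: residual muscle above the fat/muscle threshold (−29 HU),
fat below it, bone above the muscle/bone threshold (166 HU).  The outer
boundary of the residual/atrophied muscle (Sa) is obtained by thresholding
inside S, removing islands (largest connected component) and filling
holes, so enclosed fat pockets and bone islands count toward Sa.  Inside
Sa, fatty infiltration Si is the area below −29 HU and secondary bone
formation So the area above 166 HU.

Ratios
------
The implemented definitions anchor "fully healthy" at 0 and "completely
degenerated" at 1 for every ratio:

    Ra = (S − Sa) / S      atrophy (lost cross-section)
    Ri = Si / S            fatty infiltration
    Ro = So / S            secondary bone formation
    Rd = Ra + Ri + Ro      overall degeneration

A compatibility flag (``printed_formulas=True``) instead reports
Ra = Sa/S and Rd = (Sa + Si + So)/S, a variant found in parts of the
literature; note that variant assigns Rd = 1 to a fully healthy muscle,
which is inconsistent with the 0/1 anchors above, so it is not the
default.

Threshold strictness: residual muscle is HU > −29 (strict), fat HU < −29
(strict), bone HU > 166 (strict).  Pixels exactly at a threshold belong to
neither adjacent tissue class but can still enter Sa via hole filling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .postprocess import fill_holes, largest_component
from .types import CTSection, PremorbidMask, require_same_grid


@dataclass(frozen=True)
class QuantConfig:
    """Tissue-classification thresholds (HU)."""

    muscle_threshold_hu: float = -29.0
    bone_threshold_hu: float = 166.0
    printed_formulas: bool = False

    def __post_init__(self):
        if not self.muscle_threshold_hu < self.bone_threshold_hu:
            raise ValueError("muscle_threshold_hu must be < bone_threshold_hu")


@dataclass(frozen=True)
class DegenerationMeasures:
    """Surfaces and ratios for one muscle on one section.

    Surfaces are integer pixel counts; ``*_mm2`` properties convert with
    the section's pixel area.
    """

    muscle_label: str
    s_px: int
    sa_px: int
    si_px: int
    so_px: int
    pixel_area_mm2: float
    ra: float
    ri: float
    ro: float
    rd: float
    printed_formulas: bool = False

    def __post_init__(self):
        if not (0 <= self.si_px + self.so_px <= self.sa_px <= self.s_px):
            raise ValueError(
                f"surface ordering violated: Si+So={self.si_px + self.so_px}, "
                f"Sa={self.sa_px}, S={self.s_px}"
            )
        if not self.printed_formulas:
            # only the default definitions guarantee ratios in [0, 1]
            for name in ("ra", "ri", "ro", "rd"):
                v = getattr(self, name)
                if not (-1e-12 <= v <= 1 + 1e-12):
                    raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def s_mm2(self) -> float:
        return self.s_px * self.pixel_area_mm2

    @property
    def sa_mm2(self) -> float:
        return self.sa_px * self.pixel_area_mm2

    @property
    def si_mm2(self) -> float:
        return self.si_px * self.pixel_area_mm2

    @property
    def so_mm2(self) -> float:
        return self.so_px * self.pixel_area_mm2

    def as_dict(self) -> dict:
        return {
            "muscle": self.muscle_label,
            "S_px": self.s_px, "Sa_px": self.sa_px,
            "Si_px": self.si_px, "So_px": self.so_px,
            "S_mm2": self.s_mm2, "Sa_mm2": self.sa_mm2,
            "Si_mm2": self.si_mm2, "So_mm2": self.so_mm2,
            "Ra": self.ra, "Ri": self.ri, "Ro": self.ro, "Rd": self.rd,
        }


def measures_from_counts(muscle_label: str, s: int, sa: int, si: int, so: int,
                         pixel_area_mm2: float,
                         printed_formulas: bool = False) -> DegenerationMeasures:
    """Build :class:`DegenerationMeasures` from pixel counts.

    Single place where the ratio arithmetic lives, so the generator's
    bookkeeping and the image-based quantification agree exactly.
    """
    if s <= 0:
        raise ValueError("premorbid surface S must be positive")
    if printed_formulas:
        ra = sa / s
        rd = (sa + si + so) / s
    else:
        ra = (s - sa) / s
        rd = ((s - sa) + si + so) / s
    return DegenerationMeasures(
        muscle_label=muscle_label, s_px=int(s), sa_px=int(sa),
        si_px=int(si), so_px=int(so), pixel_area_mm2=pixel_area_mm2,
        ra=ra, ri=si / s, ro=so / s, rd=rd,
        printed_formulas=printed_formulas,
    )


def residual_muscle_mask(section: CTSection, premorbid: PremorbidMask,
                         config: QuantConfig = QuantConfig()) -> PremorbidMask:
    """Outer boundary of the residual/atrophied muscle (the Sa region).

    Threshold HU > ``muscle_threshold_hu`` inside the premorbid mask,
    remove islands (keep the largest 8-connected component), fill holes.
    A fully degenerated muscle legitimately yields an empty Sa.
    """
    require_same_grid(section, premorbid)
    if premorbid.area_px == 0:
        raise ValueError("premorbid mask is empty")
    thresh = (section.pixels > config.muscle_threshold_hu) & premorbid.as_bool()
    m = PremorbidMask(thresh.astype(np.uint8), premorbid.muscle_label)
    if m.area_px == 0:
        return m
    m = fill_holes(largest_component(m, connectivity=8))
    # hole filling cannot legitimately grow Sa beyond the premorbid region
    clipped = m.pixels & premorbid.pixels
    return PremorbidMask(clipped, premorbid.muscle_label)


def quantify_degeneration(section: CTSection, premorbid: PremorbidMask,
                          config: QuantConfig = QuantConfig()) -> DegenerationMeasures:
    """Quantify atrophy, fatty infiltration and bone formation for one muscle."""
    sa_mask = residual_muscle_mask(section, premorbid, config)
    s = premorbid.area_px
    sa = sa_mask.area_px
    inside = sa_mask.as_bool()
    si = int(np.count_nonzero(inside & (section.pixels < config.muscle_threshold_hu)))
    so = int(np.count_nonzero(inside & (section.pixels > config.bone_threshold_hu)))
    return measures_from_counts(
        premorbid.muscle_label, s, sa, si, so,
        section.pixel_area_mm2, printed_formulas=config.printed_formulas,
    )
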