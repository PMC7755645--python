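"""Cleanup of raw network masks: largest connected component + hole filling.

Connectivity convention: foreground components are 8-connected, background
(hole detection) is 4-connected — the standard dual pairing that avoids
topological paradoxes on the pixel grid.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import PremorbidMask

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def largest_component(mask: PremorbidMask, connectivity: int = 8) -> PremorbidMask:
    """Keep only the largest connected component (ties → lowest label id).

    An empty mask passes through unchanged.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    labels, n = ndimage.label(mask.as_bool(), structure=struct)
    if n == 0:
        return PremorbidMask(np.zeros_like(mask.pixels), mask.muscle_label)
    sizes = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1
    return PremorbidMask((labels == keep).astype(np.uint8), mask.muscle_label)


def fill_holes(mask: PremorbidMask) -> PremorbidMask:
    """Fill background regions not 4-connected to the image border.

    Border-connected concavities are left untouched.
    """
    filled = ndimage.binary_fill_holes(mask.as_bool(), structure=_STRUCT4)
    return PremorbidMask(filled.astype(np.uint8), mask.muscle_label)


def finalize_mask(mask: PremorbidMask, original_size: int) -> PremorbidMask:
    """Upscale a network-resolution mask, then clean it.

    Composition (in order): nearest-neighbor upscale to ``original_size``,
    largest connected component, hole filling.  An empty prediction stays
    empty; callers flag it via ``area_px == 0``.
    """
    from .io import upscale_mask  # local import to avoid a cycle

    up = upscale_mask(mask, original_size)
    return fill_holes(largest_component(up))
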