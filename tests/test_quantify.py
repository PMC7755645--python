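"""Threshold quantification against hand-constructed pixel-count fixtures."""

import numpy as np
import pytest

from rcquant.quantify import (QuantConfig, measures_from_counts,
                              quantify_degeneration, residual_muscle_mask)
from rcquant.types import CTSection, PremorbidMask


def rect_fixture():
    """30×40 frame; premorbid = 10×20 rectangle (S=200) of muscle at +50 HU
    with an enclosed 60-px fat pocket (−80) and a 10-px bone island (+300)."""
    hu = np.full((30, 40), -1000.0)
    pm = np.zeros((30, 40), np.uint8)
    pm[10:20, 10:30] = 1
    hu[10:20, 10:30] = 50.0
    hu[12:18, 12:22] = -80.0   # 6×10 fat pocket, ≥2 px from the boundary
    hu[12:17, 24:26] = 300.0   # 5×2 bone island
    return CTSection(hu, (1.0, 1.0)), PremorbidMask(pm)


class TestResidualMuscleMask:
    def test_uniform_muscle_fills_premorbid(self):
        hu = np.full((20, 20), -1000.0)
        pm = np.zeros((20, 20), np.uint8)
        pm[5:15, 5:15] = 1
        hu[5:15, 5:15] = 50.0
        sa = residual_muscle_mask(CTSection(hu, (1, 1)), PremorbidMask(pm))
        assert np.array_equal(sa.pixels, pm)

    def test_uniform_fat_yields_empty_sa(self):
        hu = np.full((20, 20), -100.0)
        pm = np.zeros((20, 20), np.uint8)
        pm[5:15, 5:15] = 1
        sa = residual_muscle_mask(CTSection(hu, (1, 1)), PremorbidMask(pm))
        assert sa.area_px == 0

    def test_enclosed_fat_pocket_is_inside_sa(self):
        section, pm = rect_fixture()
        sa = residual_muscle_mask(section, pm)
        assert sa.area_px == 200  # pocket counted via hole filling
        assert np.array_equal(sa.pixels, pm.pixels)

    def test_empty_premorbid_rejected(self):
        hu = np.zeros((10, 10))
        with pytest.raises(ValueError, match="empty"):
            residual_muscle_mask(CTSection(hu, (1, 1)),
                                 PremorbidMask(np.zeros((10, 10), np.uint8)))


class TestQuantifyDegeneration:
    def test_fully_healthy_anchors_at_zero(self):
        hu = np.full((20, 20), -1000.0)
        pm = np.zeros((20, 20), np.uint8)
        pm[5:15, 5:15] = 1
        hu[5:15, 5:15] = 50.0
        m = quantify_degeneration(CTSection(hu, (1, 1)), PremorbidMask(pm))
        assert (m.s_px, m.sa_px, m.si_px, m.so_px) == (100, 100, 0, 0)
        assert m.ra == m.ri == m.ro == m.rd == 0.0

    def test_fully_degenerated_anchors_at_one(self):
        hu = np.full((20, 20), -100.0)
        pm = np.zeros((20, 20), np.uint8)
        pm[5:15, 5:15] = 1
        m = quantify_degeneration(CTSection(hu, (1, 1)), PremorbidMask(pm))
        assert m.sa_px == 0
        assert m.ra == 1.0 and m.rd == 1.0

    def test_pocket_fixture_pixel_counts(self):
        section, pm = rect_fixture()
        m = quantify_degeneration(section, pm)
        assert (m.s_px, m.sa_px, m.si_px, m.so_px) == (200, 200, 60, 10)
        assert (m.ra, m.ri, m.ro, m.rd) == (0.0, 0.30, 0.05, 0.35)
        assert m.si_mm2 == 60.0  # 1 mm pixels

    def test_printed_formula_variant(self):
        """The compatibility flag reports Ra = Sa/S and
        Rd = (Sa+Si+So)/S (which anchor a fully healthy muscle at 1, not 0)."""
        section, pm = rect_fixture()
        m = quantify_degeneration(section, pm,
                                  QuantConfig(printed_formulas=True))
        assert m.ra == 1.0                      # Sa = S on this fixture
        assert m.rd == (200 + 60 + 10) / 200    # can exceed 1

    def test_pixels_exactly_at_threshold_belong_to_no_tissue_class(self):
        hu = np.full((20, 20), -1000.0)
        pm = np.zeros((20, 20), np.uint8)
        pm[5:15, 5:15] = 1
        hu[5:15, 5:15] = 50.0
        hu[8, 8] = -29.0  # on the fat/muscle threshold
        m = quantify_degeneration(CTSection(hu, (1, 1)), PremorbidMask(pm))
        assert m.si_px == 0           # not fat (strict <)
        assert m.sa_px == 100         # re-enters Sa via hole filling

    def test_growing_fat_pocket_moves_only_ri_and_rd(self):
        results = []
        for half_w in (2, 3, 4):
            hu = np.full((30, 40), -1000.0)
            pm = np.zeros((30, 40), np.uint8)
            pm[10:20, 10:30] = 1
            hu[10:20, 10:30] = 50.0
            hu[13:17, 15 - half_w:15 + half_w] = -80.0
            results.append(
                quantify_degeneration(CTSection(hu, (1, 1)), PremorbidMask(pm))
            )
        ri = [m.ri for m in results]
        rd = [m.rd for m in results]
        assert ri == sorted(ri) and len(set(ri)) == 3
        assert rd == sorted(rd) and len(set(rd)) == 3
        assert len({m.ra for m in results}) == 1
        assert len({m.ro for m in results}) == 1

    def test_threshold_shift_across_hu_gap_changes_nothing(self):
        section, pm = rect_fixture()
        base = quantify_degeneration(section, pm)
        for t in (-60.0, -29.0, -10.0, 20.0):  # inside the (−80, 50) gap
            m = quantify_degeneration(section, pm,
                                      QuantConfig(muscle_threshold_hu=t))
            assert (m.sa_px, m.si_px, m.so_px) == (base.sa_px, base.si_px,
                                                   base.so_px)

    def test_surface_ordering_invariant_enforced(self):
        with pytest.raises(ValueError, match="surface ordering"):
            measures_from_counts("SS", s=100, sa=120, si=0, so=0,
                                 pixel_area_mm2=1.0)

    def test_zero_premorbid_surface_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            measures_from_counts("SS", s=0, sa=0, si=0, so=0, pixel_area_mm2=1.0)
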