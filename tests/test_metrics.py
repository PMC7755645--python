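"""Agreement metrics against brute-force oracles and textbook formulas."""

import numpy as np
import pytest

from rcquant.metrics import (boundary_pixels, dice, hausdorff,
                             inter_rater_report, paired_t_test,
                             regression_eval)
from rcquant.types import PremorbidMask


def brute_force_hausdorff(a, b, spacing=(1.0, 1.0)):
    """All-pairs maximum of nearest-boundary distances (O(n²) oracle)."""
    pa = boundary_pixels(a) * np.asarray(spacing)
    pb = boundary_pixels(b) * np.asarray(spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def random_mask_pair(rng, n=24):
    while True:
        a = np.zeros((n, n), np.uint8)
        b = np.zeros((n, n), np.uint8)
        r0, c0 = rng.integers(2, n - 10, 2)
        r1, c1 = rng.integers(2, n - 10, 2)
        a[r0:r0 + rng.integers(3, 8), c0:c0 + rng.integers(3, 8)] = 1
        b[r1:r1 + rng.integers(3, 8), c1:c1 + rng.integers(3, 8)] = 1
        if a.sum() and b.sum():
            return PremorbidMask(a), PremorbidMask(b)


class TestDice:
    def test_identical_masks(self):
        a = np.zeros((10, 10), np.uint8)
        a[2:6, 2:6] = 1
        assert dice(PremorbidMask(a), PremorbidMask(a)) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), np.uint8)
        b = np.zeros((10, 10), np.uint8)
        a[0:2, 0:2] = 1
        b[7:9, 7:9] = 1
        assert dice(PremorbidMask(a), PremorbidMask(b)) == 0.0

    def test_set_count_example(self):
        a = np.zeros((5, 5), np.uint8)
        b = np.zeros((5, 5), np.uint8)
        a.flat[:6] = 1
        b.flat[3:7] = 1
        assert dice(PremorbidMask(a), PremorbidMask(b)) == 2 * 3 / (6 + 4)

    def test_both_empty_defined_as_one(self):
        e = PremorbidMask(np.zeros((5, 5), np.uint8))
        assert dice(e, e) == 1.0

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = random_mask_pair(rng)
            assert dice(a, b) == dice(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(PremorbidMask(np.zeros((5, 5), np.uint8)),
                 PremorbidMask(np.zeros((6, 6), np.uint8)))


class TestHausdorff:
    def test_identical_masks_zero(self):
        a = np.zeros((10, 10), np.uint8)
        a[2:6, 2:6] = 1
        assert hausdorff(PremorbidMask(a), PremorbidMask(a)) == 0.0

    def test_single_pixel_pythagoras(self):
        a = np.zeros((10, 10), np.uint8)
        b = np.zeros((10, 10), np.uint8)
        a[0, 0] = 1
        b[3, 4] = 1
        assert hausdorff(PremorbidMask(a), PremorbidMask(b)) == 5.0

    def test_pixel_size_scales_distance(self):
        a = np.zeros((10, 10), np.uint8)
        b = np.zeros((10, 10), np.uint8)
        a[0, 0] = 1
        b[0, 4] = 1
        assert hausdorff(PremorbidMask(a), PremorbidMask(b), (0.5, 0.5)) == 2.0

    def test_nested_disks_match_brute_force(self):
        yy, xx = np.mgrid[:25, :25]
        d2 = (yy - 12) ** 2 + (xx - 12) ** 2
        big = PremorbidMask((d2 <= 100).astype(np.uint8))
        small = PremorbidMask((d2 <= 64).astype(np.uint8))
        got = hausdorff(big, small)
        assert got == pytest.approx(brute_force_hausdorff(big, small))
        # continuous-geometry value is 2.0; grid rasterization adds < 1 px
        assert abs(got - 2.0) < 1.0

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a, b = random_mask_pair(rng)
            assert hausdorff(a, b) == pytest.approx(brute_force_hausdorff(a, b))

    def test_symmetry_and_triangle_sanity(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            a, b = random_mask_pair(rng)
            c, _ = random_mask_pair(rng)
            assert hausdorff(a, b) == hausdorff(b, a)
            assert hausdorff(a, c) <= hausdorff(a, b) + hausdorff(b, c) + 1e-9

    def test_empty_mask_rejected(self):
        a = np.zeros((5, 5), np.uint8)
        a[2, 2] = 1
        with pytest.raises(ValueError, match="empty"):
            hausdorff(PremorbidMask(a), PremorbidMask(np.zeros((5, 5), np.uint8)))


class TestPairedT:
    def test_identical_sequences(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p_value == 1.0

    def test_constant_shift_flags_degenerate(self):
        res = paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.t == np.inf

    def test_textbook_formula_fixture(self):
        x = np.array([88.0, 90.0, 85.0, 92.0, 87.0, 91.0])
        y = np.array([86.0, 89.0, 86.0, 90.0, 84.0, 90.0])
        d = x - y
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        res = paired_t_test(x, y)
        assert res.t == pytest.approx(t_expected)
        assert 0 < res.p_value < 1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0])


class TestRegression:
    def test_identity(self):
        r = regression_eval([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        assert r.slope == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_doubling(self):
        r = regression_eval([0.2, 0.4, 0.6], [0.1, 0.2, 0.3])
        assert r.slope == pytest.approx(2.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_normal_equations_oracle(self):
        ref = np.array([0.05, 0.12, 0.31, 0.44, 0.5])
        pred = np.array([0.08, 0.10, 0.33, 0.40, 0.55])
        xm, ym = ref.mean(), pred.mean()
        slope = ((ref - xm) * (pred - ym)).sum() / ((ref - xm) ** 2).sum()
        intercept = ym - slope * xm
        resid = pred - (slope * ref + intercept)
        r2 = 1 - (resid ** 2).sum() / ((pred - ym) ** 2).sum()
        rec = regression_eval(pred, ref)
        assert rec.slope == pytest.approx(slope)
        assert rec.intercept == pytest.approx(intercept)
        assert rec.r_squared == pytest.approx(r2)
        assert rec.r_squared == pytest.approx(rec.pearson_r ** 2)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            regression_eval([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])


class TestInterRater:
    def test_pair_counts(self):
        a = np.zeros((10, 10), np.uint8)
        a[2:7, 2:7] = 1
        m = PremorbidMask(a)
        records = inter_rater_report({"c1": [[m], [m], [m]]})
        assert len(records) == 3  # 3 raters → 3 unordered pairs
        records2 = inter_rater_report({"c1": [[m], [m]]})
        assert len(records2) == 1

    def test_single_rater_rejected(self):
        m = PremorbidMask(np.ones((4, 4), np.uint8))
        with pytest.raises(ValueError):
            inter_rater_report({"c1": [[m]]})
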