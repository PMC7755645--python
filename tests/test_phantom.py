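"""Phantom generator: exact bookkeeping, rater simulation, cohorts."""

import numpy as np
import pytest
from scipy import ndimage

from rcquant.phantom import (CohortSampler, PhantomSpec, generate_cohort,
                             generate_phantom, simulate_raters)
from rcquant.quantify import quantify_degeneration


def pairwise_dice(masks):
    from itertools import combinations

    out = []
    for a, b in combinations(masks, 2):
        am, bm = a.as_bool(), b.as_bool()
        out.append(2 * np.count_nonzero(am & bm) / (am.sum() + bm.sum()))
    return out


class TestGeneratePhantom:
    def test_healthy_muscle_has_zero_ratios(self):
        case = generate_phantom(PhantomSpec(hu_noise_sd=0.0, seed=1))
        for m in case.true_measures:
            assert m.ra == m.ri == m.ro == m.rd == 0.0

    def test_complete_atrophy_gives_rd_one(self):
        spec = PhantomSpec(image_size=64, atrophy_fraction=(1.0, 0, 0, 0),
                           hu_noise_sd=0.0, seed=2)
        case = generate_phantom(spec)
        assert case.true_measures[0].rd == 1.0
        assert case.true_measures[0].sa_px == 0

    def test_requested_fractions_realized_by_pixel_count(self):
        """Rendered fat/bone surfaces equal round(fraction·S) pixels,
        verified by counting threshold-class pixels on the image itself."""
        spec = PhantomSpec(image_size=128, fat_fraction=0.30,
                           bone_fraction=0.05, atrophy_fraction=0.0,
                           hu_noise_sd=0.0, seed=5)
        case = generate_phantom(spec)
        for mask, meas in zip(case.premorbid_masks, case.true_measures):
            inside = mask.as_bool()
            s = int(inside.sum())
            n_fat = int(np.count_nonzero(inside & (case.section.pixels < -29)))
            n_bone = int(np.count_nonzero(inside & (case.section.pixels > 166)))
            assert n_fat == round(0.30 * s) == meas.si_px
            assert n_bone == round(0.05 * s) == meas.so_px
            assert meas.rd == (n_fat + n_bone) / s
            assert abs(meas.ri - 0.30) <= 2 / s
            assert abs(meas.ro - 0.05) <= 2 / s

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            PhantomSpec(atrophy_fraction=0.6, fat_fraction=0.5)

    def test_threshold_ordering_of_hu_means_enforced(self):
        with pytest.raises(ValueError, match="hu_fat"):
            PhantomSpec(hu_fat=0.0)

    def test_premorbid_masks_single_connected_component(self):
        case = generate_phantom(PhantomSpec(seed=9))
        for m in case.premorbid_masks:
            assert ndimage.label(m.as_bool())[1] == 1

    @pytest.mark.parametrize("noise_sd", [0.0, 5.0])
    @pytest.mark.parametrize("seed", [0, 17, 23])
    def test_round_trip_identity_with_true_mask(self, noise_sd, seed):
        """Quantification on the rendered image with the true premorbid
        mask reproduces the generator's bookkeeping exactly — including
        under additive noise, which is clipped inside tissue classes."""
        spec = PhantomSpec(image_size=128, atrophy_fraction=(0.2, 0.1, 0, 0.3),
                           fat_fraction=(0.1, 0.2, 0.25, 0), bone_fraction=(0.03, 0, 0, 0),
                           hu_noise_sd=noise_sd, seed=seed)
        case = generate_phantom(spec)
        for mask, truth in zip(case.premorbid_masks, case.true_measures):
            q = quantify_degeneration(case.section, mask)
            assert (q.s_px, q.sa_px, q.si_px, q.so_px) == (
                truth.s_px, truth.sa_px, truth.si_px, truth.so_px
            )
            assert q.rd == truth.rd


class TestSimulateRaters:
    def test_zero_boundary_sd_copies_truth(self, noisy_case_with_raters):
        case = simulate_raters(noisy_case_with_raters, 3, 0.0, seed=5)
        for rater in case.rater_masks:
            for m, truth in zip(rater, case.premorbid_masks):
                assert np.array_equal(m.pixels, truth.pixels)

    def test_rater_count(self, noisy_case_with_raters):
        assert noisy_case_with_raters.n_raters == 3
        case5 = simulate_raters(noisy_case_with_raters, 5, 0.5, seed=2)
        assert case5.n_raters == 5

    def test_agreement_decreases_with_boundary_sd(self, noisy_case_with_raters):
        mean_dice = []
        for sd in (0.25, 0.5, 1.0, 2.0):
            case = simulate_raters(noisy_case_with_raters, 3, sd, seed=11)
            masks = [case.rater_masks[r][0] for r in range(3)]
            mean_dice.append(np.mean(pairwise_dice(masks)))
        assert all(d < 1 for d in mean_dice)
        assert mean_dice == sorted(mean_dice, reverse=True)

    def test_rater_masks_stay_connected(self, noisy_case_with_raters):
        case = simulate_raters(noisy_case_with_raters, 3, 2.0, seed=4)
        for rater in case.rater_masks:
            for m in rater:
                assert ndimage.label(m.as_bool())[1] == 1


class TestGenerateCohort:
    def test_fixed_seed_reproduces_cohort_exactly(self):
        a = generate_cohort(8, seed=5, n_raters=2)
        b = generate_cohort(8, seed=5, n_raters=2)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.section.pixels, cb.section.pixels)
            for ra, rb in zip(ca.rater_masks, cb.rater_masks):
                for ma, mb in zip(ra, rb):
                    assert np.array_equal(ma.pixels, mb.pixels)

    def test_cohort_size(self):
        assert len(generate_cohort(12, seed=0)) == 12

    def test_sampled_ratios_span_requested_range(self):
        sampler = CohortSampler(fat_range=(0.0, 0.5), image_size=128)
        cases = generate_cohort(25, sampler, seed=8)
        ri = [m.ri for c in cases for m in c.true_measures]
        assert 0.0 <= min(ri) and max(ri) <= 0.5 + 2 / 100
        assert max(ri) > 0.3  # the range is actually exercised
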