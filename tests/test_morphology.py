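"""Structuring-element fidelity and erosion/dilation semantics, pinned by
brute-force all-placements oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from veinseg import (
    StructuringElement,
    dilate,
    disk_element,
    erode,
    rect_element,
    refine_vessels,
    t_elements,
)

from oracles import brute_dilate, brute_erode


def masks(side=16, p=0.5):
    return st.integers(0, 2**31 - 1).map(
        lambda s: np.random.default_rng(s).random((side, side)) < p
    )


class TestElements:
    def test_t_elements_match_printed_matrices(self):
        t1, t2, t3, t4 = t_elements()
        expect_t1 = np.array(
            [[0, 0, 0, 0, 0, 0],
             [0, 0, 0, 0, 0, 0],
             [1, 1, 1, 1, 1, 1],
             [1, 1, 1, 1, 1, 1],
             [0, 0, 1, 1, 0, 0],
             [0, 0, 1, 1, 0, 0]], dtype=bool)
        expect_t2 = np.array(
            [[0, 0, 1, 1, 0, 0],
             [0, 0, 1, 1, 0, 0],
             [0, 0, 1, 1, 1, 1],
             [0, 0, 1, 1, 1, 1],
             [0, 0, 1, 1, 0, 0],
             [0, 0, 1, 1, 0, 0]], dtype=bool)
        np.testing.assert_array_equal(t1.matrix, expect_t1)
        np.testing.assert_array_equal(t2.matrix, expect_t2)
        np.testing.assert_array_equal(t3.matrix, np.flipud(expect_t1))
        np.testing.assert_array_equal(t4.matrix, np.fliplr(expect_t2))

    def test_t_element_cell_counts_and_anchor(self):
        for t in t_elements():
            assert t.matrix.sum() == 16  # 12-cell bar + 4-cell stem
            assert t.anchor == (2, 2)
            assert t.matrix[t.anchor]

    def test_disk_radius_1_is_cross(self):
        d = disk_element(1)
        np.testing.assert_array_equal(
            d.matrix, np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
        )

    def test_disk_radius_2_has_13_cells_and_symmetry(self):
        d = disk_element(2)
        assert d.matrix.sum() == 13
        np.testing.assert_array_equal(d.matrix, d.matrix[::-1])
        np.testing.assert_array_equal(d.matrix, d.matrix[:, ::-1])
        np.testing.assert_array_equal(d.matrix, d.matrix.T)

    def test_invalid_elements_rejected(self):
        with pytest.raises(ValueError):
            disk_element(0)
        with pytest.raises(ValueError):
            rect_element(0, 3)
        with pytest.raises(ValueError):
            StructuringElement(np.zeros((3, 3), dtype=bool), (1, 1))
        with pytest.raises(ValueError):
            StructuringElement(np.ones((3, 3), dtype=bool), (3, 0))


class TestErodeDilate:
    def test_all_true_mask_fixed_by_erosion(self):
        m = np.ones((10, 10), dtype=bool)
        for se in t_elements() + [disk_element(2)]:
            np.testing.assert_array_equal(erode(m, se), m)

    def test_single_pixel_erased_by_large_element(self):
        m = np.zeros((12, 12), dtype=bool)
        m[6, 6] = True
        assert not erode(m, t_elements()[0]).any()

    def test_empty_mask_fixed_by_dilation(self):
        m = np.zeros((8, 8), dtype=bool)
        for se in t_elements() + [disk_element(2)]:
            assert not dilate(m, se).any()

    def test_dilate_point_by_unit_disk_is_plus(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        out = dilate(m, disk_element(1))
        assert out.sum() == 5
        assert out[4, 4] and out[3, 4] and out[5, 4] and out[4, 3] and out[4, 5]

    @pytest.mark.parametrize("se_idx", range(5))
    def test_oracle_equivalence(self, rng, se_idx):
        ses = t_elements() + [disk_element(2)]
        se = ses[se_idx]
        for _ in range(10):
            m = rng.random((16, 16)) < 0.5
            np.testing.assert_array_equal(erode(m, se), brute_erode(m, se.matrix, se.anchor))
            np.testing.assert_array_equal(dilate(m, se), brute_dilate(m, se.matrix, se.anchor))

    def test_duality_with_reflected_element(self, rng):
        # dilation = complement of erosion of the complement by the
        # reflected element; an asymmetric element makes reflection visible
        for se in t_elements():
            m = rng.random((16, 16)) < 0.5
            dual = ~brute_erode(~m, se.reflected().matrix, se.reflected().anchor)
            np.testing.assert_array_equal(dilate(m, se), dual)

    def test_false_anchor_warns(self):
        se = StructuringElement(np.array([[1, 0], [0, 0]], dtype=bool), (1, 1))
        with pytest.warns(UserWarning):
            erode(np.ones((5, 5), dtype=bool), se)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(mask=masks())
    def test_extensivity_and_monotonicity(self, mask):
        se = disk_element(2)
        er, di = erode(mask, se), dilate(mask, se)
        assert not np.any(er & ~mask)  # erosion shrinks
        assert not np.any(mask & ~di)  # dilation grows
        sub = mask.copy()
        sub[::2] = False
        assert not np.any(erode(sub, se) & ~er)
        assert not np.any(dilate(sub, se) & ~di)

    def test_translation_equivariance_away_from_borders(self, rng):
        se = t_elements()[1]
        m = np.zeros((24, 24), dtype=bool)
        m[8:14, 8:14] = rng.random((6, 6)) < 0.6
        shifted = np.roll(m, (2, 3), axis=(0, 1))
        np.testing.assert_array_equal(
            erode(shifted, se)[8:18, 8:18], np.roll(erode(m, se), (2, 3), axis=(0, 1))[8:18, 8:18]
        )


class TestRefineVessels:
    def test_empty_mask_stays_empty(self):
        assert not refine_vessels(np.zeros((20, 20), dtype=bool)).any()

    def test_protrusions_removed_bar_kept(self):
        mask = np.zeros((30, 80), dtype=bool)
        mask[10:20, 10:70] = True  # 10 x 60 bar
        bumpy = mask.copy()
        bumpy[9, 15] = bumpy[9, 30] = bumpy[9, 55] = True  # single-pixel bumps
        out = refine_vessels(bumpy)
        # the bumps are smoothed away entirely: the result is identical to
        # refining the clean bar, whose body is preserved
        np.testing.assert_array_equal(out, refine_vessels(mask))
        assert out[10:20, 10:66].all()

    def test_matches_step_by_step_oracle_schedule(self, rng):
        b = disk_element(3)
        for _ in range(3):
            m = rng.random((32, 32)) < 0.5
            ref = m
            for t in t_elements():
                ref = brute_dilate(brute_erode(ref, t.matrix, t.anchor), b.matrix, b.anchor)
            np.testing.assert_array_equal(refine_vessels(m, 3), ref)

    def test_bounded_by_four_dilations(self, rng):
        m = rng.random((24, 24)) < 0.3
        b = disk_element(3)
        bound = m
        for _ in range(4):
            bound = dilate(bound, b)
        assert not np.any(refine_vessels(m, 3) & ~bound)
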