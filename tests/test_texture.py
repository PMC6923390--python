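"""Quantizer and the five gray-level matrix builders, including exact
agreement with brute-force enumeration oracles on random ROIs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gliorad.image import RoiMask, VolumeImage
from gliorad.texture import (
    DIRECTIONS_13,
    QuantizedRoi,
    glcm,
    glrlm,
    glszm,
    ngldm,
    ngtdm,
    quantize_roi,
    quantize_values,
)

import oracles


def qroi_from_levels(lev):
    lev = np.asarray(lev, dtype=np.int64)
    return QuantizedRoi(lev, int(max(lev.max(), 1)), RoiMask(lev > 0))


class TestQuantizer:
    def test_hand_worked_binning(self):
        # mu=0, population sigma=sqrt(5); bits=2 -> 4 bins over +-3*sqrt(5)
        out = quantize_values(np.array([-3.0, -1.0, 1.0, 3.0]), 2)
        assert out.tolist() == [2, 2, 3, 3]

    def test_constant_roi_all_level_one(self):
        assert quantize_values(np.full(10, 4.2), 6).tolist() == [1] * 10

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=40),
        st.integers(4, 8),
    )
    def test_levels_within_bounds(self, vals, bits):
        lev = quantize_values(np.asarray(vals), bits)
        assert lev.min() >= 1 and lev.max() <= 2**bits

    def test_quantize_roi_zero_outside(self):
        img = VolumeImage(np.random.default_rng(0).normal(size=(4, 4, 4)))
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        q = quantize_roi(img, RoiMask(mask), 4)
        assert (q.levels[~mask] == 0).all()
        assert (q.levels[mask] >= 1).all()


class TestWorkedExamples:
    def test_glcm_two_voxel_pair(self):
        m = glcm(qroi_from_levels(np.array([[[1, 2]]])))
        np.testing.assert_allclose(m.table, [[0, 0.5], [0.5, 0]])

    def test_glcm_uniform_roi_single_diagonal(self):
        m = glcm(qroi_from_levels(np.ones((3, 3, 3), dtype=int)))
        assert m.table[0, 0] == 1.0
        assert m.table.sum() == 1.0

    def test_glrlm_single_direction_runs(self):
        q = qroi_from_levels(np.array([[[1, 1, 2, 2]]]))
        r = glrlm(q, directions=[(0, 0, 1)])
        expect = np.zeros((2, 4), dtype=int)
        expect[0, 1] = 1  # (level 1, length 2)
        expect[1, 1] = 1  # (level 2, length 2)
        np.testing.assert_array_equal(r.table, expect)

    def test_glrlm_uniform_line_single_run(self):
        q = qroi_from_levels(np.array([[[1, 1, 1]]]))
        r = glrlm(q, directions=[(0, 0, 1)])
        assert r.table[0, 2] == 1 and r.table.sum() == 1

    def test_glszm_single_zone(self):
        m = glszm(qroi_from_levels(np.ones((2, 3, 2), dtype=int)))
        assert m.table[0, 11] == 1 and m.table.sum() == 1

    def test_glszm_diagonal_touch_is_one_zone(self):
        lev = np.zeros((2, 2, 2), dtype=int)
        lev[0, 0, 0] = lev[1, 1, 1] = 1
        m = glszm(qroi_from_levels(lev))
        assert m.table[0, 1] == 1  # one zone of size 2

    def test_ngldm_uniform_cube_center(self):
        m = ngldm(qroi_from_levels(np.ones((3, 3, 3), dtype=int)))
        assert m.table[0, 26] == 1  # the centre voxel has k = 26

    def test_ngldm_single_voxel(self):
        m = ngldm(qroi_from_levels(np.array([[[3]]])))
        assert m.table[2, 0] == 1 and m.table.sum() == 1

    def test_ngtdm_hand_case(self):
        m = ngtdm(qroi_from_levels(np.array([[[1, 2, 1]]])))
        assert m.table[0, 0] == 2.0 and m.table[0, 1] == 2
        assert m.table[1, 0] == 1.0 and m.table[1, 1] == 1

    def test_ngtdm_uniform_all_zero_s(self):
        m = ngtdm(qroi_from_levels(np.ones((3, 3, 3), dtype=int)))
        assert (m.table[:, 0] == 0).all()


class TestOracleEquivalence:
    """Exact integer agreement with exhaustive enumeration on random ROIs."""

    @pytest.mark.parametrize("seed", range(6))
    def test_all_families_random_rois(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            n_g = int(rng.integers(2, 9))
            lev = oracles.random_roi(rng, n_g)
            q = QuantizedRoi(lev, n_g, RoiMask(lev > 0))
            n_v = int((lev > 0).sum())
            g = glcm(q)
            raw = oracles.glcm_counts(lev, n_g)
            if raw.sum():
                np.testing.assert_allclose(g.table, raw / raw.sum(), atol=1e-12)
            r = glrlm(q).table
            ro = oracles.glrlm_counts(lev, n_g)
            w = max(r.shape[1], ro.shape[1])
            np.testing.assert_array_equal(oracles.pad_cols(r, w), oracles.pad_cols(ro, w))
            s = glszm(q).table
            so = oracles.glszm_counts(lev, n_g)
            assert s.shape[1] == so.shape[1]
            np.testing.assert_array_equal(s, so)
            np.testing.assert_array_equal(ngldm(q).table, oracles.ngldm_counts(lev, n_g))
            np.testing.assert_allclose(
                ngtdm(q).table, oracles.ngtdm_table(lev, n_g), atol=1e-12
            )
            # structural invariants
            assert abs(g.table.sum() - 1) < 1e-12 if raw.sum() else True
            np.testing.assert_allclose(g.table, g.table.T, atol=1e-15)
            assert (np.arange(1, r.shape[1] + 1) * r).sum() <= 13 * n_v
            assert (np.arange(1, s.shape[1] + 1) * s).sum() == n_v
            assert ngldm(q).table.sum() == n_v


class TestInvariants:
    def test_level_relabel_permutes_rows(self):
        rng = np.random.default_rng(4)
        lev = oracles.random_roi(rng, 4, max_edge=5)
        perm = rng.permutation(4) + 1
        relab = np.where(lev > 0, perm[lev - 1], 0)
        q1 = QuantizedRoi(lev, 4, RoiMask(lev > 0))
        q2 = QuantizedRoi(relab, 4, RoiMask(relab > 0))
        p = perm - 1
        np.testing.assert_array_equal(glrlm(q2).table[p], glrlm(q1).table)
        np.testing.assert_array_equal(glszm(q2).table[p], glszm(q1).table)
        np.testing.assert_allclose(glcm(q2).table[np.ix_(p, p)], glcm(q1).table)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        lev = np.zeros((9, 9, 9), dtype=np.int64)
        lev[1:5, 1:5, 1:5] = rng.integers(1, 5, size=(4, 4, 4))
        moved = np.roll(lev, (3, 2, 3), axis=(0, 1, 2))
        q1 = QuantizedRoi(lev, 4, RoiMask(lev > 0))
        q2 = QuantizedRoi(moved, 4, RoiMask(moved > 0))
        for op in (glcm, glrlm, glszm, ngldm, ngtdm):
            np.testing.assert_allclose(op(q1).table, op(q2).table)

    def test_direction_set_is_13_unique_half_space(self):
        assert len(set(DIRECTIONS_13)) == 13
        for d in DIRECTIONS_13:
            assert tuple(-x for x in d) not in DIRECTIONS_13
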