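import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pollenfoci.image_io import ZStack
from pollenfoci.masking import make_cytoplasm_masks
from pollenfoci.metrics import (
    channel_thresholds,
    section_cv,
    section_pcc,
    stack_cv,
    stack_pcc,
)
from pollenfoci.synthetic import generate_pollen_stack

from conftest import small_spec


def brute_force_cv(values):
    """Independent textbook implementation: population sd / mean via loops."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return math.sqrt(var) / mean


def brute_force_pearson(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(sum((x - ma) ** 2 for x in a))
    db = math.sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


class TestSectionCV:
    def test_constant_section_is_zero(self):
        assert section_cv(np.full(50, 7.0)) == 0.0

    def test_two_point_example(self):
        # sd_pop({1,3}) = 1, mean = 2
        assert section_cv(np.array([1.0, 3.0])) == pytest.approx(0.5)

    @given(st.floats(min_value=0.01, max_value=1e4))
    def test_scale_invariance(self, k):
        values = np.array([1.0, 2.0, 5.0, 9.0, 3.0])
        assert section_cv(values * k) == pytest.approx(section_cv(values), rel=1e-9)

    def test_undefined_cases(self):
        assert section_cv(np.array([4.0])) is None
        assert section_cv(np.zeros(10)) is None  # mean 0

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            v = rng.uniform(0.1, 100, size=rng.integers(2, 64))
            assert section_cv(v) == pytest.approx(brute_force_cv(v.tolist()), abs=1e-12)


class TestSectionPCC:
    def test_identical_channels_give_one(self, rng):
        a = rng.uniform(10, 100, size=(16, 16))
        mask = np.ones_like(a, bool)
        assert section_pcc(a, a, mask, 5, 5, min_pixels=2) == pytest.approx(1.0)

    def test_affine_anticorrelation_gives_minus_one(self, rng):
        a = rng.uniform(10, 50, size=(16, 16))
        b = 100.0 - a
        mask = np.ones_like(a, bool)
        assert section_pcc(a, b, mask, 0, 0, min_pixels=2) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self, rng):
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            a = rng.uniform(10, 100, size=(128, 128))
            b = rng.uniform(10, 100, size=(128, 128))
            r = section_pcc(a, b, np.ones_like(a, bool), 0, 0)
            if abs(r) < 0.05:  # Fisher z: sd ~ 1/sqrt(n) = 0.008 here
                hits += 1
        assert hits >= int(0.95 * n_rep)

    def test_union_vs_intersection_rules(self):
        a = np.array([[10.0, 1.0, 10.0, 1.0]])
        b = np.array([[1.0, 10.0, 10.0, 1.0]])
        mask = np.ones_like(a, bool)
        # union keeps 3 pixels, intersection only the double-positive one
        assert section_pcc(a, b, mask, 5, 5, rule="union", min_pixels=2) is not None
        assert section_pcc(a, b, mask, 5, 5, rule="intersection", min_pixels=2) is None

    def test_too_few_pixels_undefined(self, rng):
        a = rng.uniform(0, 1, size=(4, 4))
        assert section_pcc(a, a, np.ones_like(a, bool), 0.99, 0.99) is None

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            a = rng.uniform(0, 100, size=(16, 16))
            b = a * 0.5 + rng.normal(0, 10, size=(16, 16))
            b -= b.min()
            r = section_pcc(a, b, np.ones_like(a, bool), 20, 10, min_pixels=2)
            sel = (a.ravel() > 20) | (b.ravel() > 10)
            expected = brute_force_pearson(a.ravel()[sel].tolist(), b.ravel()[sel].tolist())
            assert r == pytest.approx(expected, abs=1e-12)


class TestChannelThresholds:
    def _bimodal_stack(self):
        lo = np.full((2, 16, 16), 10, np.uint16)
        lo[:, 8:, :] = 200
        return ZStack(channels={"DAPI": np.zeros_like(lo), "g": lo, "r": lo})

    def _masks(self, stack):
        from pollenfoci.masking import SectionMaskSet

        full = np.ones(stack.shape, bool)
        return SectionMaskSet(
            pollen=full,
            cytoplasm=full.copy(),
            included=np.ones(stack.n_sections, bool),
            reasons=[""] * stack.n_sections,
            background={"g": 0.0, "r": 0.0},
        )

    def test_otsu_separates_bimodal_modes(self):
        stack = self._bimodal_stack()
        thr = channel_thresholds(stack, self._masks(stack), ("g", "r"))
        assert 10 < thr["g"] < 200

    def test_identical_channels_identical_thresholds(self):
        stack = self._bimodal_stack()
        thr = channel_thresholds(stack, self._masks(stack), ("g", "r"))
        assert thr["g"] == thr["r"]

    def test_percentile_median_order_statistic(self):
        vol = np.arange(1, 101, dtype=np.uint16).reshape(1, 10, 10)
        stack = ZStack(channels={"DAPI": np.zeros_like(vol), "g": vol, "r": vol})
        thr = channel_thresholds(
            stack, self._masks(stack), ("g", "r"), method="percentile", percentile=50
        )
        assert 50 <= thr["g"] <= 51

    def test_degenerate_distribution_rejected(self):
        vol = np.full((1, 8, 8), 5, np.uint16)
        stack = ZStack(channels={"DAPI": np.zeros_like(vol), "g": vol, "r": vol})
        masks = self._masks(stack)
        with pytest.raises(ValueError, match="degenerate"):
            channel_thresholds(stack, masks, ("g", "r"))


class TestStackLevel:
    def test_single_included_section_aggregate(self):
        stack, _ = generate_pollen_stack(small_spec(seed=11))
        masks = make_cytoplasm_masks(stack)
        keep = np.flatnonzero(masks.included)[:1]
        masks.included[:] = False
        masks.included[keep] = True
        prof = stack_cv(stack, masks, "GFP")
        assert prof.n_sections_included == 1
        assert prof.aggregate == prof.section_cvs[0]

    def test_cv_scale_invariance_background_free(self):
        spec = small_spec(seed=12, background=0.0)
        stack, _ = generate_pollen_stack(spec)
        tripled = ZStack(
            channels={c: (v.astype(np.uint32) * 3).astype(np.uint16) for c, v in stack.channels.items()},
            voxel_size=stack.voxel_size,
            sample_id=stack.sample_id,
        )
        masks = make_cytoplasm_masks(stack)  # same pixel set for both
        p1 = stack_cv(stack, masks, "GFP", background=0.0)
        p2 = stack_cv(tripled, masks, "GFP", background=0.0)
        assert p1.section_indices == p2.section_indices
        np.testing.assert_allclose(p1.section_cvs, p2.section_cvs, rtol=1e-6)

    def test_aggregate_is_mean_of_sections(self):
        stack, _ = generate_pollen_stack(small_spec(seed=13))
        masks = make_cytoplasm_masks(stack)
        prof = stack_cv(stack, masks, "GFP")
        assert prof.aggregate == pytest.approx(np.mean(prof.section_cvs))
        res = stack_pcc(stack, masks)
        assert res.aggregate == pytest.approx(np.mean(res.section_rs))
        assert all(-1 <= r <= 1 for r in res.section_rs)

    def test_channel_with_itself_r_one(self):
        stack, _ = generate_pollen_stack(small_spec(seed=14))
        masks = make_cytoplasm_masks(stack)
        res = stack_pcc(stack, masks, pair=("GFP", "GFP"))
        assert res.aggregate == pytest.approx(1.0)

    def test_section_policy_identical_on_nucleus_free_stack(self):
        stack, _ = generate_pollen_stack(small_spec(seed=15))
        blank = ZStack(
            channels={
                "DAPI": np.zeros(stack.shape, np.uint16),
                "GFP": stack.channels["GFP"],
                "RFP": stack.channels["RFP"],
            },
            voxel_size=stack.voxel_size,
        )
        masks = make_cytoplasm_masks(blank)
        r_all = stack_pcc(blank, masks, section_policy="all")
        r_free = stack_pcc(blank, masks, section_policy="nucleus_free")
        assert r_all.section_rs == r_free.section_rs

    def test_no_included_sections_raises(self):
        stack, _ = generate_pollen_stack(small_spec(seed=16))
        masks = make_cytoplasm_masks(stack)
        masks.included[:] = False
        with pytest.raises(ValueError):
            stack_cv(stack, masks, "GFP")
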