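from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from pollenfoci.masking import make_cytoplasm_masks
from pollenfoci.metrics import section_cv, stack_cv
from pollenfoci.synthetic import (
    ChannelSpec,
    SyntheticSpec,
    child_seeds,
    generate_condition_series,
    generate_ct_table,
    generate_pollen_stack,
    spec_from_dict,
)

from conftest import small_spec


def _set_f(spec, f):
    return replace(
        spec, channels={n: replace(c, clustered_fraction=f) for n, c in spec.channels.items()}
    )


class TestGeneratePollenStack:
    def test_same_spec_same_seed_bit_identical(self):
        s1, _ = generate_pollen_stack(small_spec(seed=3))
        s2, _ = generate_pollen_stack(small_spec(seed=3))
        for c in s1.channels:
            np.testing.assert_array_equal(s1.channels[c], s2.channels[c])

    def test_different_seed_differs(self):
        s1, _ = generate_pollen_stack(small_spec(seed=3))
        s2, _ = generate_pollen_stack(small_spec(seed=4))
        assert any(not np.array_equal(s1.channels[c], s2.channels[c]) for c in s1.channels)

    def test_noise_free_unclustered_cytoplasm_is_smooth(self):
        # f = 0, no read noise, no shot noise: the only cytoplasm structure
        # left is the PSF roll-off at the boundary, so the interior CV is tiny
        spec = _set_f(
            small_spec(seed=5, background=0.0, gain=np.inf, read_noise_sd=0.0), 0.0
        )
        stack, truth = generate_pollen_stack(spec)
        interior = ndimage.binary_erosion(
            truth.pollen_mask & ~truth.nucleus_mask,
            structure=np.ones((1, 3, 3), bool),  # in-plane only
            iterations=4,
        )
        z = spec.shape[0] // 2
        cv = section_cv(stack.channels["GFP"][z][interior[z]].astype(float))
        assert cv is not None and cv < 0.05

    def test_total_signal_invariant_to_clustering_fraction(self):
        # clustering redistributes, does not add, signal
        base = small_spec(seed=6, background=0.0, gain=np.inf, read_noise_sd=0.0)
        totals = []
        for f in (0.0, 0.4, 0.9):
            stack, _ = generate_pollen_stack(_set_f(base, f))
            totals.append(stack.channels["GFP"].astype(np.float64).sum())
        assert np.ptp(totals) / np.mean(totals) < 0.01

    def test_shared_fraction_matches_rho_within_rounding(self):
        for seed in range(5):
            _, truth = generate_pollen_stack(small_spec(seed=seed, rho=0.37))
            n = truth.n_foci["GFP"]
            assert truth.n_shared == round(0.37 * n)
            assert abs(truth.shared_fraction - 0.37) <= 0.5 / max(n, 1)

    def test_shared_fraction_converges_to_rho(self):
        fracs = [
            generate_pollen_stack(small_spec(seed=s, rho=0.6))[1].shared_fraction
            for s in range(50)
        ]
        assert abs(np.mean(fracs) - 0.6) < 0.03

    def test_nucleus_flags_agree_with_voxel_masks(self):
        _, truth = generate_pollen_stack(small_spec(seed=8))
        areas = truth.nucleus_mask.sum(axis=(1, 2))
        pol = truth.pollen_mask.sum(axis=(1, 2))
        expected = (areas / np.maximum(pol, 1)) > 0.01
        np.testing.assert_array_equal(truth.section_has_nucleus, expected)

    def test_high_coloc_gives_high_pcc(self):
        # construction is the oracle: all foci shared, low noise
        from pollenfoci.metrics import stack_pcc

        spec = _set_f(small_spec(seed=9, rho=1.0, read_noise_sd=0.5), 0.8)
        stack, _ = generate_pollen_stack(spec)
        masks = make_cytoplasm_masks(stack)
        assert stack_pcc(stack, masks).aggregate >= 0.9

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            small_spec(rho=1.5)
        with pytest.raises(ValueError):
            small_spec(f=-0.1)

    def test_geometry_outside_volume_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            small_spec(pollen_semiaxes=(20.0, 45.0, 45.0))


class TestConditionSeries:
    def test_count_labels_and_seed_uniqueness(self):
        series = generate_condition_series(
            small_spec(), f_by_condition={"a": 0.1, "b": 0.5, "c": 0.3}, n_replicates=3, seed=1
        )
        assert len(series) == 9
        assert {s.condition for s, _ in series} == {"a", "b", "c"}
        seeds = child_seeds(1, 9)
        assert len(set(seeds)) == 9

    def test_cv_ordering_follows_programmed_f(self):
        series = generate_condition_series(
            small_spec(),
            f_by_condition={"control": 0.1, "hs1h": 0.5, "hs24h": 0.3},
            n_replicates=6,
            seed=2,
        )
        means = {}
        by_cond: dict[str, list[float]] = {}
        for stack, _ in series:
            masks = make_cytoplasm_masks(stack)
            by_cond.setdefault(stack.condition, []).append(
                stack_cv(stack, masks, "GFP").aggregate
            )
        means = {c: np.mean(v) for c, v in by_cond.items()}
        assert means["hs1h"] > means["hs24h"] > means["control"]

    def test_single_replicate(self):
        series = generate_condition_series(
            small_spec(), f_by_condition={"a": 0.1, "b": 0.5}, n_replicates=1, seed=3
        )
        assert len(series) == 2

    def test_errors(self):
        with pytest.raises(ValueError, match="two conditions"):
            generate_condition_series(small_spec(), f_by_condition={"a": 0.1})
        with pytest.raises(ValueError):
            generate_condition_series(
                small_spec(), f_by_condition={"a": 0.1, "b": 0.2}, rho_by_condition={"a": 1.0}
            )


class TestCtTableGenerator:
    def test_zero_noise_null_folds_identical_arms(self):
        table, _ = generate_ct_table(
            ["g1"], ["1h"], {}, n_bio=3, n_tech=2, noise_sd=0.0, seed=0
        )
        t = table[table.treatment == "treated"]["ct"].to_numpy()
        c = table[table.treatment == "control"]["ct"].to_numpy()
        np.testing.assert_array_equal(np.sort(t), np.sort(c))

    def test_fold_two_lowers_ct_one_cycle(self):
        table, _ = generate_ct_table(
            ["g1"], ["1h"], {("g1", "1h"): 2.0}, n_bio=2, n_tech=1, noise_sd=0.0, seed=0
        )
        by = table.groupby(["gene", "treatment"])["ct"].mean()
        assert by[("g1", "treated")] == pytest.approx(by[("g1", "control")] - 1.0)
        # references untouched
        assert by[("GAPC1", "treated")] == by[("GAPC1", "control")]

    def test_row_count_combinatorics(self):
        genes = [f"g{i}" for i in range(6)]  # +2 references = 8 genes
        table, _ = generate_ct_table(genes, ["1h"], {}, n_bio=4, n_tech=2, seed=1)
        per_arm = table.groupby("treatment").size()
        assert (per_arm == 8 * 4 * 2).all()
        assert len(table) == 128

    def test_non_positive_fold_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            generate_ct_table(["g1"], ["1h"], {("g1", "1h"): 0.0}, seed=0)


def test_spec_from_dict_round_trips_nested_fields():
    spec = spec_from_dict(
        {
            "seed": 7,
            "shape": [10, 64, 64],
            "voxel_size": [1.0, 0.3, 0.3],
            "pollen_semiaxes": [3.0, 25.0, 25.0],
            "vn": {"center": [5.0, 30.0, 32.0], "radius_um": 1.5},
            "sc": [
                {"center": [5.0, 26.0, 36.0], "radius_um": 0.8},
                {"center": [4.0, 25.0, 28.0], "radius_um": 0.8},
            ],
            "channels": {"GFP": {"clustered_fraction": 0.2}, "RFP": {}},
        }
    )
    assert spec.seed == 7
    assert spec.channels["GFP"].clustered_fraction == 0.2
    generate_pollen_stack(spec)  # geometry is valid and renders
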