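import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pulmopet import (
    CellCountRecord,
    LobeMaskVolume,
    ScalarVolume,
    VolumeGrid,
    anova_on_ranks,
    bal_concentrations,
    gravity_profile,
    kruskal_wallis_h,
    lobe_summary,
    median_iqr,
    pairwise_ranks,
    subject_table_fixture,
)
from pulmopet.regional import FunctionalMaps


def brute_force_kruskal_h(groups):
    """Independent H computation: explicit sorting, tie-group enumeration."""
    pooled = [x for vals in groups.values() for x in vals]
    sorted_vals = sorted(pooled)

    def rank_of(v):
        positions = [i + 1 for i, s in enumerate(sorted_vals) if s == v]
        return sum(positions) / len(positions)

    n = len(pooled)
    h = 12.0 / (n * (n + 1)) * sum(
        len(vals) * (sum(rank_of(v) for v in vals) / len(vals)) ** 2
        for vals in groups.values()
    ) - 3 * (n + 1)
    tie_counts = {}
    for v in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    corr = 1 - sum(t**3 - t for t in tie_counts.values()) / (n**3 - n)
    return h / corr if corr > 0 else 0.0


class TestMedianIqr:
    # printed summary row of the subject table, reproduced exactly
    @pytest.mark.parametrize(
        "column,decimals,expected",
        [
            ("age_yr", 0, (30, 25, 33)),
            ("height_cm", 1, (171.5, 163.2, 179.7)),
            ("bmi_kg_m2", 1, (24.7, 22.7, 27.6)),
            ("fev1_l", 2, (3.75, 3.64, 3.99)),
            ("fvc_l", 2, (4.50, 4.40, 4.95)),
            ("fev1_fvc", 2, (0.81, 0.80, 0.82)),
            ("dose", 0, (370, 185, 370)),
        ],
    )
    def test_subject_table_cells(self, column, decimals, expected):
        values = subject_table_fixture()[column].tolist()
        med, q1, q3 = median_iqr(values, decimals=decimals)
        assert (med, q1, q3) == pytest.approx(expected)

    def test_single_value_degenerate(self):
        assert median_iqr([4.2]) == pytest.approx((4.2, 4.2, 4.2))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_unrounded_quantiles_match_numpy_linear(self, values):
        med, q1, q3 = median_iqr(values)
        np_med, np_q1, np_q3 = np.percentile(values, [50, 25, 75])
        assert q1 == pytest.approx(np_q1, abs=1e-9)
        assert q3 == pytest.approx(np_q3, abs=1e-9)
        assert med == pytest.approx(np_med, abs=1e-9)


class TestKruskalWallis:
    def test_hand_computed_no_ties(self):
        # {1,2},{3,4},{5,6}: H = 12/(6*7)*(2*1.5^2+2*3.5^2+2*5.5^2) - 21
        h, p = kruskal_wallis_h({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert h == pytest.approx(12 / 42 * (2 * 1.5**2 + 2 * 3.5**2 + 2 * 5.5**2) - 21)

    def test_identical_groups_no_effect(self):
        h, p = kruskal_wallis_h({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_all_values_identical(self):
        h, p = kruskal_wallis_h({"a": [5, 5], "b": [5, 5]})
        assert (h, p) == (0.0, 1.0)

    def test_matches_brute_force_on_small_inputs(self, rng):
        for trial in range(30):
            k = rng.integers(2, 4)
            sizes = rng.integers(2, 5, size=k)
            while sizes.sum() > 12:
                sizes = rng.integers(2, 5, size=k)
            groups = {
                f"g{i}": rng.integers(0, 6, size=s).astype(float).tolist()
                for i, s in enumerate(sizes)
            }
            if len({v for vals in groups.values() for v in vals}) == 1:
                continue
            h, _ = kruskal_wallis_h(groups)
            assert h == pytest.approx(brute_force_kruskal_h(groups), abs=1e-10), groups

    def test_matches_scipy(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.3, 1, 7).tolist() for i in range(3)}
        h, p = kruskal_wallis_h(groups)
        ref = sps.kruskal(*groups.values())
        assert h == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_monotone_transform_invariance(self, rng):
        groups = {f"g{i}": rng.normal(i, 1, 5).tolist() for i in range(3)}
        h1, _ = kruskal_wallis_h(groups)
        h2, _ = kruskal_wallis_h({g: list(np.exp(v)) for g, v in groups.items()})
        assert h2 == pytest.approx(h1, abs=1e-12)


class TestPairwise:
    def three_groups(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        return {
            "baseline": rng.normal(1.0, 0.05, 6),
            "diluent": rng.normal(1.0, 0.05, 6),
            "allergen": rng.normal(1.0, 0.05, 6) + shift,
        }

    def test_identical_groups_nothing_significant(self):
        g = {"baseline": [1, 2, 3], "diluent": [1, 2, 3], "allergen": [1, 2, 3]}
        dec = pairwise_ranks(g)
        assert not any(d.significant for d in dec.values())

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="allergen"):
            pairwise_ranks({"baseline": [1, 2], "diluent": [3, 4]})

    def test_label_permutation_equivariance(self):
        g = self.three_groups(shift=-0.5, seed=3)
        dec = pairwise_ranks(g)
        swapped = {"baseline": g["diluent"], "diluent": g["baseline"], "allergen": g["allergen"]}
        dec_sw = pairwise_ranks(swapped)
        assert dec[("allergen", "baseline")].statistic == pytest.approx(
            dec_sw[("allergen", "diluent")].statistic
        )
        assert dec[("diluent", "baseline")].statistic == pytest.approx(
            dec_sw[("diluent", "baseline")].statistic
        )

    def test_strong_shift_detected_in_most_replicates(self):
        # allergen shifted 3 IQR below both controls: the two allergen pairs
        # are flagged in >= 95% of 200 replicates (exact permutation test)
        rng = np.random.default_rng(0)
        flagged = 0
        false_pos = 0
        n_rep = 200
        for rep in range(n_rep):
            base = rng.normal(1.0, 0.05, 6)
            dil = rng.normal(1.0, 0.05, 6)
            pooled = np.concatenate([base, dil])
            iqr = np.percentile(pooled, 75) - np.percentile(pooled, 25)
            alg = rng.normal(1.0, 0.05, 6) - 3 * iqr
            dec = pairwise_ranks(
                {"baseline": base, "diluent": dil, "allergen": alg},
                method="permutation",
                seed=rep,
            )
            flagged += (
                dec[("allergen", "diluent")].significant
                and dec[("allergen", "baseline")].significant
            )
            false_pos += dec[("diluent", "baseline")].significant
        assert flagged / n_rep >= 0.95
        # the null pair fires at about the nominal alpha, not more
        assert false_pos / n_rep <= 0.08

    def test_anova_on_ranks_bundles_pairwise(self):
        g = self.three_groups(shift=-0.5, seed=1)
        cmp = anova_on_ranks(g)
        assert set(cmp.pairwise) == {
            ("allergen", "diluent"),
            ("allergen", "baseline"),
            ("diluent", "baseline"),
        }
        assert 0 <= cmp.p_value <= 1
        assert "ANOVA on ranks" in cmp.summary()


class TestLobeSummary:
    def test_uniform_maps_give_unity(self, phantom):
        _, _, mask, _ = phantom
        ones = ScalarVolume(mask.grid, np.ones(mask.grid.dims), "q_rel")
        out = lobe_summary(FunctionalMaps(q_rel=ones, sv=ones.with_values(ones.values, "sv")), mask)
        assert (out.table["q_rel"] == 1.0).all()
        assert (out.table["sv"] == 1.0).all()

    def test_allergen_direction_from_phantom_truth(self, phantom):
        _, _, mask, truth = phantom
        q = ScalarVolume(mask.grid, truth.q_rel_normalized(), "q_rel")
        out = lobe_summary(FunctionalMaps(q_rel=q), mask).table.set_index("lobe")
        assert out.loc["allergen", "q_rel"] < out.loc["baseline", "q_rel"]
        assert out.loc["allergen", "q_rel"] < out.loc["diluent", "q_rel"]

    def test_fully_flagged_lobe_rejected(self, phantom):
        _, _, mask, _ = phantom
        ones = ScalarVolume(mask.grid, np.ones(mask.grid.dims), "q_rel")
        flags = mask.role_mask("allergen")
        with pytest.raises(ValueError, match="allergen"):
            lobe_summary(FunctionalMaps(q_rel=ones, low_signal=flags), mask)


def slab_mask_and_height():
    """2x2x16 grid, gravity along z; lobes partition x-columns and z-halves."""
    grid = VolumeGrid((2, 2, 16), (1.0, 1.0, 2.0), gravity_axis=2, dependent_positive=False)
    labels = np.zeros(grid.dims, dtype=np.int32)
    labels[0, :, :] = 1  # baseline slab: 32 voxels spanning all heights
    labels[1, :, :8] = 2
    labels[1, :, 8:] = 3
    mask = LobeMaskVolume(grid, labels, {"baseline": 1, "diluent": 2, "allergen": 3})
    height = grid.height_coordinate()
    h = height - height[labels > 0].min()
    return grid, mask, h


class TestGravityProfile:
    def test_equal_division_16_voxels(self):
        grid, mask, h = slab_mask_and_height()
        q = ScalarVolume(grid, np.ones(grid.dims), "q_rel")
        prof = gravity_profile(q, mask, n_bins=8)
        # diluent lobe has 16 voxels -> 8 bins of exactly 2
        assert prof.lobes["diluent"]["n_voxels"].tolist() == [2] * 8

    def test_uniform_field_and_increasing_heights(self):
        grid, mask, h = slab_mask_and_height()
        q = ScalarVolume(grid, np.full(grid.dims, 2.5), "q_rel")
        prof = gravity_profile(q, mask)
        for df in prof.lobes.values():
            assert (df["mean_q"] == 2.5).all()
            assert (np.diff(df["mean_height_mm"]) > 0).all()

    def test_linear_field_matches_analytic_mid_bin_values(self):
        grid, mask, h = slab_mask_and_height()
        a, b = 3.0, 0.5
        q = ScalarVolume(grid, a + b * h, "q_rel")
        prof = gravity_profile(q, mask, n_bins=8)
        df = prof.lobes["baseline"]
        # baseline slab: 32 voxels, heights 2z for z=0..15, 4 voxels per bin
        # bin k holds layers z=2k,2k+1 -> mean height 4k+1, mean q = a+b(4k+1)
        for k in range(8):
            expected_h = 4.0 * k + 1.0
            assert df.loc[k, "mean_height_mm"] == pytest.approx(expected_h, abs=1e-9)
            assert df.loc[k, "mean_q"] == pytest.approx(a + b * expected_h, abs=1e-6)

    def test_bins_partition_each_lobe(self, phantom):
        _, _, mask, truth = phantom
        q = ScalarVolume(mask.grid, truth.q_rel_normalized(), "q_rel")
        prof = gravity_profile(q, mask)
        for role in ("baseline", "diluent", "allergen"):
            assert prof.lobes[role]["n_voxels"].sum() == mask.role_mask(role).sum()
            counts = prof.lobes[role]["n_voxels"]
            assert counts.max() - counts.min() <= 1

    def test_lobe_smaller_than_bins_rejected(self):
        grid = VolumeGrid((2, 2, 2), (1, 1, 1), gravity_axis=2)
        labels = np.zeros(grid.dims, dtype=np.int32)
        labels[0, 0, 0] = 1
        labels[1, :, :] = 2
        labels[0, 1, :] = 3
        mask = LobeMaskVolume(grid, labels, {"baseline": 1, "diluent": 2, "allergen": 3})
        q = ScalarVolume(grid, np.ones(grid.dims), "q_rel")
        with pytest.raises(ValueError, match="baseline"):
            gravity_profile(q, mask, n_bins=8)


class TestBalConcentrations:
    def test_hand_division(self):
        rec = CellCountRecord("allergen", 60.0, 1.2e6, 3e5, 2e5, 7e5)
        conc = bal_concentrations(rec)
        assert conc["total_per_ml"] == pytest.approx(2e4)

    def test_zero_eosinophils(self):
        rec = CellCountRecord("baseline", 50.0, 1e5, 0.0, 4e4, 6e4)
        assert bal_concentrations(rec)["eosinophils_per_ml"] == 0.0

    def test_differential_sum_bounded_by_total(self):
        rec = CellCountRecord("diluent", 40.0, 2e6, 5e5, 5e5, 9e5)
        conc = bal_concentrations(rec)
        diff_sum = (
            conc["eosinophils_per_ml"]
            + conc["neutrophils_per_ml"]
            + conc["mononuclear_per_ml"]
        )
        assert diff_sum <= conc["total_per_ml"]
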