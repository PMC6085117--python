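"""Clone-level statistics: potency, rescaled sizes, QQ-R2, rank tests."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pancmorph import (CloneRecord, EmpiricalDistribution,
                       center_periphery_split, chi_square_potency,
                       classify_potency, ks_two_sample, mann_whitney,
                       potency_summary, qq_r2, rescaled_distribution)


def _clone(acinar=0.0, ductal=0.0, islet=0.0, **kw):
    defaults = dict(clone_id="c1", mouse_id="M1", color="RFP",
                    position=(0.0, 0.0, 0.0))
    defaults.update(kw)
    return CloneRecord(volume_acinar=acinar, volume_ductal=ductal,
                       volume_islet=islet, **defaults)


def _table(rows):
    recs = []
    for i, (a, d, isl) in enumerate(rows):
        recs.append({"clone_id": f"c{i}", "mouse_id": "M1", "color": "RFP",
                     "x_um": 0.0, "y_um": 0.0, "z_um": 0.0,
                     "vol_acinar_um3": a, "vol_ductal_um3": d,
                     "vol_islet_um3": isl, "n_branches": 1,
                     "induction": "E12.5", "collection": "P14"})
    return pd.DataFrame(recs)


class TestPotency:
    def test_all_three_compartments_is_tripotent(self):
        pot, lineages = classify_potency(_clone(acinar=10, ductal=5, islet=2))
        assert pot == "tri"
        assert lineages == {"acinar", "ductal", "islet"}

    def test_acinar_only_is_unipotent(self):
        pot, lineages = classify_potency(_clone(acinar=10))
        assert (pot, lineages) == ("uni", frozenset({"acinar"}))

    def test_exhaustive_presence_patterns(self):
        # all 7 non-empty presence patterns map to the right potency class
        for pattern in product([0.0, 5.0], repeat=3):
            if all(v == 0 for v in pattern):
                continue
            pot, lineages = classify_potency(_clone(*pattern))
            assert len(lineages) == sum(v > 0 for v in pattern)
            assert pot == {1: "uni", 2: "bi", 3: "tri"}[len(lineages)]

    def test_volume_at_threshold_counts_as_absent(self):
        pot, lineages = classify_potency(_clone(acinar=5, ductal=2),
                                         presence_threshold=2.0)
        assert lineages == {"acinar"}

    def test_empty_clone_raises(self):
        df = _table([(1.0, 0, 0)])
        with pytest.raises(ValueError):
            classify_potency(df.iloc[0], presence_threshold=10.0)


class TestPotencySummary:
    def test_fractions(self):
        df = _table([(1, 0, 0), (2, 0, 0), (1, 1, 0), (1, 1, 1)])
        out = potency_summary(df)
        row = out.loc["all"]
        assert (row["frac_uni"], row["frac_bi"], row["frac_tri"]) == \
            (0.50, 0.25, 0.25)
        assert row["n_clones"] == 4

    def test_grouping_partitions_clones(self):
        df = _table([(1, 0, 0)] * 6)
        df["color"] = ["RFP", "RFP", "GFP", "YFP", "CFP", "CFP"]
        out = potency_summary(df, group_by="color")
        assert out["n_clones"].sum() == 6
        assert np.allclose(
            out[["frac_uni", "frac_bi", "frac_tri"]].sum(axis=1), 1.0)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            potency_summary(_table([]))


class TestRescaledDistribution:
    def test_constant_sample(self):
        df = _table([(1, 0, 0)] * 4)
        dist = rescaled_distribution(df, "acinar")
        assert np.all(dist.rescaled == 1.0)
        assert dist.tail(0.5) == 1.0
        assert dist.tail(1.5) == 0.0

    def test_ten_percent_exceed_three_times_mean(self):
        # 9 small + 1 large arranged so exactly 10% of rescaled sizes > 3
        sizes = [1.0] * 9 + [31.0]   # mean 4.0; 31/4 = 7.75 > 3; 1/4 < 3
        df = _table([(s, 0, 0) for s in sizes])
        dist = rescaled_distribution(df, "acinar")
        assert dist.tail(3.0) == pytest.approx(0.1)

    def test_tail_matches_counting_oracle(self, rng):
        sizes = rng.lognormal(0, 1, size=200)
        dist = EmpiricalDistribution(sizes)
        for x in rng.uniform(0, 4, size=10):
            brute = np.sum(sizes > x * sizes.mean()) / sizes.size
            assert dist.tail(float(x)) == pytest.approx(brute)

    def test_rescaled_mean_is_one(self, rng):
        dist = EmpiricalDistribution(rng.lognormal(2, 1, size=500))
        assert dist.rescaled.mean() == pytest.approx(1.0, abs=1e-12)

    def test_tail_monotone_nonincreasing(self, rng):
        dist = EmpiricalDistribution(rng.lognormal(0, 1, size=300))
        xs = np.linspace(0, 5, 100)
        tails = dist.tail(xs)
        assert np.all(np.diff(tails) <= 0)
        assert dist.tail(0.0) == 1.0

    def test_zero_sizes_excluded_and_minimum_enforced(self):
        df = _table([(1, 0, 0), (0, 2, 0), (0, 3, 0)])
        with pytest.raises(ValueError):
            rescaled_distribution(df, "acinar")  # only one positive acinar
        dist = rescaled_distribution(df, "ductal")
        assert len(dist) == 2

    def test_total_compartment(self):
        df = _table([(1, 1, 0), (2, 0, 2)])
        dist = rescaled_distribution(df, "total")
        assert sorted(dist.values) == [2.0, 4.0]


class TestQqR2:
    def test_identical_samples_give_one(self, rng):
        a = EmpiricalDistribution(rng.lognormal(0, 1, 50))
        assert qq_r2(a, a) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        vals = rng.lognormal(0, 1, 50)
        a = EmpiricalDistribution(vals)
        b = EmpiricalDistribution(2.0 * vals)
        assert qq_r2(a, b) == pytest.approx(1.0)

    def test_small_sample_hand_computation(self):
        a = EmpiricalDistribution([1.0, 2.0, 3.0])
        b = EmpiricalDistribution([1.0, 2.0, 10.0])
        # independent oracle: same grid p=(i-.5)/3, type-7 interpolation
        qa = np.quantile(a.rescaled, [1 / 6, 3 / 6, 5 / 6], method="linear")
        qb = np.quantile(b.rescaled, [1 / 6, 3 / 6, 5 / 6], method="linear")
        expected = 1 - np.sum((qb - qa) ** 2) / np.sum((qb - qb.mean()) ** 2)
        assert qq_r2(a, b) == pytest.approx(expected)

    def test_near_symmetry_for_similar_samples(self, rng):
        vals = rng.lognormal(0, 1, 300)
        a = EmpiricalDistribution(vals)
        b = EmpiricalDistribution(vals ** 1.03)  # mild distortion, same draws
        assert qq_r2(a, b) > 0.9
        assert abs(qq_r2(a, b) - qq_r2(b, a)) < 0.05

    def test_degenerate_reference_raises(self):
        a = EmpiricalDistribution([1.0, 2.0])
        b = EmpiricalDistribution([3.0, 3.0])
        with pytest.raises(ValueError):
            qq_r2(a, b)


class TestMannWhitney:
    def test_separated_pairs_enumeration(self):
        u, p = mann_whitney([1, 2], [3, 4], mode="exact")
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3], mode="exact")
        assert p == pytest.approx(1.0)

    def test_exact_matches_scipy_exact(self, rng):
        # scipy's exact method is the independent oracle (no ties)
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(size=5)
            u, p = mann_whitney(a, b, mode="exact")
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact")
            assert u == pytest.approx(float(ref.statistic))
            assert p == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_exact_close_to_asymptotic_at_n6(self, rng):
        # calibration: |p_exact - p_asymptotic| <= 0.05 for continuous data
        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            _, p_ex = mann_whitney(a, b, mode="exact")
            _, p_as = mann_whitney(a, b, mode="asymptotic")
            assert abs(p_ex - p_as) <= 0.05

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKs:
    def test_complete_separation(self):
        d, p = ks_two_sample([1, 2], [3, 4], mode="exact")
        assert d == pytest.approx(1.0)
        assert p == pytest.approx(1 / 3)  # 2 of 6 assignments fully separate

    def test_identical_samples_give_zero_d(self):
        d, _ = ks_two_sample([1, 2, 3], [1, 2, 3], mode="exact")
        assert d == pytest.approx(0.0)

    def test_d_matches_scipy(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(1.0, 1, size=30)
        d, _ = ks_two_sample(a, b, mode="asymptotic")
        assert d == pytest.approx(float(sps.ks_2samp(a, b).statistic))


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        chi2, dof, p = chi_square_potency([[10, 20], [10, 20], [5, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_formula_2x2(self):
        obs = np.array([[10, 20], [20, 10]])
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        exp = row * col / obs.sum()
        expected_chi2 = np.sum((obs - exp) ** 2 / exp)
        chi2, dof, _ = chi_square_potency(obs)
        assert chi2 == pytest.approx(expected_chi2)
        assert dof == 1

    def test_column_permutation_invariance(self):
        t1 = [[8, 16], [12, 24], [5, 10]]
        t2 = [[16, 8], [24, 12], [10, 5]]
        assert chi_square_potency(t1)[0] == pytest.approx(
            chi_square_potency(t2)[0])

    def test_zero_expected_raises(self):
        with pytest.raises(ValueError):
            chi_square_potency([[0, 0], [1, 2]])


class TestCenterPeriphery:
    def _positions_table(self, radii):
        rows = []
        for i, r in enumerate(radii):
            rows.append({"clone_id": f"c{i}", "mouse_id": "M1",
                         "color": "RFP", "x_um": r, "y_um": 0.0, "z_um": 0.0,
                         "vol_acinar_um3": 1.0, "vol_ductal_um3": 0.0,
                         "vol_islet_um3": 0.0, "n_branches": 1,
                         "induction": "E12.5", "collection": "P14"})
        return pd.DataFrame(rows)

    def test_inner_two_thirds_is_center(self):
        df = self._positions_table([0.5, 0.8])
        center, periph = center_periphery_split(df, (0, 0, 0), 1.0)
        assert list(center["clone_id"]) == ["c0"]
        assert list(periph["clone_id"]) == ["c1"]

    def test_partition_and_boundary_stability(self, rng):
        radii = rng.uniform(0, 1, size=50)
        df = self._positions_table(radii)
        c, p = center_periphery_split(df, (0, 0, 0), 1.0)
        assert len(c) + len(p) == 50
        eps = 0.01
        c2, p2 = center_periphery_split(df, (0, 0, 0), 1.0,
                                        center_fraction=2 / 3 + eps)
        moved = set(c2["clone_id"]) - set(c["clone_id"])
        for cid in moved:
            r = float(df.loc[df["clone_id"] == cid, "x_um"].iloc[0])
            assert abs(r - 2 / 3) <= eps + 1e-12

    def test_bad_radius_raises(self):
        with pytest.raises(ValueError):
            center_periphery_split(self._positions_table([0.1]), (0, 0, 0), 0)
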