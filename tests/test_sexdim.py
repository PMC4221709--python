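"""Dimorphism statistics: thresholds, z-test, permutation test, scan
comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dimorph as dm
from dimorph.mixedmodel import AssocResult
from dimorph.sexdim import design_matrix


def _assoc(betas, ses, mafs=None, tested=None):
    m = len(betas)
    t = pd.DataFrame({
        "chrom": ["1"] * m,
        "snp": [f"s{j}" for j in range(m)],
        "bp": np.arange(1, m + 1),
        "beta": np.asarray(betas, dtype=float),
        "se": np.asarray(ses, dtype=float),
        "chisq": np.nan,
        "p": np.nan,
        "maf": np.asarray(mafs if mafs is not None else [0.3] * m, dtype=float),
        "n": m,
        "tested": tested if tested is not None else [True] * m,
        "reason": [""] * m,
    })
    return AssocResult(t)


class TestThresholds:
    def test_paper_snp_count(self):
        sugg, gw = dm.significance_thresholds(39454)
        assert f"{sugg:.1e}" == "2.5e-05"
        assert gw == pytest.approx(1.2673e-6, rel=1e-4)

    def test_unit_case(self):
        assert dm.significance_thresholds(1) == (1.0, 0.05)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            dm.significance_thresholds(0)


class TestZDimorphism:
    def test_equal_effects_give_zero(self):
        dim = dm.z_dimorphism(_assoc([0.5], [0.2]), _assoc([0.5], [0.1]))
        row = dim.table.iloc[0]
        assert row["z"] == 0.0 and row["p_z"] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        dim = dm.z_dimorphism(_assoc([1.0], [0.5]), _assoc([0.2], [0.3]))
        assert dim.table["z"].iloc[0] == pytest.approx(0.8 / np.sqrt(0.34))
        assert dim.table["z"].iloc[0] == pytest.approx(1.372, abs=1e-3)

    def test_stratum_swap_negates_z(self):
        m = _assoc([1.0, -0.3], [0.5, 0.2])
        f = _assoc([0.2, 0.4], [0.3, 0.3])
        a, b = dm.z_dimorphism(m, f), dm.z_dimorphism(f, m)
        assert np.allclose(a.table["z"], -b.table["z"])
        assert np.allclose(a.table["p_z"], b.table["p_z"])

    def test_low_maf_flagged(self):
        dim = dm.z_dimorphism(
            _assoc([1.0, 1.0], [0.5, 0.5], mafs=[0.3, 0.01]),
            _assoc([0.0, 0.0], [0.5, 0.5]),
        )
        assert dim.table["tested"].tolist() == [True, False]
        assert dim.table["reason"].iloc[1] == "low_maf"

    def test_untested_stratum_propagates(self):
        dim = dm.z_dimorphism(
            _assoc([1.0], [0.5], tested=[False]), _assoc([0.0], [0.5])
        )
        assert not dim.table["tested"].iloc[0]
        assert dim.table["reason"].iloc[0] == "untested_stratum"

    def test_one_sided_directions(self):
        m, f = _assoc([1.0], [0.5]), _assoc([0.2], [0.3])
        p_m = dm.z_dimorphism(m, f, one_sided="male").table["p_z"].iloc[0]
        p_f = dm.z_dimorphism(m, f, one_sided="female").table["p_z"].iloc[0]
        assert p_m + p_f == pytest.approx(1.0)
        assert p_m < 0.5 < p_f


class TestStratifiedScans:
    def test_small_stratum_skipped(self, f2_cohort):
        gf, tt = f2_cohort
        K = dm.genomic_kinship(gf)
        sex = np.array(["F"] * gf.n_samples)
        sex[:10] = "M"
        scans = dm.stratified_scans(
            gf, tt["bodyweight"].to_numpy(), sex, tt["batch"], K
        )
        assert scans.male is None and "male" in scans.skipped
        assert scans.female is not None and scans.combined is not None

    def test_three_scans_produced(self, f2_cohort):
        gf, tt = f2_cohort
        K = dm.genomic_kinship(gf)
        scans = dm.stratified_scans(
            gf, tt["bodyweight"].to_numpy(), tt["sex"], tt["batch"], K
        )
        for label in ("male", "female", "combined"):
            res = getattr(scans, label)
            assert res is not None and res.table["tested"].any()
        assert set(scans.fits) == {"male", "female", "combined"}

    def test_equal_effect_qtl_detected_by_combined(self):
        from dimorph.validation import _qtl_cohort

        gf, tt, qtl = _qtl_cohort(99, 0.6, 0.6)
        sugg, _ = dm.significance_thresholds(gf.n_snps)
        K = dm.genomic_kinship(gf)
        scans = dm.stratified_scans(
            gf, tt["t"].to_numpy(), tt["sex"], tt["batch"], K
        )
        snp = gf.snps["snp"].iloc[qtl]
        pc = scans.combined.table.set_index("snp").loc[snp, "p"]
        bm = scans.male.table.set_index("snp").loc[snp, "beta"]
        bf = scans.female.table.set_index("snp").loc[snp, "beta"]
        assert pc < sugg
        assert np.sign(bm) == np.sign(bf)
        assert abs(bm - bf) < 0.5 * max(abs(bm), abs(bf))

    def test_opposite_effects_cancel_in_combined(self):
        from dimorph.validation import _qtl_cohort

        gf, tt, qtl = _qtl_cohort(101, 0.5, -0.5)
        sugg, _ = dm.significance_thresholds(gf.n_snps)
        K = dm.genomic_kinship(gf)
        scans = dm.stratified_scans(
            gf, tt["t"].to_numpy(), tt["sex"], tt["batch"], K
        )
        snp = gf.snps["snp"].iloc[qtl]
        pm = scans.male.table.set_index("snp").loc[snp, "p"]
        pf = scans.female.table.set_index("snp").loc[snp, "p"]
        pc = scans.combined.table.set_index("snp").loc[snp, "p"]
        assert pm < sugg and pf < sugg
        assert pc > max(pm, pf)


class TestPermutationTest:
    def test_flat_kinship_observed_zero_p_one(self):
        # identity kinship: flat REML profile, h2 pinned to 0 in every
        # stratum and permutation, so the observed statistic is 0 and p = 1
        rng = np.random.default_rng(21)
        n = 80
        y = rng.standard_normal(n)
        sex = np.array(["M", "F"] * (n // 2))
        batch = rng.integers(0, 2, n)
        K = dm.KinshipMatrix(np.eye(n), [f"i{i}" for i in range(n)])
        res = dm.heritability_permutation_test(y, sex, batch, K, B=50, seed=3)
        assert res.observed == 0.0
        assert res.pvalue == 1.0

    def test_pvalue_lower_bound_and_reproducibility(self, f2_cohort):
        gf, tt = f2_cohort
        K = dm.genomic_kinship(gf)
        args = (tt["bodyweight"].to_numpy(), tt["sex"], tt["batch"], K)
        r1 = dm.heritability_permutation_test(*args, B=30, seed=5)
        r2 = dm.heritability_permutation_test(*args, B=30, seed=5)
        assert r1.pvalue == r2.pvalue
        assert 1 / 31 <= r1.pvalue <= 1.0

    def test_multi_trait_matches_single(self, f2_cohort):
        gf, tt = f2_cohort
        K = dm.genomic_kinship(gf)
        y = tt["bodyweight"].to_numpy()
        single = dm.heritability_permutation_test(
            y, tt["sex"], tt["batch"], K, B=20, seed=7
        )
        multi = dm.heritability_permutation_test(
            np.column_stack([y, y]), tt["sex"], tt["batch"], K, B=20, seed=7
        )
        assert len(multi) == 2
        assert multi[0].pvalue == single.pvalue
        assert multi[0].h2_male == pytest.approx(single.h2_male)


class TestCompareScans:
    def test_identical_sets(self):
        c = dm.ScanComparison.from_sets({"a", "b"}, {"a", "b"}, 0.01)
        assert c.shared_pct_of_union == 100.0
        assert c.n_stratified_only == 0

    def test_disjoint_sets(self):
        c = dm.ScanComparison.from_sets(set(map(str, range(10))),
                                        set(map(str, range(10, 20))), 0.01)
        assert c.shared_pct_of_union == 0.0
        assert c.stratified_only_pct_of_combined == 100.0

    def test_set_arithmetic_oracle(self):
        strat = {str(i) for i in range(51, 164)}
        comb = {str(i) for i in range(1, 101)}
        c = dm.ScanComparison.from_sets(strat, comb)
        assert c.n_intersection == 50
        assert c.n_stratified_only == 63
        assert c.stratified_only_pct_of_combined == pytest.approx(63.0)
        assert c.shared_pct_of_union == pytest.approx(100 * 50 / 163, abs=0.05)

    def test_inclusion_exclusion_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            a = {str(x) for x in rng.integers(0, 50, rng.integers(0, 40))}
            b = {str(x) for x in rng.integers(0, 50, rng.integers(0, 40))}
            c = dm.ScanComparison.from_sets(a, b)
            assert c.n_union == len(a | b)
            assert (c.n_intersection + c.n_stratified_only
                    + c.n_combined_only) == c.n_union

    def test_from_assoc_results(self):
        male = _assoc([1.0, 0.1, 2.0], [0.1, 0.1, 0.1])
        male.table["p"] = [1e-8, 0.5, 1e-9]
        comb = _assoc([1.0, 0.1, 0.1], [0.1, 0.1, 0.1])
        comb.table["p"] = [1e-8, 0.5, 0.9]
        c = dm.compare_scans(male, None, comb, threshold=1e-5)
        assert c.n_stratified == 2 and c.n_combined == 1
        assert c.n_intersection == 1 and c.n_stratified_only == 1


class TestZdistShift:
    def test_identical_samples(self):
        rng = np.random.default_rng(41)
        z = rng.standard_normal(300)
        t, p = dm.zdist_shift_test(z, z)
        assert abs(t) < 1e-9 and p > 0.99

    def test_shifted_subset_detected(self):
        rng = np.random.default_rng(42)
        t, p = dm.zdist_shift_test(
            rng.standard_normal(500), rng.normal(3, 1, 500)
        )
        assert p < 1e-10 and t > 0

    def test_singleton_subset_no_crash(self):
        rng = np.random.default_rng(43)
        t, p = dm.zdist_shift_test(rng.standard_normal(100), [2.5, 2.6])
        assert np.isfinite(t) and 0 <= p <= 1
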