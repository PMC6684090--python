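"""Traditional analysis: normalization, activities, tests, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mprakit.errors import DegenerateSampleError, InsufficientDataError, MPRAError
from mprakit.frequentist import (
    FrequentistMPRA,
    bh_fdr,
    compute_activities,
    depth_normalize,
    filter_low_dna,
    run_frequentist,
)
from mprakit.frequentist import test_variant_t as welch_test
from mprakit.frequentist import test_variant_u as u_test

from conftest import make_design, make_table


def random_table(rng, n_barcodes=12, n_dna=2, n_rna=3, high=200):
    cols = {f"d{i}": rng.integers(1, high, n_barcodes) for i in range(n_dna)}
    cols.update({f"r{i}": rng.integers(0, high, n_barcodes) for i in range(n_rna)})
    mats = {f"d{i}": "DNA" for i in range(n_dna)}
    mats.update({f"r{i}": "RNA" for i in range(n_rna)})
    return make_table(cols, mats)


class TestDepthNormalize:
    def test_equal_sums_unchanged(self):
        table = make_table({"d1": [10, 20], "d2": [20, 10]}, {"d1": "DNA", "d2": "DNA"})
        norm = depth_normalize(table)
        assert (norm.samples["depth_factor"] == 1.0).all()
        np.testing.assert_allclose(norm.counts, table.counts)

    def test_forced_factors(self):
        table = make_table({"d1": [100], "d2": [300]}, {"d1": "DNA", "d2": "DNA"})
        norm = depth_normalize(table)
        assert norm.samples["depth_factor"].tolist() == [0.5, 1.5]
        np.testing.assert_allclose(norm.counts["d1"], [200.0])

    def test_random_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            table = random_table(rng, n_barcodes=50)
            norm = depth_normalize(table)
            for material in ("DNA", "RNA"):
                cols = table.samples_of(material)
                sums = table.counts[cols].sum()
                expected_factors = sums / sums.mean()
                got = norm.samples.loc[cols, "depth_factor"]
                np.testing.assert_allclose(got, expected_factors)
                assert np.isclose(got.mean(), 1.0)
                np.testing.assert_allclose(
                    norm.counts[cols], table.counts[cols] / expected_factors
                )

    def test_zero_sum_column(self):
        table = make_table({"d1": [0, 0], "d2": [1, 2]}, {"d1": "DNA", "d2": "DNA"})
        with pytest.raises(DegenerateSampleError):
            depth_normalize(table)


class TestFilterLowDna:
    def test_zero_dna_removed(self):
        table = depth_normalize(
            make_table({"d1": [0, 10], "d2": [0, 10], "r1": [5, 5]},
                       {"d1": "DNA", "d2": "DNA", "r1": "RNA"})
        )
        kept, removed = filter_low_dna(table, min_norm_dna=0.5)
        assert removed == ["BC0000"] and len(kept.counts) == 1

    def test_zero_threshold_vacuous(self):
        rng = np.random.default_rng(1)
        table = depth_normalize(random_table(rng))
        kept, removed = filter_low_dna(table, min_norm_dna=0.0)
        assert removed == [] and len(kept.counts) == len(table.counts)

    def test_random_matches_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            table = depth_normalize(random_table(rng, high=4))
            kept, removed = filter_low_dna(table, min_norm_dna=1.0)
            dna = table.samples_of("DNA")
            oracle_removed = [
                bc for bc in table.counts.index
                if table.counts.loc[bc, dna].mean() < 1.0
            ]
            assert removed == oracle_removed
            assert set(kept.counts.index) == set(table.counts.index) - set(removed)


class TestComputeActivities:
    def make(self, dna, rna):
        n = len(dna[0])
        cols = {f"d{i}": v for i, v in enumerate(dna)}
        cols.update({f"r{i}": v for i, v in enumerate(rna)})
        mats = {f"d{i}": "DNA" for i in range(len(dna))}
        mats.update({f"r{i}": "RNA" for i in range(len(rna))})
        table = make_table(cols, mats)
        design = make_design(
            list(table.counts.index), ["v1"] * n,
            ["ref"] * (n // 2) + ["alt"] * (n - n // 2),
        )
        return table, design

    def test_unit_ratio_gives_zero(self):
        table, design = self.make([[4, 4]], [[4, 4]])
        acts = compute_activities(depth_normalize(table), design)
        np.testing.assert_allclose(acts.activities["activity"], 0.0, atol=1e-12)

    def test_e_ratio_gives_one(self):
        # normRNA = e * meanNormDNA on an already-normalized table
        from mprakit.io import CountTable
        counts = pd.DataFrame({"d1": [10.0], "r1": [10.0 * np.e]}, index=["BC0000"])
        samples = pd.DataFrame({"material": ["DNA", "RNA"]}, index=["d1", "r1"])
        table = CountTable(counts, samples, normalized=True)
        design = make_design(list(table.counts.index), ["v1"], ["ref"])
        acts = compute_activities(table, design)
        np.testing.assert_allclose(acts.activities["activity"], 1.0)

    def test_random_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            table, design = self.make(
                [rng.integers(0, 30, 10) for _ in range(2)],
                [rng.integers(0, 30, 10) for _ in range(3)],
            )
            norm = depth_normalize(table)
            acts = compute_activities(norm, design)
            # independent recomputation, plain loops
            expected = {}
            dropped = 0
            dna_cols = ["d0", "d1"]
            for bc in norm.counts.index:
                mean_dna = norm.counts.loc[bc, dna_cols].mean()
                for r in ["r0", "r1", "r2"]:
                    v = norm.counts.loc[bc, r]
                    if v > 0 and mean_dna > 0:
                        expected[(bc, r)] = np.log(v / mean_dna)
                    else:
                        dropped += 1
            got = acts.activities.set_index(["barcode", "sample"])["activity"]
            assert set(got.index) == set(expected)
            for key, val in expected.items():
                assert np.isclose(got[key], val)
            assert acts.n_dropped == dropped

    def test_column_scaling_invariance(self):
        # depth normalization absorbs per-sample scale factors: activities
        # change by at most a material-wide additive constant (the factors
        # renormalize by the material mean), so every transcription shift
        # and both test p-values are exactly invariant
        rng = np.random.default_rng(4)
        table, design = self.make(
            [rng.integers(1, 30, 8) for _ in range(2)],
            [rng.integers(1, 30, 8) for _ in range(3)],
        )
        scaled = table.counts.copy()
        scaled["r1"] *= 7
        scaled["d0"] *= 3
        table2 = make_table(
            {c: scaled[c].to_numpy() for c in scaled.columns},
            {c: table.samples.loc[c, "material"] for c in scaled.columns},
        )
        acts1 = compute_activities(depth_normalize(table), design)
        acts2 = compute_activities(depth_normalize(table2), design)
        merged = acts1.activities.merge(
            acts2.activities, on=["barcode", "sample"], suffixes=("_1", "_2")
        )
        diffs = merged["activity_2"] - merged["activity_1"]
        np.testing.assert_allclose(diffs, diffs.iloc[0], atol=1e-12)
        res1 = run_frequentist(table, design)
        res2 = run_frequentist(table2, design)
        np.testing.assert_allclose(
            res1.transcription_shift, res2.transcription_shift, atol=1e-12
        )
        np.testing.assert_allclose(res1.t_p, res2.t_p, atol=1e-12)
        np.testing.assert_allclose(res1.u_p, res2.u_p, atol=1e-12)


class TestWelchT:
    def test_identical_groups(self):
        shift, p = welch_test([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert shift == 0.0 and p == 1.0

    def test_constant_identical_groups(self):
        shift, p = welch_test([0.0] * 4, [0.0] * 4)
        assert shift == 0.0 and p == 1.0

    def test_textbook_welch_oracle(self):
        rng = np.random.default_rng(5)
        ref = np.zeros(4) + rng.normal(0, 1e-3, 4)
        alt = np.ones(4) + rng.normal(0, 1e-3, 4)
        shift, p = welch_test(ref, alt)
        assert abs(shift - 1.0) < 0.01 and p < 0.01
        # textbook Welch formula
        v1, v2 = alt.var(ddof=1) / 4, ref.var(ddof=1) / 4
        t = (alt.mean() - ref.mean()) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / 3 + v2**2 / 3)
        p_oracle = 2 * stats.t.sf(abs(t), df)
        assert np.isclose(p, p_oracle)

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        ref, alt = rng.normal(0, 1, 10), rng.normal(0.4, 1, 12)
        s1, p1 = welch_test(ref, alt)
        s2, p2 = welch_test(alt, ref)
        assert np.isclose(s1, -s2) and np.isclose(p1, p2)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            welch_test([1.0], [1.0, 2.0])


class TestMannWhitneyU:
    def test_identical_groups_exact(self):
        assert u_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_complete_separation_exact(self):
        # U = 0; 1 of C(6,3)=20 assignments is as extreme, two-sided p = 0.1
        assert np.isclose(u_test([1, 2, 3], [4, 5, 6]), 0.1)

    def test_exact_close_to_asymptotic_n6(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            ref, alt = rng.normal(0, 1, 6), rng.normal(0, 1, 6)
            p_exact = u_test(ref, alt)
            p_approx = stats.mannwhitneyu(
                alt, ref, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_exact - p_approx) < 0.02

    def test_exact_matches_scipy_exact(self):
        # independent oracle on tie-free inputs where scipy's exact method applies
        rng = np.random.default_rng(8)
        for _ in range(25):
            n1, n2 = rng.integers(2, 8, 2)
            pooled = rng.permutation(100)[: n1 + n2].astype(float)
            ref, alt = pooled[:n1], pooled[n1:]
            p_mine = u_test(ref, alt)
            p_scipy = stats.mannwhitneyu(
                alt, ref, alternative="two-sided", method="exact"
            ).pvalue
            assert np.isclose(p_mine, p_scipy, atol=1e-12)

    def test_large_n_uses_tie_corrected_normal(self):
        rng = np.random.default_rng(9)
        ref = np.repeat([1.0, 2.0, 3.0], 5)
        alt = np.repeat([2.0, 3.0, 4.0], 5)
        p = u_test(ref, alt)
        p_scipy = stats.mannwhitneyu(
            alt, ref, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert np.isclose(p, p_scipy)


class TestBHFdr:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p(self):
        assert bh_fdr([1.0]).tolist() == [1.0]

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            q = bh_fdr(p)
            _, q_oracle, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_oracle)
            assert (q >= p - 1e-12).all()

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_property_matches_brute_force(self, p):
        p = np.asarray(p)
        q = bh_fdr(p)
        # brute-force step-up definition
        m = len(p)
        for i, pi in enumerate(p):
            candidates = [
                p_j * m / (np.sum(p <= p_j + 1e-300))
                for p_j in p if p_j >= pi
            ]
            # direct definition on sorted scale
            order = np.argsort(p, kind="stable")
            sorted_p = p[order]
            ranks = np.arange(1, m + 1)
            vals = sorted_p * m / ranks
            mins = np.minimum.accumulate(vals[::-1])[::-1]
            expected = min(1.0, mins[np.where(order == i)[0][0]])
            assert np.isclose(q[i], expected)

    def test_domain_error(self):
        with pytest.raises(MPRAError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(MPRAError):
            bh_fdr([0.5, np.nan])


class TestRunFrequentist:
    def test_single_variant_q_equals_p(self):
        rng = np.random.default_rng(11)
        table = make_table(
            {"d1": rng.integers(20, 60, 8), "d2": rng.integers(20, 60, 8),
             "r1": rng.integers(20, 60, 8), "r2": rng.integers(20, 60, 8)},
            {"d1": "DNA", "d2": "DNA", "r1": "RNA", "r2": "RNA"},
        )
        design = make_design(list(table.counts.index), ["v1"] * 8,
                             ["ref"] * 4 + ["alt"] * 4)
        res = run_frequentist(table, design)
        assert len(res) == 1
        assert np.isclose(res.t_q[0], res.t_p[0])
        assert np.isclose(res.u_q[0], res.u_p[0])

    def test_allele_swap_negates_shifts(self, medium_experiment):
        table, design, _ = medium_experiment
        res = run_frequentist(table, design)
        res_sw = run_frequentist(table, design.swap_alleles())
        np.testing.assert_allclose(
            res_sw.transcription_shift, -res.transcription_shift, atol=1e-12
        )
        np.testing.assert_allclose(res_sw.t_p, res.t_p, atol=1e-12)
        np.testing.assert_allclose(res_sw.u_p, res.u_p, atol=1e-12)
        np.testing.assert_allclose(res_sw.t_q, res.t_q, atol=1e-12)

    def test_shift_definition(self, medium_experiment):
        # shift = mean(alt activities) - mean(ref activities), recomputed
        table, design, _ = medium_experiment
        est = FrequentistMPRA().fit(table, design)
        acts = est.activities_.activities
        for vid, group in acts.groupby("variant_id"):
            expected = (
                group.loc[group.allele == "alt", "activity"].mean()
                - group.loc[group.allele == "ref", "activity"].mean()
            )
            got = est.results_.set_index("variant_id").loc[vid, "transcription_shift"]
            assert np.isclose(got, expected)

    def test_insufficient_data_reported_na(self):
        # one allele entirely zero in RNA -> no observations -> NA row
        table = make_table(
            {"d1": [30, 30, 30, 30], "r1": [0, 0, 25, 31], "r2": [0, 0, 40, 22]},
            {"d1": "DNA", "r1": "RNA", "r2": "RNA"},
        )
        design = make_design(list(table.counts.index), ["v1"] * 4,
                             ["ref", "ref", "alt", "alt"])
        res = run_frequentist(table, design)
        assert res.n_obs_ref[0] == 0 and res.n_obs_alt[0] == 4
        assert np.isnan(res.t_p[0]) and np.isnan(res.t_q[0])

    def test_estimator_params_clone(self):
        from sklearn.base import clone
        est = FrequentistMPRA(min_norm_dna=2.5)
        est2 = clone(est)
        assert est2.get_params()["min_norm_dna"] == 2.5
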