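"""Degree groups, descriptive stats, correlation and rank tests."""

import logging

import numpy as np
import pytest
from scipy import stats

from relkit import (
    Pedigree,
    RelationshipMatrix,
    a_matrix,
    compare_correlations,
    depth_correlation_table,
    describe,
    group_pairs,
    pearson_test,
    scenario_report,
    wilcoxon_signed_rank,
)
import pandas as pd

from conftest import oracle_wilcoxon_pvalue


def rel_matrix(values, method="A_ped"):
    values = np.asarray(values, dtype=float)
    ids = [f"s{i}" for i in range(values.shape[0])]
    return RelationshipMatrix(ids=ids, values=values, method=method)


class TestGroupPairs:
    def test_degree_bins(self):
        """0.503 / 0.30 / 0.01 land in first / second / less."""
        V = np.eye(4)
        V[0, 1] = V[1, 0] = 0.503
        V[0, 2] = V[2, 0] = 0.30
        V[0, 3] = V[3, 0] = 0.01
        g = group_pairs(rel_matrix(V))
        assert [tuple(x) for x in g.first] == [(0, 1)]
        assert [tuple(x) for x in g.second] == [(0, 2)]
        assert (0, 3) in {tuple(x) for x in g.less}

    def test_quarter_boundary_is_second_degree(self):
        V = np.eye(2)
        V[0, 1] = V[1, 0] = 0.25
        g = group_pairs(rel_matrix(V))
        assert len(g.second) == 1 and len(g.less) == 0

    def test_parent_offspring_among_four(self):
        p = Pedigree.from_records(
            [("A", "0", "0"), ("B", "0", "0"), ("C", "A", "0"), ("D", "0", "0")]
        )
        g = group_pairs(a_matrix(p))
        assert len(g.first) == 1
        assert len(g.second) == 0
        assert len(g.less) == 5

    def test_partition_covers_all_pairs(self):
        rng = np.random.default_rng(8)
        V = rng.uniform(0, 0.9, size=(20, 20))
        V = (V + V.T) / 2
        np.fill_diagonal(V, 1.0)
        g = group_pairs(rel_matrix(V))
        assert len(g.first) + len(g.second) + len(g.less) == 20 * 19 // 2

    def test_super_unity_routed_to_first_with_warning(self, caplog):
        V = np.array([[1.3, 1.1], [1.1, 1.3]])
        with caplog.at_level(logging.WARNING):
            g = group_pairs(rel_matrix(V))
        assert len(g.first) == 1
        assert any(">= 1" in r.message for r in caplog.records)


class TestDescribe:
    def test_constant_pair(self):
        d = describe([0.5, 0.5])
        assert d["min"] == d["mean"] == d["max"] == 0.5 and d["var"] == 0.0

    def test_zero_one(self):
        d = describe([0.0, 1.0])
        assert d["mean"] == 0.5 and d["var"] == pytest.approx(0.5)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            describe([1.0])


class TestPearson:
    def test_identity_not_different_from_one(self):
        x = np.arange(10.0)
        res = pearson_test(x, x)
        assert res.r == pytest.approx(1.0)
        assert not res.different_from_one
        assert res.different_from_zero

    def test_orthogonal_not_different_from_zero(self):
        x = np.array([1.0, -1.0] * 4)
        y = np.array([1.0, 1.0, -1.0, -1.0] * 2)
        assert abs(np.dot(x - x.mean(), y - y.mean())) < 1e-12
        res = pearson_test(x, y)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert not res.different_from_zero

    def test_high_r_large_n_flagged_vs_zero_not_vs_one(self):
        """r ~ 0.999 at n = 4000 is overwhelmingly different from 0 but not
        from 1 at the default epsilon (the 0.999 chip-scenario pattern)."""
        rng = np.random.default_rng(10)
        x = rng.normal(size=4000)
        y = x + 0.045 * rng.normal(size=4000)
        res = pearson_test(x, y)
        assert res.r > 0.998
        assert res.different_from_zero
        assert not res.different_from_one

    def test_p_vs_zero_matches_closed_form_t(self):
        rng = np.random.default_rng(101)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        res = pearson_test(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        assert 2 * stats.t.sf(abs(t), res.n - 2) == pytest.approx(
            res.p_vs_zero, rel=1e-6
        )

    def test_moderate_r_flagged_different_from_one(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=200)
        y = x + rng.normal(size=200)
        res = pearson_test(x, y)
        assert res.different_from_one

    def test_matches_brute_force_covariance(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=(2, 57))
        res = pearson_test(x, y)
        r_manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res.r == pytest.approx(r_manual, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_test(np.ones(5), np.arange(5.0))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_test(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestWilcoxon:
    def test_three_identical_shifts(self):
        """All differences -1 over 3 pairs: exact two-sided p = 2/8."""
        res = wilcoxon_signed_rank(np.array([1.0, 2, 3]), np.array([2.0, 3, 4]))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.25)

    def test_degenerate_equal_samples(self, caplog):
        x = np.arange(5.0)
        with caplog.at_level(logging.WARNING):
            res = wilcoxon_signed_rank(x, x)
        assert res.p_value == 1.0 and res.method == "degenerate"

    def test_strong_shift_is_overwhelming(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=500)
        y = x + 1.0 + rng.normal(size=500)
        res = wilcoxon_signed_rank(y, x)
        assert res.method == "approx"
        assert res.p_value < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        d = rng.normal(size=n)  # continuous draws: no ties in |d|
        res = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert res.p_value == pytest.approx(oracle_wilcoxon_pvalue(d), abs=1e-10)


class TestCompareCorrelations:
    def test_equal_correlations_give_p_one(self):
        assert compare_correlations(0.5, 50, 0.5, 80).p_value == pytest.approx(1.0)

    def test_depth_contrast_order_of_magnitude(self):
        """r = 0.395 (n=118) vs r = 0.721 (n=44): the Fisher-z p-value sits
        in the ~0.01 band."""
        res = compare_correlations(0.395, 118, 0.721, 44)
        assert 0.002 < res.p_value < 0.05

    def test_enormous_contrast(self):
        assert compare_correlations(0.9, 1000, 0.1, 1000).p_value < 1e-10

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 100, 0.5, 100)


class TestDepthCorrelationTable:
    def make_tables(self, rng):
        ids = [f"s{i}" for i in range(30)]
        F_ped = pd.Series(rng.uniform(0, 0.3, 30), index=ids)
        groups = {1: ids, 2: ids[:20], 4: ids[:10]}
        return ids, F_ped, groups

    def test_identical_tables_give_unit_correlation(self):
        rng = np.random.default_rng(14)
        ids, F_ped, groups = self.make_tables(rng)
        table = depth_correlation_table(F_ped, {"G": F_ped.copy()}, groups)
        assert np.allclose(table["r"], 1.0)

    def test_shuffled_genomic_f_destroys_signal(self):
        rng = np.random.default_rng(15)
        ids, F_ped, groups = self.make_tables(rng)
        shuffled = pd.Series(
            rng.permutation(F_ped.to_numpy()), index=ids
        )
        table = depth_correlation_table(F_ped, {"G": shuffled}, {1: ids})
        assert abs(table["r"].iloc[0]) < 0.5

    def test_small_groups_skipped(self, caplog):
        rng = np.random.default_rng(16)
        ids, F_ped, groups = self.make_tables(rng)
        groups[8] = ids[:2]
        with caplog.at_level(logging.WARNING):
            table = depth_correlation_table(F_ped, {"G": F_ped}, groups)
        assert 8 not in set(table["depth"])


class TestScenarioReport:
    def build_inputs(self, rng, n=12):
        records = [("A", "0", "0"), ("B", "0", "0"), ("C", "0", "0")]
        for i in range(n - 3):
            records.append((f"k{i}", "A", "B" if i % 2 else "C"))
        ped = Pedigree.from_records(records)
        ids = [r[0] for r in records]
        A = a_matrix(ped, ids=ids)
        genomic = {}
        for label in ("G_SNP_5+", "G_WGS_5+"):
            noise = rng.normal(scale=0.05, size=A.values.shape)
            V = A.values + (noise + noise.T) / 2
            genomic[label] = RelationshipMatrix(
                ids=ids, values=V, method="G_yang", scenario="5+", n_variants=100
            )
        return A, genomic, ped

    def test_report_shape_and_determinism(self):
        rng = np.random.default_rng(17)
        A, genomic, ped = self.build_inputs(rng)
        rep1 = scenario_report(A, genomic, ped, depth_thresholds=(1,))
        rep2 = scenario_report(A, genomic, ped, depth_thresholds=(1,))
        assert len(rep1.variant_counts) == 3  # A_ped + 2 genomic
        pd.testing.assert_frame_equal(rep1.correlations, rep2.correlations)
        pd.testing.assert_frame_equal(rep1.descriptive, rep2.descriptive)

    def test_id_mismatch_rejected(self):
        rng = np.random.default_rng(18)
        A, genomic, ped = self.build_inputs(rng)
        bad = genomic["G_SNP_5+"]
        renamed = RelationshipMatrix(
            ids=[f"x{i}" for i in range(bad.n)],
            values=bad.values,
            method=bad.method,
        )
        with pytest.raises(ValueError, match="id mismatch"):
            scenario_report(A, {"G": renamed}, ped)
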