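"""Genotype loading, summaries, MAF scenarios and chip subsetting."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relkit import (
    GenotypeMatrix,
    ScenarioSpec,
    apply_maf_scenario,
    maf_mask,
    read_genotypes,
    subset_chip,
    variant_stats,
    write_matrix,
)

from conftest import random_genotypes

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1,length=1000000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
)


def write_vcf(path, body: str) -> str:
    path.write_text(VCF_HEADER + body)
    return str(path)


class TestReadGenotypes:
    def test_vcf_gt_coding(self, tmp_path):
        """Hom-ref / het / hom-alt map to ALT counts 0 / 1 / 2."""
        vcf = write_vcf(
            tmp_path / "a.vcf",
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n",
        )
        g = read_genotypes(vcf)
        assert g.sample_ids == ["s1", "s2", "s3"]
        assert g.variant_ids == ["rs1", "rs2"]
        np.testing.assert_array_equal(g.calls, [[0, 0], [1, 1], [2, 2]])
        assert list(g.variant_class) == ["SNP", "SNP"]

    def test_multiallelic_records_are_skipped(self, tmp_path, caplog):
        body = "".join(
            f"1\t{100 * (i + 1)}\trs{i}\tA\t{'G,T' if i == 2 else 'G'}\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            for i in range(5)
        )
        vcf = write_vcf(tmp_path / "multi.vcf", body)
        with caplog.at_level(logging.WARNING):
            g = read_genotypes(vcf)
        assert g.n_variants == 4
        assert "rs2" not in g.variant_ids
        assert any("biallelic" in r.message for r in caplog.records)

    def test_indel_classification(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "indel.vcf",
            "1\t100\trs1\tAT\tA\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n",
        )
        assert list(read_genotypes(vcf).variant_class) == ["INDEL"]

    def test_matrix_roundtrip_identity(self, tmp_path, small_genotypes):
        path = tmp_path / "m.tsv"
        write_matrix(small_genotypes, path)
        g2 = read_genotypes(path, format="matrix")
        assert g2.sample_ids == small_genotypes.sample_ids
        assert g2.variant_ids == small_genotypes.variant_ids
        np.testing.assert_array_equal(g2.calls, small_genotypes.calls)

    def test_matrix_invalid_call_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("variant_id\ts1\ts2\nv1\t0\t3\n")
        with pytest.raises(ValueError, match="invalid call 3"):
            read_genotypes(path)

    def test_missing_policies(self, tmp_path):
        path = tmp_path / "miss.tsv"
        path.write_text("variant_id\ts1\ts2\ts3\nv1\t0\t.\t2\nv2\t1\t1\t1\n")
        with pytest.raises(ValueError, match="v1"):
            read_genotypes(path, missing_policy="fail")
        g_drop = read_genotypes(path, missing_policy="drop_variant")
        assert g_drop.variant_ids == ["v2"]
        g_imp = read_genotypes(path, missing_policy="mean_impute")
        assert g_imp.calls[1, 0] == 1  # mean of (0, 2) rounds to 1

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_genotypes("does_not_exist.tsv")


class TestVariantStats:
    def test_symmetric_column(self):
        g = GenotypeMatrix(["a", "b", "c"], ["v"], np.array([[0], [1], [2]]))
        s = variant_stats(g)
        assert s.p[0] == 0.5 and s.maf[0] == 0.5 and s.mac[0] == 3

    def test_monomorphic_column(self):
        g = GenotypeMatrix(["a", "b"], ["v"], np.zeros((2, 1), dtype=int))
        s = variant_stats(g)
        assert s.p[0] == 0.0 and s.maf[0] == 0.0 and s.mac[0] == 0

    def test_two_copies_in_118_fails_one_percent_rule(self):
        """With 118 diploids, 2 minor copies give MAF 2/236 < 1%."""
        calls = np.zeros((118, 1), dtype=np.int8)
        calls[0, 0] = 1
        calls[1, 0] = 1
        g = GenotypeMatrix([f"s{i}" for i in range(118)], ["v"], calls)
        s = variant_stats(g)
        assert s.mac[0] == 2
        assert s.maf[0] == pytest.approx(2 / 236)
        assert not maf_mask(g, ScenarioSpec.from_name("1+"))[0]

    def test_invariant_to_sample_order_and_orientation(self, small_genotypes):
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_genotypes.n_samples)
        shuffled = GenotypeMatrix(
            [small_genotypes.sample_ids[i] for i in perm],
            small_genotypes.variant_ids,
            small_genotypes.calls[perm],
        )
        np.testing.assert_allclose(
            variant_stats(shuffled).p, variant_stats(small_genotypes).p
        )
        flipped = GenotypeMatrix(
            small_genotypes.sample_ids,
            small_genotypes.variant_ids,
            2 - small_genotypes.calls,
        )
        s, sf = variant_stats(small_genotypes), variant_stats(flipped)
        np.testing.assert_allclose(sf.p, 1 - s.p)
        np.testing.assert_allclose(sf.maf, s.maf)
        np.testing.assert_array_equal(sf.mac, s.mac)


class TestMafScenarios:
    def test_interval_membership(self):
        """MAFs 0.004 / 0.03 / 0.20: only 0.03 sits inside 1_5."""
        n = 500
        calls = np.zeros((n, 3), dtype=np.int8)
        for v, maf in enumerate((0.004, 0.03, 0.20)):
            k = int(round(2 * n * maf))  # minor copies as heterozygotes
            calls[:k, v] = 1
        g = GenotypeMatrix([f"s{i}" for i in range(n)], ["a", "b", "c"], calls)
        kept = apply_maf_scenario(g, ScenarioSpec.from_name("1_5"))
        assert kept.variant_ids == ["b"]

    def test_boundary_maf_exactly_5_percent(self):
        """MAF = 0.05 belongs to 5+ and not to 1_5 (half-open intervals)."""
        n = 100
        calls = np.zeros((n, 1), dtype=np.int8)
        calls[:10, 0] = 1  # 10 copies / 200 alleles = 0.05
        g = GenotypeMatrix([f"s{i}" for i in range(n)], ["v"], calls)
        assert maf_mask(g, ScenarioSpec.from_name("5+"))[0]
        assert not maf_mask(g, ScenarioSpec.from_name("1_5"))[0]

    def test_maf_half_kept_at_top(self):
        g = GenotypeMatrix(["a", "b"], ["v"], np.array([[0], [2]]))
        assert maf_mask(g, ScenarioSpec.from_name("5+"))[0]

    def test_monomorphic_never_passes(self):
        g = GenotypeMatrix(["a", "b"], ["v"], np.full((2, 1), 2, dtype=int))
        assert not maf_mask(g, ScenarioSpec("custom", 0.0, 0.5))[0]

    def test_empty_result_warns_not_raises(self, caplog):
        g = GenotypeMatrix(["a", "b"], ["v"], np.array([[0], [0]]))
        with caplog.at_level(logging.WARNING):
            kept = apply_maf_scenario(g, ScenarioSpec.from_name("5+"))
        assert kept.n_variants == 0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 40), m=st.integers(1, 60))
    def test_scenario_partition_property(self, seed, n, m):
        """Variants kept by 1+ are the disjoint union of 5+ and 1_5 keeps."""
        g = random_genotypes(np.random.default_rng(seed), n, m)
        kept = {
            s: set(apply_maf_scenario(g, ScenarioSpec.from_name(s)).variant_ids)
            for s in ("5+", "1+", "1_5")
        }
        assert kept["5+"] & kept["1_5"] == set()
        assert kept["5+"] | kept["1_5"] == kept["1+"]

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("bad", 0.3, 0.2)


class TestSubsetChip:
    def test_overlap(self, small_genotypes):
        sub = subset_chip(small_genotypes, ["v1", "v4", "nope"])
        assert sub.variant_ids == ["v1", "v4"]

    def test_empty_list(self, small_genotypes, caplog):
        with caplog.at_level(logging.WARNING):
            sub = subset_chip(small_genotypes, [])
        assert sub.n_variants == 0

    def test_duplicates_collapse(self, small_genotypes):
        sub = subset_chip(small_genotypes, ["v2", "v2", "v2"])
        assert sub.variant_ids == ["v2"]
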