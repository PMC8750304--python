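import pytest

from recessix.variant_model import (
    CohortVariantTable,
    GenotypeCall,
    GvcfParseError,
    MergeError,
    NonVariantBlock,
    SampleGVCF,
    VariantRecord,
    merge_gvcfs,
    missing_call,
    read_cohort_tsv,
    read_gvcf,
    to_sample_gvcfs,
    write_cohort_tsv,
)

from conftest import random_sample_gvcf, write_gvcf_text
from oracles import brute_force_merge_cell, union_site_keys


class TestVariantRecord:
    def test_rejects_degenerate_alleles(self):
        with pytest.raises(ValueError):
            VariantRecord("chr1", 0, "A", "G")
        with pytest.raises(ValueError):
            VariantRecord("chr1", 5, "A", "A")
        with pytest.raises(ValueError):
            VariantRecord("chr1", 5, "AN", "A")
        with pytest.raises(ValueError):
            VariantRecord("chr1", 5, "", "A")

    def test_rejects_unnormalized_indel(self):
        # shared leading base beyond the single anchor base
        with pytest.raises(ValueError):
            VariantRecord("chr1", 5, "ATG", "ATC")
        # proper left-anchored deletion and insertion are fine
        assert VariantRecord("chr1", 5, "ATG", "A").end == 7
        assert VariantRecord("chr1", 5, "A", "ACG").end == 5

    def test_genotype_ad_cannot_exceed_depth(self):
        with pytest.raises(ValueError):
            GenotypeCall("S", "het", dp=10, gqx=30, ad_ref=6, ad_alt=5)


class TestReadGvcf:
    def test_parses_variant_and_block(self, tmp_path):
        path = write_gvcf_text(
            tmp_path,
            "S1",
            [
                "chr1\t50\t.\tN\t<NON_REF>\t.\t.\tEND=99\tGT:DP:GQX\t0/0:30:50",
                "chr1\t100\t.\tA\tG\t500\t.\t.\tGT:DP:GQX:AD\t0/1:40:60:20,20",
            ],
        )
        sample = read_gvcf(path)
        assert len(sample.variants) == 1 and len(sample.blocks) == 1
        variant, call = sample.variants[0]
        assert variant.key == ("chr1", 100, "A", "G")
        assert (call.zygosity, call.dp, call.gqx, call.ad_alt) == ("het", 40, 60, 20)
        block = sample.blocks[0]
        assert (block.start, block.end, block.min_dp, block.min_gqx) == (50, 99, 30, 50)

    def test_empty_body(self, tmp_path):
        sample = read_gvcf(write_gvcf_text(tmp_path, "S1", []))
        assert sample.variants == [] and sample.blocks == []

    def test_block_overlapping_own_variant_rejected(self, tmp_path):
        path = write_gvcf_text(
            tmp_path,
            "S1",
            [
                "chr1\t50\t.\tN\t<NON_REF>\t.\t.\tEND=200\tGT:DP:GQX\t0/0:30:50",
                "chr1\t100\t.\tA\tG\t500\t.\t.\tGT:DP:GQX:AD\t0/1:40:60:20,20",
            ],
        )
        with pytest.raises(GvcfParseError, match="inside"):
            read_gvcf(path)

    def test_unsorted_records_name_offender(self, tmp_path):
        path = write_gvcf_text(
            tmp_path,
            "S1",
            [
                "chr1\t200\t.\tA\tG\t500\t.\t.\tGT:DP:GQX:AD\t0/1:40:60:20,20",
                "chr1\t100\t.\tC\tT\t500\t.\t.\tGT:DP:GQX:AD\t0/1:40:60:20,20",
            ],
        )
        with pytest.raises(GvcfParseError, match="100"):
            read_gvcf(path)

    def test_multiallelic_row_is_decomposed(self, tmp_path):
        path = write_gvcf_text(
            tmp_path,
            "S1",
            ["chr1\t100\t.\tA\tG,T\t500\t.\t.\tGT:DP:GQX:AD\t1/2:60:70:5,30,25"],
        )
        sample = read_gvcf(path)
        assert [v.alt for v, _ in sample.variants] == ["G", "T"]
        calls = [c for _, c in sample.variants]
        assert [c.ad_alt for c in calls] == [30, 25]
        assert all(c.zygosity == "het" for c in calls)

    def test_gqx_falls_back_to_min_gq_qual(self, tmp_path):
        header_line = "chr1\t100\t.\tA\tG\t35\t.\t.\tGT:DP:GQ:AD\t0/1:40:50:20,20"
        path = tmp_path / "s.g.vcf"
        text = write_gvcf_text(tmp_path, "S1", [header_line]).read_text()
        path.write_text(text.replace("GQX,Number=1", "GQ,Number=1"))
        sample = read_gvcf(path)
        assert sample.gqx_imputed
        assert sample.variants[0][1].gqx == 35  # min(GQ=50, QUAL=35)


class TestMerge:
    def _sample(self, sid, variants=(), blocks=()):
        return SampleGVCF(sample_id=sid, variants=list(variants), blocks=list(blocks))

    def test_block_backfills_hom_ref(self):
        v = VariantRecord("chr1", 100, "A", "G", 500.0)
        a = self._sample("A", [(v, GenotypeCall("A", "het", 40, 60, 20, 20))])
        b = self._sample("B", blocks=[NonVariantBlock("chr1", 50, 200, 30, 45)])
        table = merge_gvcfs([a, b])
        assert table.call(0, "A").zygosity == "het"
        bcall = table.call(0, "B")
        assert (bcall.zygosity, bcall.dp, bcall.gqx, bcall.ad_ref) == (
            "hom_ref", 30, 45, 30,
        )

    def test_uncovered_position_is_missing(self):
        v = VariantRecord("chr1", 100, "A", "G", 500.0)
        a = self._sample("A", [(v, GenotypeCall("A", "het", 40, 60, 20, 20))])
        b = self._sample("B")
        table = merge_gvcfs([a, b])
        assert table.call(0, "B").is_missing

    def test_duplicate_sample_id_rejected(self):
        with pytest.raises(MergeError, match="duplicate"):
            merge_gvcfs([self._sample("A"), self._sample("A")])

    def test_conflicting_records_within_sample_rejected(self):
        v = VariantRecord("chr1", 100, "A", "G", 500.0)
        s = self._sample(
            "A",
            [
                (v, GenotypeCall("A", "het", 40, 60, 20, 20)),
                (v, GenotypeCall("A", "hom_alt", 40, 60, 0, 40)),
            ],
        )
        with pytest.raises(GvcfParseError, match="duplicate"):
            merge_gvcfs([s])

    def test_matches_brute_force_oracle_on_random_cohorts(self, rng):
        """Merge output equals per-(site, sample) linear-scan classification."""
        positions = list(range(10, 500, 10))
        for _ in range(25):
            n = int(rng.integers(1, 6))
            samples = [
                random_sample_gvcf(rng, f"S{i}", positions) for i in range(n)
            ]
            table = merge_gvcfs(samples)
            by_id = {s.sample_id: s for s in samples}
            expected_keys = union_site_keys(samples)
            assert [s.key for s in table.sites] == expected_keys
            for i, site in enumerate(table.sites):
                for sid in table.sample_ids:
                    got = table.call(i, sid)
                    want = brute_force_merge_cell(by_id[sid], site)
                    assert (
                        got.zygosity, got.dp, got.gqx, got.ad_ref, got.ad_alt
                    ) == (
                        want.zygosity, want.dp, want.gqx, want.ad_ref, want.ad_alt
                    )

    def test_merge_is_idempotent_and_order_invariant(self, rng):
        positions = list(range(10, 300, 7))
        samples = [random_sample_gvcf(rng, f"S{i}", positions) for i in range(4)]
        table = merge_gvcfs(samples)
        again = merge_gvcfs(to_sample_gvcfs(table))
        assert again.sites == table.sites
        assert again.genotypes == table.genotypes
        reordered = merge_gvcfs(list(reversed(samples)))
        assert reordered.sites == table.sites
        assert reordered.sample_ids == table.sample_ids
        assert reordered.genotypes == table.genotypes


class TestCohortTsv:
    def test_round_trip_with_missing_cell(self, tmp_path):
        v = VariantRecord("chr1", 100, "A", "G", 512.25)
        table = CohortVariantTable(
            sites=[v],
            sample_ids=["A", "B"],
            genotypes=[[GenotypeCall("A", "het", 40, 60, 20, 20), missing_call("B")]],
        )
        path = tmp_path / "cohort.tsv"
        write_cohort_tsv(table, path)
        lines = path.read_text().splitlines()
        assert lines[1].startswith("chrom\tpos")
        assert lines[2].split("\t")[-1] == "./."
        back = read_cohort_tsv(path)
        assert back.sites == table.sites
        assert back.genotypes == table.genotypes
        assert back.sample_ids == table.sample_ids

    def test_table_invariants_enforced(self):
        v1 = VariantRecord("chr1", 200, "A", "G")
        v2 = VariantRecord("chr1", 100, "A", "G")
        with pytest.raises(ValueError, match="sorted"):
            CohortVariantTable(
                sites=[v1, v2],
                sample_ids=["A"],
                genotypes=[[missing_call("A")], [missing_call("A")]],
            )
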