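import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recessix.case_studies import (
    nonsense_case_transcript,
    nonsense_variant,
    splice_case_transcript,
    splice_variant,
)
from recessix.consequence_annotator import (
    CDSCoordinate,
    OutsideTranscriptError,
    PrematureStopError,
    ReferenceMismatchError,
    annotate_consequence,
    classify_impact,
    format_c_position,
    map_genomic_to_cds,
    parse_c_position,
    translate_cds,
)
from recessix.toygenome import build_transcript, make_cds
from recessix.variant_model import VariantRecord

from conftest import random_toy_transcript
from oracles import (
    brute_force_c_coordinate,
    brute_force_high_impact,
    stop_gain_by_full_translation,
)


class TestCoordinateMapping:
    def test_first_cds_base_is_c1(self):
        model = nonsense_case_transcript()
        gpos = model.genomic_position_of_cds(1)
        coord = map_genomic_to_cds(model, gpos)
        assert (coord.region, coord.pos, coord.intron_offset) == ("cds", 1, 0)

    def test_acceptor_minus_two_before_c615(self):
        model = splice_case_transcript()
        gpos = model.genomic_position_of_cds(615) - 2
        coord = map_genomic_to_cds(model, gpos)
        assert (coord.region, coord.pos, coord.intron_offset) == ("cds", 615, -2)
        assert format_c_position(coord) == "c.615-2"

    def test_utr_positions_get_distinct_coordinates(self):
        model = nonsense_case_transcript()
        before_atg = model.genomic_position_of_cds(1) - 1
        coord = map_genomic_to_cds(model, before_atg)
        assert (coord.region, coord.pos) == ("utr5", 1)
        after_stop = model.genomic_position_of_cds(600) + 1
        coord = map_genomic_to_cds(model, after_stop)
        assert (coord.region, coord.pos) == ("utr3", 1)

    def test_outside_span_raises(self):
        model = nonsense_case_transcript()
        with pytest.raises(OutsideTranscriptError):
            map_genomic_to_cds(model, 1)

    def test_matches_spliced_walk_oracle_on_random_transcripts(self, rng):
        """Mapping equals an independent walk along the spliced transcript,
        on both strands, exonic and intronic positions alike."""
        for _ in range(8):
            model = random_toy_transcript(rng)
            lo, hi = model.span
            positions = rng.integers(lo, hi + 1, size=120)
            for gpos in positions:
                coord = map_genomic_to_cds(model, int(gpos))
                assert (
                    coord.region, coord.pos, coord.intron_offset
                ) == brute_force_c_coordinate(model, int(gpos))


class TestHgvsRoundTrip:
    @settings(max_examples=300, derandomize=True)
    @given(
        region=st.sampled_from(["cds", "utr5", "utr3"]),
        pos=st.integers(1, 100000),
        offset=st.integers(-500, 500),
    )
    def test_parse_inverts_format(self, region, pos, offset):
        coord = CDSCoordinate(region=region, pos=pos, intron_offset=offset)
        back = parse_c_position(format_c_position(coord))
        assert (back.region, back.pos, back.intron_offset) == (region, pos, offset)

    @pytest.mark.parametrize("text", ["c.250", "c.615-2", "c.88+1", "c.-5", "c.*12+3"])
    def test_known_strings_round_trip(self, text):
        assert format_c_position(parse_c_position(text)) == text


class TestAnnotateSnv:
    def test_nonsense_worked_example(self):
        model = nonsense_case_transcript()
        c = annotate_consequence(model, nonsense_variant(model))
        assert c.so_term == "stop_gained"
        assert c.impact_tier == "HIGH"
        assert c.hgvs_c == "c.250C>T"
        assert c.hgvs_p == "p.Gln84Ter"
        assert c.affected_codon_index == 84

    def test_splice_acceptor_worked_example(self):
        model = splice_case_transcript()
        c = annotate_consequence(model, splice_variant(model))
        assert c.so_term == "splice_acceptor_variant"
        assert c.impact_tier == "HIGH"
        assert c.hgvs_c == "c.615-2A>G"

    def test_synonymous_third_position(self):
        # CTG -> CTA is still Leu
        model = nonsense_case_transcript()
        gpos = model.genomic_position_of_cds(6)  # codon 2 = CTG filler
        v = VariantRecord(model.chrom, gpos, "G", "A", 100.0)
        c = annotate_consequence(model, v)
        assert c.so_term == "synonymous_variant"
        assert c.impact_tier == "LOW"
        assert c.hgvs_p == "p.Leu2="

    def test_missense_and_codon_arithmetic(self, rng):
        model = nonsense_case_transcript()
        for cds_pos in rng.integers(4, 597, size=30):
            cds_pos = int(cds_pos)
            gpos = model.genomic_position_of_cds(cds_pos)
            ref = model.genome.fetch(model.chrom, gpos, gpos)
            alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
            c = annotate_consequence(
                model, VariantRecord(model.chrom, gpos, ref, alt, 10.0)
            )
            if c.affected_codon_index is not None:
                assert c.affected_codon_index == (cds_pos - 1) // 3 + 1

    def test_reference_mismatch_raises(self):
        model = nonsense_case_transcript()
        gpos = model.genomic_position_of_cds(250)
        with pytest.raises(ReferenceMismatchError):
            annotate_consequence(
                model, VariantRecord(model.chrom, gpos, "A", "T", 10.0)
            )

    def test_stop_gain_agrees_with_full_translation_oracle(self, rng):
        """Over >=1000 random SNVs: stop_gained iff translating the whole
        mutant CDS shows a new stop at that codon."""
        checked = 0
        while checked < 1000:
            model = random_toy_transcript(rng)
            n = len(model.cds_sequence)
            for cds_pos in rng.integers(4, n - 3, size=40):
                cds_pos = int(cds_pos)
                gpos = model.genomic_position_of_cds(cds_pos)
                ref_tx = model.tx_base(gpos)
                alt_tx = "AGCT"[int(rng.integers(4))]
                if alt_tx == ref_tx:
                    continue
                flip = model.strand == "-"
                comp = str.maketrans("ACGT", "TGCA")
                ref_g = ref_tx.translate(comp) if flip else ref_tx
                alt_g = alt_tx.translate(comp) if flip else alt_tx
                c = annotate_consequence(
                    model, VariantRecord(model.chrom, gpos, ref_g, alt_g, 10.0)
                )
                expected = stop_gain_by_full_translation(model, cds_pos, alt_tx)
                assert (c.so_term == "stop_gained") == expected
                checked += 1

    def test_strand_mirror_gives_identical_annotations(self, rng):
        """A transcript and its reverse-complement mirror must agree on c./p."""
        cds = make_cds(80, overrides={20: "CAG", 40: "TGG"})
        parts = [81, 80, 79]
        kw = dict(exon_coding_parts=parts, utr5="AAAA", utr3="GGGG",
                  intron_lengths=[30, 44])
        plus = build_transcript(cds, strand="+", **kw)
        minus = build_transcript(cds, strand="-", **kw)
        comp = str.maketrans("ACGT", "TGCA")
        for cds_pos in [1, 58, 118, 145, 239]:
            gp = plus.genomic_position_of_cds(cds_pos)
            gm = minus.genomic_position_of_cds(cds_pos)
            ref_tx = plus.tx_base(gp)
            alt_tx = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_tx]
            cp = annotate_consequence(
                plus, VariantRecord(plus.chrom, gp, ref_tx, alt_tx, 10.0)
            )
            cm = annotate_consequence(
                minus,
                VariantRecord(
                    minus.chrom, gm, ref_tx.translate(comp), alt_tx.translate(comp), 10.0
                ),
            )
            assert (cp.so_term, cp.hgvs_c, cp.hgvs_p) == (
                cm.so_term, cm.hgvs_c, cm.hgvs_p
            )


class TestHighImpactOracleAgreement:
    def test_high_tier_matches_brute_force_over_random_variants(self, rng):
        """The impact tier assigned by the annotator agrees with an
        independent brute-force loss-of-function check (full mutant
        translation + explicit spliced walks) for random SNVs and small
        deletions on random transcripts."""
        checked = 0
        for _ in range(10):
            model = random_toy_transcript(rng)
            lo, hi = model.span
            for gpos in rng.integers(lo, hi + 1, size=60):
                gpos = int(gpos)
                if rng.random() < 0.3 and gpos + 3 <= hi:
                    d = int(rng.integers(1, 3))
                    ref = model.genome.fetch(model.chrom, gpos, gpos + d)
                    variant = VariantRecord(model.chrom, gpos, ref, ref[0], 10.0)
                else:
                    ref = model.genome.fetch(model.chrom, gpos, gpos)
                    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
                    variant = VariantRecord(model.chrom, gpos, ref, alt, 10.0)
                consequence = annotate_consequence(model, variant)
                assert (consequence.impact_tier == "HIGH") == (
                    brute_force_high_impact(model, variant)
                ), (variant, consequence.so_term)
                checked += 1
        assert checked >= 500


class TestAnnotateIndel:
    def test_77nt_coding_deletion_is_frameshift(self):
        model = splice_case_transcript()
        # delete coding bases 41..117 (within exon 1): anchor at c.40
        g40 = model.genomic_position_of_cds(40)
        g117 = model.genomic_position_of_cds(117)
        ref = model.genome.fetch(model.chrom, g40, g117)
        v = VariantRecord(model.chrom, g40, ref, ref[0], 100.0)
        c = annotate_consequence(model, v)
        assert c.so_term == "frameshift_variant"
        assert c.hgvs_c == "c.41_117del"

    def test_inframe_deletion(self):
        model = nonsense_case_transcript()
        g = model.genomic_position_of_cds(9)  # delete codons 4-5 (6 bases)
        ref = model.genome.fetch(model.chrom, g, g + 6)
        v = VariantRecord(model.chrom, g, ref, ref[0], 100.0)
        c = annotate_consequence(model, v)
        assert c.so_term == "inframe_deletion"
        assert c.impact_tier == "MODERATE"

    def test_deletion_hitting_acceptor_is_splice(self):
        model = splice_case_transcript()
        g615 = model.genomic_position_of_cds(615)
        anchor = g615 - 4  # deletes the intronic -3,-2,-1 bases
        ref = model.genome.fetch(model.chrom, anchor, anchor + 3)
        c = annotate_consequence(
            model, VariantRecord(model.chrom, anchor, ref, ref[0], 100.0)
        )
        assert c.so_term == "splice_acceptor_variant"


class TestTranslation:
    @pytest.mark.parametrize(
        ("n_codons_total", "n_residues"), [(200, 199), (531, 530), (2, 1)]
    )
    def test_translation_lengths(self, n_codons_total, n_residues):
        model = build_transcript(
            make_cds(n_codons_total),
            exon_coding_parts=[3 * n_codons_total],
            utr5="AA",
            utr3="GG",
        )
        assert len(translate_cds(model)) == n_residues

    def test_600nt_and_1593nt_case_transcripts(self):
        assert len(translate_cds(nonsense_case_transcript())) == 199
        assert len(translate_cds(splice_case_transcript())) == 530

    def test_internal_stop_reports_codon(self):
        model = build_transcript(
            make_cds(50, overrides={10: "TGA"}), exon_coding_parts=[150]
        )
        with pytest.raises(PrematureStopError) as exc:
            translate_cds(model)
        assert exc.value.codon_index == 10


class TestImpactMap:
    @pytest.mark.parametrize(
        ("term", "tier"),
        [
            ("stop_gained", "HIGH"),
            ("frameshift_variant", "HIGH"),
            ("splice_acceptor_variant", "HIGH"),
            ("missense_variant", "MODERATE"),
            ("synonymous_variant", "LOW"),
            ("intron_variant", "MODIFIER"),
        ],
    )
    def test_fixed_map(self, term, tier):
        assert classify_impact(term) == tier

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError):
            classify_impact("regulatory_region_variant")

    def test_deep_intronic_snv_is_modifier(self):
        model = splice_case_transcript()
        gpos = model.genomic_position_of_cds(615) - 25
        c = annotate_consequence(
            model,
            VariantRecord(
                model.chrom, gpos,
                model.genome.fetch(model.chrom, gpos, gpos),
                "A" if model.genome.fetch(model.chrom, gpos, gpos) != "A" else "G",
                10.0,
            ),
        )
        assert c.so_term == "intron_variant"
        assert c.impact_tier == "MODIFIER"
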