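"""Published worked examples: the two patient candidates and the two KO assays.

The discovery study behind these numbers reported, for two consanguineous
non-obstructive-azoospermia patients, one homozygous loss-of-function variant
each in a testis-specific gene: a nonsense variant c.250C>T (p.Gln84Ter) in
exon 3 of *C1orf185* (five exons, 199-residue protein) and a splice-acceptor
variant c.615-2A>G in intron 5 of *CCT6B* (14 exons, 530-residue protein),
both with gnomAD AF below 1% (5.02e-3 and 3.53e-3) and absent from a local
control cohort of 445 exomes. The mouse validation excised intra-exonic
frameshift deletions from the orthologs: a 77 bp deletion (c.41_117del) in
*4930522H14Rik* exon 2 genotyped by a 457 bp WT / 380 bp KO amplicon, and a
155 bp deletion in *Cct6b* exon 4 genotyped by a 535 bp WT / 380 bp KO
amplicon.

Everything here is reconstructed from those published annotations; the toy
transcripts reproduce the reported coordinate geometry (CDS lengths, the CAG
codon at c.250-252, an exon boundary at c.615), not the real gene sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

from .consequence_annotator import HIGH, LOW, Consequence, TranscriptModel
from .crispr_toolkit import DeletionDesign
from .prioritizer import (
    AnnotatedVariant,
    ControlCohort,
    FrequencyAnnotations,
)
from .toygenome import build_transcript, make_cds
from .variant_model import (
    HET,
    HOM_ALT,
    HOM_REF,
    GenotypeCall,
    VariantRecord,
    missing_call,
)

PATIENT_NONSENSE = "P0365"  # carries the C1orf185-like stop-gain
PATIENT_SPLICE = "P0280"  # carries the CCT6B-like splice-acceptor
CONTROL_COHORT_SIZE = 445


def nonsense_case_transcript() -> TranscriptModel:
    """Five-exon toy with a 600 nt CDS (199 residues) and CAG at c.250-252.

    c.250 opens codon 84 ((250-1)//3 + 1), so a C>T there turns Gln84 into a
    stop — the p.Gln84Ter geometry.
    """
    cds = make_cds(200, overrides={84: "CAG"})
    return build_transcript(
        cds,
        exon_coding_parts=[120, 120, 120, 120, 120],
        chrom="toy_c1orf185",
        gene_id="C1orf185",
        transcript_id="C1orf185.t1",
    )


def nonsense_variant(model: TranscriptModel) -> VariantRecord:
    gpos = model.genomic_position_of_cds(250)
    return VariantRecord(model.chrom, gpos, "C", "T", site_quality=1000.0)


def splice_case_transcript() -> TranscriptModel:
    """Fourteen-exon toy with a 1593 nt CDS (530 residues) and an exon
    boundary exactly at c.615, so intron 5's acceptor-2 base is c.615-2."""
    cds = make_cds(531)
    parts = [123, 123, 123, 123, 122]  # coding 1..614 over exons 1-5
    rest = 1593 - sum(parts)  # 979 over exons 6-14
    parts += [109] * 8 + [rest - 109 * 8]
    return build_transcript(
        cds,
        exon_coding_parts=parts,
        chrom="toy_cct6b",
        gene_id="CCT6B",
        transcript_id="CCT6B.t1",
    )


def splice_variant(model: TranscriptModel) -> VariantRecord:
    """The A>G at the second intronic base upstream of the exon opening at c.615."""
    exon6_first = model.genomic_position_of_cds(615)
    step = 1 if model.strand == "+" else -1
    gpos = exon6_first - 2 * step
    ref = model.genome.fetch(model.chrom, gpos, gpos)
    alt = "G" if model.strand == "+" else "C"
    return VariantRecord(model.chrom, gpos, ref, alt, site_quality=1000.0)


# ---------------------------------------------------------------------------
# Cascade worked example


def _good_call(sample: str, zygosity: str) -> GenotypeCall:
    ad_alt = {HOM_ALT: 48, HET: 25, HOM_REF: 0}[zygosity]
    return GenotypeCall(sample, zygosity, dp=50, gqx=80, ad_ref=50 - ad_alt,
                        ad_alt=ad_alt)


def _annotated(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene: str,
    consequence: Consequence,
    afs: FrequencyAnnotations,
    genotypes: dict[str, GenotypeCall],
    ratio: float,
    specific: bool,
) -> AnnotatedVariant:
    return AnnotatedVariant(
        variant=VariantRecord(chrom, pos, ref, alt, site_quality=1000.0),
        gene_id=gene,
        consequence=consequence,
        frequencies=afs,
        genotypes=genotypes,
        specificity_ratio=ratio,
        is_tissue_specific=specific,
    )


@dataclass
class CascadeWorkedExample:
    variants: list[AnnotatedVariant]
    probands: list[str]
    control_cohort: ControlCohort
    expected_candidate_keys: dict[str, tuple[str, int, str, str]]
    #: designed first-failing predicate per distractor key
    distractor_design: dict[tuple[str, int, str, str], str]


def cascade_worked_example() -> CascadeWorkedExample:
    """The two patients' published candidate annotations plus six distractors,
    each built to trip a designated cascade predicate first."""
    p1, p2 = PATIENT_NONSENSE, PATIENT_SPLICE

    stop_gain = _annotated(
        "chr1", 59_217_000, "G", "A", "C1orf185",
        Consequence("stop_gained", HIGH, "c.250C>T", "p.Gln84Ter", 84,
                    "C1orf185", "C1orf185.t1"),
        FrequencyAnnotations(af_gnomad=5.02e-3),
        {p1: _good_call(p1, HOM_ALT), p2: _good_call(p2, HOM_REF)},
        ratio=80.0, specific=True,
    )
    splice = _annotated(
        "chr17", 33_288_000, "T", "C", "CCT6B",
        Consequence("splice_acceptor_variant", HIGH, "c.615-2A>G", "", None,
                    "CCT6B", "CCT6B.t1"),
        FrequencyAnnotations(af_gnomad=3.53e-3),
        {p1: _good_call(p1, HOM_REF), p2: _good_call(p2, HOM_ALT)},
        ratio=60.0, specific=True,
    )

    distractors = {}
    distractors["recessive_model"] = _annotated(
        "chr2", 1_000, "C", "T", "GENE_HET",
        Consequence("stop_gained", HIGH, "c.100C>T", "p.Gln34Ter", 34),
        FrequencyAnnotations(af_gnomad=1e-4),
        {p1: _good_call(p1, HET), p2: _good_call(p2, HET)},
        ratio=50.0, specific=True,
    )
    distractors["frequency"] = _annotated(
        "chr2", 2_000, "G", "T", "GENE_COMMON",
        Consequence("stop_gained", HIGH, "c.200G>T", "p.Glu67Ter", 67),
        FrequencyAnnotations(af_gnomad=0.02),
        {p1: _good_call(p1, HOM_ALT), p2: _good_call(p2, HOM_ALT)},
        ratio=50.0, specific=True,
    )
    distractors["control_cohort"] = _annotated(
        "chr2", 3_000, "A", "G", "GENE_INCTRL",
        Consequence("stop_gained", HIGH, "c.300A>G", "p.Lys100Ter", 100),
        FrequencyAnnotations(af_gnomad=2e-4),
        {p1: _good_call(p1, HOM_ALT), p2: _good_call(p2, HOM_ALT)},
        ratio=50.0, specific=True,
    )
    distractors["impact"] = _annotated(
        "chr2", 4_000, "T", "C", "GENE_SYN",
        Consequence("synonymous_variant", LOW, "c.400T>C", "p.Leu134=", 134),
        FrequencyAnnotations(af_gnomad=1e-4),
        {p1: _good_call(p1, HOM_ALT), p2: _good_call(p2, HOM_ALT)},
        ratio=50.0, specific=True,
    )
    distractors["tissue_specificity"] = _annotated(
        "chr2", 5_000, "C", "A", "GENE_BROAD",
        Consequence("stop_gained", HIGH, "c.500C>A", "p.Ser167Ter", 167),
        FrequencyAnnotations(af_gnomad=1e-4),
        {p1: _good_call(p1, HOM_ALT), p2: _good_call(p2, HOM_ALT)},
        ratio=1.2, specific=False,
    )
    distractors["genotype_quality"] = _annotated(
        "chr2", 6_000, "G", "C", "GENE_LOWQ",
        Consequence("stop_gained", HIGH, "c.600G>C", "p.Glu200Ter", 200),
        FrequencyAnnotations(af_gnomad=1e-4),
        {p1: missing_call(p1), p2: missing_call(p2)},
        ratio=50.0, specific=True,
    )

    control = ControlCohort(
        n_controls=CONTROL_COHORT_SIZE,
        counts={distractors["control_cohort"].key: (1, 0)},
    )
    variants = [stop_gain, splice, *distractors.values()]
    return CascadeWorkedExample(
        variants=variants,
        probands=[p1, p2],
        control_cohort=control,
        expected_candidate_keys={p1: stop_gain.key, p2: splice.key},
        distractor_design={v.key: why for why, v in distractors.items()},
    )


# ---------------------------------------------------------------------------
# Mouse knockout assays

RIK_WT_AMPLICON = 457
CCT6B_WT_AMPLICON = 535
#: Fig-level deletion length for the Cct6b line; consistent with the reported
#: 535 -> 380 bp amplicon shift but NOT with the reported span c.354_505del
#: (which covers 152 bases). The length is treated as authoritative for
#: genotyping arithmetic; the span is carried with an inconsistency note.
CCT6B_REPORTED_DELETION_LENGTH = 155


def rik_design() -> DeletionDesign:
    """The 77 bp frameshift deletion c.41_117del in 4930522H14Rik exon 2."""
    return DeletionDesign(gene_id="4930522H14Rik", target_exon_index=2,
                          cut5=41, cut3=117)


def cct6b_reported_span_design() -> DeletionDesign:
    """The Cct6b deletion as per its reported coordinate span c.354_505del."""
    return DeletionDesign(
        gene_id="Cct6b",
        target_exon_index=4,
        cut5=354,
        cut3=505,
        note=(
            "reported span covers 152 bases but the reported length and the "
            "WT/KO amplicon shift (535->380) are 155 bp; length 155 is used "
            "for genotyping arithmetic"
        ),
    )
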