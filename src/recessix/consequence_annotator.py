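"""Transcript-model consequence engine: impact classes and HGVS c./p. strings.

This is a self-contained mini-annotator for SNVs and small indels against an
exon/CDS transcript model. Coding positions are numbered in HGVS c. space (the
A of the initiator ATG is c.1); intronic positions are exon-anchored with a
signed offset (c.615-2 is the second nucleotide of the splice acceptor
consensus upstream of the coding base numbered 615). Protein effects use
three-letter HGVS p. notation (p.Gln84Ter).

Reference-allele verification against the genome sequence is mandatory:
silent coordinate bugs are the dominant failure mode of annotators, and a
mismatch raises rather than annotating garbage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Mapping, Optional, Sequence

import gffutils
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .variant_model import VariantRecord

HIGH = "HIGH"
MODERATE = "MODERATE"
LOW = "LOW"
MODIFIER = "MODIFIER"

#: SO term -> impact tier. The two canonical intronic bases on each side of an
#: exon are splice_acceptor/donor (HIGH); intronic offsets 3-8 are reported as
#: splice_region_variant but left at MODIFIER, like deep intronic positions.
IMPACT_MAP: Mapping[str, str] = {
    "stop_gained": HIGH,
    "frameshift_variant": HIGH,
    "splice_acceptor_variant": HIGH,
    "splice_donor_variant": HIGH,
    "stop_lost": HIGH,
    "start_lost": HIGH,
    "missense_variant": MODERATE,
    "inframe_deletion": MODERATE,
    "inframe_insertion": MODERATE,
    "synonymous_variant": LOW,
    "splice_region_variant": MODIFIER,
    "intron_variant": MODIFIER,
    "5_prime_UTR_variant": MODIFIER,
    "3_prime_UTR_variant": MODIFIER,
}

_TIER_RANK = {HIGH: 0, MODERATE: 1, LOW: 2, MODIFIER: 3}

SPLICE_CANONICAL_WINDOW = 2
SPLICE_REGION_WINDOW = 8


class OutsideTranscriptError(ValueError):
    pass


class ReferenceMismatchError(ValueError):
    pass


class PrematureStopError(ValueError):
    def __init__(self, codon_index: int):
        super().__init__(f"internal stop codon at codon {codon_index}")
        self.codon_index = codon_index


class Genome:
    """1-based-inclusive sequence access over in-memory contigs."""

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def contig_names(self) -> list[str]:
        return list(self._contigs)

    def contig_length(self, chrom: str) -> int:
        return len(self._contigs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._contigs:
            raise KeyError(f"unknown contig {chrom!r}")
        if start < 1 or end > len(self._contigs[chrom]) or start > end:
            raise ValueError(f"bad interval {chrom}:{start}-{end}")
        return self._contigs[chrom][start - 1 : end]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with Path(path).open("w") as fh:
            for name, seq in self._contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class CDSCoordinate:
    """HGVS-style coding coordinate.

    region "cds": pos counts from the A of ATG (= 1). region "utr5": pos is the
    distance upstream of ATG (c.-pos). region "utr3": pos is the distance past
    the stop codon (c.*pos). A non-zero intron_offset marks an intronic
    position anchored to the nearest exonic base.
    """

    region: str  # cds | utr5 | utr3
    pos: int
    intron_offset: int = 0
    exon_index: Optional[int] = None
    intron_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.region not in ("cds", "utr5", "utr3"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def is_intronic(self) -> bool:
        return self.intron_offset != 0


def format_c_position(coord: CDSCoordinate) -> str:
    prefix = {"cds": "", "utr5": "-", "utr3": "*"}[coord.region]
    offset = f"{coord.intron_offset:+d}" if coord.intron_offset else ""
    return f"c.{prefix}{coord.pos}{offset}"


_C_POSITION_RE = re.compile(r"^c\.(\*|-)?(\d+)([+-]\d+)?$")


def parse_c_position(text: str) -> CDSCoordinate:
    m = _C_POSITION_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse HGVS c. position {text!r}")
    region = {"*": "utr3", "-": "utr5", None: "cds"}[m.group(1)]
    return CDSCoordinate(
        region=region,
        pos=int(m.group(2)),
        intron_offset=int(m.group(3)) if m.group(3) else 0,
    )


@dataclass
class TranscriptModel:
    """Exon structure + CDS frame of one transcript on a genome."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]  # genomic, ascending, 1-based inclusive
    cds_start: int  # genomic (min CDS coordinate)
    cds_end: int  # genomic (max CDS coordinate)
    genome: Genome

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons {s1}-{e1}, {s2}-{e2}")
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"bad exon interval {s}-{e}")
        if not self.span[0] <= self.cds_start <= self.cds_end <= self.span[1]:
            raise ValueError("CDS must lie within the exon span")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @cached_property
    def exons_tx(self) -> list[tuple[int, int]]:
        """Exons ordered 5'->3' in transcript orientation."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    @cached_property
    def _tx_positions(self) -> list[int]:
        pos: list[int] = []
        for s, e in self.exons_tx:
            rng = range(s, e + 1) if self.strand == "+" else range(e, s - 1, -1)
            pos.extend(rng)
        return pos

    @cached_property
    def _maps(self) -> dict:
        """Per-position lookups in transcript orientation."""
        cds_positions: list[int] = []
        utr5: dict[int, int] = {}
        utr3: dict[int, int] = {}
        exon_of: dict[int, int] = {}
        i_tx = 0
        for exon_index, (s, e) in enumerate(self.exons_tx, start=1):
            rng = range(s, e + 1) if self.strand == "+" else range(e, s - 1, -1)
            for g in rng:
                exon_of[g] = exon_index
        seen_cds = 0
        n_cds = sum(
            max(0, min(e, self.cds_end) - max(s, self.cds_start) + 1)
            for s, e in self.exons
        )
        for g in self._tx_positions:
            if self.cds_start <= g <= self.cds_end:
                cds_positions.append(g)
                seen_cds += 1
            elif seen_cds == 0:
                utr5[g] = 0  # placeholder, distance filled below
            else:
                utr3[g] = len(utr3) + 1
        # 5' UTR distances count backwards from ATG: last pre-CDS base is c.-1
        pre = [g for g in self._tx_positions if g in utr5]
        for dist, g in enumerate(reversed(pre), start=1):
            utr5[g] = dist
        cds_index = {g: i + 1 for i, g in enumerate(cds_positions)}
        assert len(cds_positions) == n_cds
        return {
            "cds_positions": cds_positions,
            "cds_index": cds_index,
            "utr5": utr5,
            "utr3": utr3,
            "exon_of": exon_of,
        }

    @cached_property
    def introns_tx(self) -> list[tuple[int, int, int, int]]:
        """(donor_gpos, acceptor_gpos, intron_start_g, intron_end_g) per intron,
        in transcript order; donor/acceptor are the flanking exonic bases."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons_tx, self.exons_tx[1:]):
            if self.strand == "+":
                donor, acceptor = e1, s2
                lo, hi = e1 + 1, s2 - 1
            else:
                donor, acceptor = s1, e2
                lo, hi = e2 + 1, s1 - 1
            out.append((donor, acceptor, lo, hi))
        return out

    @property
    def cds_length(self) -> int:
        return len(self._maps["cds_positions"])

    @cached_property
    def cds_sequence(self) -> str:
        """Spliced CDS in transcript orientation (starts at c.1)."""
        parts = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                parts.append(self.genome.fetch(self.chrom, lo, hi))
        seq = "".join(parts)
        return seq if self.strand == "+" else _revcomp(seq)

    def genomic_position_of_cds(self, cds_pos: int) -> int:
        positions = self._maps["cds_positions"]
        if not 1 <= cds_pos <= len(positions):
            raise ValueError(f"cds position {cds_pos} outside 1..{len(positions)}")
        return positions[cds_pos - 1]

    def tx_base(self, gpos: int) -> str:
        """Reference base at gpos, reported on the transcript strand."""
        base = self.genome.fetch(self.chrom, gpos, gpos)
        return base if self.strand == "+" else _revcomp(base)


def map_genomic_to_cds(model: TranscriptModel, gpos: int) -> CDSCoordinate:
    """Map a genomic position to an HGVS coding coordinate.

    Intronic positions anchor to the nearer exon boundary (ties go to the
    donor side, per HGVS convention for the middle of an intron): the first
    intronic base past a donor is +1, the last base before an acceptor is -1.
    """
    lo, hi = model.span
    if not lo <= gpos <= hi:
        raise OutsideTranscriptError(
            f"{model.transcript_id}: position {gpos} outside span {lo}-{hi}"
        )
    maps = model._maps
    if gpos in maps["exon_of"]:
        return _exonic_coordinate(model, gpos)
    for intron_index, (donor, acceptor, ilo, ihi) in enumerate(
        model.introns_tx, start=1
    ):
        if ilo <= gpos <= ihi:
            d_donor = abs(gpos - donor)
            d_acceptor = abs(acceptor - gpos)
            if d_donor <= d_acceptor:
                anchor = _exonic_coordinate(model, donor)
                offset = d_donor
            else:
                anchor = _exonic_coordinate(model, acceptor)
                offset = -d_acceptor
            return CDSCoordinate(
                region=anchor.region,
                pos=anchor.pos,
                intron_offset=offset,
                exon_index=anchor.exon_index,
                intron_index=intron_index,
            )
    raise OutsideTranscriptError(f"position {gpos} not locatable")  # pragma: no cover


def _exonic_coordinate(model: TranscriptModel, gpos: int) -> CDSCoordinate:
    maps = model._maps
    exon_index = maps["exon_of"][gpos]
    if gpos in maps["cds_index"]:
        return CDSCoordinate("cds", maps["cds_index"][gpos], 0, exon_index)
    if gpos in maps["utr5"]:
        return CDSCoordinate("utr5", maps["utr5"][gpos], 0, exon_index)
    return CDSCoordinate("utr3", maps["utr3"][gpos], 0, exon_index)


@dataclass(frozen=True)
class Consequence:
    so_term: str
    impact_tier: str
    hgvs_c: str
    hgvs_p: str = ""
    affected_codon_index: Optional[int] = None
    gene_id: str = ""
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.so_term in (
            "stop_gained",
            "frameshift_variant",
            "splice_acceptor_variant",
            "splice_donor_variant",
            "stop_lost",
            "start_lost",
        ) and self.impact_tier != HIGH:
            raise ValueError(f"{self.so_term} must be HIGH impact")


def classify_impact(so_term: str) -> str:
    try:
        return IMPACT_MAP[so_term]
    except KeyError:
        raise ValueError(f"unknown SO term {so_term!r}") from None


def impact_rank(tier: str) -> int:
    """0 is most severe; usable as a sort key."""
    return _TIER_RANK[tier]


def translate_cds(model: TranscriptModel) -> str:
    """Standard-code translation of the CDS, excluding the terminal stop."""
    cds = model.cds_sequence
    if len(cds) % 3:
        raise ValueError(f"{model.transcript_id}: CDS length {len(cds)} not divisible by 3")
    protein = str(Seq(cds).translate())
    if not protein.endswith("*"):
        raise ValueError(f"{model.transcript_id}: CDS does not end in a stop codon")
    body = protein[:-1]
    if "*" in body:
        raise PrematureStopError(body.index("*") + 1)
    return body


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def _codon(model: TranscriptModel, codon_index: int) -> str:
    start = (codon_index - 1) * 3
    return model.cds_sequence[start : start + 3]


def _verify_reference(model: TranscriptModel, variant: VariantRecord) -> None:
    if variant.chrom != model.chrom:
        raise OutsideTranscriptError(
            f"variant on {variant.chrom}, transcript on {model.chrom}"
        )
    observed = model.genome.fetch(variant.chrom, variant.pos, variant.end)
    if observed != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos}: REF {variant.ref} does not match "
            f"genome {observed}"
        )


def annotate_consequence(
    model: TranscriptModel, variant: VariantRecord
) -> Consequence:
    """Annotate one normalized bi-allelic variant against one transcript."""
    _verify_reference(model, variant)
    lo, hi = model.span
    if variant.end < lo or variant.pos > hi:
        raise OutsideTranscriptError(
            f"variant {variant.chrom}:{variant.pos} does not overlap "
            f"{model.transcript_id} ({lo}-{hi})"
        )
    if variant.is_snv:
        return _annotate_snv(model, variant)
    return _annotate_indel(model, variant)


def _finish(model: TranscriptModel, so_term: str, hgvs_c: str, hgvs_p: str = "",
            codon: Optional[int] = None) -> Consequence:
    return Consequence(
        so_term=so_term,
        impact_tier=classify_impact(so_term),
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
        affected_codon_index=codon,
        gene_id=model.gene_id,
        transcript_id=model.transcript_id,
    )


def _annotate_snv(model: TranscriptModel, variant: VariantRecord) -> Consequence:
    coord = map_genomic_to_cds(model, variant.pos)
    ref_tx = variant.ref if model.strand == "+" else _revcomp(variant.ref)
    alt_tx = variant.alt if model.strand == "+" else _revcomp(variant.alt)
    hgvs_c = f"{format_c_position(coord)}{ref_tx}>{alt_tx}"
    if coord.is_intronic:
        off = coord.intron_offset
        if 1 <= off <= SPLICE_CANONICAL_WINDOW:
            return _finish(model, "splice_donor_variant", hgvs_c)
        if -SPLICE_CANONICAL_WINDOW <= off <= -1:
            return _finish(model, "splice_acceptor_variant", hgvs_c)
        if abs(off) <= SPLICE_REGION_WINDOW:
            return _finish(model, "splice_region_variant", hgvs_c)
        return _finish(model, "intron_variant", hgvs_c)
    if coord.region == "utr5":
        return _finish(model, "5_prime_UTR_variant", hgvs_c)
    if coord.region == "utr3":
        return _finish(model, "3_prime_UTR_variant", hgvs_c)

    codon_index = (coord.pos - 1) // 3 + 1
    within = (coord.pos - 1) % 3
    ref_codon = _codon(model, codon_index)
    if ref_codon[within] != ref_tx:  # pragma: no cover - guarded by _verify_reference
        raise ReferenceMismatchError(
            f"codon {codon_index} base {within + 1} is {ref_codon[within]}, "
            f"expected {ref_tx}"
        )
    alt_codon = ref_codon[:within] + alt_tx + ref_codon[within + 1 :]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref != "*" and aa_alt == "*":
        so, hgvs_p = "stop_gained", f"p.{_aa3(aa_ref)}{codon_index}Ter"
    elif aa_ref == "*" and aa_alt != "*":
        so, hgvs_p = "stop_lost", f"p.Ter{codon_index}{_aa3(aa_alt)}ext*?"
    elif codon_index == 1 and aa_alt != aa_ref:
        so, hgvs_p = "start_lost", "p.Met1?"
    elif aa_alt == aa_ref:
        so, hgvs_p = "synonymous_variant", f"p.{_aa3(aa_ref)}{codon_index}="
    else:
        so, hgvs_p = (
            "missense_variant",
            f"p.{_aa3(aa_ref)}{codon_index}{_aa3(aa_alt)}",
        )
    return _finish(model, so, hgvs_c, hgvs_p, codon_index)


def _annotate_indel(model: TranscriptModel, variant: VariantRecord) -> Consequence:
    maps = model._maps
    deleted = list(range(variant.pos + 1, variant.end + 1))
    inserted = variant.alt[1:]
    anchor_coding = variant.pos in maps["cds_index"]
    coding_deleted = [g for g in deleted if g in maps["cds_index"]]
    coding_inserted = len(inserted) if anchor_coding else 0
    net = coding_inserted - len(coding_deleted)

    # canonical splice bases hit by the deleted span
    splice_term = None
    for donor, acceptor, ilo, ihi in model.introns_tx:
        step = 1 if model.strand == "+" else -1
        donor_bases = {donor + step, donor + 2 * step}
        acceptor_bases = {acceptor - step, acceptor - 2 * step}
        hit = set(deleted)
        if hit & acceptor_bases:
            splice_term = "splice_acceptor_variant"
            break
        if hit & donor_bases:
            splice_term = "splice_donor_variant"
            break

    hgvs_c = _indel_hgvs_c(model, variant, deleted, inserted)

    if coding_deleted or coding_inserted:
        first_codon = None
        if coding_deleted:
            first_cds = min(maps["cds_index"][g] for g in coding_deleted)
            first_codon = (first_cds - 1) // 3 + 1
        elif anchor_coding:
            first_codon = (maps["cds_index"][variant.pos] - 1) // 3 + 1
        if net % 3 != 0:
            aa = str(Seq(_codon(model, first_codon)).translate()) if first_codon else "?"
            return _finish(
                model,
                "frameshift_variant",
                hgvs_c,
                f"p.{_aa3(aa)}{first_codon}fs" if first_codon else "",
                first_codon,
            )
        so = "inframe_insertion" if net > 0 else "inframe_deletion"
        return _finish(model, so, hgvs_c, "", first_codon)
    if splice_term:
        return _finish(model, splice_term, hgvs_c)
    regions = set()
    for g in deleted or [variant.pos]:
        if g in maps["exon_of"]:
            regions.add(
                "utr5" if g in maps["utr5"] else "utr3" if g in maps["utr3"] else "cds"
            )
        else:
            regions.add("intron")
    if regions <= {"intron"}:
        return _finish(model, "intron_variant", hgvs_c)
    if "utr5" in regions:
        return _finish(model, "5_prime_UTR_variant", hgvs_c)
    return _finish(model, "3_prime_UTR_variant", hgvs_c)


def _indel_hgvs_c(
    model: TranscriptModel,
    variant: VariantRecord,
    deleted: list[int],
    inserted: str,
) -> str:
    def pos_part(g: int) -> str:
        return format_c_position(map_genomic_to_cds(model, g))[2:]

    if deleted:
        first, last = (deleted[0], deleted[-1])
        if model.strand == "-":
            first, last = last, first
        span = pos_part(first) if first == last else f"{pos_part(first)}_{pos_part(last)}"
        if inserted:
            ins_tx = inserted if model.strand == "+" else _revcomp(inserted)
            return f"c.{span}delins{ins_tx}"
        return f"c.{span}del"
    # pure insertion between the anchor and the next transcript base
    ins_tx = inserted if model.strand == "+" else _revcomp(inserted)
    a = variant.pos
    b = variant.pos + (1 if model.strand == "+" else -1)
    lo, hi = model.span
    b = min(max(b, lo), hi)
    return f"c.{pos_part(a)}_{pos_part(b)}ins{ins_tx}"


def annotate_most_severe(
    models: Sequence[TranscriptModel], variant: VariantRecord
) -> Consequence:
    """Annotate against every overlapping transcript; report the most severe."""
    results = []
    for model in models:
        try:
            results.append(annotate_consequence(model, variant))
        except OutsideTranscriptError:
            continue
    if not results:
        raise OutsideTranscriptError(
            f"variant {variant.chrom}:{variant.pos} overlaps no supplied transcript"
        )
    return min(results, key=lambda c: impact_rank(c.impact_tier))


# ---------------------------------------------------------------------------
# GFF3 input


def read_transcripts_gff3(
    gff_path: str | Path, genome: Genome
) -> list[TranscriptModel]:
    """Load gene/mRNA/exon/CDS features from a GFF3 file into transcript models."""
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for mrna in db.features_of_type("mRNA"):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons or not cds:
            raise ValueError(f"{mrna.id}: mRNA lacks exon or CDS features")
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_start=min(s for s, _ in cds),
                cds_end=max(e for _, e in cds),
                genome=genome,
            )
        )
    return models
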