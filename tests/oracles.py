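"""Independent brute-force oracles used by the property and acceptance tests.

Each oracle recomputes an answer from first principles (linear scans, full
mutant translation, explicit spliced walks) without touching the cached
index structures of the implementation it checks.
"""

from __future__ import annotations

from Bio.Seq import Seq

from recessix.consequence_annotator import TranscriptModel
from recessix.variant_model import (
    GenotypeCall,
    SampleGVCF,
    VariantRecord,
    missing_call,
)


def brute_force_merge_cell(
    sample: SampleGVCF, site: VariantRecord
) -> GenotypeCall:
    """Classify one (site, sample) pair by linear scan: called / in-block /
    uncovered."""
    for variant, call in sample.variants:
        if variant.key == site.key:
            return call
    for block in sample.blocks:
        if block.covers(site.chrom, site.pos):
            return GenotypeCall(
                sample_id=sample.sample_id,
                zygosity="hom_ref",
                dp=block.min_dp,
                gqx=block.min_gqx,
                ad_ref=block.min_dp,
                ad_alt=0,
            )
    return missing_call(sample.sample_id)


def union_site_keys(samples: list[SampleGVCF]) -> list[tuple]:
    return sorted({v.key for s in samples for v, _ in s.variants})


def spliced_positions(model: TranscriptModel) -> list[int]:
    """Genomic positions of the spliced transcript, 5'->3', by explicit walk."""
    out: list[int] = []
    exons = model.exons if model.strand == "+" else list(reversed(model.exons))
    for s, e in exons:
        rng = range(s, e + 1) if model.strand == "+" else range(e, s - 1, -1)
        out.extend(rng)
    return out


def brute_force_c_coordinate(
    model: TranscriptModel, gpos: int
) -> tuple[str, int, int]:
    """(region, pos, intron_offset) for a genomic position, computed by a
    spliced walk plus nearest-boundary arithmetic."""
    tx = spliced_positions(model)
    in_cds = [g for g in tx if model.cds_start <= g <= model.cds_end]
    cds_of = {g: i + 1 for i, g in enumerate(in_cds)}
    if gpos in cds_of:
        return ("cds", cds_of[gpos], 0)
    if gpos in set(tx):
        idx = tx.index(gpos)
        first_cds_idx = tx.index(in_cds[0])
        last_cds_idx = tx.index(in_cds[-1])
        if idx < first_cds_idx:
            return ("utr5", first_cds_idx - idx, 0)
        return ("utr3", idx - last_cds_idx, 0)
    # intronic: nearest flanking exonic base along the genome
    exonic = set(tx)
    left = gpos
    while left not in exonic:
        left -= 1
    right = gpos
    while right not in exonic:
        right += 1
    d_left, d_right = gpos - left, right - gpos
    # donor side = the exonic base that comes first in transcript order
    donor_g, acceptor_g = (left, right) if model.strand == "+" else (right, left)
    d_donor = abs(gpos - donor_g)
    d_acceptor = abs(acceptor_g - gpos)
    if d_donor <= d_acceptor:
        anchor, offset = donor_g, d_donor
    else:
        anchor, offset = acceptor_g, -d_acceptor
    region, pos, _ = brute_force_c_coordinate(model, anchor)
    return (region, pos, offset)


def stop_gain_by_full_translation(
    model: TranscriptModel, cds_pos: int, alt_tx: str
) -> bool:
    """Does replacing CDS base cds_pos with alt_tx create a new in-frame stop
    at that codon? Decided by translating the entire mutant CDS."""
    cds = model.cds_sequence
    mutant = cds[: cds_pos - 1] + alt_tx + cds[cds_pos:]
    ref_aa = str(Seq(cds).translate())
    mut_aa = str(Seq(mutant).translate())
    codon = (cds_pos - 1) // 3
    return mut_aa[codon] == "*" and ref_aa[codon] != "*"


def brute_force_high_impact(model: TranscriptModel, variant: VariantRecord) -> bool:
    """Re-derive whether a variant is HIGH impact (stop gain/loss, start loss,
    canonical splice, coding frameshift) from explicit spliced walks and full
    mutant translation."""
    comp = str.maketrans("ACGT", "TGCA")
    if variant.is_snv:
        region, pos, offset = brute_force_c_coordinate(model, variant.pos)
        if offset != 0:
            return abs(offset) <= 2
        if region != "cds":
            return False
        alt_tx = variant.alt if model.strand == "+" else variant.alt.translate(comp)
        cds = model.cds_sequence
        mutant = cds[: pos - 1] + alt_tx + cds[pos:]
        codon = (pos - 1) // 3
        ref_aa = str(Seq(cds[codon * 3 : codon * 3 + 3]).translate())
        mut_aa = str(Seq(mutant[codon * 3 : codon * 3 + 3]).translate())
        return (
            (mut_aa == "*" and ref_aa != "*")
            or (ref_aa == "*" and mut_aa != "*")
            or (codon == 0 and mut_aa != ref_aa)
        )
    # indel: canonical splice hit or out-of-frame coding change
    deleted = list(range(variant.pos + 1, variant.end + 1))
    coords = [brute_force_c_coordinate(model, g) for g in deleted]
    if any(off != 0 and abs(off) <= 2 for _, _, off in coords):
        return True
    n_coding_deleted = sum(
        1 for region, _, off in coords if region == "cds" and off == 0
    )
    anchor_region, _, anchor_off = brute_force_c_coordinate(model, variant.pos)
    n_inserted = (
        len(variant.alt) - 1
        if anchor_region == "cds" and anchor_off == 0
        else 0
    )
    if n_coding_deleted == 0 and n_inserted == 0:
        return False
    return (n_inserted - n_coding_deleted) % 3 != 0


def splice_site_distance(model: TranscriptModel, gpos: int) -> int | None:
    """Signed distance to the nearest exon boundary for intronic positions
    (+k past a donor, -k before an acceptor), None for exonic positions."""
    region, pos, offset = brute_force_c_coordinate(model, gpos)
    return offset if offset != 0 else None
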