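"""Deterministic toy transcript construction for examples and tests.

`build_transcript` lays out UTR5 + coding exons (split by GT..AG introns) +
UTR3 on a fresh contig, on either strand, and returns a fully wired
:class:`TranscriptModel`. The minus-strand build reverse-complements the whole
gene onto the contig, so a transcript and its mirror share identical spliced
coordinates — handy for strand-correctness checks.
"""

from __future__ import annotations

from typing import Optional, Sequence

from Bio.Seq import Seq

from .consequence_annotator import Genome, TranscriptModel


def build_transcript(
    cds: str,
    exon_coding_parts: Sequence[int],
    utr5: str = "ACGTAC",
    utr3: str = "GTACGT",
    intron_lengths: Optional[Sequence[int]] = None,
    strand: str = "+",
    chrom: str = "toy1",
    gene_id: str = "TOYGENE",
    transcript_id: str = "TOYGENE.t1",
    pad: int = 10,
) -> TranscriptModel:
    """Assemble a toy gene and its contig from explicit coding-exon sizes."""
    cds = cds.upper()
    if sum(exon_coding_parts) != len(cds):
        raise ValueError(
            f"exon coding parts sum to {sum(exon_coding_parts)}, CDS is {len(cds)} nt"
        )
    n_exons = len(exon_coding_parts)
    if intron_lengths is None:
        intron_lengths = [50] * (n_exons - 1)
    if len(intron_lengths) != n_exons - 1:
        raise ValueError("need one intron length per exon junction")
    if any(il < 4 for il in intron_lengths):
        raise ValueError("introns must be >= 4 nt (GT..AG)")

    pieces: list[str] = []
    exon_rel: list[tuple[int, int]] = []
    cursor = 0
    cds_cursor = 0
    for i, part in enumerate(exon_coding_parts):
        exon_seq = cds[cds_cursor : cds_cursor + part]
        cds_cursor += part
        if i == 0:
            exon_seq = utr5 + exon_seq
        if i == n_exons - 1:
            exon_seq = exon_seq + utr3
        exon_rel.append((cursor + 1, cursor + len(exon_seq)))
        pieces.append(exon_seq)
        cursor += len(exon_seq)
        if i < n_exons - 1:
            il = intron_lengths[i]
            pieces.append("GT" + "C" * (il - 4) + "AG")
            cursor += il
    gene_seq = "".join(pieces)
    L = len(gene_seq)
    cds_rel = (len(utr5) + 1, exon_rel[-1][1] - len(utr3))

    flank = "T" * pad
    if strand == "+":
        contig = flank + gene_seq + flank
        exons = [(pad + a, pad + b) for a, b in exon_rel]
        cds_start, cds_end = pad + cds_rel[0], pad + cds_rel[1]
    else:
        contig = flank + str(Seq(gene_seq).reverse_complement()) + flank
        exons = sorted((pad + L - b + 1, pad + L - a + 1) for a, b in exon_rel)
        cds_start = pad + L - cds_rel[1] + 1
        cds_end = pad + L - cds_rel[0] + 1
    genome = Genome({chrom: contig})
    return TranscriptModel(
        gene_id=gene_id,
        transcript_id=transcript_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        genome=genome,
    )


def make_cds(n_codons_total: int, overrides: Optional[dict[int, str]] = None) -> str:
    """ATG + Leu filler + TAA, with 1-based codon overrides (e.g. {84: "CAG"})."""
    if n_codons_total < 2:
        raise ValueError("need at least start + stop")
    codons = ["CTG"] * n_codons_total
    codons[0] = "ATG"
    codons[-1] = "TAA"
    for idx, codon in (overrides or {}).items():
        if not 1 <= idx <= n_codons_total:
            raise ValueError(f"codon override {idx} out of range")
        codons[idx - 1] = codon
    return "".join(codons)
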