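from __future__ import annotations

import numpy as np
import pytest

from recessix.toygenome import build_transcript
from recessix.variant_model import (
    GenotypeCall,
    NonVariantBlock,
    SampleGVCF,
    VariantRecord,
)

GVCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=END,Number=1,Type=Integer,Description="Block end">
##ALT=<ID=NON_REF,Description="Non-variant block">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GQX,Number=1,Type=Integer,Description="Quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def gvcf_text(sample: str, body_lines: list[str]) -> str:
    """Assemble GVCF text from raw data lines (tab-joined by the caller)."""
    return GVCF_HEADER.format(sample=sample) + "".join(
        line + "\n" for line in body_lines
    )


def write_gvcf_text(tmp_path, sample: str, body_lines: list[str]):
    path = tmp_path / f"{sample}.g.vcf"
    path.write_text(gvcf_text(sample, body_lines))
    return path


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def random_toy_transcript(rng: np.random.Generator, strand: str | None = None):
    """A random toy transcript plus its generative layout (for oracles)."""
    n_exons = int(rng.integers(2, 7))
    n_codons = int(rng.integers(40, 120))
    sense = [
        c for c in ("CTG", "GCT", "TAC", "CAA", "GGA", "TCC", "ATT", "CGA")
    ]
    codons = ["ATG"] + [sense[int(rng.integers(len(sense)))] for _ in range(n_codons - 2)]
    codons.append("TAA")
    cds = "".join(codons)
    min_part = 9
    free = len(cds) - min_part * n_exons
    cuts = np.sort(rng.integers(0, free + 1, n_exons - 1))
    parts = (np.diff(np.concatenate([[0], cuts, [free]])) + min_part).tolist()
    introns = [int(rng.integers(10, 60)) for _ in range(n_exons - 1)]
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    model = build_transcript(
        cds,
        exon_coding_parts=parts,
        utr5="A" * int(rng.integers(3, 12)),
        utr3="G" * int(rng.integers(3, 12)),
        intron_lengths=introns,
        strand=strand,
    )
    return model


def make_call(
    sample="S1", zygosity="het", dp=50, gqx=60, ad_ref=None, ad_alt=None
) -> GenotypeCall:
    if ad_alt is None:
        ad_alt = 0 if zygosity == "hom_ref" else dp // 2
    if ad_ref is None:
        ad_ref = dp - ad_alt
    return GenotypeCall(sample, zygosity, dp=dp, gqx=gqx, ad_ref=ad_ref, ad_alt=ad_alt)


def random_sample_gvcf(
    rng: np.random.Generator, sample_id: str, positions: list[int]
) -> SampleGVCF:
    """Random variants at a subset of positions + random non-overlapping blocks."""
    chosen = sorted(
        int(p) for p in rng.choice(positions, size=int(rng.integers(0, len(positions) + 1)), replace=False)
    )
    variants = []
    for pos in chosen:
        ref, alt = ("A", "G") if rng.random() < 0.5 else ("C", "T")
        zyg = ["het", "hom_alt", "hom_ref"][int(rng.integers(3))]
        dp = int(rng.integers(5, 90))
        ad_alt = int(rng.integers(0, dp + 1))
        variants.append(
            (
                VariantRecord("chr1", pos, ref, alt, site_quality=100.0),
                GenotypeCall(sample_id, zyg, dp=dp, gqx=int(rng.integers(0, 99)),
                             ad_ref=dp - ad_alt, ad_alt=ad_alt),
            )
        )
    blocks = []
    cursor = 1
    while cursor < max(positions) + 50 and len(blocks) < 8:
        start = cursor + int(rng.integers(0, 40))
        end = start + int(rng.integers(0, 60))
        if not any(start <= v.pos <= end for v, _ in variants):
            blocks.append(
                NonVariantBlock("chr1", start, end, min_dp=int(rng.integers(0, 80)),
                                min_gqx=int(rng.integers(0, 99)))
            )
        cursor = end + 1 + int(rng.integers(0, 20))
    return SampleGVCF(sample_id=sample_id, variants=variants, blocks=blocks)
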