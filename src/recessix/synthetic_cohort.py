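"""Synthetic exome-cohort generator.

Emulates the statistical inputs of a recessive-discovery exome study with no
external downloads: a toy genome with multi-exon protein-coding genes (valid
ATG…stop CDSs, GT…AG introns, UTRs, both strands), a GTEx-like tissue × gene
expression table in which a configurable fraction of genes is testis-specific,
per-sample GVCFs for patients and controls with background variants drawn from
a rare-shifted allele-frequency spectrum under (optionally inbred)
Hardy-Weinberg genotypes, and one planted homozygous loss-of-function variant
per patient in a testis-specific gene, absent from every control.

What this emulates — and what it does not: genotype sampling, depth/quality
noise and the allele-frequency spectrum are modeled; read-level errors,
alignment artifacts, segmental duplications and real human gene structure are
not. A pipeline that recovers every planted variant here is shown to be
logically correct, not immune to real-data artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .consequence_annotator import Genome, TranscriptModel
from .prioritizer import ControlCohort, ExpressionProfile
from .variant_model import (
    HET,
    HOM_ALT,
    GenotypeCall,
    NonVariantBlock,
    SampleGVCF,
    VariantRecord,
)

logger = logging.getLogger(__name__)

TISSUES = ("testis", "brain", "liver", "lung", "heart", "kidney", "muscle", "ovary")
_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

PLANT_STOP_GAINED = "stop_gained"
PLANT_SPLICE_ACCEPTOR = "splice_acceptor_variant"
PLANT_FRAMESHIFT = "frameshift_variant"
_PLANT_TYPES = (PLANT_STOP_GAINED, PLANT_SPLICE_ACCEPTOR, PLANT_FRAMESHIFT)


@dataclass(frozen=True)
class CohortSimConfig:
    n_patients: int = 2
    n_controls: int = 50
    n_genes: int = 200
    n_background_variants: int = 5000
    # AF spectrum: beta-distributed rare mass plus a common-variant component,
    # so the MAF filters have real work to do.
    af_beta_a: float = 0.2
    af_beta_b: float = 5.0
    common_fraction: float = 0.15
    common_af_low: float = 0.05
    common_af_high: float = 0.5
    # probability both patient alleles are identical by descent; default is
    # the first-cousin-offspring coefficient. Controls are outbred.
    inbreeding_coefficient: float = 0.0625
    fraction_testis_specific: float = 0.1
    planted: tuple[str, ...] = (PLANT_STOP_GAINED, PLANT_SPLICE_ACCEPTOR)
    deletion_fraction: float = 0.06
    mean_dp: float = 60.0
    dp_dispersion: float = 8.0
    gqx_mean: float = 60.0
    gqx_sd: float = 18.0
    novel_af_fraction: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_controls, self.n_genes) < 1:
            raise ValueError("cohort counts must be positive")
        if not 0.0 <= self.inbreeding_coefficient <= 1.0:
            raise ValueError("inbreeding coefficient must lie in [0, 1]")
        for name in ("common_fraction", "fraction_testis_specific",
                     "deletion_fraction", "novel_af_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for p in self.planted:
            if p not in _PLANT_TYPES:
                raise ValueError(f"unknown planted consequence {p!r}")


@dataclass
class Reference:
    genome: Genome
    transcripts: list[TranscriptModel]
    expression: dict[str, ExpressionProfile]
    testis_specific_genes: set[str]

    def transcript_for(self, gene_id: str) -> TranscriptModel:
        return next(t for t in self.transcripts if t.gene_id == gene_id)

    def write_fasta(self, path: str | Path) -> None:
        self.genome.write_fasta(path)

    def write_gff3(self, path: str | Path) -> None:
        write_gff3(self.transcripts, path)

    def write_expression_tsv(self, path: str | Path) -> None:
        rows = []
        for gene_id, prof in self.expression.items():
            rows.append({"gene_id": gene_id, **prof.levels})
        pd.DataFrame(rows, columns=["gene_id", *TISSUES]).to_csv(
            path, sep="\t", index=False, float_format="%.4f"
        )


@dataclass(frozen=True)
class PlantedVariant:
    patient: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    consequence: str
    af_gnomad: float

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TruthTable:
    planted: list[PlantedVariant]

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {p.key for p in self.planted}


@dataclass
class SimulatedCohort:
    samples: list[SampleGVCF]
    patient_ids: list[str]
    control_ids: list[str]
    af_table: pd.DataFrame
    control_cohort: ControlCohort
    truth: TruthTable
    #: truth genotype code per (variant key, sample): 0/1/2 copies of ALT
    genotype_codes: dict[tuple[str, int, str, str], dict[str, int]]
    redraws: int = 0


# ---------------------------------------------------------------------------
# Reference generation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, n)])


def _generate_gene(
    rng: np.random.Generator, gene_id: str, transcript_id: str, chrom: str,
    offset: int, genome_parts: list[str],
) -> TranscriptModel:
    """Append one gene's sequence to genome_parts and return its model.

    The gene is built in transcript orientation (UTR5 + coding exons split by
    GT..AG introns + UTR3) and reverse-complemented onto the genome for minus
    -strand genes.
    """
    n_codons = int(rng.integers(110, 400))  # incl. ATG, excl. stop
    cds = (
        "ATG"
        + "".join(rng.choice(_SENSE_CODONS, n_codons - 1))
        + str(rng.choice(_STOPS))
    )
    # partition the CDS over 3-14 exons, >= 40 coding bases each; short CDSs
    # cap the exon count so the partition stays feasible
    min_part = 40
    n_exons = int(rng.integers(3, min(14, len(cds) // min_part) + 1))
    free = len(cds) - min_part * n_exons
    cuts = np.sort(rng.integers(0, free + 1, n_exons - 1))
    parts = np.diff(np.concatenate([[0], cuts, [free]])) + min_part
    utr5 = _random_seq(rng, int(rng.integers(6, 31)))
    utr3 = _random_seq(rng, int(rng.integers(6, 31)))

    pieces: list[str] = []
    exon_rel: list[tuple[int, int]] = []
    cursor = 0
    cds_cursor = 0
    for i, part in enumerate(parts):
        part = int(part)
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
            intron = "GT" + _random_seq(rng, int(rng.integers(36, 246))) + "AG"
            pieces.append(intron)
            cursor += len(intron)
    gene_seq = "".join(pieces)
    L = len(gene_seq)
    cds_rel = (len(utr5) + 1, exon_rel[-1][1] - len(utr3))

    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "+":
        genome_parts.append(gene_seq)
        exons = [(offset + a, offset + b) for a, b in exon_rel]
        cds_start, cds_end = offset + cds_rel[0], offset + cds_rel[1]
    else:
        genome_parts.append(str(Seq(gene_seq).reverse_complement()))
        exons = sorted((offset + L - b + 1, offset + L - a + 1) for a, b in exon_rel)
        cds_start = offset + L - cds_rel[1] + 1
        cds_end = offset + L - cds_rel[0] + 1
    return TranscriptModel(
        gene_id=gene_id,
        transcript_id=transcript_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        genome=None,  # attached once the contig is assembled
    )


def simulate_reference(cfg: CohortSimConfig, seed: int) -> Reference:
    """Generate the toy genome, transcript models and expression table."""
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    genome_parts: list[str] = []
    models: list[TranscriptModel] = []
    offset = 0
    for i in range(cfg.n_genes):
        spacer = _random_seq(rng, int(rng.integers(80, 121)))
        genome_parts.append(spacer)
        offset += len(spacer)
        gene_id = f"GENE{i + 1:04d}"
        model = _generate_gene(
            rng, gene_id, f"{gene_id}.t1", chrom, offset, genome_parts
        )
        offset = model.span[1]
        models.append(model)
    genome = Genome({chrom: "".join(genome_parts)})
    for m in models:
        m.genome = genome

    n_specific = max(1, round(cfg.fraction_testis_specific * cfg.n_genes))
    specific = set(
        rng.choice([m.gene_id for m in models], size=n_specific, replace=False)
    )
    expression: dict[str, ExpressionProfile] = {}
    for m in models:
        if m.gene_id in specific:
            testis = float(rng.uniform(20, 150))
            levels = {t: float(rng.uniform(0, testis / 10)) for t in TISSUES}
            levels["testis"] = testis
        else:
            base = float(rng.uniform(5, 50))
            levels = {t: base * float(rng.uniform(0.5, 1.5)) for t in TISSUES}
        expression[m.gene_id] = ExpressionProfile(gene_id=m.gene_id, levels=levels)
    return Reference(
        genome=genome,
        transcripts=models,
        expression=expression,
        testis_specific_genes=specific,
    )


def write_gff3(models: Sequence[TranscriptModel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            fh.write(
                f"{m.chrom}\trecessix\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\trecessix\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            cds_seen = 0
            exon_iter = m.exons if m.strand == "+" else list(reversed(m.exons))
            cds_rows = []
            for s, e in exon_iter:
                clo, chi = max(s, m.cds_start), min(e, m.cds_end)
                if clo <= chi:
                    phase = (3 - cds_seen % 3) % 3
                    cds_rows.append((clo, chi, phase))
                    cds_seen += chi - clo + 1
            for k, (s, e) in enumerate(m.exons, start=1):
                fh.write(
                    f"{m.chrom}\trecessix\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon{k};Parent={m.transcript_id}\n"
                )
            for k, (s, e, phase) in enumerate(sorted(cds_rows), start=1):
                fh.write(
                    f"{m.chrom}\trecessix\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID={m.transcript_id}.cds{k};Parent={m.transcript_id}\n"
                )


def read_expression_tsv(path: str | Path) -> dict[str, ExpressionProfile]:
    df = pd.read_csv(path, sep="\t")
    tissues = [c for c in df.columns if c != "gene_id"]
    return {
        r.gene_id: ExpressionProfile(
            gene_id=r.gene_id,
            levels={t: float(getattr(r, t)) for t in tissues},
        )
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# Planted loss-of-function variants


def _plant_stop_gained(
    model: TranscriptModel, rng: np.random.Generator
) -> tuple[VariantRecord, str]:
    cds = model.cds_sequence
    n_codons = len(cds) // 3
    candidates = []
    for codon_index in range(2, n_codons):  # skip ATG and the terminal stop
        codon = cds[(codon_index - 1) * 3 : codon_index * 3]
        for within in range(3):
            for alt in _BASES:
                if alt == codon[within]:
                    continue
                mutant = codon[:within] + alt + codon[within + 1 :]
                if mutant in _STOPS and codon not in _STOPS:
                    cds_pos = (codon_index - 1) * 3 + within + 1
                    candidates.append((cds_pos, codon[within], alt))
    if not candidates:
        raise ValueError(f"{model.gene_id}: no stop-gain site available")
    cds_pos, ref_tx, alt_tx = candidates[int(rng.integers(len(candidates)))]
    gpos = model.genomic_position_of_cds(cds_pos)
    flip = model.strand == "-"
    comp = str.maketrans("ACGT", "TGCA")
    ref_g = ref_tx.translate(comp) if flip else ref_tx
    alt_g = alt_tx.translate(comp) if flip else alt_tx
    return (
        VariantRecord(model.chrom, gpos, ref_g, alt_g, site_quality=2000.0),
        PLANT_STOP_GAINED,
    )


def _plant_splice_acceptor(
    model: TranscriptModel, rng: np.random.Generator
) -> tuple[VariantRecord, str]:
    maps = model._maps
    coding_introns = [
        i
        for i, (donor, acceptor, _, _) in enumerate(model.introns_tx)
        if donor in maps["cds_index"] and acceptor in maps["cds_index"]
    ]
    if not coding_introns:
        raise ValueError(f"{model.gene_id}: no fully coding intron")
    i = coding_introns[int(rng.integers(len(coding_introns)))]
    _, acceptor, _, _ = model.introns_tx[i]
    step = 1 if model.strand == "+" else -1
    gpos = acceptor - 2 * step  # acceptor-2: the A of the intron-terminal AG
    ref_g = model.genome.fetch(model.chrom, gpos, gpos)
    alt_g = "G" if model.strand == "+" else "C"  # A>G on the transcript strand
    return (
        VariantRecord(model.chrom, gpos, ref_g, alt_g, site_quality=2000.0),
        PLANT_SPLICE_ACCEPTOR,
    )


def _plant_frameshift(
    model: TranscriptModel, rng: np.random.Generator
) -> tuple[VariantRecord, str]:
    spans = []
    for s, e in model.exons:
        lo, hi = max(s, model.cds_start), min(e, model.cds_end)
        if hi - lo >= 6:
            spans.append((lo, hi))
    if not spans:
        raise ValueError(f"{model.gene_id}: no exon roomy enough for a deletion")
    lo, hi = spans[int(rng.integers(len(spans)))]
    d = int(rng.choice([1, 2]))
    pos = int(rng.integers(lo, hi - d))
    ref = model.genome.fetch(model.chrom, pos, pos + d)
    return (
        VariantRecord(model.chrom, pos, ref, ref[0], site_quality=2000.0),
        PLANT_FRAMESHIFT,
    )


_PLANTERS = {
    PLANT_STOP_GAINED: _plant_stop_gained,
    PLANT_SPLICE_ACCEPTOR: _plant_splice_acceptor,
    PLANT_FRAMESHIFT: _plant_frameshift,
}


# ---------------------------------------------------------------------------
# Cohort simulation


def simulate_cohort(
    cfg: CohortSimConfig, reference: Reference, seed: int
) -> SimulatedCohort:
    """Draw background + planted variants and assemble per-sample GVCFs.

    Background genotypes follow inbreeding-adjusted Hardy-Weinberg:
    P(hom_alt) = p^2 + F p (1 - p), P(het) = 2 p (1 - p)(1 - F), with F
    applied to patients only. Planted variants are hom_alt in their patient
    and absent everywhere else. Per-call depth is overdispersed
    (negative-binomial) so sub-threshold DP genuinely occurs.
    """
    rng = np.random.default_rng(seed)
    patient_ids = [f"P{i + 1:04d}" for i in range(cfg.n_patients)]
    control_ids = [f"C{i + 1:04d}" for i in range(cfg.n_controls)]
    sample_ids = patient_ids + control_ids
    n_samples = len(sample_ids)
    chrom = reference.transcripts[0].chrom

    # ---- planted variants, one per patient, in distinct testis-specific genes
    specific_genes = sorted(reference.testis_specific_genes)
    if len(specific_genes) < cfg.n_patients:
        raise ValueError("not enough testis-specific genes to plant into")
    gene_choice = rng.choice(len(specific_genes), size=cfg.n_patients, replace=False)
    planted: list[PlantedVariant] = []
    occupied: set[int] = set()
    for k, patient in enumerate(patient_ids):
        consequence = cfg.planted[k % len(cfg.planted)]
        model = reference.transcript_for(specific_genes[int(gene_choice[k])])
        variant, intended = _PLANTERS[consequence](model, rng)
        af = float(rng.uniform(0.002, 0.009))
        planted.append(
            PlantedVariant(
                patient=patient,
                chrom=variant.chrom,
                pos=variant.pos,
                ref=variant.ref,
                alt=variant.alt,
                gene_id=model.gene_id,
                consequence=intended,
                af_gnomad=af,
            )
        )
        occupied.update(range(variant.pos, variant.end + 1))

    # ---- background variant sites
    gene_spans = [m.span for m in reference.transcripts]
    span_lengths = np.array([hi - lo + 1 for lo, hi in gene_spans], dtype=float)
    span_probs = span_lengths / span_lengths.sum()
    records: list[VariantRecord] = []
    seen: set[int] = set(occupied)
    redraws = 0
    target = cfg.n_background_variants
    while len(records) < target:
        gi = int(rng.choice(len(gene_spans), p=span_probs))
        lo, hi = gene_spans[gi]
        pos = int(rng.integers(lo, hi + 1))
        is_del = rng.random() < cfg.deletion_fraction
        d = int(rng.integers(1, 3)) if is_del else 0
        if pos + d > hi:
            continue
        span = set(range(pos, pos + d + 1))
        if span & seen:
            redraws += 1
            continue
        ref = reference.genome.fetch(chrom, pos, pos + d)
        if d == 0:
            alt = _BASES[int(rng.integers(0, 4))]
            while alt == ref:
                alt = _BASES[int(rng.integers(0, 4))]
        else:
            alt = ref[0]
        # integer-valued QUAL survives the float32 VCF round-trip exactly
        records.append(
            VariantRecord(chrom, pos, ref, alt,
                          site_quality=float(rng.integers(100, 3000)))
        )
        seen |= span
    if redraws:
        logger.info("re-drew %d colliding background variants", redraws)

    # ---- allele frequencies and genotype codes
    n_bg = len(records)
    is_common = rng.random(n_bg) < cfg.common_fraction
    afs = np.where(
        is_common,
        rng.uniform(cfg.common_af_low, cfg.common_af_high, n_bg),
        np.clip(rng.beta(cfg.af_beta_a, cfg.af_beta_b, n_bg), 1e-4, 0.999),
    )
    f_vec = np.array(
        [cfg.inbreeding_coefficient] * cfg.n_patients + [0.0] * cfg.n_controls
    )
    p = afs[:, None]
    q = 1.0 - p
    p_hom = p * p + f_vec[None, :] * p * q
    p_het = 2.0 * p * q * (1.0 - f_vec[None, :])
    u = rng.random((n_bg, n_samples))
    codes = np.where(u < p_hom, 2, np.where(u < p_hom + p_het, 1, 0)).astype(np.int8)

    all_records = list(records)
    all_codes = [codes]
    for pv in planted:
        row = np.zeros((1, n_samples), dtype=np.int8)
        row[0, sample_ids.index(pv.patient)] = 2
        all_codes.append(row)
        all_records.append(
            VariantRecord(pv.chrom, pv.pos, pv.ref, pv.alt, site_quality=2000.0)
        )
    codes = np.vstack(all_codes)

    # ---- per-call depth/quality draws for every carried variant
    carrier_idx = np.argwhere(codes > 0)
    n_calls = len(carrier_idx)
    r = cfg.dp_dispersion
    dp = rng.negative_binomial(r, r / (r + cfg.mean_dp), n_calls) + 1
    gqx = np.clip(rng.normal(cfg.gqx_mean, cfg.gqx_sd, n_calls), 0, 99).astype(int)
    is_hom = codes[carrier_idx[:, 0], carrier_idx[:, 1]] == 2
    ad_alt = rng.binomial(dp, np.where(is_hom, 0.97, 0.5))
    ad_ref = dp - ad_alt

    planted_keys = {pv.key: pv for pv in planted}
    per_sample_variants: list[list[tuple[VariantRecord, GenotypeCall]]] = [
        [] for _ in sample_ids
    ]
    for call_i, (vi, sj) in enumerate(carrier_idx):
        variant = all_records[vi]
        sid = sample_ids[sj]
        if variant.key in planted_keys:
            # the planted call is a clean, well-supported homozygote
            c_dp = int(rng.integers(35, 80))
            c_alt = int(round(c_dp * 0.96))
            call = GenotypeCall(sid, HOM_ALT, dp=c_dp, gqx=int(rng.integers(60, 99)),
                                ad_ref=c_dp - c_alt, ad_alt=c_alt)
        else:
            call = GenotypeCall(
                sid,
                HOM_ALT if is_hom[call_i] else HET,
                dp=int(dp[call_i]),
                gqx=int(gqx[call_i]),
                ad_ref=int(ad_ref[call_i]),
                ad_alt=int(ad_alt[call_i]),
            )
        per_sample_variants[sj].append((variant, call))

    # ---- non-variant blocks tiling each gene span, split at own variants
    samples: list[SampleGVCF] = []
    for sj, sid in enumerate(sample_ids):
        variants = sorted(per_sample_variants[sj], key=lambda vc: vc[0].pos)
        cut_spans = [(v.pos, v.end) for v, _ in variants]
        blocks: list[NonVariantBlock] = []
        ci = 0
        for lo, hi in gene_spans:
            cursor = lo
            while ci < len(cut_spans) and cut_spans[ci][1] < lo:
                ci += 1
            cj = ci
            segment_cuts = []
            while cj < len(cut_spans) and cut_spans[cj][0] <= hi:
                segment_cuts.append(cut_spans[cj])
                cj += 1
            for cs, ce in segment_cuts:
                if cursor <= cs - 1:
                    blocks.append(_draw_block(rng, cfg, chrom, cursor, cs - 1))
                cursor = ce + 1
            if cursor <= hi:
                blocks.append(_draw_block(rng, cfg, chrom, cursor, hi))
        sample = SampleGVCF(sample_id=sid, variants=variants, blocks=blocks)
        samples.append(sample)

    # ---- population AF annotations (a slice of the background is "novel")
    af_rows = []
    for i, (variant, af) in enumerate(zip(records, afs)):
        if rng.random() < cfg.novel_af_fraction:
            continue
        af_rows.append(
            {
                "chrom": variant.chrom,
                "pos": variant.pos,
                "ref": variant.ref,
                "alt": variant.alt,
                "af_gnomad": round(float(af), 6),
                "af_1000g": (
                    round(float(min(af * rng.uniform(0.5, 1.5), 0.999)), 6)
                    if rng.random() > 0.3
                    else np.nan
                ),
                "af_esp": (
                    round(float(min(af * rng.uniform(0.5, 1.5), 0.999)), 6)
                    if rng.random() > 0.3
                    else np.nan
                ),
            }
        )
    for pv in planted:
        af_rows.append(
            {
                "chrom": pv.chrom,
                "pos": pv.pos,
                "ref": pv.ref,
                "alt": pv.alt,
                "af_gnomad": round(pv.af_gnomad, 6),
                # any secondary-database value stays strictly under the
                # recessive 1% bound
                "af_1000g": round(float(pv.af_gnomad * rng.uniform(0.5, 1.0)), 6),
                "af_esp": np.nan,
            }
        )
    af_table = pd.DataFrame(
        af_rows, columns=["chrom", "pos", "ref", "alt", "af_gnomad", "af_1000g", "af_esp"]
    ).sort_values(["chrom", "pos", "ref", "alt"], ignore_index=True)

    # ---- truth control counts (from the simulated genotype codes)
    n_pat = cfg.n_patients
    control_counts: dict[tuple[str, int, str, str], tuple[int, int]] = {}
    genotype_codes: dict[tuple[str, int, str, str], dict[str, int]] = {}
    for vi, variant in enumerate(all_records):
        row = codes[vi]
        genotype_codes[variant.key] = {
            sid: int(row[j]) for j, sid in enumerate(sample_ids)
        }
        het = int((row[n_pat:] == 1).sum())
        hom = int((row[n_pat:] == 2).sum())
        if het or hom:
            control_counts[variant.key] = (het, hom)
    control_cohort = ControlCohort(n_controls=cfg.n_controls, counts=control_counts)

    return SimulatedCohort(
        samples=samples,
        patient_ids=patient_ids,
        control_ids=control_ids,
        af_table=af_table,
        control_cohort=control_cohort,
        truth=TruthTable(planted=planted),
        genotype_codes=genotype_codes,
        redraws=redraws,
    )


def _draw_block(
    rng: np.random.Generator, cfg: CohortSimConfig, chrom: str, start: int, end: int
) -> NonVariantBlock:
    r = cfg.dp_dispersion
    return NonVariantBlock(
        chrom=chrom,
        start=start,
        end=end,
        min_dp=int(rng.negative_binomial(r, r / (r + cfg.mean_dp)) + 1),
        min_gqx=int(np.clip(rng.normal(cfg.gqx_mean, cfg.gqx_sd), 0, 99)),
    )


# ---------------------------------------------------------------------------
# GVCF emission


def write_gvcf(
    sample: SampleGVCF, path: str | Path, contig_lengths: Mapping[str, int]
) -> None:
    """Emit one sample's GVCF as VCF 4.2 text (variant rows + END blocks)."""
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.info.add("END", 1, "Integer", "End position of a non-variant block")
    header.add_line('##ALT=<ID=NON_REF,Description="Non-variant block">')
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQX", 1, "Integer", "Conservative genotype quality")
    header.formats.add("AD", "R", "Integer", "Allele-supporting read counts")
    header.add_sample(sample.sample_id)

    events: list[tuple[int, int, object]] = []
    for v, c in sample.variants:
        events.append((v.pos, 0, (v, c)))
    for b in sample.blocks:
        events.append((b.start, 1, b))
    events.sort(key=lambda e: (e[0], e[1]))

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for _, kind, payload in events:
            if kind == 0:
                v, c = payload
                rec = out.new_record(
                    contig=v.chrom,
                    start=v.pos - 1,
                    alleles=(v.ref, v.alt),
                    qual=v.site_quality,
                )
                gt = {HET: (0, 1), HOM_ALT: (1, 1)}.get(c.zygosity, (0, 0))
                rec.samples[0]["GT"] = gt
                rec.samples[0]["DP"] = c.dp
                rec.samples[0]["GQX"] = c.gqx
                rec.samples[0]["AD"] = (c.ad_ref, c.ad_alt)
            else:
                b = payload
                rec = out.new_record(
                    contig=b.chrom, start=b.start - 1, stop=b.end,
                    alleles=("N", "<NON_REF>"), qual=None,
                )
                rec.samples[0]["GT"] = (0, 0)
                rec.samples[0]["DP"] = b.min_dp
                rec.samples[0]["GQX"] = b.min_gqx
            out.write(rec)


# ---------------------------------------------------------------------------
# Recovery scoring


@dataclass(frozen=True)
class PlantedOutcome:
    planted: PlantedVariant
    recovered: bool
    rank: Optional[int]


@dataclass
class RecoveryReport:
    outcomes: list[PlantedOutcome]
    false_positives: list[tuple[str, tuple[str, int, str, str]]]  # (patient, key)

    @property
    def recovery_rate(self) -> float:
        if not self.outcomes:
            return 0.0
        return sum(o.recovered for o in self.outcomes) / len(self.outcomes)


def score_recovery(
    results: Mapping[str, "CascadeResult"], truth: TruthTable
) -> RecoveryReport:
    """Compare per-patient cascade output with the planted truth."""
    outcomes = []
    false_positives = []
    truth_by_patient = {pv.patient: pv for pv in truth.planted}
    for patient, result in results.items():
        keys = result.candidate_keys()
        pv = truth_by_patient.get(patient)
        if pv is not None:
            recovered = pv.key in keys
            outcomes.append(
                PlantedOutcome(
                    planted=pv,
                    recovered=recovered,
                    rank=keys.index(pv.key) + 1 if recovered else None,
                )
            )
        for key in keys:
            if pv is None or key != pv.key:
                false_positives.append((patient, key))
    return RecoveryReport(outcomes=outcomes, false_positives=false_positives)
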