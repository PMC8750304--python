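"""Domain types for variants, genotypes and the multi-sample GVCF merge.

A GVCF carries two kinds of rows: ordinary variant calls, and *non-variant
blocks* — intervals over which the caller asserts a confident homozygous
reference genotype, summarized by the block's minimum depth and quality.
Merging per-sample GVCFs into a cohort table therefore classifies every
(site, sample) pair as either *called* (the sample has an explicit record for
that exact allele), *in-block* (the position falls inside one of the sample's
non-variant blocks, yielding a hom-ref genotype at block depth/quality) or
*uncovered* (genotype unknown).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pysam

NUCLEOTIDES = frozenset("ACGT")

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"
ZYGOSITIES = (HOM_REF, HET, HOM_ALT, MISSING)


class GvcfParseError(ValueError):
    """Raised for malformed or out-of-order GVCF content."""


class MergeError(ValueError):
    """Raised when per-sample GVCFs cannot be merged consistently."""


@dataclass(frozen=True)
class VariantRecord:
    """A normalized bi-allelic SNV or short indel."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    site_quality: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        for allele in (self.ref, self.alt):
            if set(allele) - NUCLEOTIDES:
                raise ValueError(f"allele {allele!r} contains non-ACGT characters")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        # Left-normalization: an indel shares only the single VCF anchor base.
        if len(self.ref) > 1 and len(self.alt) > 1 and self.ref[1] == self.alt[1]:
            raise ValueError(
                f"{self.ref}>{self.alt} shares leading bases beyond the anchor; "
                "record is not normalized"
            )
        if self.site_quality < 0:
            raise ValueError("site_quality must be non-negative")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def end(self) -> int:
        """Last reference base touched by this record (1-based inclusive)."""
        return self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    zygosity: str
    dp: int = 0
    gqx: int = 0
    ad_ref: int = 0
    ad_alt: int = 0

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if min(self.dp, self.gqx, self.ad_ref, self.ad_alt) < 0:
            raise ValueError("dp/gqx/ad fields must be non-negative")
        if self.ad_ref + self.ad_alt > self.dp:
            raise ValueError(
                f"ad_ref + ad_alt = {self.ad_ref + self.ad_alt} exceeds dp = {self.dp}"
            )

    @property
    def is_missing(self) -> bool:
        return self.zygosity == MISSING

    @property
    def carries_alt(self) -> bool:
        return self.zygosity in (HET, HOM_ALT)


MISSING_CALL_FIELDS = dict(zygosity=MISSING, dp=0, gqx=0, ad_ref=0, ad_alt=0)


def missing_call(sample_id: str) -> GenotypeCall:
    return GenotypeCall(sample_id=sample_id, **MISSING_CALL_FIELDS)


@dataclass(frozen=True)
class NonVariantBlock:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    min_dp: int
    min_gqx: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"block start {self.start} > end {self.end}")
        if self.min_dp < 0 or self.min_gqx < 0:
            raise ValueError("block min_dp/min_gqx must be non-negative")

    def covers(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class SampleGVCF:
    """One exome's called variants plus reference-confirmed intervals."""

    sample_id: str
    variants: list[tuple[VariantRecord, GenotypeCall]] = field(default_factory=list)
    blocks: list[NonVariantBlock] = field(default_factory=list)
    gqx_imputed: bool = False  # GQX absent from input, min(GQ, QUAL) substituted

    def validate(self) -> None:
        keys = [v.key for v, _ in self.variants]
        order = [(v.chrom, v.pos) for v, _ in self.variants]
        if order != sorted(order):
            first_bad = next(
                o for i, o in enumerate(order) if i and o < order[i - 1]
            )
            raise GvcfParseError(
                f"{self.sample_id}: variants not sorted; first offending position "
                f"{first_bad[0]}:{first_bad[1]}"
            )
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise GvcfParseError(f"{self.sample_id}: duplicate record at {dup}")
        by_chrom: dict[str, list[NonVariantBlock]] = {}
        for b in self.blocks:
            by_chrom.setdefault(b.chrom, []).append(b)
        for chrom, blist in by_chrom.items():
            spans = [(b.start, b.end) for b in blist]
            if spans != sorted(spans):
                raise GvcfParseError(f"{self.sample_id}: blocks on {chrom} not sorted")
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise GvcfParseError(
                        f"{self.sample_id}: overlapping blocks "
                        f"{chrom}:{s1}-{e1} and {chrom}:{s2}-{e2}"
                    )
        for v, _ in self.variants:
            b = self._covering_block(v.chrom, v.pos)
            if b is not None and b.start < v.pos < b.end:
                raise GvcfParseError(
                    f"{self.sample_id}: variant {v.chrom}:{v.pos} lies strictly "
                    f"inside non-variant block {b.chrom}:{b.start}-{b.end}"
                )

    def _block_index(self) -> dict[str, tuple[list[int], list[NonVariantBlock]]]:
        index: dict[str, tuple[list[int], list[NonVariantBlock]]] = {}
        for b in self.blocks:
            starts, blist = index.setdefault(b.chrom, ([], []))
            starts.append(b.start)
            blist.append(b)
        return index

    def _covering_block(self, chrom: str, pos: int) -> NonVariantBlock | None:
        return find_covering_block(self._block_index(), chrom, pos)


def find_covering_block(
    index: Mapping[str, tuple[list[int], list[NonVariantBlock]]],
    chrom: str,
    pos: int,
) -> NonVariantBlock | None:
    """Locate the (sorted, non-overlapping) block covering chrom:pos, if any."""
    entry = index.get(chrom)
    if entry is None:
        return None
    starts, blocks = entry
    i = bisect.bisect_right(starts, pos) - 1
    if i >= 0 and blocks[i].end >= pos:
        return blocks[i]
    return None


@dataclass
class CohortVariantTable:
    """Merged site × sample genotype matrix, the substrate of every filter."""

    sites: list[VariantRecord]
    sample_ids: list[str]
    genotypes: list[list[GenotypeCall]]  # genotypes[i][j]: site i, sample j

    def __post_init__(self) -> None:
        if len(self.genotypes) != len(self.sites):
            raise ValueError("one genotype row required per site")
        for row in self.genotypes:
            if len(row) != len(self.sample_ids):
                raise ValueError("one genotype per sample required at every site")
        keys = [s.key for s in self.sites]
        if keys != sorted(keys):
            raise ValueError("sites must be sorted by (chrom, pos, ref, alt)")
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate site in cohort table")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in cohort table") from None

    def call(self, site_index: int, sample_id: str) -> GenotypeCall:
        return self.genotypes[site_index][self.sample_index(sample_id)]

    def rows(self) -> Iterator[tuple[VariantRecord, dict[str, GenotypeCall]]]:
        for site, row in zip(self.sites, self.genotypes):
            yield site, dict(zip(self.sample_ids, row))


# ---------------------------------------------------------------------------
# GVCF reading


def _decode_gt(gt: tuple | None, alt_index: int) -> str:
    if gt is None or any(a is None for a in gt):
        return MISSING
    hits = sum(1 for a in gt if a == alt_index)
    if hits >= 2:
        return HOM_ALT
    if hits == 1:
        return HET
    return HOM_REF


def _sample_gqx(sample, qual: float | None) -> tuple[int, bool]:
    """GQX if present; otherwise the conservative min(GQ, site QUAL) fallback."""
    gqx = sample.get("GQX")
    if gqx is not None:
        return int(gqx), False
    gq = sample.get("GQ")
    candidates = [v for v in (gq, qual) if v is not None]
    if not candidates:
        return 0, True
    return int(min(candidates)), True


def read_gvcf(path: str | Path) -> SampleGVCF:
    """Parse a single-sample GVCF (VCF 4.2 text, optionally bgzipped).

    Non-variant blocks are rows with no ALT allele (or ``<NON_REF>``) carrying
    ``INFO/END``. Multi-allelic rows are decomposed into one bi-allelic
    :class:`VariantRecord` per ALT.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise GvcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    with vcf:
        if len(vcf.header.samples) != 1:
            raise GvcfParseError(
                f"{path}: expected exactly 1 sample, found {len(vcf.header.samples)}"
            )
        sample_id = vcf.header.samples[0]
        out = SampleGVCF(sample_id=sample_id)
        gqx_imputed = False
        # data lines start after the header
        lineno = str(vcf.header).count("\n")
        for rec in vcf:
            lineno += 1
            try:
                sample = rec.samples[0]
                alts = [a for a in (rec.alts or ()) if a != "<NON_REF>"]
                if not alts:
                    end = rec.info.get("END", rec.stop)
                    dp = sample.get("DP") or 0
                    gqx, imputed = _sample_gqx(sample, rec.qual)
                    gqx_imputed |= imputed
                    out.blocks.append(
                        NonVariantBlock(
                            chrom=rec.chrom,
                            start=rec.pos,
                            end=int(end),
                            min_dp=int(dp),
                            min_gqx=gqx,
                        )
                    )
                    continue
                ad = sample.get("AD")
                dp = int(sample.get("DP") or 0)
                gqx, imputed = _sample_gqx(sample, rec.qual)
                gqx_imputed |= imputed
                for ai, alt in enumerate(alts, start=1):
                    variant = VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        site_quality=float(rec.qual or 0.0),
                    )
                    ad_ref = int(ad[0]) if ad and ad[0] is not None else 0
                    ad_alt = int(ad[ai]) if ad and len(ad) > ai and ad[ai] is not None else 0
                    call = GenotypeCall(
                        sample_id=sample_id,
                        zygosity=_decode_gt(sample.get("GT"), ai),
                        dp=max(dp, ad_ref + ad_alt),
                        gqx=gqx,
                        ad_ref=ad_ref,
                        ad_alt=ad_alt,
                    )
                    out.variants.append((variant, call))
            except (ValueError, KeyError) as exc:
                raise GvcfParseError(f"{path}: line {lineno}: {exc}") from exc
    out.gqx_imputed = gqx_imputed
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Merge


def merge_gvcfs(samples: Sequence[SampleGVCF]) -> CohortVariantTable:
    """Merge per-sample GVCFs into one cohort table.

    For every union site and every sample: keep the sample's own call for that
    exact allele if it has one; otherwise assert hom-ref at block depth/quality
    when the position falls inside one of the sample's non-variant blocks;
    otherwise the genotype is missing. A site inside a sample's block but with
    an allele the sample never called is still hom-ref for that sample — block
    semantics assert reference confidence over the whole interval.
    """
    if not samples:
        raise MergeError("at least one sample is required")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise MergeError(f"duplicate sample_id {dup!r}")
    for s in samples:
        s.validate()

    order = {sid: samples[i] for i, sid in enumerate(ids)}
    sample_ids = sorted(ids)

    site_map: dict[tuple[str, int, str, str], VariantRecord] = {}
    call_map: dict[str, dict[tuple[str, int, str, str], GenotypeCall]] = {}
    for s in samples:
        calls: dict[tuple[str, int, str, str], GenotypeCall] = {}
        for variant, call in s.variants:
            if variant.key in calls:
                raise MergeError(
                    f"{s.sample_id}: conflicting records at "
                    f"{variant.chrom}:{variant.pos} {variant.ref}>{variant.alt}"
                )
            calls[variant.key] = call
            prev = site_map.get(variant.key)
            if prev is None or variant.site_quality > prev.site_quality:
                site_map[variant.key] = variant
        call_map[s.sample_id] = calls

    block_indexes = {s.sample_id: s._block_index() for s in samples}

    sites = [site_map[k] for k in sorted(site_map)]
    genotypes: list[list[GenotypeCall]] = []
    for site in sites:
        row: list[GenotypeCall] = []
        for sid in sample_ids:
            call = call_map[sid].get(site.key)
            if call is None:
                block = find_covering_block(block_indexes[sid], site.chrom, site.pos)
                if block is not None:
                    call = GenotypeCall(
                        sample_id=sid,
                        zygosity=HOM_REF,
                        dp=block.min_dp,
                        gqx=block.min_gqx,
                        ad_ref=block.min_dp,
                        ad_alt=0,
                    )
                else:
                    call = missing_call(sid)
            row.append(call)
        genotypes.append(row)
    del order
    return CohortVariantTable(sites=sites, sample_ids=sample_ids, genotypes=genotypes)


def to_sample_gvcfs(table: CohortVariantTable) -> list[SampleGVCF]:
    """Project a cohort table back onto per-sample GVCFs.

    Non-missing calls (including explicit hom-ref) become variant records;
    missing calls are simply uncovered. ``merge_gvcfs`` of the projections
    reproduces the table exactly.
    """
    out = []
    for j, sid in enumerate(table.sample_ids):
        variants = [
            (site, row[j])
            for site, row in zip(table.sites, table.genotypes)
            if not row[j].is_missing
        ]
        out.append(SampleGVCF(sample_id=sid, variants=variants))
    return out


# ---------------------------------------------------------------------------
# Cohort TSV round-trip

COHORT_TSV_SCHEMA_VERSION = "1"
_FIXED_COLUMNS = ("chrom", "pos", "ref", "alt", "qual")
_GT_TOKEN = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_TOKEN_GT = {v: k for k, v in _GT_TOKEN.items()}


def _format_call(call: GenotypeCall) -> str:
    if call.is_missing:
        return "./."
    return (
        f"{_GT_TOKEN[call.zygosity]}:{call.dp}:{call.gqx}:{call.ad_ref},{call.ad_alt}"
    )


def _parse_call(token: str, sample_id: str) -> GenotypeCall:
    if token == "./.":
        return missing_call(sample_id)
    gt, dp, gqx, ad = token.split(":")
    ad_ref, ad_alt = ad.split(",")
    return GenotypeCall(
        sample_id=sample_id,
        zygosity=_TOKEN_GT[gt],
        dp=int(dp),
        gqx=int(gqx),
        ad_ref=int(ad_ref),
        ad_alt=int(ad_alt),
    )


def write_cohort_tsv(table: CohortVariantTable, path: str | Path) -> None:
    """Write the cohort table as TSV (one row per site; schema is versioned)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"##cohort_tsv_schema={COHORT_TSV_SCHEMA_VERSION}\n")
        fh.write("\t".join(_FIXED_COLUMNS + tuple(table.sample_ids)) + "\n")
        for site, row in zip(table.sites, table.genotypes):
            cells = [
                site.chrom,
                str(site.pos),
                site.ref,
                site.alt,
                repr(site.site_quality),
            ]
            cells.extend(_format_call(c) for c in row)
            fh.write("\t".join(cells) + "\n")


def read_cohort_tsv(path: str | Path) -> CohortVariantTable:
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    lines = [ln for ln in lines if not ln.startswith("##")]
    if not lines:
        raise ValueError(f"{path}: no header line")
    header = lines[0].split("\t")
    if tuple(header[: len(_FIXED_COLUMNS)]) != _FIXED_COLUMNS:
        raise ValueError(f"{path}: unexpected column header {header[:5]}")
    sample_ids = header[len(_FIXED_COLUMNS) :]
    sites, genotypes = [], []
    for ln in lines[1:]:
        cells = ln.split("\t")
        sites.append(
            VariantRecord(
                chrom=cells[0],
                pos=int(cells[1]),
                ref=cells[2],
                alt=cells[3],
                site_quality=float(cells[4]),
            )
        )
        genotypes.append(
            [
                _parse_call(tok, sid)
                for tok, sid in zip(cells[len(_FIXED_COLUMNS) :], sample_ids)
            ]
        )
    return CohortVariantTable(sites=sites, sample_ids=sample_ids, genotypes=genotypes)
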