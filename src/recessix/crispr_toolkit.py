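"""Dual-gRNA intra-exonic frameshift-deletion design and PCR genotyping math.

The knockout strategy excises ~100 bp between two guide cut sites inside a
single coding exon near the start of the gene. A deleted length that is not a
multiple of 3 shifts the reading frame and truncates the protein. Genotyping
is a single PCR across the deletion: the knockout allele's amplicon is shorter
than the wild-type amplicon by exactly the deleted length, so WT / HET / HOM
animals are read straight off a gel's band pattern.

Guide *sequence* selection (PAM scanning, off-target scoring) is deliberately
behind an interface stub: only the deletion geometry is modeled here.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Protocol

from .consequence_annotator import TranscriptModel


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class DeletionDesign:
    """An intra-exonic deletion spanning cDNA coordinates cut5..cut3 inclusive."""

    gene_id: str
    target_exon_index: int  # 1-based, transcript order
    cut5: int  # cDNA (c.) coordinate of first deleted base
    cut3: int  # cDNA coordinate of last deleted base
    note: str = ""

    def __post_init__(self) -> None:
        if self.cut5 < 1 or self.cut3 < self.cut5:
            raise DesignError(f"bad deletion span {self.cut5}..{self.cut3}")

    @property
    def length(self) -> int:
        return self.cut3 - self.cut5 + 1

    @property
    def frameshift(self) -> bool:
        return self.length % 3 != 0

    @property
    def guide_spacing(self) -> int:
        """Distance between the two cut sites = deleted length."""
        return self.length

    @property
    def hgvs_c(self) -> str:
        return f"c.{self.cut5}_{self.cut3}del"


@dataclass(frozen=True)
class GenotypingAssay:
    wt_amplicon: int
    ko_amplicon: int
    primer_pair: str = ""

    def __post_init__(self) -> None:
        if self.wt_amplicon <= 0 or self.ko_amplicon <= 0:
            raise DesignError("amplicon sizes must be positive")
        if self.ko_amplicon >= self.wt_amplicon:
            raise DesignError("KO amplicon must be shorter than WT amplicon")

    @property
    def deletion_length(self) -> int:
        return self.wt_amplicon - self.ko_amplicon


class GuidePicker(Protocol):
    """Interface stub for gRNA sequence selection; geometry only is modeled."""

    def pick(self, exon_sequence: str, cut_position: int) -> str: ...


def exon_coding_span(model: TranscriptModel, exon_index: int) -> tuple[int, int]:
    """cDNA (c.) coordinates covered by coding bases of the given exon."""
    if not 1 <= exon_index <= model.n_exons:
        raise DesignError(
            f"{model.gene_id}: exon {exon_index} outside 1..{model.n_exons}"
        )
    maps = model._maps
    cds = [
        maps["cds_index"][g]
        for g, ei in maps["exon_of"].items()
        if ei == exon_index and g in maps["cds_index"]
    ]
    if not cds:
        raise DesignError(f"{model.gene_id}: exon {exon_index} has no coding bases")
    return min(cds), max(cds)


def design_deletion(
    model: TranscriptModel,
    exon_index: int,
    approx_spacing: int = 100,
    spacing_tolerance: int = 15,
    seed: int = 0,
) -> DeletionDesign:
    """Place a frameshift deletion of ~approx_spacing bp inside one coding exon.

    The deleted length is the frameshift-compatible (length % 3 != 0) value
    closest to approx_spacing within spacing_tolerance that fits in the exon's
    coding span; among tied placements the start is drawn with the given seed,
    so the design is deterministic for a fixed seed.
    """
    lo, hi = exon_coding_span(model, exon_index)
    span = hi - lo + 1
    lengths = [
        L
        for L in range(
            max(1, approx_spacing - spacing_tolerance),
            approx_spacing + spacing_tolerance + 1,
        )
        if L % 3 != 0 and L <= span
    ]
    if span < max(1, approx_spacing - spacing_tolerance):
        raise DesignError(
            f"{model.gene_id}: exon {exon_index} coding span {span} bp is too "
            f"short for a ~{approx_spacing} bp deletion"
        )
    if not lengths:
        raise DesignError(
            f"{model.gene_id}: no frameshift-compatible length within "
            f"{approx_spacing}±{spacing_tolerance} bp fits exon {exon_index}"
        )
    length = min(lengths, key=lambda L: (abs(L - approx_spacing), L))
    starts = range(lo, hi - length + 2)
    start = random.Random(seed).choice(list(starts))
    return DeletionDesign(
        gene_id=model.gene_id,
        target_exon_index=exon_index,
        cut5=start,
        cut3=start + length - 1,
    )


def predict_amplicons(
    wt_amplicon: int,
    deletion: DeletionDesign | int,
    primer_pair: str = "",
) -> GenotypingAssay:
    """KO amplicon size for a PCR spanning the deletion: wt - deleted length."""
    length = deletion.length if isinstance(deletion, DeletionDesign) else int(deletion)
    if length <= 0:
        raise DesignError("deletion length must be positive")
    if length >= wt_amplicon:
        raise DesignError(
            f"deletion of {length} bp does not fit inside a {wt_amplicon} bp amplicon"
        )
    return GenotypingAssay(
        wt_amplicon=wt_amplicon,
        ko_amplicon=wt_amplicon - length,
        primer_pair=primer_pair,
    )


WT = "WT"
HET = "HET"
HOM = "HOM"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class BandCall:
    genotype: str
    matched_wt: tuple[int, ...] = ()
    matched_ko: tuple[int, ...] = ()
    unmatched: tuple[int, ...] = ()

    @property
    def report(self) -> str:
        return (
            f"{self.genotype}: wt bands {list(self.matched_wt)}, "
            f"ko bands {list(self.matched_ko)}, unmatched {list(self.unmatched)}"
        )


def call_genotype_from_bands(
    observed: Iterable[int],
    assay: GenotypingAssay,
    tolerance: int = 10,
) -> BandCall:
    """Call WT / HET / HOM from observed gel band sizes (± tolerance bp).

    A band matching neither allele yields UNCLASSIFIED with the offending
    sizes reported rather than a forced call.
    """
    bands = sorted(set(int(b) for b in observed))
    if not bands:
        raise ValueError("at least one observed band is required")
    wt_hits, ko_hits, unmatched = [], [], []
    for b in bands:
        d_wt = abs(b - assay.wt_amplicon)
        d_ko = abs(b - assay.ko_amplicon)
        if d_wt <= tolerance and d_wt <= d_ko:
            wt_hits.append(b)
        elif d_ko <= tolerance:
            ko_hits.append(b)
        else:
            unmatched.append(b)
    if unmatched:
        genotype = UNCLASSIFIED
    elif wt_hits and ko_hits:
        genotype = HET
    elif wt_hits:
        genotype = WT
    else:
        genotype = HOM
    return BandCall(
        genotype=genotype,
        matched_wt=tuple(wt_hits),
        matched_ko=tuple(ko_hits),
        unmatched=tuple(unmatched),
    )
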