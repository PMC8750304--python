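"""Filter-and-rank cascade for recessive loss-of-function candidates.

The cascade converts an annotated cohort table into a per-patient candidate
list under an autosomal-recessive model: keep HIGH-impact variants that are
homozygous in the proband, rare in every population database (gnomAD > 1%,
1000 Genomes > 3% or ESP6500 > 5% are filtered; the recessive model further
requires AF < 1%), absent from a locally sequenced control cohort, and in a
gene highly and specifically expressed in the target tissue (testis). Each
excluded variant is logged with the first failing predicate so the whole run
is auditable: |input| = |candidates| + |exclusions| always.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .consequence_annotator import HIGH, Consequence, impact_rank
from .variant_model import GenotypeCall, HOM_ALT, VariantRecord


@dataclass(frozen=True)
class FrequencyAnnotations:
    af_gnomad: Optional[float] = None
    af_1000g: Optional[float] = None
    af_esp: Optional[float] = None

    def __post_init__(self) -> None:
        for name, v in self.items():
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")

    def items(self):
        return (
            ("af_gnomad", self.af_gnomad),
            ("af_1000g", self.af_1000g),
            ("af_esp", self.af_esp),
        )

    @property
    def max_present(self) -> float:
        """Largest known AF; 0 for a variant absent from every database (novel)."""
        present = [v for _, v in self.items() if v is not None]
        return max(present) if present else 0.0

    @property
    def is_novel(self) -> bool:
        return all(v is None for _, v in self.items())


@dataclass
class ControlCohort:
    """Genotype counts over locally sequenced control exomes."""

    n_controls: int
    counts: dict[tuple[str, int, str, str], tuple[int, int]]  # key -> (het, hom_alt)

    def __post_init__(self) -> None:
        for key, (het, hom) in self.counts.items():
            if het < 0 or hom < 0 or het + hom > self.n_controls:
                raise ValueError(f"control counts {het}+{hom} exceed n={self.n_controls}")

    def carriers(self, key: tuple[str, int, str, str]) -> int:
        het, hom = self.counts.get(key, (0, 0))
        return het + hom

    @classmethod
    def from_table(cls, table, control_ids: Sequence[str]) -> "ControlCohort":
        """Derive control counts from the control columns of a cohort table."""
        idx = [table.sample_index(s) for s in control_ids]
        counts = {}
        for site, row in zip(table.sites, table.genotypes):
            het = sum(1 for j in idx if row[j].zygosity == "het")
            hom = sum(1 for j in idx if row[j].zygosity == HOM_ALT)
            if het or hom:
                counts[site.key] = (het, hom)
        return cls(n_controls=len(control_ids), counts=counts)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ControlCohort":
        df = pd.read_csv(path, sep="\t", comment="#")
        n = int(df.attrs.get("n_controls", 0)) if df.attrs else 0
        with Path(path).open() as fh:
            first = fh.readline()
        if first.startswith("#n_controls="):
            n = int(first.strip().split("=", 1)[1])
        counts = {
            (r.chrom, int(r.pos), r.ref, r.alt): (int(r.het), int(r.hom_alt))
            for r in df.itertuples()
        }
        return cls(n_controls=n, counts=counts)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"#n_controls={self.n_controls}\n")
            fh.write("chrom\tpos\tref\talt\thet\thom_alt\n")
            for (chrom, pos, ref, alt), (het, hom) in sorted(self.counts.items()):
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{het}\t{hom}\n")


@dataclass(frozen=True)
class ExpressionProfile:
    gene_id: str
    levels: Mapping[str, float]  # tissue -> TPM-like level

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.levels.values()):
            raise ValueError("expression levels must be non-negative")


@dataclass(frozen=True)
class PrioritizationConfig:
    max_af_gnomad: float = 0.01
    max_af_1000g: float = 0.03
    max_af_esp: float = 0.05
    recessive_max_af: float = 0.01
    require_absent_in_controls: bool = True
    max_control_carriers: int = 0
    min_specificity_ratio: float = 5.0
    min_target_tpm: float = 1.0
    impact_floor: str = HIGH
    target_tissue: str = "testis"

    def __post_init__(self) -> None:
        for name in ("max_af_gnomad", "max_af_1000g", "max_af_esp", "recessive_max_af"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.min_specificity_ratio <= 0:
            raise ValueError("min_specificity_ratio must be positive")


@dataclass
class AnnotatedVariant:
    """A cohort site joined to everything the cascade needs."""

    variant: VariantRecord
    gene_id: str
    consequence: Consequence
    frequencies: FrequencyAnnotations
    genotypes: Mapping[str, GenotypeCall]
    specificity_ratio: float = 0.0
    is_tissue_specific: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.variant.key


# ---------------------------------------------------------------------------
# Predicates


def apply_frequency_filter(
    v: AnnotatedVariant, cfg: PrioritizationConfig = PrioritizationConfig()
) -> bool:
    """True when retained. Filtered iff any database AF exceeds its cap;
    a missing value is treated as 0 (novel variant)."""
    f = v.frequencies
    return not (
        (f.af_gnomad or 0.0) > cfg.max_af_gnomad
        or (f.af_1000g or 0.0) > cfg.max_af_1000g
        or (f.af_esp or 0.0) > cfg.max_af_esp
    )


def apply_cohort_filter(
    v: AnnotatedVariant,
    cohort: ControlCohort,
    cfg: PrioritizationConfig = PrioritizationConfig(),
) -> bool:
    """True when retained: no more than max_control_carriers controls carry
    the ALT allele ("absent" = zero carriers under the default config)."""
    if not cfg.require_absent_in_controls:
        return True
    if cohort.n_controls == 0:
        warnings.warn(
            "control cohort is empty; cohort filter retains everything",
            stacklevel=2,
        )
        return True
    return cohort.carriers(v.key) <= cfg.max_control_carriers


def apply_recessive_model(
    v: AnnotatedVariant,
    proband: str,
    cfg: PrioritizationConfig = PrioritizationConfig(),
) -> bool:
    """True iff the proband is homozygous-ALT and the variant is rare
    (largest known population AF strictly below recessive_max_af)."""
    if proband not in v.genotypes:
        raise KeyError(f"proband {proband!r} absent from genotype map")
    call = v.genotypes[proband]
    return call.zygosity == HOM_ALT and v.frequencies.max_present < cfg.recessive_max_af


def compute_tissue_specificity(
    profile: ExpressionProfile,
    target: str = "testis",
    min_specificity_ratio: float = 5.0,
    min_target_tpm: float = 1.0,
) -> tuple[float, bool]:
    """Specificity ratio = target level / max(other tissues' levels).

    Ratio is +inf when only the target tissue is expressed, and 0 when the
    target itself is silent. A gene is called specific when the ratio meets
    min_specificity_ratio and the target level meets min_target_tpm.
    """
    if not profile.levels:
        raise ValueError(f"{profile.gene_id}: empty expression profile")
    if target not in profile.levels:
        raise ValueError(f"{profile.gene_id}: target tissue {target!r} not profiled")
    level = profile.levels[target]
    others = [v for t, v in profile.levels.items() if t != target]
    max_other = max(others) if others else 0.0
    if level == 0:
        ratio = 0.0
    elif max_other == 0:
        ratio = math.inf
    else:
        ratio = level / max_other
    is_specific = ratio >= min_specificity_ratio and level >= min_target_tpm
    return ratio, is_specific


# ---------------------------------------------------------------------------
# Cascade

PREDICATE_ORDER = (
    "genotype_quality",
    "impact",
    "frequency",
    "control_cohort",
    "recessive_model",
    "tissue_specificity",
)


@dataclass(frozen=True)
class Exclusion:
    key: tuple[str, int, str, str]
    gene_id: str
    failed_predicate: str


@dataclass
class CascadeResult:
    proband: str
    candidates: list[AnnotatedVariant]
    exclusions: list[Exclusion]

    def candidate_keys(self) -> list[tuple[str, int, str, str]]:
        return [c.key for c in self.candidates]


def evaluate_predicates(
    v: AnnotatedVariant,
    proband: str,
    cohort: ControlCohort,
    cfg: PrioritizationConfig,
) -> dict[str, bool]:
    """Every predicate's verdict for one variant (used by cascade and audit)."""
    call = v.genotypes.get(proband)
    if call is None:
        raise KeyError(f"proband {proband!r} absent from genotype map")
    return {
        "genotype_quality": not call.is_missing,
        "impact": impact_rank(v.consequence.impact_tier) <= impact_rank(cfg.impact_floor),
        "frequency": apply_frequency_filter(v, cfg),
        "control_cohort": apply_cohort_filter(v, cohort, cfg),
        "recessive_model": apply_recessive_model(v, proband, cfg),
        "tissue_specificity": v.is_tissue_specific,
    }


def run_cascade(
    variants: Iterable[AnnotatedVariant],
    proband: str,
    cohort: ControlCohort,
    cfg: PrioritizationConfig = PrioritizationConfig(),
) -> CascadeResult:
    """Apply every predicate to every variant; rank the survivors.

    The candidate set is the conjunction of all predicates, so it does not
    depend on the order in which they are applied; the exclusion log names the
    first failing predicate in the documented PREDICATE_ORDER.
    """
    candidates, exclusions = [], []
    for v in variants:
        verdicts = evaluate_predicates(v, proband, cohort, cfg)
        failed = next((p for p in PREDICATE_ORDER if not verdicts[p]), None)
        if failed is None:
            candidates.append(v)
        else:
            exclusions.append(Exclusion(v.key, v.gene_id, failed))
    candidates.sort(
        key=lambda v: (
            impact_rank(v.consequence.impact_tier),
            -v.specificity_ratio,
            v.frequencies.max_present,
            v.key,
        )
    )
    return CascadeResult(proband=proband, candidates=candidates, exclusions=exclusions)


def candidates_to_frame(result: CascadeResult) -> pd.DataFrame:
    rows = []
    for rank, v in enumerate(result.candidates, start=1):
        rows.append(
            {
                "rank": rank,
                "proband": result.proband,
                "chrom": v.variant.chrom,
                "pos": v.variant.pos,
                "ref": v.variant.ref,
                "alt": v.variant.alt,
                "gene_id": v.gene_id,
                "so_term": v.consequence.so_term,
                "impact": v.consequence.impact_tier,
                "hgvs_c": v.consequence.hgvs_c,
                "hgvs_p": v.consequence.hgvs_p,
                "max_af": v.frequencies.max_present,
                "novel": v.frequencies.is_novel,
                "specificity_ratio": v.specificity_ratio,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "proband", "chrom", "pos", "ref", "alt", "gene_id",
            "so_term", "impact", "hgvs_c", "hgvs_p", "max_af", "novel",
            "specificity_ratio",
        ],
    )


def exclusions_to_frame(result: CascadeResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "proband": result.proband,
                "chrom": e.key[0],
                "pos": e.key[1],
                "ref": e.key[2],
                "alt": e.key[3],
                "gene_id": e.gene_id,
                "failed_predicate": e.failed_predicate,
            }
            for e in result.exclusions
        ],
        columns=["proband", "chrom", "pos", "ref", "alt", "gene_id", "failed_predicate"],
    )
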