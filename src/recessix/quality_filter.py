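"""Per-genotype-call quality gate.

A call is discarded when its read depth is below 10, its conservative genotype
quality (GQX) is below 20, or fewer than 15% of its informative reads support
the ALT allele. Hom-ref calls are exempt from the ALT-fraction test, and a
failing call is set to missing rather than deleting the whole cohort site, so
one bad sample cannot erase a site for everyone else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .variant_model import CohortVariantTable, GenotypeCall, missing_call

REASON_MISSING = "missing_genotype"
REASON_LOW_DP = "low_dp"
REASON_LOW_GQX = "low_gqx"
REASON_LOW_ALT_FRACTION = "low_alt_fraction"
REASON_NO_INFORMATIVE_READS = "no_informative_reads"
REASON_SITE_DROPPED = "site_dropped_all_calls_missing"


@dataclass(frozen=True)
class QualityThresholds:
    min_dp: int = 10
    min_gqx: int = 20
    min_alt_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.min_dp < 0 or self.min_gqx < 0:
            raise ValueError("min_dp and min_gqx must be non-negative")
        if not 0.0 <= self.min_alt_fraction <= 1.0:
            raise ValueError("min_alt_fraction must lie in [0, 1]")


def failure_reason(
    call: GenotypeCall, thresholds: QualityThresholds = QualityThresholds()
) -> Optional[str]:
    """Reason code for a failing call, or None when the call passes.

    Thresholds are inclusive: dp == min_dp passes, as does an ALT fraction of
    exactly min_alt_fraction — the discard rule is strictly "less than".
    """
    if call.is_missing:
        return REASON_MISSING
    if call.dp < thresholds.min_dp:
        return REASON_LOW_DP
    if call.gqx < thresholds.min_gqx:
        return REASON_LOW_GQX
    if call.carries_alt and thresholds.min_alt_fraction > 0:
        informative = call.ad_ref + call.ad_alt
        if informative == 0:
            return REASON_NO_INFORMATIVE_READS
        if call.ad_alt / informative < thresholds.min_alt_fraction:
            return REASON_LOW_ALT_FRACTION
    return None


def call_passes(
    call: GenotypeCall, thresholds: QualityThresholds = QualityThresholds()
) -> bool:
    return failure_reason(call, thresholds) is None


@dataclass(frozen=True)
class CallAudit:
    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    reason: str


@dataclass
class QualityFilterResult:
    table: CohortVariantTable
    audit: list[CallAudit] = field(default_factory=list)

    def write_audit_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("chrom\tpos\tref\talt\tsample_id\treason\n")
            for a in self.audit:
                fh.write(
                    f"{a.chrom}\t{a.pos}\t{a.ref}\t{a.alt}\t{a.sample_id}\t{a.reason}\n"
                )


def apply_quality_filter(
    table: CohortVariantTable,
    thresholds: QualityThresholds = QualityThresholds(),
) -> QualityFilterResult:
    """Set failing calls to missing; drop sites once every call is missing.

    Already-missing input calls are left untouched and not re-audited, which
    makes the filter idempotent.
    """
    sites, genotypes, audit = [], [], []
    for site, row in zip(table.sites, table.genotypes):
        new_row = []
        for call in row:
            if call.is_missing:
                new_row.append(call)
                continue
            reason = failure_reason(call, thresholds)
            if reason is None:
                new_row.append(call)
            else:
                audit.append(
                    CallAudit(
                        chrom=site.chrom,
                        pos=site.pos,
                        ref=site.ref,
                        alt=site.alt,
                        sample_id=call.sample_id,
                        reason=reason,
                    )
                )
                new_row.append(missing_call(call.sample_id))
        if all(c.is_missing for c in new_row):
            audit.append(
                CallAudit(
                    chrom=site.chrom,
                    pos=site.pos,
                    ref=site.ref,
                    alt=site.alt,
                    sample_id="*",
                    reason=REASON_SITE_DROPPED,
                )
            )
            continue
        sites.append(site)
        genotypes.append(new_row)
    filtered = CohortVariantTable(
        sites=sites, sample_ids=list(table.sample_ids), genotypes=genotypes
    )
    return QualityFilterResult(table=filtered, audit=audit)
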