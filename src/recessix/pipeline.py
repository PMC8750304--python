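"""End-to-end discovery workflow: merge -> quality filter -> annotate -> prioritize.

`run_discovery` is the in-memory engine used by tests and experiments;
`run_pipeline` is the file-based front (paths in a config, TSVs and a run
manifest out) with byte-identical output for identical config + inputs.
"""

from __future__ import annotations

import bisect
import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .consequence_annotator import (
    Genome,
    OutsideTranscriptError,
    TranscriptModel,
    read_transcripts_gff3,
)
from .prioritizer import (
    AnnotatedVariant,
    CascadeResult,
    ControlCohort,
    ExpressionProfile,
    FrequencyAnnotations,
    PrioritizationConfig,
    candidates_to_frame,
    compute_tissue_specificity,
    evaluate_predicates,
    exclusions_to_frame,
    run_cascade,
)
from .quality_filter import QualityThresholds, apply_quality_filter
from .synthetic_cohort import read_expression_tsv
from .variant_model import CohortVariantTable, SampleGVCF, merge_gvcfs, read_gvcf


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def af_lookup_from_frame(df: pd.DataFrame) -> dict:
    """(chrom,pos,ref,alt) -> FrequencyAnnotations from an AF table."""

    def _clean(v) -> Optional[float]:
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    return {
        (r.chrom, int(r.pos), r.ref, r.alt): FrequencyAnnotations(
            af_gnomad=_clean(r.af_gnomad),
            af_1000g=_clean(r.af_1000g),
            af_esp=_clean(r.af_esp),
        )
        for r in df.itertuples()
    }


class _TranscriptIndex:
    """Positional lookup over non-overlapping transcript spans."""

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        spans = sorted((t.span[0], t.span[1], t) for t in transcripts)
        self._los = [s[0] for s in spans]
        self._spans = spans

    def find(self, pos: int) -> Optional[TranscriptModel]:
        i = bisect.bisect_right(self._los, pos) - 1
        if i >= 0:
            lo, hi, t = self._spans[i]
            if lo <= pos <= hi:
                return t
        return None


def annotate_table(
    table: CohortVariantTable,
    transcripts: Sequence[TranscriptModel],
    af_lookup: Mapping[tuple, FrequencyAnnotations],
    expression: Mapping[str, ExpressionProfile],
    cfg: PrioritizationConfig,
) -> tuple[list[AnnotatedVariant], list[tuple]]:
    """Join consequence, population AF and expression onto every cohort site.

    Returns (annotated variants, keys of sites overlapping no transcript).
    Tissue specificity is computed once per gene at the config's thresholds.
    """
    from .consequence_annotator import annotate_consequence

    index = _TranscriptIndex(transcripts)
    specificity: dict[str, tuple[float, bool]] = {}
    for gene_id, profile in expression.items():
        specificity[gene_id] = compute_tissue_specificity(
            profile,
            target=cfg.target_tissue,
            min_specificity_ratio=cfg.min_specificity_ratio,
            min_target_tpm=cfg.min_target_tpm,
        )
    annotated: list[AnnotatedVariant] = []
    unannotated: list[tuple] = []
    for site, genotypes in table.rows():
        model = index.find(site.pos)
        if model is None:
            unannotated.append(site.key)
            continue
        consequence = annotate_consequence(model, site)
        ratio, is_specific = specificity.get(model.gene_id, (0.0, False))
        annotated.append(
            AnnotatedVariant(
                variant=site,
                gene_id=model.gene_id,
                consequence=consequence,
                frequencies=af_lookup.get(site.key, FrequencyAnnotations()),
                genotypes=genotypes,
                specificity_ratio=ratio,
                is_tissue_specific=is_specific,
            )
        )
    return annotated, unannotated


@dataclass
class DiscoveryResult:
    table: CohortVariantTable
    annotated: list[AnnotatedVariant]
    results: dict[str, CascadeResult]
    stage_counts: dict[str, int]
    quality_audit: list
    unannotated: list[tuple]

    def candidates_frame(self) -> pd.DataFrame:
        frames = [candidates_to_frame(r) for r in self.results.values()]
        return pd.concat(frames, ignore_index=True) if frames else candidates_to_frame(
            CascadeResult(proband="", candidates=[], exclusions=[])
        )

    def exclusions_frame(self) -> pd.DataFrame:
        frames = [exclusions_to_frame(r) for r in self.results.values()]
        return pd.concat(frames, ignore_index=True) if frames else exclusions_to_frame(
            CascadeResult(proband="", candidates=[], exclusions=[])
        )


def run_discovery(
    samples: Sequence[SampleGVCF],
    transcripts: Sequence[TranscriptModel],
    af_lookup: Mapping[tuple, FrequencyAnnotations],
    expression: Mapping[str, ExpressionProfile],
    proband_ids: Sequence[str],
    control_cohort: Optional[ControlCohort] = None,
    control_ids: Optional[Sequence[str]] = None,
    thresholds: QualityThresholds = QualityThresholds(),
    config: PrioritizationConfig = PrioritizationConfig(),
) -> DiscoveryResult:
    """Merge per-sample GVCFs and run the full cascade for every proband.

    The control cohort may be supplied directly (an external genotype
    database) or derived from the merged table's own control columns.
    """
    try:
        table = merge_gvcfs(samples)
    except Exception as exc:
        raise PipelineError("merge", str(exc)) from exc
    n_merged = table.n_sites

    qres = apply_quality_filter(table, thresholds)
    table = qres.table

    if control_cohort is None:
        if control_ids is None:
            raise PipelineError(
                "prioritize", "either control_cohort or control_ids is required"
            )
        control_cohort = ControlCohort.from_table(table, control_ids)

    try:
        annotated, unannotated = annotate_table(
            table, transcripts, af_lookup, expression, config
        )
    except OutsideTranscriptError as exc:
        raise PipelineError("annotate", str(exc)) from exc

    results = {}
    for proband in proband_ids:
        if proband not in table.sample_ids:
            raise PipelineError("prioritize", f"proband {proband!r} not in cohort")
        results[proband] = run_cascade(annotated, proband, control_cohort, config)

    stage_counts = {
        "sites_merged": n_merged,
        "sites_after_quality": table.n_sites,
        "sites_dropped_by_quality": n_merged - table.n_sites,
        "sites_annotated": len(annotated),
        "sites_without_transcript": len(unannotated),
    }
    for proband, res in results.items():
        stage_counts[f"candidates_{proband}"] = len(res.candidates)
        stage_counts[f"exclusions_{proband}"] = len(res.exclusions)
    return DiscoveryResult(
        table=table,
        annotated=annotated,
        results=results,
        stage_counts=stage_counts,
        quality_audit=qres.audit,
        unannotated=unannotated,
    )


# ---------------------------------------------------------------------------
# File-based front


@dataclass
class PipelineConfig:
    gvcf_paths: list[str]
    gff3_path: str
    fasta_path: str
    af_table_path: str
    expression_path: str
    proband_ids: list[str]
    control_table_path: Optional[str] = None
    control_ids: list[str] = field(default_factory=list)
    output_dir: str = "results/discovery"
    seed: int = 0
    min_dp: int = 10
    min_gqx: int = 20
    min_alt_fraction: float = 0.15
    prioritization: PrioritizationConfig = field(default_factory=PrioritizationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        pcfg = PrioritizationConfig(**raw.pop("prioritization", {}))
        return cls(prioritization=pcfg, **raw)

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [
                *self.gvcf_paths,
                self.gff3_path,
                self.fasta_path,
                self.af_table_path,
                self.expression_path,
                *( [self.control_table_path] if self.control_table_path else [] ),
            ]
            if not Path(p).exists()
        ]
        if missing:
            raise PipelineError("startup", f"missing input paths: {missing}")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> DiscoveryResult:
    """Load inputs from config paths, run discovery, write TSVs + manifest."""
    config.validate_paths()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    samples = [read_gvcf(p) for p in config.gvcf_paths]
    genome = Genome.from_fasta(config.fasta_path)
    transcripts = read_transcripts_gff3(config.gff3_path, genome)
    af_lookup = af_lookup_from_frame(pd.read_csv(config.af_table_path, sep="\t"))
    expression = read_expression_tsv(config.expression_path)
    control_cohort = (
        ControlCohort.from_tsv(config.control_table_path)
        if config.control_table_path
        else None
    )
    result = run_discovery(
        samples=samples,
        transcripts=transcripts,
        af_lookup=af_lookup,
        expression=expression,
        proband_ids=config.proband_ids,
        control_cohort=control_cohort,
        control_ids=config.control_ids or None,
        thresholds=QualityThresholds(
            min_dp=config.min_dp,
            min_gqx=config.min_gqx,
            min_alt_fraction=config.min_alt_fraction,
        ),
        config=config.prioritization,
    )

    result.candidates_frame().to_csv(
        out_dir / "candidates.tsv", sep="\t", index=False, float_format="%.6g"
    )
    result.exclusions_frame().to_csv(
        out_dir / "exclusions.tsv", sep="\t", index=False
    )
    audit_rows = pd.DataFrame(
        [
            {
                "chrom": a.chrom, "pos": a.pos, "ref": a.ref, "alt": a.alt,
                "sample_id": a.sample_id, "reason": a.reason,
            }
            for a in result.quality_audit
        ],
        columns=["chrom", "pos", "ref", "alt", "sample_id", "reason"],
    )
    audit_rows.to_csv(out_dir / "quality_audit.tsv", sep="\t", index=False)
    manifest = {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stage_counts": result.stage_counts,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result


def explain_variant(
    result: DiscoveryResult,
    key: tuple[str, int, str, str],
    proband: str,
    control_cohort: ControlCohort,
    cfg: PrioritizationConfig = PrioritizationConfig(),
) -> str:
    """Human-readable trace of every predicate's inputs and verdict."""
    match = next((v for v in result.annotated if v.key == key), None)
    if match is None:
        raise KeyError(f"variant {key} not in the annotated table")
    verdicts = evaluate_predicates(match, proband, control_cohort, cfg)
    call = match.genotypes[proband]
    f = match.frequencies
    lines = [
        f"{key[0]}:{key[1]} {key[2]}>{key[3]} ({match.gene_id}, "
        f"{match.consequence.hgvs_c}) for proband {proband}",
        f"  genotype_quality  {'PASS' if verdicts['genotype_quality'] else 'FAIL'}  "
        f"zygosity={call.zygosity} dp={call.dp} gqx={call.gqx}",
        f"  impact            {'PASS' if verdicts['impact'] else 'FAIL'}  "
        f"{match.consequence.so_term} -> {match.consequence.impact_tier} "
        f"(floor {cfg.impact_floor})",
        f"  frequency         {'PASS' if verdicts['frequency'] else 'FAIL'}  "
        f"gnomAD={f.af_gnomad} 1000G={f.af_1000g} ESP={f.af_esp}",
        f"  control_cohort    {'PASS' if verdicts['control_cohort'] else 'FAIL'}  "
        f"carriers={control_cohort.carriers(key)}/{control_cohort.n_controls}",
        f"  recessive_model   {'PASS' if verdicts['recessive_model'] else 'FAIL'}  "
        f"zygosity={call.zygosity} max_af={f.max_present:.4g} "
        f"(< {cfg.recessive_max_af})",
        f"  tissue_specificity {'PASS' if verdicts['tissue_specificity'] else 'FAIL'} "
        f"ratio={match.specificity_ratio:.3g}",
        f"  verdict: {'CANDIDATE' if all(verdicts.values()) else 'EXCLUDED'}",
    ]
    return "\n".join(lines)
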