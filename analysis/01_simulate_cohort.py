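#!/usr/bin/env python
"""Simulate the study cohort: 2 consanguineous patients + 50 controls.

Generates the toy reference (200 genes, testis-specific subset), plants one
homozygous loss-of-function variant per patient in a testis-specific gene,
and writes every pipeline input (FASTA, GFF3, expression, AF table, control
table, per-sample GVCFs, ready-to-run config) under scratch/sim/. A small
summary and the planted truth go to results/.
"""

from pathlib import Path

import yaml

from recessix.synthetic_cohort import (
    CohortSimConfig,
    simulate_cohort,
    simulate_reference,
    write_gvcf,
)

SEED = 17
SIM_DIR = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    cfg = CohortSimConfig()
    reference = simulate_reference(cfg, SEED)
    cohort = simulate_cohort(cfg, reference, SEED)

    (SIM_DIR / "gvcfs").mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    reference.write_fasta(SIM_DIR / "genome.fa")
    reference.write_gff3(SIM_DIR / "genes.gff3")
    reference.write_expression_tsv(SIM_DIR / "expression.tsv")
    cohort.af_table.to_csv(SIM_DIR / "af_table.tsv", sep="\t", index=False)
    cohort.control_cohort.write_tsv(SIM_DIR / "controls.tsv")
    lengths = {c: reference.genome.contig_length(c) for c in reference.genome.contig_names()}
    gvcf_paths = []
    for sample in cohort.samples:
        path = SIM_DIR / "gvcfs" / f"{sample.sample_id}.g.vcf"
        write_gvcf(sample, path, lengths)
        gvcf_paths.append(str(path))

    config = {
        "gvcf_paths": gvcf_paths,
        "gff3_path": str(SIM_DIR / "genes.gff3"),
        "fasta_path": str(SIM_DIR / "genome.fa"),
        "af_table_path": str(SIM_DIR / "af_table.tsv"),
        "expression_path": str(SIM_DIR / "expression.tsv"),
        "control_table_path": str(SIM_DIR / "controls.tsv"),
        "proband_ids": cohort.patient_ids,
        "output_dir": "results/discovery",
        "seed": SEED,
    }
    (SIM_DIR / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))

    with (RESULTS / "planted_truth.tsv").open("w") as fh:
        fh.write("patient\tchrom\tpos\tref\talt\tgene_id\tconsequence\taf_gnomad\n")
        for pv in cohort.truth.planted:
            fh.write(
                f"{pv.patient}\t{pv.chrom}\t{pv.pos}\t{pv.ref}\t{pv.alt}\t"
                f"{pv.gene_id}\t{pv.consequence}\t{pv.af_gnomad:.6f}\n"
            )
    n_specific = len(reference.testis_specific_genes)
    print(
        f"simulated {len(cohort.samples)} samples over {cfg.n_genes} genes "
        f"({n_specific} testis-specific), {cfg.n_background_variants} background "
        f"variants, {len(cohort.truth.planted)} planted LoF variants"
    )
    print(f"inputs under {SIM_DIR}/ ; run 02_run_discovery.py next")


if __name__ == "__main__":
    main()
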