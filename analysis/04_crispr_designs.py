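#!/usr/bin/env python
"""Knockout-design arithmetic: published assays + de novo designs.

First reproduces the two published genotyping assays (77 bp and 155 bp
intra-exonic frameshift deletions, both collapsing to a 380 bp KO amplicon),
then places fresh ~100 bp dual-gRNA frameshift deletions in early coding
exons of the simulated testis-specific candidate genes. Writes
results/crispr_designs.tsv.
"""

from pathlib import Path

from recessix.case_studies import (
    CCT6B_REPORTED_DELETION_LENGTH,
    CCT6B_WT_AMPLICON,
    RIK_WT_AMPLICON,
    cct6b_reported_span_design,
    rik_design,
)
from recessix.crispr_toolkit import DesignError, design_deletion, predict_amplicons
from recessix.synthetic_cohort import CohortSimConfig, simulate_reference

SEED = 17


def main() -> None:
    rows = []

    rik = rik_design()
    assay = predict_amplicons(RIK_WT_AMPLICON, rik)
    rows.append(("4930522H14Rik", rik.target_exon_index, rik.hgvs_c, rik.length,
                 rik.frameshift, assay.wt_amplicon, assay.ko_amplicon, "published"))
    cct = cct6b_reported_span_design()
    assay = predict_amplicons(CCT6B_WT_AMPLICON, CCT6B_REPORTED_DELETION_LENGTH)
    rows.append(("Cct6b", cct.target_exon_index, cct.hgvs_c,
                 CCT6B_REPORTED_DELETION_LENGTH, True,
                 assay.wt_amplicon, assay.ko_amplicon,
                 "published; span/length inconsistency flagged"))
    print(f"published assays reproduce KO amplicons: "
          f"{rows[0][6]} bp and {rows[1][6]} bp")

    # de novo designs in the simulated testis-specific genes
    reference = simulate_reference(CohortSimConfig(), SEED)
    designed = 0
    for gene_id in sorted(reference.testis_specific_genes)[:10]:
        model = reference.transcript_for(gene_id)
        for exon_index in range(2, model.n_exons):  # early, not the first exon
            try:
                design = design_deletion(model, exon_index, approx_spacing=100,
                                         seed=SEED)
            except DesignError:
                continue
            wt = design.length + 300  # primers ~150 bp either side of the cuts
            assay = predict_amplicons(wt, design)
            rows.append((gene_id, exon_index, design.hgvs_c, design.length,
                         design.frameshift, assay.wt_amplicon, assay.ko_amplicon,
                         "de novo"))
            designed += 1
            break
    print(f"placed de novo frameshift deletions in {designed} simulated genes")

    out = Path("results/crispr_designs.tsv")
    out.parent.mkdir(exist_ok=True)
    with out.open("w") as fh:
        fh.write("gene_id\texon\tdeletion\tlength_bp\tframeshift\t"
                 "wt_amplicon_bp\tko_amplicon_bp\tsource\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
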