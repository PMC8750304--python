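#!/usr/bin/env python
"""Run the discovery pipeline on the simulated cohort from 01_simulate_cohort.

Merges the 52 GVCFs, applies the DP/GQX/ALT-fraction quality gate, annotates
consequences against the toy transcript models, and runs the recessive
testis-specific cascade for both probands. Candidates, exclusion audit and
the run manifest land in results/discovery/; the planted variants from
results/planted_truth.tsv should appear at rank 1.
"""

from pathlib import Path

import pandas as pd

from recessix.pipeline import PipelineConfig, run_pipeline

CONFIG = Path("scratch/sim/config.yaml")


def main() -> None:
    if not CONFIG.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    result = run_pipeline(PipelineConfig.from_yaml(CONFIG))
    for stage, count in result.stage_counts.items():
        print(f"{stage:30s} {count}")

    candidates = pd.read_csv("results/discovery/candidates.tsv", sep="\t")
    truth = pd.read_csv("results/planted_truth.tsv", sep="\t")
    print("\ncandidates:")
    print(candidates.to_string(index=False))
    planted = set(zip(truth.chrom, truth.pos, truth.ref, truth.alt))
    found = set(zip(candidates.chrom, candidates.pos, candidates.ref, candidates.alt))
    print(f"\nplanted variants recovered: {len(planted & found)}/{len(planted)}")


if __name__ == "__main__":
    main()
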