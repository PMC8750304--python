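# Methods

## Cohort merge from GVCFs

The pipeline's input boundary is one GVCF per exome: variant rows plus
*non-variant blocks* — intervals over which the caller asserts a confident
homozygous-reference genotype, summarized by the block's minimum depth
(`min_dp`) and minimum conservative genotype quality (`min_gqx`). The merge
takes the union of all samples' variant alleles as the site list, then
classifies every (site, sample) pair:

* **called** — the sample has an explicit record for that exact
  (chrom, pos, ref, alt); its genotype call is kept verbatim;
* **in-block** — the position lies inside one of the sample's blocks; the
  genotype is hom-ref with `dp = min_dp`, `gqx = min_gqx`,
  `ad_ref = min_dp`, `ad_alt = 0`. This applies even when the site's allele
  differs from anything the sample called: block semantics assert reference
  confidence over the whole interval;
* **uncovered** — otherwise the genotype is missing (`./.`). The GVCF
  convention does not dictate this case; treating it as missing rather than
  hom-ref is this package's choice, because asserting a reference genotype
  without coverage evidence would silently deflate cohort allele counts.

Multi-allelic rows are decomposed to one bi-allelic record per ALT on read,
since every downstream filter is per-allele. Sites are ordered by
(chrom, pos, ref, alt) and sample columns by sample id, which makes the merge
invariant to input order. When the same site is contributed by several
samples with different QUAL values the maximum is kept. GQX is a
caller-specific conservative quality; when an input GVCF lacks it, the
fallback is min(GQ, site QUAL), and the sample is flagged (`gqx_imputed`).

## Genotype-call quality gate

A call is discarded when DP < 10, GQX < 20, or — for calls carrying the ALT
allele — fewer than 15% of informative reads (`ad_alt / (ad_ref + ad_alt)`)
support the ALT. All three thresholds are inclusive ("less than" fails, the
boundary passes), hom-ref calls are exempt from the ALT-fraction test, and an
ALT call with zero informative reads fails with its own reason code. A
failing call becomes missing rather than deleting the site — the rule
filters *calls*, not sites, so one bad sample cannot erase a cohort site —
and a site is dropped only once every call at it is missing. Each action is
logged with a reason code; the filter is idempotent and monotone in every
threshold.

## Consequence annotation

Transcripts are modeled as ordered genomic exon intervals plus CDS start/end
on a genome sequence; coordinates follow HGVS c. space (A of the initiator
ATG = c.1, 5′UTR positions c.-k, 3′UTR c.\*k, intronic positions anchored to
the nearest exonic base with a signed offset; the midpoint of an intron
belongs to the donor side). Conventions:

* canonical splice window = the 2 intronic bases each side of an exon
  (acceptor −1/−2, donor +1/+2) → `splice_acceptor_variant` /
  `splice_donor_variant`, HIGH impact. Intronic offsets 3–8 are reported as
  `splice_region_variant` but remain MODIFIER tier;
* exonic SNVs are classified by mutating the affected codon
  (codon index = ⌊(cds_pos − 1)/3⌋ + 1): stop_gained / stop_lost /
  start_lost / missense / synonymous, with three-letter HGVS p. strings
  (p.Gln84Ter);
* indels count the *coding* bases inserted minus deleted; a net change not
  divisible by 3 is a frameshift (HIGH), otherwise in-frame (MODERATE); a
  deletion clipping a canonical splice base is a splice variant;
* nonsense-mediated decay is not modeled: a stop-gain is HIGH regardless of
  its position, since truncation and transcript degradation are both
  loss-of-function outcomes;
* the REF allele is verified against the genome before any classification —
  silent coordinate bugs are the dominant failure mode of annotators, so a
  mismatch raises instead of annotating;
* multi-transcript loci annotate against each overlapping transcript and
  report the most severe consequence.

CDS translation uses the standard code, excludes the terminal stop, and
reports the codon index of any premature internal stop as an error.

## Prioritization cascade

Six predicates, evaluated as a pure conjunction (the survivor set is
independent of evaluation order; the exclusion log names the first failure
in a documented order):

| predicate | rule | default |
|---|---|---|
| genotype_quality | proband call survived the quality gate | — |
| impact | impact tier ≥ floor | HIGH |
| frequency | not (gnomAD > 1% or 1000G > 3% or ESP > 5%) | per-database caps |
| control_cohort | ALT carriers among controls ≤ cap | 0 ("absent") |
| recessive_model | proband hom-alt and max known AF < 1% | 0.01, strict |
| tissue_specificity | ratio ≥ 5 and target ≥ 1 TPM | testis |

Interpretation choices: "absent from controls" means zero ALT carriers (not
merely zero homozygotes), with a `max_control_carriers` override; a variant
missing from every population database is treated as AF 0 and flagged novel —
filtering unknowns would discard exactly the discovery target; the
specificity thresholds (ratio ≥ 5, ≥ 1 TPM) are package defaults for a
property the source material states only qualitatively. The tissue
specificity ratio is target / max(others), +∞ when only the target is
expressed and 0 when the target is silent. Candidates are ranked by impact
tier, then descending specificity ratio, then ascending AF. Hemizygous-X
logic is out of the default path. An empty control cohort retains everything
with a warning.

## Knockout-design arithmetic

A dual-gRNA deletion is represented by its cDNA span [cut5, cut3], 1-based
inclusive, so c.41_117del covers 77 bases; frameshift ⇔ length mod 3 ≠ 0.
`design_deletion` places the frameshift-compatible length closest to the
requested guide spacing (default 100 ± 15 bp) inside one coding exon, with
seeded tie-breaking among equivalent placements. Genotyping assumes one
primer pair spanning the deletion: KO amplicon = WT amplicon − length; band
calls match observed sizes within ± tolerance (default 10 bp) and return
WT / HET / HOM, or UNCLASSIFIED with a report when a band matches neither
allele. One published assay reports a deletion length (155 bp, consistent
with its 535 → 380 bp amplicon shift) that contradicts its coordinate span
(c.354_505del = 152 bases); the length is taken as authoritative for
amplicon arithmetic and the span is carried with an inconsistency note.
Guide sequence selection (PAM scanning, off-target scoring) is deliberately
behind an interface stub — only the geometry is modeled.

## Synthetic cohort

The simulator generates everything the pipeline consumes, deterministically
per seed.

**Reference.** 200 genes (default) on one contig, 3–14 exons each, CDS of
110–399 codons built from sense codons (ATG…stop, no internal stops),
GT..AG introns of 40–250 bp, 6–30 bp UTRs, both strands. 10% of genes are
testis-specific in the expression table (testis 20–150 TPM, every other
tissue below testis/10, so ratio ≥ 10); the rest are broadly expressed
(tissue levels within 0.5–1.5× of a common base, ratio ≤ 3), so the
specificity predicate has an unambiguous truth.

**Variants.** 5000 background variants (default; 94% SNVs, 6% 1–2 bp
deletions) at positions drawn across gene spans. Allele frequencies follow a
rare-shifted mixture: Beta(0.2, 5) with probability 0.85, plus a common
component Uniform(0.05, 0.5) with probability 0.15, so the MAF filters have
real work to do. Genotypes follow inbreeding-adjusted Hardy–Weinberg,
P(hom-alt) = p² + F·p(1−p), P(het) = 2p(1−p)(1−F), with F = 0.0625 (the
first-cousin-offspring coefficient) applied to patients only — the modeled
patients are consanguineous, the controls outbred. 10% of background
variants are left out of the AF table ("novel"). Per-call depth is
negative-binomial (mean 60, dispersion 8) and GQX ~ N(60, 18) clipped to
[0, 99], so sub-threshold DP/GQX genuinely occur; site QUALs are
integer-valued so VCF text round-trips exactly.

**Planted truth.** One variant per patient in a distinct testis-specific
gene — stop-gain (found by scanning codons for single-base stop creations),
splice-acceptor −2 A>G, or a 1–2 bp intra-exonic frameshift deletion —
homozygous in its patient with clean supporting reads, absent from every
other sample, and assigned AF in (0.002, 0.009). Non-variant blocks tile
every gene span per sample, split around that sample's own variant spans.
Control genotype counts are tabulated from the simulated truth codes.

**What this does and does not emulate.** Genotype sampling, coverage noise
and the AF spectrum are modeled; read-level errors, alignment artifacts,
segmental duplication, linkage structure and real human gene architecture
are not. Recovery of every planted variant therefore demonstrates the
pipeline's logical correctness under the modeled noise, not robustness to
real-data artifacts. The background variant load per exome is an
order-of-magnitude placeholder, configurable rather than calibrated.

## Experiment sizes and determinism

The recovery experiment uses 20 independently seeded cohorts of 2 patients +
50 controls, 200 genes and 5000 background variants — enough to exercise
every predicate with distractors while keeping the whole suite fast. The
control-cohort size is a parameter (its published analogue is reported
inconsistently at 445 and 485 exomes). All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; reruns of the same config
produce byte-identical outputs, and the run manifest records the config
hash, seed and per-stage counts.

## Known limitations

* No compound-heterozygote phasing, de novo model, CNV/AZF-microdeletion
  detection or X-hemizygous path in the default cascade.
* The annotator covers SNVs and small indels against single-isoform toy
  models; regulatory features, protein domains and known-variation lookups
  are out of scope.
* HGVS support covers the coordinate/SNV/del/delins/ins forms the pipeline
  emits, not the full nomenclature.
* The quality gate's per-call (rather than per-site) discard convention is
  documented as this package's choice; the original wording does not decide
  the case.
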