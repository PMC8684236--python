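# somacohort

Desk-scale analysis of somatic SNV/InDel cohorts from tumor–normal
whole-genome sequencing, built around the low-burden benign-tumor setting
of craniopharyngioma (CP): 26 tumor/normal pairs split into 16
adamantinomatous (ACP) and 10 papillary (PCP) subtypes, with roughly 760
SNVs and 39 InDels per tumor, CTNNB1-exon-3 drivers in ACP and BRAF V600E
in PCP, mutually exclusively.

The package is aimed at method developers and analysts who want every
stage of such a study — multi-caller consensus filtering, panel-of-normals
artifact removal, coding annotation, mutational spectra and signature
refitting, kataegis and chromosome-terminal analysis, cohort driver
statistics — runnable and testable on a laptop. A first-class synthetic
cohort generator emulates the callers' outputs with known truth, so every
stage can be validated against planted ground truth instead of
inaccessible patient data.

## What it computes

**Consensus filtering.** Base substitutions are accepted when the
Mutect2-like caller reported them with PASS status; InDels when both the
Strelka2-like and Varscan2-like callers agree. Retained candidates must
then satisfy, all evaluated and enumerated per call:

- variant allele fraction (VAF) ≥ 0.10,
- mean base quality ≥ 20,
- SNVs: normal depth > 14 and tumor depth > 8,
- InDels: tumor depth > 10 and Varscan2-like p ≤ 0.001,
- site not in the panel of normals (recurrent artifact/germline
  background built from the matched normals),
- site outside the low-complexity mask (InDels use the full REF
  footprint).

**Spectra and signatures.** Substitutions collapse onto the pyrimidine
strand into the six base-pair classes C:G>A:T … T:A>G:C and, with their
5′/3′ flanks, into the 96 trinucleotide channels X[R>A]Y. A spectrum
**m** (96-vector of channel frequencies) is decomposed against a reference
signature matrix **S** (96 × K, columns summing to 1) as

    m ≈ S w,   w ≥ 0,  Σ w ≤ 1,

by greedy forward selection with golden-section line searches (plus
pairwise mass transfers when the Σ w = 1 constraint binds), minimising
‖m − S w‖²; exposures below a cutoff (default 0.06) are zeroed.

**Clustering.** Rainfall inter-mutation distances per chromosome; kataegis
events as maximal runs of ≥ 6 consecutive mutations with mean
inter-mutation distance ≤ 1 kb; and a permutation test for enrichment in
the outermost 5% of each chromosome's non-gap span (the telomere-adjacent
region in a telomere-gapped reference), with p = (1 + #{perm ≥ obs}) /
(n_perm + 1) under uniform placement over the non-gap genome.

**Cohort report.** Tumor mutational burden (mutations/Mb, default
denominator 3,088.27 Mb — the non-gap human genome), region and
coding-effect proportion tables with explicit denominators, the age–burden
Pearson correlation, and subtype × driver 2×2 tables with a two-sided
Fisher exact test (hypergeometric enumeration) formalising CTNNB1/BRAF
mutual exclusivity.

## Worked example

```python
from somacohort import run_pipeline

res = run_pipeline("bundle", seed=7)   # generates + analyses a 26-pair cohort
s = res["summary"]
print(s["filter_performance"])
print(s["terminal_enrichment"])
print({k: v["mean"] for k, v in s["signature_summary"].items()})
```

prints

```
{'tp': 20947, 'fp': 0, 'fn': 456, 'precision': 1.0, 'recall': 0.9786945755267953, 'f1': 0.989232585596222}
{'observed_fraction': 0.3500739962763164, 'expected_fraction': 0.10012572290671361, 'permutation_p': 0.000999000999000999}
{'S1': 0.1758, 'S2': 0.6919, 'S3': 0.0851, 'S4': 0.0, 'S5': 0.0}
```

Reading: of 21,403 planted somatic variants, the consensus filter
recovered 97.9% with no false positives (every injected artifact was
removed by the panel of normals, the mask or the VAF rule; the misses are
the emulated callers' false negatives). 35.0% of retained mutations fall
in the chromosome-terminal windows against 10.0% expected, p ≈ 0.001 at
1,000 permutations — the generator plants 30% of mutations near the
telomere-adjacent ends, and the test detects it. The refitted signature
exposures (means over 26 samples) recover the generating mixture of 0.18
S1 + 0.65 S2 + 0.10 S3, with the flat 7% remainder absorbed mostly by the
broad clock-like S2.

The report bundle written to `bundle/` contains `summary.json`,
`per_sample.tsv`, `proportions.tsv`, `exposures.tsv`, `spectra_96.tsv`,
`rainfall.tsv`, `kataegis.bed`/`.tsv`, `terminal_enrichment.json`,
`log.txt`, and under `bundle/inputs/` the complete synthetic inputs
(FASTA, gap/mask BED, GFF3, per-caller and normal VCFs, sample TSV, truth
JSON, YAML config).

The same pipeline is available from the shell:

```
somacohort run --out bundle --seed 7
somacohort filter --tumor-vcfs A=...,B=...,C=... --normal-vcfs ... --mask mask.bed --out retained.tsv
somacohort annotate / signatures / kataegis ...
```

YAML config keys mirror `somacohort.CohortConfig` (counts, chromosome
lengths, signature mixture, kataegis clusters, terminal bias, caller error
rates, seed); `bundle/inputs/config.yaml` from any run is a valid starting
point.

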