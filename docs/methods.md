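# Methods

This note documents the models, default parameters and numerical choices
behind `somacohort`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one defensible
choice existed.

## The synthetic cohort generator

The generator is the package's substitute for patient data: it produces a
small reference genome, a planted somatic truth set per tumor, and the
emulated per-caller VCFs plus matched-normal VCFs that the analysis
consumes. Everything downstream treats those files exactly as it would
treat real caller output.

### Reference genome

Three chromosomes of 2.0, 1.2 and 0.8 Mb (configurable, ≥ 2 chromosomes
of ≥ 200 kb each). This scale was chosen so that, at ~760 SNVs per tumor,
the background inter-mutation distance (~5 kb) sits well above the 1 kb
kataegis threshold — on a smaller genome the background alone would be
"clustered" and the rainfall analysis meaningless. All mutation counts are
per genome, so the downstream arithmetic is independent of genome size;
only TMB uses the genome length, and synthetic runs pass their own.

Telomere-like N gaps (3 kb) cap both ends of every chromosome and one 5 kb
interior gap stands in for an assembly gap, so "terminal windows"
(outermost 5% of the non-gap span per end, both ends) are genuinely
telomere-adjacent. Low-complexity tracts (homopolymers and short tandem
repeats, ~1 per 25 kb, 40–200 bp) are written into the sequence and
recorded in the mask BED; they avoid gene bodies so that coding truth
variants are never mask-filtered.

The gene model contains four multi-exon protein-coding transcripts on both
strands, written directly into the sequence as intact ORFs:

- `CTNB1L` (+): the ACP driver locus. Its third exon carries hotspot
  codons orthologous to CTNNB1's S33/S37/T41/S45 plus a GCA codon 43 and
  codons 44–56 sized to host the composite driver event (below).
- `BRAFL` (−): codon 600 is GTG; the middle-base transversion yields the
  V600E-like Val→Glu missense.
- `FBXW7L` (−): codon 425 is TGG; a middle-base G→A transition yields the
  premature stop (p.W425X), exercising the nonsense path through a
  minus-strand transcript.
- `CHD8L` (+): codon 463 is CGG; G→A yields p.R463Q.

### Truth mutations

Per sample, the background SNV count is Poisson with mean 760 scaled by an
age factor (1 + 0.6·(age − mean age)/age range), which reproduces a
positive age–burden correlation; Poisson is an assumption — the source
cohort reports only a range of per-tumor coding counts, not a variance
model. Each SNV's 96-channel is drawn from the sample's signature mixture
(default 0.18 S1 + 0.65 S2 + 0.10 S3 over the bundled synthetic matrix,
remainder flat) and placed uniformly over genomic positions whose
pyrimidine-collapsed reference trinucleotide matches the channel, on
either strand, excluding gaps and the mask. 30% of background SNVs
(`terminal_bias`) are forced into the terminal windows, emulating the
telomere-proximal enrichment the analysis is designed to detect; the rest
are uniform over the whole eligible genome, so `terminal_bias = 0` is an
exact uniform null. InDels (Poisson, mean 39) are 1–5 bp deletions and
1–4 bp insertions at uniform eligible positions.

Kataegis clusters are planted per sample from a configured list (default:
8 mutations in 3 kb on chr1, 9 in 2.5 kb on chr2), positions uniform
within the span. Drivers are assigned as fixed counts — 11 of 16 ACP and
7 of 10 PCP samples (the source cohort's observed fractions) — mutually
exclusively by construction: ACP carriers get one hotspot missense SNV in
`CTNB1L` exon 3, except one designated carrier who gets the composite
event (codon-43 C>G missense plus the 39-nt in-frame deletion of codons
44–56, the p.A43G + delP44_D56 analogue); PCP carriers get the V600E-like
SNV.

### Caller emulation

Three call sets per tumor: caller A (Mutect2-like) emits SNVs with PASS
flags, caller B (Strelka2-like) emits SNVs and InDels, caller C
(Varscan2-like) emits InDels with a p-value. Evidence fields (normal/tumor
depth, alt reads, VAF, mean base quality, InDel p) are drawn once per true
variant and shared across callers.

True-variant evidence is drawn *conditional on passing the threshold
filters* — depths 15+Poisson(14) normal and 9/11+Poisson(18) tumor, VAF
uniform(0.15, 0.55) with alt reads rounded consistently, base quality
round(N(32,4)) clipped to [20, 40], InDel p uniform(1e-6, 5e-4). This is a
deliberate design choice: the generator models well-covered clonal somatic
variants, and marginal-evidence sites are represented explicitly by the
injected false positives rather than by the tails of the true-variant
distributions. It makes "zero caller error ⇒ the filter recovers the truth
set exactly" a structural property, which in turn makes filter defects
visible as exact mismatches rather than statistical noise.

False positives are injected per caller at a configurable rate (default
0.05 per true call, Poisson), split among three mechanisms, each targeted
at one filter rule: shared artifact sites (low VAF, present in ≥ 2 normal
VCFs → removed by the panel of normals), masked-region sites (healthy
evidence → removed by the mask rule), and low-VAF sites (VAF
uniform(0.02, 0.08) with base quality on the full [2, 40] range → removed
by the VAF rule). False negatives drop each true variant from each caller
independently (default 2%). Because an SNV needs caller A and an InDel
needs B∧C, the expected recall at defaults is ≈ 0.98 for SNVs and ≈ 0.96
for InDels; precision is ≈ 1 by construction of the FP mechanisms. The
observed default-cohort F1 of ≈ 0.99 is therefore a property of the error
model, not a tuned number.

### What the generator does not emulate

No reads (no FASTQ/BAM), no sequencing-error or mapping-error model, no
copy number, structural variants, purity/ploidy, or subclonal structure;
VAFs are drawn, not computed from coverage simulation; caller errors are
independent across callers, whereas real callers share failure modes.
Passing tests therefore demonstrate that the *analysis logic* is correct
under the stated statistical structure — not that the thresholds
themselves are optimal for real data.

## Filtering

"Over 14/8" and "over 10" are read strictly (depth > 14, > 8, > 10), with
14 mapped to the normal and 8 to the tumor following the "normal/tumor"
ordering; all cut-offs are configurable. VAF is compared as reported by
the caller (it is the caller's "mutation rate of the locus"), not
recomputed from reads. The panel of normals is keyed on exact
(chromosome, position, alt) triples; the default membership rule is "seen
in ≥ 1 normal" (conservative; the count is a parameter). Mask overlap for
InDels uses the full REF footprint, since a deletion spanning a repeat
edge is a repeat artifact. Consensus requires A-PASS for SNVs and B∧C for
InDels — the most literal reading of the published rule; whether an SNV
seen by both B and C but not A should survive is ambiguous in the source
and resolved here against survival. All rule failures are enumerated per
call (no short-circuiting), so filter reports show every reason a call
failed.

## Annotation

Region classes are exonic / intronic / intergenic with exonic (CDS
overlap, any transcript) taking precedence; UTRs are not modelled
separately because only CDS effects feed the downstream tables, and
stop-loss/splice classes are likewise out of scope. Effects come from
strand-aware codon substitution and translation under the standard code;
when transcripts disagree, the longest CDS wins, ties broken
alphabetically by gene name, making reports deterministic. In-frame
deletions are named `p.<aa1><pos1>_<aa2><pos2>del`, frameshifts
`p.<aa><pos>fs`, stops `X`.

## Spectra

Channel order is the conventional interchange layout (C>A, C>G, C>T, T>A,
T>C, T>G × 16 flank pairs, lexicographic). InDels are excluded from
spectra (substitution-only by definition) but included in rainfall
distances. Cohort spectra are pooled counts by default; the mean of
per-sample proportions is also exposed, since published cohort panels are
ambiguous between the two. Variants whose flank contains N are excluded
and counted, not errored.

## Signature refitting

The fit minimises squared error between the observed frequency vector and
a non-negative combination of reference columns with weight sum ≤ 1,
using greedy forward selection: each round re-optimises the single best
weight by golden-section search (bracket tolerance 1e-4) and applies the
best move. Two numerical points discovered during development:

- **Stopping scale.** Convergence is declared when the per-round decrease
  of the *root*-SSE falls below `tol` (default 1e-5). Measuring
  improvement on raw SSE stops far too early on frequency-scale data
  (SSE ~ 1e-3), freezing the fit right after the first, overshooting
  signature.
- **Active sum constraint.** When Σw reaches 1, no single-weight move can
  travel along the simplex face, and coordinate descent can stall at a
  non-optimal boundary point. The search therefore also evaluates pairwise
  mass transfers (w_i − t, w_j + t) whenever Σw is within 0.02 of 1.
  With both move types the objective is a convex quadratic over a
  box-plus-simplex set and the search reaches the constrained global
  optimum (verified against dense grid search in the test suite).

After convergence, weights below the cutoff (default 0.06) are zeroed and
the search re-runs restricted to the survivors. Exposures are reported
un-normalised by default (the shortfall from 1 is unexplained spectrum);
renormalisation to sum 1 is available as an option since published
per-patient contribution bars typically are renormalised. No
trinucleotide-abundance renormalisation is applied: whole-genome counts
are fitted against genome-normalised signatures directly; a per-channel
weight vector hook exists for other designs. Reference matrices are plain
TSVs; the bundled matrix is five synthetic, well-separated signatures
built deterministically in code (no proprietary catalogue is shipped).
Samples with fewer than 50 mutations are refused and flagged rather than
fitted.

## Clustering and terminal enrichment

Kataegis uses the community working definition (≥ 6 consecutive mutations,
mean inter-mutation distance ≤ 1 kb; both parameters exposed), with
overlapping qualifying runs merged into maximal events. The terminal
windows are the outermost 5% of each chromosome's non-gap span per end —
the fraction is a parameter, since "close to the telomeres" has no
standard quantification. The permutation null places mutations uniformly
over non-gap bases, ignoring trinucleotide composition and the
low-complexity mask; this is the simplest defensible null and a known
limitation. The p-value uses the add-one estimator, so its floor is
1/(n_perm + 1) — at the default 1,000 permutations, "p ≤ 0.001" means the
observed count exceeded every permutation. The enrichment test itself is
this package's formalisation; the observation it formalises was reported
descriptively.

## Cohort statistics

Percentages are rounded half-up to 2 decimals and always reported with
their denominator so each printed number recomputes from printed numbers;
TMB is rounded to 3 decimals, with the non-gap human genome length
(3,088.27 Mb) as the default denominator. The age correlation is a
standard Pearson r with the two-sided t-transform p (n − 2 df), applied to
total mutations by default (SNV-only is available — the source text's
"total somatic mutations" suggests both). Driver mutual exclusivity is
tested with a two-sided Fisher exact test computed by direct
hypergeometric enumeration (a published test statistic is not available
for this comparison; the test is this package's addition). Samples
carrying both drivers are reported, never suppressed.

## Problem sizes and determinism

Defaults throughout are the emulated study conditions: 26 samples,
~760 + 39 mutations each, ~4 Mb genome. The test suite additionally uses a
reduced cohort (7 samples, 150 + 12 mutations, 0.7 Mb) that preserves
every structural feature; property tests and oracles (dense grid search,
exhaustive window enumeration, full-protein translation diffs, exhaustive
hypergeometric sums) run at sizes where exhaustive computation is exact.
Every random draw flows from a single integer seed through named
`numpy.random.Generator` streams (one per pipeline stage), so reports are
byte-reproducible; JSON output is key-sorted and timestamp-free for the
same reason.
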