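# Methods

## Data model and coordinate conventions

A mature miRNA is a 19–25 nt DNA-alphabet sequence stored 5'→3'; every
position reported anywhere in the package is 1-based on this sequence.
Reads are 36 nt, single-end, sense-strand only (the cloning protocol the
pipeline models is strand-specific), so every insert is followed by 3'
adapter sequence.

## Synthetic-data generator

The generator emulates a two-genotype (wild type vs ADAR2 knockout) brain
small-RNA experiment at desk scale. Per read: a source miRNA is drawn from
the genotype's expression weights (multinomial with the requested depth);
each edited site on the source converts independently with its true
frequency (A→G on an A, T→C on a T); the insert plus adapter (tiled if
necessary) is cut to the read length; finally every base is substituted
with probability ε_seq = 0.001, uniformly to one of the three other bases.
Editing is applied before sequencing error and independently across reads
and sites — the simplest generative model consistent with per-site
binomial editing frequencies and a single global error rate. Quality
strings are constant 'I' because no downstream stage uses qualities.

Default conditions: 600 miRNAs; a log-normal expression body whose five
largest weights are rescaled to jointly carry 48% of reads (the observed
head-heaviness of brain libraries); 100,000 reads per replicate, three
replicates per genotype (a real sequencing lane yields tens of millions of
reads; depth here is reduced ~300-fold, which scales coverage but not
rates); ~30 edited sites
with wild-type frequencies between 2% and 80% (the strongest site at 80%),
64% of them placed in the seed region (positions 2–7). Knockout
frequencies follow the dependence proportions the analysis is meant to
recover — 26% of sites lost, 25% reduced by at least half, 11% increased
by at least half, the rest shared — with the six highest-frequency sites
forced into the lost/reduced classes (the most highly edited miRNAs are
ADAR2 targets).

Two deliberate restrictions:

* Sites are planted only at internal positions 2..L−1. A substitution at
  the first or last aligned position is clipped by any local alignment
  (clipping a terminal mismatch always raises the score), so terminal
  editing is invisible to the read-mapping approach; reported editing
  positions in real data likewise start at position 2.
* Replicates differ only by multinomial sampling. Real replicates carry
  extra biological dispersion, library-preparation and ligation bias,
  isomiR length variants and non-miRNA reads; none of these are modelled.
  Passing tests therefore demonstrate statistical correctness of the
  pipeline under its stated noise model, not robustness to un-modelled
  artefacts (e.g. the ~100% mappable fraction here vs ~70% in real
  libraries).

## Adapter trimming

The trimmer finds the leftmost read position where a prefix of the adapter
matches the read suffix with at most `floor(0.1 × overlap)` substitutions
and overlap ≥ 3 — classic 3'-adapter semantics, substitutions only. The
length filter keeps 18–28 nt, bracketing the 19–25 nt isolation window
with one base of slack for isomiRs. The batch implementation vectorizes
the overlap scan across equal-length reads and is tested to be identical
to the per-read scan.

## Alignment and mapping

Reads are aligned with affine-gap Smith-Waterman against the forward
strand only. Scoring: match +4, mismatch −3, gap open −10, gap extend −4,
minimum reported score 48 (~12 matched bases). The penalties keep
|mismatch| < 2·match deliberately: with a harsher mismatch (e.g. the
common +2/−3), a local alignment clips a mismatch at the second aligned
position (penalty 3 saved > 2 match points lost), silently deleting
editing evidence at mature position 2 — inside the seed region, where
editing concentrates. With the chosen ratios only a strictly terminal
mismatch can be clipped. Because the alignment is local, no explicit
trimming of read ends is needed.

Hits are filtered to ≥90% identity, counting each indel column as a
difference, and ≤2 mismatches; a read's equal-scoring retained hits are
weighted 1/k; reads with more than 8 equally good references are discarded
as unplaceable.

Tie-breaking is deterministic: the alignment ends at the maximal-score
cell that is first in (read position, reference position) order, and the
traceback prefers diagonal over gap-in-reference over gap-in-read, closing
gaps as early as possible.

Implementation notes: the DP fill batches all (read, candidate) pairs into
one vectorized computation; within a row, the gap-in-read term is computed
with a prefix scan, which is exact because opening a gap from a cell whose
best path ends in such a gap is dominated whenever gap_open ≤ gap_extend.
`map_reads` collapses duplicate read sequences (aligning each unique
sequence once and carrying the multiplicity) and prefilters candidate
references through an exact 7-mer index — standard seed-and-extend mapper
practice. The exhaustive all-references path remains available
(`exhaustive=True`) and the heuristic is tested to agree with it on
simulated libraries; the score and the mismatch list of every alignment
are tested against an independent plain-loop DP implementation.

## Count tables and mismatch spectrum

Every retained hit deposits `weight × multiplicity` onto the observed base
at each aligned reference position; matches land on the reference base.
The 12-type mismatch spectrum sums substitution columns by (ref base →
read base) and is normalized by the replicate's total mismatch weight
*before* any cross-replicate comparison; genotypes are compared per type
with a classical (equal-variance, two-sided) Student t-test on the
normalized fractions, n = 3 per group.

## Editing caller

For each adenosine of each miRNA whose weighted read count is ≥100 in
every replicate of a genotype, the observed reference/alternative split
(n = A+G) is tested with a one-degree-of-freedom goodness-of-fit
statistic, expected counts n·(1−r) and n·r. The null alt rate r is the
replicate's global non-A→G substitution rate over all aligned columns
(substitutions that cannot arise from A-to-I editing estimate the
technical noise floor); a per-type variant (r/11) is available behind
`null_mode="per_type"` since the aggregate-vs-per-type choice is a genuine
ambiguity — the aggregate reading is the default and is conservative
(larger expected G count, fewer calls). No Yates correction. The test is
one-sided by construction: p is set to 1 whenever the observed alt
fraction does not exceed r, so depletion is never called as editing.

P-values are Benjamini–Hochberg adjusted within each replicate
(statsmodels' step-up implementation, verified in tests against the
textbook recursion), and a site is called in a genotype when q ≤ 0.05 in
all replicates (default) or in at least k of n (`consistency="k_of_n"`,
k = 2) — both consistency conventions appear in practice and both are
implemented. The reported editing level is the pooled count frequency
alt/(ref+alt) summed over replicates, which is the maximum-likelihood
estimate under the binomial model and the quantity the 3-SE accuracy
checks refer to; per-replicate frequencies are stored alongside.

The χ² statistic runs on raw weighted counts. Per-lane depth
normalization is applied only to the abundance analyses: rescaling counts
before a count-based goodness-of-fit would destroy its calibration
(normalized counts are not observations), so the caller uses counts and
the abundance module uses RPM.

The T→C analog replaces the estimated null rate with the fixed sequencing
error rate 0.001, because the global T→C rate itself would be contaminated
by any genuine T→C signal under test.

## Abundance analysis

Counts are normalized to reads per million mapped miRNA reads per
replicate. Two nested expression sets: the inventory (≥10 reads in every
replicate) and the analysis set (≥100 reads in every replicate of both
genotypes). The signed fold is mean(KO)/mean(WT), reported as its negative
reciprocal for decreases so |fold| ≥ 1 always. Classification as up/down
requires |fold| ≥ 1.3, a two-sided Student t-test p < 0.1 on the RPMs
(log-RPM behind a flag; the plain-RPM default matches the simple t-test
convention), and direction consistency, operationalized as: every
replicate-index-paired KO/WT ratio shares the sign of the mean fold.

## Annotation

Seed region: positions 2–7 (the target-pairing core as used for the
positional enrichment analysis; an alternative 2–8 convention exists and
the window is configurable). Dependence classification from pooled WT/KO
frequencies: ADAR2-exclusive if the knockout level falls below a 0.5%
detection floor (the floor operationalizes "no longer detectable" and is
configurable); ADAR2-dependent at a ≥50% relative drop; ADAR1-preferred at
a ≥50% relative rise; shared otherwise. Context tabulation reports the 5'
and 3' neighbor bases with an "edge" sentinel at miRNA boundaries.
Known-site flagging takes a user-supplied TSV; no literature database is
bundled.

## Retargeting

Canonical seed-match classes only: 8mer (reverse complement of miRNA
positions 2–8 followed by an A opposite position 1), 7mer-m8, 7mer-A1;
6mers are excluded by default and available behind a flag. Every
occurrence of the 6-nt seed core in a UTR is classified by its flanks,
with 8mer > 7mer-m8 > 7mer-A1 precedence at a locus; overlapping loci are
each reported. A UTR is a target of an isoform if it carries at least one
site. No context scores, conservation filtering or 3'-supplementary
pairing — target-set *composition* against a user-supplied UTR collection
is the deliverable, not reproduction of counts from any external UTR
database.

## Operating characteristics (benchmarks module)

`mirnaedit.benchmarks` packages four seeded simulation studies, used both
by the test suite and by `scripts/acceptance.py`:

* **Null calibration** — 300 miRNAs, no editing, 100k reads × 3
  replicates per seed: the per-replicate fraction of tested A-sites with
  q ≤ 0.05 and the all-replicate call rate. Both sit near zero — BH plus
  the one-sided gate is strongly sub-nominal under the null.
* **Recovery** — 25 sites at 5/10/25/50/80% on hosts with ≥600 expected
  reads per replicate: sensitivity and the fraction of frequency
  estimates within 3 binomial SE.
* **Genotype contrast** — wild type with editing vs knockout with all
  A→G editing removed, 30k reads per replicate: fraction of seeds in
  which the normalized A→G fraction drops significantly (t-test p<0.05).
* **Abundance** — ten 2-fold-up and ten 2-fold-down miRNAs at analysis-set
  coverage: sign accuracy and fold-estimate error against the true RPM
  folds implied by the normalized expression weights (planting a fold
  change renormalizes all weights, so the truth is computed from the
  weight ratios, not assumed to be exactly 2.0).

Problem sizes (depths of 10⁴–10⁵ reads, 80–600 miRNAs, 5–20 seeds per
study) are chosen so each study completes in minutes on one CPU while
keeping per-site coverages in the regime the thresholds refer to
(≥100–1000 reads per miRNA).

## Known limitations

* Terminal-position editing (position 1 and the last position) is
  invisible by construction of local alignment; this mirrors the method
  being modelled rather than a removable defect.
* The caller assumes mismatches are independent across reads; PCR
  duplicates or ligation bias would violate this and are not modelled.
* Precursor-level analyses (hairpin structure, the base opposing an edited
  site, processing-efficiency mechanics) are out of scope: only mature
  sequences are examined.
* The simulator produces no indels, no quality-score variation and no
  non-miRNA background reads.
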