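# Methods

## Scope and data model

`mirmove` analyzes the quantitative readouts of a miRNA-mobility study:
small-RNA sequencing libraries, tissue-pair band-intensity or Cp tables,
differential tables with an FDR column, and parent/pool variant tables.
Alignment engines, variant callers and effect predictors are deliberately
out of scope — variant tables arrive with allele fractions (`AF`) and effect
classes (`EFF`) already annotated, and read classification is performed
directly against the small reference bundle rather than through a
genome-scale aligner.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) and
VCF (1-based) are converted at the IO boundary. Sequences are normalized to
the DNA alphabet (U→T) on input; user-facing sequence output uses the RNA
alphabet.

## Anchored tailing/trimming estimate

A read is *anchored* to an annotation when its length is 18–26 nt and its
5′ end coincides with the annotation's biological 5′ position on the
annotated strand. The read is compared base-by-base to the genomic template
from that position; positions beyond the annotated 3′ end are treated as
potentially non-templated (a tail) and never count as mismatches. The
default mismatch allowance inside the templated span is 0; a permissive
mode (≤ 2) exists for libraries where modified reads also carry internal
edits. Anchored reads partition into exact / shorter / longer /
anomalous; the anomalous bucket (same length as the mature, non-identical)
is only reachable with a positive mismatch allowance and is excluded from
both ratios, since a three-way shorter/exact/longer scheme leaves such
reads unassigned.

Indices are log2 ratios: trim = log2(shorter/exact), tail =
log2(longer/exact). Base 2 matches fold-change convention. When either
count is zero the index is undefined (NaN) and excluded from summaries; an
optional +1 pseudo-count mode (off by default) defines all ratios at the
cost of shrinkage. Reads anchoring at multiple loci are counted at every
locus up to a cap of 500, beyond which the read is dropped as
unassignable — the behaviour of a report-all aligner with a multi-mapping
ceiling.

## Isoform (alternative-processing) estimate

A read qualifies for a locus when it matches the strand-oriented genomic
sequence perfectly (no mismatches or gaps) at a position fully inside the
annotation enlarged by ±5 nt, with length within ±1 nt of the mature. The
exact-mature count is subtracted from the qualifying count to give "other"
reads (mis- or alternatively processed species), and the index is
log2(exact/other). A miRNA enters the summary only if at least one genotype
has ≥ 5 qualifying reads in every one of its replicates — a floor that
suppresses ratios built from a handful of reads. Only the annotated strand
is searched.

Boxplot-style summaries use linear-interpolation quartiles and 1.5 × IQR
whiskers clipped to the data, with undefined values counted separately.

## Synthetic small-RNA libraries

`simulate_reads` draws each read's class from a mixture (exact, 3′-trimmed,
3′-tailed, end-shifted isoform) and allocates reads to miRNAs multinomially
(log-uniform relative abundances by default — the field lacks a canonical
abundance law, and log-uniform spans the dynamic range of real libraries).
Non-templated tails draw from a U-dominant alphabet (U 0.85, A/C/G 0.05
each), reflecting uridylation of unmethylated 3′ ends. Three constructions
keep the truth table exactly recoverable:

* tail lengths are truncated so tailed reads stay ≤ 26 nt and trim lengths
  so trimmed reads stay ≥ 18 nt — otherwise modified reads would silently
  leave the anchored window and bias index recovery by construction;
* the first tail base is resampled to differ from the next templated
  genomic base, so a tailed read can never masquerade as a templated
  extension;
* isoforms are generated by shifting ends on the genomic template, never by
  mutating bases, so they remain perfectly aligned, as the isoform estimate
  requires. The truth table records, per read, both the generative class
  and the anchored label an exact classifier should produce (a 3′-only
  shifted isoform legitimately lands in the shorter/longer buckets; a
  5′-shifted isoform is unanchored).

What the generator does **not** emulate: per-base sequencing error, quality
score variation, pri/pre-miRNA structure, ligation bias, or genomic repeat
structure. Passing tests therefore demonstrate correctness of the counting
and index arithmetic under clean alignments, not robustness to sequencing
artifacts.

## Tissue experiment model and movement statistics

The two-compartment model sets emitter expectation *A·b* and recipient
expectation *A·b·m* per genotype (*b* > 0 biogenesis factor, *m* ∈ [0, 1]
movement efficiency). Measurement noise is multiplicative log-normal with
σ specified on the log2 scale (default 0.2), because intensities are
positive and blot-quantification error scales with signal. A lane factor
multiplies both the target and the loading-control intensity, so loading
normalization cancels it exactly; at σ = 0 the recipient/emitter ratio
equals *m* identically.

Ratios are formed per replicate from loading-normalized values (pairing by
replicate index; an unpaired mode using tissue means exists for designs
without physical lane pairing). The percent-reduction headline uses the
ratio of arithmetic means, 100·(1 − mean(test)/mean(ref)); a geometric-mean
variant is reported alongside because with log-normal noise it is the
maximum-likelihood analogue, and the arithmetic/geometric choice is a
genuine free parameter of such analyses. Negative reductions (test moves
more) are allowed and flagged.

The decision tree for group comparisons: Shapiro–Wilk per group (reported
as warnings only — with n = 4 the test has little power, so it does not
gate the analysis), a two-sided F test of variance equality at α = 0.05
choosing Student's t versus Welch's t, and one-way ANOVA + Tukey HSD for
more than two groups. The F-test threshold of 0.05 is a package choice; the
test itself (not the threshold) is standard.

## qPCR quantification

`Cp = offset − log2(expression) + N(0, σ)` (offset 30 by default; only Cp
differences matter). Relative expression is 2^−ΔCp with ΔCp measured
against the mean Cp of the declared reference targets within the same
sample, then normalized to the mean of the control condition per target.
At σ = 0 this inverts the simulator exactly provided reference-target
expressions are constant across samples — the assumption that makes
reference genes references.

## EMS candidate filtering

Candidates must (i) be absent from the parent table (keyed by chrom, pos,
ref, alt), (ii) be EMS-type transitions — canonically G→A or C→T on the
reference strand, with an all-transitions mode accepting A→G/T→C since
strand context of annotation pipelines varies, (iii) have allele fraction
≥ 0.99 ("fixed in the pool"; literal 1.0 is brittle against sequencing
error, so the threshold is a flag), and (iv) carry a missense or splice
effect. Arbitrary annotation strings map onto the internal effect
vocabulary via an alias table. The simulator plants one homozygous causal
transition among shared background variants (uniform AF) and pool-private
variants (AF ≈ Normal(0.5, 0.05), the expectation for unselected
heterozygous background in a segregating pool; a uniform-AF mode exists for
false-positive calibration, where the per-variant false-positive rate is
bounded by P(EMS type)·P(AF ≥ 0.99)·P(effect in set)).

## Differential crossing

Flagging is strict: FDR < α (default 0.05), so a record at exactly 0.05 is
never differential. Direction derives from the sign of mean_b − mean_a
because the consumed tables are not guaranteed to carry a log-fold-change
column. Considered targets are transcripts present in both the target map
and the measured table; mapped-but-unmeasured transcripts are excluded from
the denominator and reported as `n_unmatched`. The scatter preparation adds
+1 to raw count means for log-scale plotting.

## Problem sizes and numerical choices

The validation runs use: 10 reference bundles × 1,000 reads for
brute-force agreement; depth 2 × 10⁴ over 20 loci for index recovery
(per-locus standard error ≈ 0.1 log2 units, ≈ 0.025 after averaging);
200 simulated tissue experiments at n = 4 for recovery and 1,000 for test
calibration; 100 parent/pool pairs with 500 background variants for EMS
recovery. These sizes put Monte-Carlo uncertainty well inside the asserted
bands while keeping the whole validation under a minute per stage.
Deterministic seeding is mandatory throughout (`numpy.random.default_rng`;
no global state); identical seeds give byte-identical outputs.

## Known limitations

* The anchored classifier scans every read against every annotation —
  appropriate for bundles of tens of loci, not a genome-scale miRNA
  annotation set.
* Same-sequence loci are double-counted by design (every locus receives the
  read); there is no fractional multi-mapping assignment.
* The statistical decision tree mirrors common practice in the field but
  inherits its weaknesses: variance pre-tests distort downstream type-I
  error slightly, and normality testing at n ≤ 4 is uninformative (hence
  warnings, not gates).
* Percent-reduction confidence intervals are not computed; the p-value
  refers to the difference in mean ratios, not to the reduction estimate
  itself.
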