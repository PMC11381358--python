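# Methods

This note records the models, defaults and design choices behind each
stage, and what the synthetic generator does and does not emulate.

## Tail calling from soft clips

Full-length cDNA long reads mapped splice-aware carry the non-templated
poly(A) tail as a terminal soft clip. The caller takes, per primary mapped
read, the transcript-3′ clip: the trailing clip for forward alignments and
the leading clip (reverse-complemented) for reverse alignments, so the
returned sequence always reads 5′→3′ along the transcript with its first
base immediately after the cleavage site.

A clip is accepted as a tail when

- its length ≥ `min_len` (default 5 nt), and
- its adenine fraction ≥ `min_frac_a` (default 0.85, **inclusive**, so a
  17/20 clip passes).

Choices worth stating: the A-fraction boundary is inclusive because the
requirement is stated as a percentage without a strictness convention and
an inclusive bound is the natural reading; the 5-nt floor suppresses 1–2 nt
clip noise from imperfect trimming (no minimum is standard, so it is
configurable); the reported tail length is the *entire* clip including
non-A bases, because guanylated/uridylated residues are part of real
tails and the composition stage depends on them. Secondary and
supplementary alignments are excluded (one tail call per molecule).
Adapter removal is assumed upstream; clips are not re-trimmed.

## Gene assignment and summaries

Reads are assigned by maximal overlap of their reference span with gene
spans on the same strand (the read's strand is the transcript strand
implied by the alignment orientation). This is a bed-style overlap, not
exon-aware: for 3′-anchored reads the full span against the gene span is
adequate and much simpler. Exact-overlap ties are *dropped* rather than
double-counted so per-gene distributions stay disjoint.

Summary statistics per (group, condition): mean, median, quartiles by
linear interpolation between order statistics (the numpy default, stated
so results are bit-for-bit reproducible), the number of observations, and
Pearson's **second** skewness coefficient

    skew = 3 (mean − median) / s,   s = sample SD (n − 1 denominator),

undefined (NaN) when n < 2 or s = 0. Moment skewness was the other
candidate reading of "skew"; the median-based form was chosen because it
pairs naturally with the median-centric tail statistics and is robust for
the small per-gene counts. Isoform-level summaries join an upstream
read→isoform table (with intron-retention flags); conflicting assignments
for a read are an error, absent reads are skipped.

## Differential testing

Per gene with ≥ `min_reads` (default 100) passing reads in *each*
condition, a two-sided Mann–Whitney U test compares tail-length
distributions, using the tie-corrected normal approximation with
continuity correction — group sizes passing the filter make the
approximation accurate, and tail lengths are heavily tied integers, so the
tie correction matters. Exact enumeration appears only as a test oracle.
Replicates are pooled per condition before testing. Benjamini–Hochberg
step-up adjustment is applied across genes and calls made at FDR < 0.05;
direction is the sign of the median difference. The 100-read floor is the
dataset-description value and is configurable: counts of significant genes
are sensitive to it.

## Tail composition

Profiles anchor tails either at the cleavage site (position 0 = first tail
base, counting 3′-ward; default range 400 nt) or at the 3′ end (position
0 = terminal base, counting 5′-ward; default range 50 nt). T is reported
as U (tails are RNA); N is excluded from numerator and denominator. At
each position the condition comparison is a Welch t-test on per-read
binary non-A indicators among the tails covering that position. Whether
such tests should be computed over reads or over replicate summaries is
genuinely open; per-read indicators were chosen for power and determinism
(a replicate-proportion mode would be the conservative alternative). No
multiplicity correction is applied across positions — the per-position
p = 0.05 reference is presentation-level.

## Turnover kinetics

Mutation calling counts, per read, transcript-space reference-T sites
(genomic A for minus-strand genes) passing three filters: base quality
≥ 40, distance ≥ 5 nt from both read ends, and not in the SNP/artifact
mask; a passing site is a conversion when the read base is the
transcript-space C (genomic G on the minus strand). Reference bases come
from a FASTA or from MD tags.

Per gene, reads follow a two-component binomial mixture: with probability
θ (fraction-new) a read is labeled with conversion rate p_new, otherwise
background rate p_old. EM maximizes

    Σ_i log[ θ·Bin(n_TC,i | n_T,i, p_new) + (1−θ)·Bin(n_TC,i | n_T,i, p_old) ]

with convergence at Δll < 1e-8 or 500 iterations; the log-likelihood is
monotone by construction and checked in tests. p_old can be fixed from an
unlabeled (no-s4U) control via `estimate_background_rate` — the
recommended mode — or co-estimated. If the components collapse
(p_new ≈ p_old) the mixture is unidentifiable and θ is reported as 0.
This deliberately replaces a full hierarchical replicate-aware model with
a per-gene estimator whose contract — the kinetic quantities — is directly
testable by simulation; it is not expected to reproduce a hierarchical
estimator's shrinkage behavior at low coverage.

Kinetics: θ is clamped at 1 − 1e-6 before k_deg = −ln(1−θ)/t_label
(t_label default 2 h) to keep rates finite; k_syn = k_deg × expression
level under the steady-state assumption, with expression supplied
externally (TPM or normalized counts) — no internal quantification.
Cross-condition comparisons use log₂ ratios, Pearson correlations, and
median-tail bins of width 50 nt.

## Binding fits

Fraction bound is I_nitro/(I_nitro + I_nylon) (protein-bound RNA retained
on nitrocellulose, free RNA on nylon; both zero is undefined). The
hyperbola f(c) = f_max·c/(c + K_d) is fit by least squares from three K_d
starts (min, geometric mean, max of the concentrations), f_max bounded in
(0, 1.2] to tolerate normalization noise; the best-RSS solution is kept
and a curvature-free (constant) series is rejected as degenerate.
Concentrations are nM throughout; the default simulated design is the
two-fold dilution series 4 µM → 62.5 nM.

## Synthetic data: what it emulates, and what it does not

The generator lays non-overlapping single-exon genes with random strands
on one chromosome and emits reads consisting of the 3′ portion of the gene
body plus a tail. Defaults mirror the study conditions the pipeline
targets: control median tail 100 nt with a 1.2× (20 %) lengthening in the
perturbed condition; negative binomial tail lengths with size r = 10
(SD ≈ 33 nt at median 100, a realistic per-gene spread — the empirical
tail-length family is not known, so any overdispersed family would do, and
the NB is parameterized by its median by solving P(X ≤ m) = 0.5 for the
mean); non-A substitutions confined to the terminal 10 tail positions
(3′-end-anchored, as observed; window configurable); labeling parameters
p_new = 0.05, p_old = 0.002, 2 h window; binding series on the 4 µM →
62.5 nM design. Minus-strand genes are written with the tail as a leading
soft clip of (mostly) T in SAM orientation, purely to exercise strand
handling.

Not emulated: sequencing error in gene bodies, splicing structure
(isoform tables are plain TSV fixtures), UMI/adapter chemistry, coverage
biases, or library-size effects. Passing tests therefore demonstrate
correctness of the *computations* under known truth — exact clip
round-trips, calibrated error control, unbiased parameter recovery — not
robustness to alignment artifacts in real libraries.

All generators take explicit seeds and identical seeds give byte-identical
outputs; there is no global random state.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to give stable Monte
Carlo behavior: 10,000 reads for tail round-trips, 2000 genes × 100 reads
for null FDR calibration, 300 genes × 200 reads for power, 2000 tails per
condition for composition, 5000 reads per θ for the EM grid, and 7–21
points per binding fit. The package itself streams alignments and has no
intrinsic scale limit.

## Known limitations

- Gene assignment is span-based, not exon-aware; antisense pairs
  overlapping on opposite strands are handled, but same-strand nested
  genes resolve purely by overlap length, with ties dropped.
- The per-gene mixture EM shares no information across genes or
  replicates; low-coverage genes (< 20 reads) are skipped rather than
  shrunk.
- The composition t-test treats reads as independent units; biological
  replicate variance is not modeled.
- Tail calling trusts the aligner's clip boundaries; internal priming and
  residual adapter are out of scope.
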