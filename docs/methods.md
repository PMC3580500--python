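# Methods

This note documents the analysis implemented by `cpgchrom`: its
assumptions, parameter choices, numerical details, and the scope of what
the synthetic-data tests can and cannot demonstrate.

## Coordinates and gene models

All coordinates are 0-based and half-open, as in BED. A gene is anchored
at its most 5' transcription start site; for a minus-strand gene the TSS
is the right-most base of the annotated extent and `end` lies to its
left. Oriented profiles map relative position +k to the genomic base k bp
downstream in the direction of transcription, so minus-strand windows are
reflected; promoter sequences are reverse-complemented before scanning.

Genes shorter than 3 kb are removed (so that windows extending 3 kb
downstream of the TSS stay within genic sequence), as are genes whose TSS
lies within 500 bp of any other gene's annotated extent (so that upstream
windows are not contaminated by neighbouring genes). Short genes still
count as neighbours when testing isolation, which makes the filter
idempotent. An optional flag restricts the analysis to genes with a
single annotated start site.

## Promoter classification

Island overlap is a point test: a gene is a CpG-promoter gene iff its TSS
lies in `[start, end)` of an island interval. The boundary base is
excluded by the half-open convention; the choice is recorded here because
annotation sources do not state one.

The sequence-based HCP/ICP/LCP scheme scans the strand-oriented promoter
(−1,200..+300 bp; 1,500 bp total) with a 500 bp window sliding in 1 bp
steps (the step is a parameter; classifications are stable under
coarsening to 5 bp on smoothly varying sequence, which the tests check).
The CpG observed/expected ratio of a window of length L is
N_CpG · L / (N_C · N_G), the standard composition-normalised dinucleotide
ratio; it is defined as 0 when a window lacks C or G entirely. HCP
requires some window with o/e > 0.75 and GC% > 55; LCP requires every
window at o/e ≤ 0.48; everything else is ICP. N bases count as neither C
nor G and never form a CpG; GC% is computed over non-N bases, and windows
with more than 10% N are skipped. Only the dinucleotide CG counts — the
ratio is *not* reverse-complement invariant, by construction.

## Expression tiers and matched sets

Expression values are linear-scale; ranking is ascending with ties broken
lexicographically by gene identifier for reproducibility. Tier splitting
is by rank into equal thirds, any remainder going to the lowest tier.
Probe-level data can be collapsed beforehand: probes mapping to more than
one gene are discarded and each gene keeps its maximum replicate-averaged
probe value (the "most sensitive probe" is not formally defined anywhere;
maximum signal is this package's recorded interpretation, and users with
a better probe-sensitivity model should collapse upstream).

Matching is greedy nearest-neighbour without replacement: per tier,
non-CpG genes are drawn uniformly without replacement from a seeded
generator, and each draw is paired with the unused same-tier CpG gene of
nearest log expression, accepted only if |Δ ln expr| ≤ 0.1 (≈ ±10%).
Unmatched draws — typically genes with extreme expression for which no
similarly expressed gene of the other class exists — are simply replaced
by further draws until the quota is met or the tier is exhausted; the
result then reports fewer pairs with a warning rather than padding.
Greedy matching is not globally optimal, but it is deterministic given
the seed, respects the hard tolerance, and in seeded replicates produces
tier-wise expression distributions that a rank-sum test cannot tell
apart, which is the property the downstream comparison needs.

## Dyad tracks

Identical reads (same chromosome, start, end, and strand) are collapsed
to one to suppress amplification bias; including strand in the duplicate
key prevents merging genuine sense/antisense coverage. Each read's start
is shifted 75 bp in its sequencing direction — approximately half the
isolated fragment length, and a parameter — to estimate the nucleosome
dyad: plus-strand dyad = start + 75, minus-strand dyad = (end − 1) − 75,
since BED stores the leftmost coordinate and a minus read's 5' end is its
right edge. Dyads that fall off a chromosome are discarded and counted.
Tracks store exact integer tallies; the depth normalisation (to 10
million fragments by default) is carried as a multiplier applied at
read-out, so count conservation is exact at all times.

## Profiles, smoothing, background subtraction

Profile matrices cover 500 bp upstream to 3 kb downstream of the TSS by
default. Off-chromosome positions are zero-filled, flagged, and excluded
from averages rather than imputed. Rows hold scaled counts so that
averages are comparable across marks sequenced to different depths.

The smoother is a locally weighted polynomial regression: at each
position the 180 nearest positions (absolute span, a parameter) are fit
with a degree-2 polynomial under tricube weights, and the fitted value at
the centre is kept. Because profile grids are uniform, all interior
positions share one precomputed smoother row; edge positions are fit
individually with clamped windows. The confidence band is the fit ± 2
pointwise standard errors of the linear smoother, with residual variance
estimated globally as RSS / (n − tr(L)); ±2 SE approximates a 95% band
and is configurable. The implementation reproduces constants and linear
trends exactly and agrees with R's `loess(…, degree = 2, surface =
"direct")` to ~1e-12 on test fixtures.

Background subtraction slides a centred 75 bp window (1 bp steps) over
both the modification and the nucleosome-occupancy track, differences the
scaled window sums per gene and position, and reports the across-gene
mean ± 2 SE under a Normal assumption. Both tracks must be rescaled to
the same target depth; windows at array edges are truncated, never
wrapped, and the matrices are built with a half-window margin so the
reported range has full windows.

## Promoter statistics

**Asymmetry.** Score = (dyads in [−500, 0)) / (dyads in [−500, +500)),
the TSS base itself counting as downstream — the boundary assignment is a
recorded convention, and the complement identity under reflection is
asserted in tests on fixtures with an empty TSS base. Genes with no reads
in the window are excluded and reported. Group comparison is the
two-sided Wilcoxon rank-sum test with tie correction by default; the
variance-zero degenerate case (all scores tied) returns p = 1. Small
tie-free groups (≤ 8 per side) use the exact null distribution, which the
tests verify against full enumeration. A paired signed-rank variant is
available for expression-matched pairs; both tests are offered because
either can be argued for matched designs, and the default follows the
unpaired formulation.

**Peak shift.** Per gene, the leftmost argmax of its profile row over
[0, 2000] bp inclusive. The default operates on the raw row; a moving-
window option (75 bp) is provided because single-base argmax on sparse
rows is noise-dominated, and the recovery tests use it. Peak positions
are Spearman-correlated with expression rank (tie-corrected, two-sided).

**CTCF enrichment.** Each promoter class is split independently into ten
equal expression bins; per bin the fraction of promoters overlapping a
CTCF site is reported with a 95% Wilson score interval (well-behaved at
fractions near 0 or 1; the interval method is a package choice). Overlap
is either a TSS point test or a ±window intersection. The overall 2×2
class-by-overlap table is tested by χ² without continuity correction —
cell counts in this design are large — and a degenerate table (empty
margin) short-circuits to χ² = 0, p = 1.

## Synthetic data: what it emulates and what it does not

The generator lays out alternating-strand genes of 5 kb spaced 9.5 kb
apart on one chromosome, so the length and isolation filters retain
everything; a CpG island of 500–1,500 bp is centred on each designated
CpG TSS. Promoter sequences come from first-order Markov chains whose
C→G transition probability is the control knob (CpG-rich: GC ≈ 60%,
o/e ≈ 1.3; CpG-poor: GC ≈ 40%, o/e ≈ 0.1), resampled up to a bounded
number of times until the windowed scan confirms the intended class.
Expression is i.i.d. lognormal (ln-scale mean 5.0, sd 1.5 — a heavy-
tailed spread comparable to linear-scale microarray intensities) and
independent of promoter class, which is what makes expression matching
feasible.

Chromatin models place dyads from a mixture of: a uniform background; a
phased Gaussian nucleosome array (first dyad +50 bp, 185 bp period, sd
40 bp); a nucleosome-depleted-region multiplier (default 0.15) over
[−200, 0) that is constitutive for CpG promoters and gated to high
expression for non-CpG promoters; an expression-tier-dependent gene-body
modification peak (e.g. centres 500/800/1,100 bp for low/medium/high
tiers); and a promoter-proximal dual peak (±250 bp, sd 75 bp) whose
upstream weight (0.7 for CpG, 0.45 for non-CpG in the default set) sets
the planted asymmetry. Component masses are scaled so a typical gene's
rate integrates to ≈ 1, making the expected read count per gene equal to
the configured depth (default 50; the recovery tests use 80–150 so that
per-gene statistics are informative). Reads are emitted as 151 bp
fragments on a uniformly random strand, positioned so that the 75 bp
shift recovers the planted dyad exactly from either strand. All
randomness descends from one seed through spawned per-gene substreams.

The generator does *not* emulate real sequence composition, mappability,
MNase digestion bias, cell-type mixtures, or correlated biological
replicates. Passing recovery tests therefore demonstrates that the
pipeline's inference is correct when its assumptions hold — not that the
assumptions hold in any particular real dataset.

## Problem sizes

The test suite and the acceptance script run the matching study at 3,000
genes per promoter class (100 seeds), the chromatin-recovery studies at
300 genes with 20 seeded replicates, the classifier study at 1,000
promoters per class, and the end-to-end pipeline at 200 genes with four
tracks; these sizes give stable statistics for every quantity reported
while keeping a full run in the tens of seconds.

## Known limitations

- Greedy matching can drop more genes than an optimal-assignment matcher
  near the expression extremes; the quota/replacement scheme compensates
  in practice but the matcher is not optimal.
- The loess band uses a global residual-variance estimate; strongly
  heteroscedastic profiles would need a local estimate.
- Peak detection reports a single leftmost maximum and has no notion of
  peak width or multi-modality.
- BED is the only read format in this version (no BAM), and bedGraph the
  only track export (no bigWig).
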