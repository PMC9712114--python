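# Methods

## Scope and data model

`hapcells` operates on four tables tied to a fixed bin grid (default 500-kb
bins, 1-based inclusive coordinates; BED converts at the I/O boundary):
per-cell integer copy number states with GC-corrected "raw" copy, per-cell
haplotype-block allele counts (B count / total count with a ±1 orientation
flag per block), cell QC records (quality, S-phase flag, contamination
fraction, clone label) and an optional centromere table.  Raw copy is the
GC-corrected read count scaled so each cell's mean over unmasked bins equals
its ploidy; the scaling convention matters because amplification thresholds
are expressed on the copy scale.  Bins with mappability ≤ 0.99 or overlapping
a blacklist are masked; cells with quality < 0.75, an S-phase flag or > 5%
contaminating reads are removed.  S-phase and contamination classification
are upstream inputs, not computed here.

## Haplotype-specific copy number inference

Conditioning on the cell's total integer state t per bin, the hidden state is
(a, b) with a + b = t.  Emissions are Beta-Binomial over the bin's aggregated
oriented allele counts with mean mu = b/(a+b) shrunk into [eps, 1−eps]
(eps = 0.01; sequencing error makes pure-allele observations imperfect) and
concentration s (default 50, estimable by method of moments from balanced
regions).  Transitions route probability e (default 0.95; 0.999 is the
documented setting for noisy samples) to the phase-preserving successor — the
state in the next bin's space with nearest B-allele fraction, ties to the
smaller b — and spread the rest uniformly; this defines transitions across
bins whose totals differ.  Totals above t_max = 12 are capped for the state
space (bounds growth at high-level amplifications) while keeping the BAF
grid.  Bins with t = 0 carry the single state (0, 0); observed counts there
are counted as discordant and ignored.  Decoding is exact per-chromosome
Viterbi; reported posteriors are forward–backward marginals of the decoded
state.  The initial distribution is uniform over the first bin's states.

Phasing proceeds in three stages:

1. **Aggregate initialization** — each block is oriented so its
   population-aggregate BAF is ≤ 0.5 (allele B = chromosome-level minor
   allele); ties keep the current orientation, empty blocks are dropped.
2. **Switch-error correction** — aggregate BAF is noise-dominated wherever
   most cells are allelically balanced, so block orientations are chained by
   local covariance: walking each chromosome, a block whose per-cell BAF
   deviations covary negatively (z < −2) with the mean deviation of up to 4
   preceding blocks is flipped.  Links without significant signal keep the
   aggregate orientation; in fully balanced stretches orientation is
   inconsequential because the states there are symmetric.
3. **Regional re-phasing** — after each Viterbi pass, every cell receives a
   regional imbalance sign per contiguous imbalanced run of its decoded path
   (the run-level majority of mu − 0.5).  Each block is then re-oriented
   against the signed count deviations of the cells imbalanced there,
   flipping on z < −2, and decoding repeats (up to max_phase_iters = 10).
   The run-level sign is what breaks the stuck configuration in which a
   mis-oriented sub-run mirrors the decoded path: a bin-level vote is blind
   to it, the regional majority is not.  This matters precisely in the
   parallel-CNA regime, where two small cell subsets are altered on opposite
   homologues inside a region that is balanced in everyone else.

Finally A/B labels are canonicalized per chromosome so the aggregate BAF of
allele B is ≤ 0.5.  Phasing is therefore defined up to a per-chromosome label
swap, and accuracy metrics allow that swap.

## Copy-number statistics

Cell ploidy is the modal state over unmasked bins (ties to the smaller
state).  Pseudobulk consensus profiles take the per-bin mode of states and of
(a, b) pairs (ties to the smaller value / lexicographically smaller pair) and
the median of raw copy and BAF.  Missegregation rescales cells whose ploidy
differs from the clone consensus (state × clone_ploidy / cell_ploidy, rounded
half away from zero — no rounding rule is standard, this one is symmetric)
and flags a chromosome when a single non-zero offset covers ≥ 75% of its
unmasked bins.  Gain/loss segments are maximal runs of unmasked bins above or
below ploidy; masked bins neither break nor extend a run, and runs spanning
≤ 1.5 Mbp are discarded as noise.  HLAMP bins require ≥ 10 cells at raw copy
≥ 10; their copy variance is the across-cell variance of raw copy divided by
cell ploidy and centered on the clone mean, making it invariant to clone
ploidy and clone-level amplitude.  "Variable" amplitude between clones uses
max/min clone consensus copy ≥ 2 (inclusive; a zero minimum is infinite and
variable).  Locus feature vectors (±15 Mbp window clipped at chromosome ends)
comprise the Shannon entropy of haplotype-state frequencies, SV counts and
type proportions from a supplied SV table, translocation chromosome counts,
locus/chromosome copy ratio, mean state, mean segment size and count, and
mean minor-allele copy; features are standardized before Ward clustering with
the cluster number chosen by silhouette width.

Disjoint segmentations take the union of group-level breakpoints and
genotype every cell per segment by the modal (total, a, b) triple.  Two
segmentation sources are provided: clone-consensus segmentations, and a
recurrent-breakpoint segmentation that keeps per-cell change points carried
by more than 1% of cells (matching the parallel-CNA prevalence rule) and
merges positions within 5 bins of a better-supported one — half the minimum
reportable parallel-CNA span — as jitter of the same breakpoint.  The latter
is required for rare subclonal events, which never shift a clone consensus.

## Serration

Clone-consensus segments are classified against their neighbours (local
minimum / maximum / intermediate; terminal segments use the one-sided rule),
and cell segments (states rescaled to clone ploidy) may only match clone
segments whose relation they share, taking the maximal-overlap compatible
segment (ties leftmost).  A cell carries a clone breakpoint when it has
matches to both flanking consensus segments; its breakpoint position is the
first bin of the right-hand match.  Cells noisier than the mean |raw −
state| of stable cells (≤ 5 unmasked bins each side of the breakpoint,
clipped at chromosome ends) are removed; the serration score is the fraction
of retained cells at rare positions, where rare means strictly below 5% of
retained cells.  Summaries cover only eligible events (≥ 100 cells, flanking
consensus segments totalling ≥ 20 Mbp) and report the fraction scoring
≥ 0.15.

## Evolutionary statistics

The copy-number transformation distance counts minimal ±1 contiguous-interval
operations turning one integer profile into another, with values floored at
zero and zeroed positions never regaining copies (a zero source position with
positive target is infeasible).  It is computed by a dynamic program over the
number of deletion and amplification intervals covering each position,
justified by the existence of an optimal solution with all deletions before
all amplifications; positions with target zero decouple the amplification
chain and permit deletion overshoot.  The DP is verified exhaustively against
a breadth-first-search oracle in the test suite.  The WGD-aware distance is
d = min(d1, d2, d3) with d2, d3 the distances after doubling either profile,
incremented by one when a doubled route is strictly better (ties resolve to
the plain distance without increment); distances sum per chromosome per
haplotype.  Pairwise matrices subsample 250 cells (seeded) and symmetrize by
taking the smaller direction, since a homologue lost in one cell makes one
direction infeasible.

Parallel CNAs are disjoint segments > 4 Mbp where both homologues deviate
from their modal values in more than 1% of cells each; the total-copy CCF
assigns clonal (> 80%), subclonal (20–80%] or rare (≤ 20%) status.  Event
rates reconstruct ancestral binary states (gained / not gained, lost / not
lost relative to the modal total) on the supplied phylogeny with the Sankoff
algorithm at unit transition cost, summing parsimony scores per segment class
— whole chromosome (≥ 95% of unmasked bins), arm (≥ 95% of one arm), else
segmental; the 95% tolerance is this package's choice — and dividing by the
number of cells.  Cophenetic diversity is the mean pairwise tip path length.

## scRNA allelic imbalance

SNP counts are oriented with the DNA-derived block phasing, aggregated per
cell over segments ≥ 10 Mbp, and cells with fewer than 200 total SNP counts
are dropped.  DNA–RNA concordance is the Pearson correlation of per-segment
mean BAF across modalities (undefined below 3 shared segments).  The
nearest-neighbour enrichment score is log2(observed / expected fraction of
same-state neighbours), expected being the global state fraction; the log
makes 0 a perfectly mixed neighbourhood, positive values overrepresentation,
and an observed zero a censored −inf.

## Synthetic populations

The generator walks a random clone genealogy from a diploid (1,1) ancestor,
applying haplotype-specific gains and losses at whole-chromosome, arm and
segment scales (Poisson-distributed per clone lineage), optional root WGD,
explicit planted clone events, parallel events (independent cell subsets
altered on opposite homologues), serrate breakpoints (per-cell boundary =
modal ± (geometric(p) − 1) with random sign, so p is the stable fraction) and
HLAMP loci with lognormal per-cell amplitude jitter affecting read depth.
Readouts: bin reads ~ NegativeBinomial(mean = 50 reads per copy, dispersion
10 — DLP+-like shallow, ~100 reads per diploid 500-kb bin), block totals by
binomial thinning (20% of reads allele-informative, two blocks per bin,
~20 counts per diploid bin), B counts ~ BetaBinomial(mu, s = 50), block
polarity randomized with phase-switch errors at 0.002 per cell-block.  All
draws come from one seeded generator; identical seeds give byte-identical
outputs.

The generator emulates clone-structured copy number variation, not real
sequencing: there is no GC or mappability bias (off by default to keep
fixtures interpretable), no doublets or S-phase cells, no replication-timing
structure, and total integer states are taken as given rather than called
from reads.  Passing tests therefore demonstrate correct inference under the
stated generative model at realistic depths; they do not certify performance
on real libraries with correlated coverage noise or total-CN calling errors.

Accuracy against ground truth reports bin-level state accuracy (up to the
per-chromosome label swap) and LOH precision/recall at the genotyped disjoint
segment level — the unit at which segment calls are compared across cells —
rather than on raw per-bin runs, where isolated Beta-Binomial tail flips
(~2 per 10^4 bin-cells at depth 20) would each count as a false segment.

## Numerical and degenerate-input conventions

Modal ties resolve to the smaller value throughout, for determinism.  BAF is
undefined (NaN) where totals are zero.  Medians of real-valued fields average
the middle pair.  Clones with a single cell clone-center to zero.  Events
with no stable breakpoint cells are skipped and logged; scores over fewer
than two retained cells are NaN.  Zero-length inputs raise.  The pipeline
fans one seed out to per-module substreams so stages can be re-run
independently; every CLI run writes a manifest with resolved parameters, seed
and version.

## Problem sizes

Default test and acceptance runs use 120–500 cells on two chromosomes of
60–100 bins at ~20 allele counts per bin — large enough for every statistic's
operating regime (LOH and parallel-event recovery, serration eligibility at
100+ cells) while keeping the full suite under a minute of compute.  Oracle
equivalence checks are exhaustive where the state space permits (all profile
pairs of length ≤ 4 with entries ≤ 4 for the transformation distance) and
seeded-random otherwise (Viterbi versus path enumeration at ≤ 8 bins,
Sankoff versus exhaustive labellings at ≤ 8 tips).
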