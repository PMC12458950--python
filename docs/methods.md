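# Methods

This note documents the models, conventions and numerical choices behind
`clonetrace`, and what its synthetic benchmarks do and do not demonstrate
about real data.

## Barcode library model

A barcode library is a degenerate IUPAC pattern (per-position degeneracy
1–4) plus a realized diversity and an MOI. The pattern space size is the
exact integer product of per-position degeneracies; sampling draws each
position independently, which is exactly uniform over the space, with a
uniqueness retry loop (capped at 100·n attempts) that only matters when the
request approaches the space size. The true commercial oligo design of the
265-nt barcode is proprietary to the vendor sheet; `default_barcode_pattern`
supplies a configurable `NWSN`-repeat stand-in and is documented as such.

Two design statistics justify clonal interpretation. With integrations per
cell K ~ Poisson(m), the fraction of barcoded cells carrying more than one
barcode is (1 − e^(−m)(1+m))/(1 − e^(−m)); at the conventional transduction
ceiling m = 0.4 this is ≈ 18.7%, which is why multi-candidate cells are
flagged rather than force-assigned downstream. With n cells drawing
uniformly from L barcodes, the expected number of cells sharing their
barcode is n(1 − (1 − 1/L)^(n−1)); at library scale (millions) versus
experiment scale (tens of thousands of cells) this is negligible.

## Tag extraction

Reads are scanned for the 33-nt vector-backbone anchor on both strands;
per-window Hamming distance is computed vectorized (an exact-substring
shortcut handles the error-free majority). The hit with fewest mismatches
wins; ties prefer the forward strand, and within a strand the leftmost
minimum wins. Positions are 0-based, half-open, and reported in the
anchor-strand orientation of the read. The default mismatch budget is 2
(~6% of the anchor): random 33-mer hits at that radius are vanishingly rare,
so specificity is not materially traded for sensitivity.

The clone tag is the 15 bases abutting the anchor — by default on the 5′
side (`before_anchor`), i.e. the 3′ terminus of the transcribed barcode;
`after_anchor` is selectable for constructs read from the other end. Tags
containing N are discarded; each failure returns a reason code
(`no_anchor`, `truncated`, `ambiguous_base`) tallied by the tabulator.

Error correction is a directional-adjacency collapse in the UMI-denoising
tradition: tag b is absorbed into tag a when hamming(a,b) ≤ 1 and
count(a) ≥ 2·count(b) − 1, processing tags from highest count down with
lexicographic tie-breaks. The pass repeats until a fixed point: a single
greedy pass is not always idempotent, because a parent's accumulated count
can enable a merge between two originally stable tags, and idempotence plus
input-order independence are properties the rest of the pipeline relies on.
Total counts are conserved; the merge log records every absorbed tag with
its fully resolved parent. Correction runs on counts pooled across cells
(an error tag's parent may sit in another cell), then corrected tags are
tabulated per (cell, clone) with read and distinct-UMI support.

Clone assignment per cell: candidate tags need ≥ 2 distinct UMIs (read
counts stand in when the input carries no UMIs); one candidate names the
clone, none leaves the cell unassigned, and a runner-up reaching 20% of the
top support flags a multiplet. These thresholds are exposed; the defaults
assume droplet data of typical depth.

Full-length barcode reconstruction anchors every read of a clone at its
anchor coordinate and takes a per-position simple majority over covering
reads; ties and uncovered positions yield N. The barcode occupies the 265
bases ending at the anchor start (`before_anchor`) or starting after the
anchor end.

## Clone dynamics and fate classification

Clone proportions are fractions of assigned cells (multiplets and
unassigned cells excluded from the denominator). To compare abundance
across time points with wildly different tumor sizes, proportions are
multiplied by tumor volume (mm³) and a dimensionless global
transcriptional-activity factor; the activity factor defaults to 1, and
when expression data exist it can be estimated as mean counts per cell
relative to a reference time point. How the original activity normalizer
was defined is not something the abundance tables pin down, so it is kept
as an explicit, documented input.

Each clone's mass series is divided by its own maximum before fitting.
This is the central scale convention: it makes a single absolute RSS
threshold (0.1) meaningful across clones spanning orders of magnitude and
makes classification invariant to uniform rescaling of the series. The fit
minimizes Σ (y − A·e^(±kt))² over A ∈ (0, 2], k ∈ [0, 1]/day, seeded by a
log-linear regression (pseudocount 1e-6) plus a coarse profile search over
k with A solved in closed form (Â = Σy·e / Σe²), then polished with bounded
least squares at tight tolerances. Noise-free exponentials are recovered to
|Δk| < 1e-6; on random series the attained RSS matches a dense 400×400
(A, k) grid search within 1e-3.

Fate rules, applied in order: a clone whose proportion never reaches the
low-abundance floor (default 1e-4, roughly single-cell detection at typical
cell counts) is Multi-fate outright; otherwise both models are fit and a
model passes when RSS < 0.1 with k > 1e-6 (a zero rate carries no
direction). Exactly one passing model names the fate — decay → Sensitive,
growth → Persister. When both pass, the lower RSS wins and an exact tie is
Multi-fate; when neither passes, Multi-fate. The k > 1e-6 guard keeps flat
trajectories (which both models fit perfectly with k = 0) from being
assigned a direction by numerical noise.

Shannon diversity uses natural logs over categories with positive counts;
the variance estimator is (Σ pᵢ ln²pᵢ − H²)/N + (S−1)/(2N²), i.e. the
first-order delta-method term plus the small-sample correction, and
Hutcheson's t-test uses t = (H₁−H₂)/√(Var₁+Var₂) with Welch-style degrees
of freedom floored at 1. Identical samples return t = 0, p = 1 by
convention; zero pooled variance with unequal H is rejected as degenerate.

## CNV burden

The CNV score of a cell is the fraction of genes whose inferred relative
copy number lies strictly outside [0.9, 1.1] — boundary values do not
count, matching the indicator form of the definition. CNV–expression
coupling is assessed per cell (Spearman over genes present in both
matrices, no imputation), then summarized per clone group by the median;
cells with constant vectors are dropped with a warning rather than given a
fabricated rank correlation.

## Spatial statistics

The field of view is tiled into n×n equal rectangles; interior patch edges
are half-open (boundary points go to the lower-left patch) and the outer
right/top edges are closed, so every point lands in exactly one patch and
counts are conserved. Presence per channel is count ≥ 1 by default (the
binarization rule is a free choice; it is exposed). The 2×2 presence table
feeds Fisher's exact test with the two-sided minimum-likelihood p
(hypergeometric probabilities ≤ the observed table's, margins fixed) and
the sample odds ratio a·d/(b·c) (∞ when b·c = 0 with a·d > 0, NaN when both
products vanish).

One calibration subtlety is worth stating plainly: an exact conditional
test on a discrete support is conservative — under the null,
P(p ≤ α) ≤ α strictly — so raw Fisher p-values are super-uniform and a
two-sided uniformity test on them rejects no matter how correct the
implementation. The calibration diagnostic used here is therefore the
randomized probability-integral transform `fisher_null_pit`: with margins
fixed, the exact null distribution of the p-value is enumerated and
u = P(p < p_obs) + U·P(p = p_obs) is returned, which is Uniform(0,1) if and
only if the test is calibrated. The benchmarks check both that the PIT is
uniform and that raw p-values are not anti-conservative at conventional α.

Moran's I is (n/W)·Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)² with W the raw weight
sum; weights default to a binary distance band on spot coordinates
(row-standardization optional, rook lattice adjacency available for
gridded data) since spot-array neighborhood conventions vary. The
permutation test shuffles values over positions, includes the observed
arrangement in the null set, and is two-sided around the null mean; the
analytic null expectation is −1/(n−1).

## Synthetic-data generators

`simulate_clone_dynamics` draws sensitive clones as A·e^(−kt) with
k ~ U(0.05, 0.2)/day, persisters as A·e^(+kt) with k ~ U(0.02, 0.08)/day,
and multi-fate clones as flat trajectories at 1–5 × 10⁻⁶ relative
amplitude; within-fate amplitudes follow a symmetric Dirichlet
(concentration 5 — moderate, realistic clone-size inequality), with
sensitive clones holding 95% of the initial tumor mass and persisters 5%.
Observation noise is multiplicative log-normal (default sd 0.05). Tumor
volume is taken proportional to total simulated clone mass, scaled to
500 mm³ at day 0 (the typical treatment-start volume): this makes the
proportion × volume normalization recover each clone's exponential mass
exactly, which is the coherence the classifier's model assumes, and the
decline-to-nadir-then-regrowth volume curve emerges from the fate mix
rather than being imposed. The curve does not reproduce a mid-treatment
plateau; none of the benchmarks depend on one.

`simulate_reads` builds each read as flank + 250-nt barcode body + 15-nt
tag + anchor + flank, applies i.i.d. substitutions, reverse-complements
about half the reads, and attaches unique 16-nt cell tags and 12-nt UMIs.
`simulate_cnv_matrix` plants amplified (~1.3) and deleted (~0.7) gene
blocks over a Normal(1, 0.02) baseline clipped inside the neutral band, so
the per-cell score recovers the planted fraction exactly, with optional
multiplicative CNV–expression coupling per group.
`simulate_colocalized_points` drives both channels from a latent patch
grid: channel A occupies patches at rate 0.2 (clone-specific FISH signals
are sparse in a section), and for each A patch channel B re-uses it with
probability `co_occurrence` or picks a uniform patch otherwise, so
co-occurrence 0 is exact independence. All generators are bit-reproducible
under a fixed seed.

What the benchmarks show — and do not. The simulators reproduce the
statistical structure the methods assume: exponential clone kinetics,
uniform substitution errors, rectangular block CNVs, patch-level spatial
coupling. Real data add complications deliberately out of scope here: PCR
jackpotting and chimeras, cell-barcode collisions and ambient RNA, CNV
segmentation artifacts, tissue-geometry confounds. Passing benchmarks
demonstrate correctness of the statistics and robustness at realistic
noise levels, not immunity to those artifacts.

## Problem sizes

The standard benchmark sizes are 300 clones (100 per fate) for fate
recovery, 50,000 reads (100 clones × 25 cells × 20 reads) at 1%
substitution error for the extraction round trip, every 2×2 table with
N ≤ 30 for the Fisher oracle sweep, 10⁶ Poisson draws per MOI for the
Monte-Carlo check, 10,000 permutations for the Moran null, and 500
replicates for co-localization calibration — sizes at which the stochastic
checks have comfortable margins while the whole suite runs in minutes on a
laptop.
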