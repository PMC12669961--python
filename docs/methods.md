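# Methods

This note documents the models and numerical choices behind `devenh`: what
each stage computes, which parameters matter, what the synthetic study does
and does not emulate, and where the design was genuinely open.

## Coordinate and insertion conventions

Fragment records are 0-based half-open `(chrom, start, end, barcode)`. The
two fragment endpoints are treated as the two Tn5 insertion sites, already
offset-corrected as in standard fragments files; no further +4/−5 shift is
applied. All window counting uses the insertion coordinates `start` and
`end − 1`. SNP positions are 1-based; a SNP at position *p* overlaps a peak
`[start, end)` iff `start ≤ p − 1 < end`. Every boundary comparison in the
cascade is strict exactly where the study words it strictly ("more than
2.75", "less than 1 × 10⁻⁵", "r² > 0.9") and inclusive where it is not
(score ≥ 25, score ≥ 10, FDR ≤ 0.01 for markers).

## Per-cell quality control

RNA mode drops cells below `median − k·MAD` on library size and genes
detected (k = 1 each) and above `median + 2·MAD` on mitochondrial fraction,
plus a fixed 50,000-UMI doublet ceiling; aggregated mode relaxes the MADs to
(2.5, 3, 3) and uses the 99.5th-quantile ceiling. The MAD is the raw median
absolute deviation — the 1.4826 normal-consistency factor is **not** applied
by default (a `mad_scaled` flag enables it). One-sided MAD filters are not
idempotent in general (re-estimating the median/MAD on a truncated sample
can move the threshold); in practice a single pass removes the gross
outliers and a second pass on the retained core is a no-op, which is what
the tests assert.

ATAC mode retains cells with TSS enrichment ≥ 4 and ≥ 1000 fragments. The
TSS enrichment score aggregates insertions over all TSSs, comparing the
signal windows (TSS ± 50 bp) with distal flanks ([−2000, −1900] and
[+1900, +2000]):

    score = (n_signal + 1) / (n_flank · signal_bp / flank_bp + 1)

i.e. a pseudocount of one insertion on each side after rescaling the flank
count to the signal width. Adding the pseudocount to *counts* rather than to
per-bp *rates* keeps the score discriminative at single-cell depth (a per-bp
pseudocount of 1 would pin every sparse cell to a score of ~1) while
preserving the limiting behaviour: a cell with no promoter-proximal signal
scores ≤ 1, and flat deep coverage converges to 1. Windows are configurable.

In-silico doublet detection synthesizes `n/4` pseudo-cells as sums of random
cell pairs, co-embeds them with real cells by **depth-sensitive** LSI
(IDF-weighted raw counts, no per-cell normalization, no binarization — a
pair-sum then separates from singlets by both composition and total signal),
and flags a real cell when the synthetic fraction among its 25 nearest
neighbours exceeds 2× the global synthetic fraction. Keeping the synthetic
fraction well below 1/enrichment makes the threshold attainable;
row-normalized embeddings were rejected because they collapse pair-sums of a
homogeneous population onto the singlet cloud.

## Gene filtering, normalization, HVGs, metacells

Genes with mean UMI per cell below 0.01 are removed (computed after cell
QC). Size factors use pooled deconvolution: cells are ring-ordered by
library size; each pool (sizes 21, 41, 61 by default) contributes one linear
equation `Σ_{j∈pool} θ_j = median_g(pool_sum_g / ref_g)` against the average
pseudo-cell, solved by sparse least squares with low-weight library-size
anchor rows for conditioning; factors are scaled to geometric mean 1 and
must be positive (an error advises larger pools otherwise). Normalized
expression is `log(1 + 10⁶ · count / (factor · mean library size))` —
division by the size factor, scaling so cell totals average one million,
then a natural log with pseudo-count 1.

HVG selection decomposes per-gene variance of normalized expression into a
technical component — a lowess trend of variance on mean (frac = 0.3) — and
a biological residual. The p-value is a normal upper-tail test on the
residual standardized by a robust scale (1.4826 × MAD of residuals, so the
mostly-null gene set defines the null spread), BH-adjusted; a gene is an HVG
iff biological variance > 0.5 and FDR < 0.05. On Poisson nulls
(500 × 500) the realized false-positive rate is ~0 at FDR 0.05 and
`P(p < 0.05) ≈ 0.05`.

Pseudo-multiome metacells average exactly ten cells sampled without
replacement per cluster, independently per modality; the sampled memberships
are returned so each metacell can be recomputed by hand.

## Peak calling and LSI

With model building and local background disabled, summit calling reduces to
fixed-window pileup: every insertion is extended to a 150 bp window starting
at `pos − 75`; per-bp pileup is compared against the global mean rate
λ = (insertions × 150) / genome length with a Poisson upper tail. Candidate
regions are maximal runs where the per-bp p-value is below a fixed 0.1
(independent of the final q cutoff, so tightening `q_max` always yields a
nested subset of summits); within a region the summit is the midpoint of the
bins within ~3 Poisson standard deviations of the maximum (a flat-top
plateau's noisy argmax would otherwise wander); the summit's p-value is
BH-corrected across all candidate summits and summits with q < 0.1 are kept,
scored as −log₁₀(q).

Summits expand to `[summit − 250, summit + 251)` — width exactly 501 — and
are merged by greedy score-ranked iteration: keep the best-scoring
candidate, discard all overlapping candidates, repeat. Ties break by
coordinate so the result is input-order invariant; edge summits are shifted
inward (never clipped) and flagged. Per-cluster peak sets are called
independently and merged into a union set the same way; a union peak carries
each cluster's best overlapping score, the combined score is the maximum,
and the developmental-only score comes from a separate call on developmental
cells — peaks without one are rejected by the cascade with an explicit
reason.

LSI is term frequency (per-cell normalization of the binarized matrix) ×
`log(1 + n_cells / (1 + df))`, followed by truncated SVD (ARPACK, so results
are deterministic and row-order equivariant); the first component is dropped
when |r| > 0.9 against depth.

## Differential accessibility

Two accessibility scales are used deliberately. `mean_diff` is computed on
`log1p` counts depth-normalized to the median cell — the scale on which the
cascade's 0.03 mean-difference threshold is meaningful for a moderately
accessible peak. `log2fc` is computed on counts-per-million means with a
pseudo-count ε = 1: at CPM scale a genuinely accessible peak's group mean is
~10–300, so ε guards zeros without flattening real fold changes. (Scaling
raw means to the median cell depth instead — where per-peak means are ~0.1 —
would let ε dominate and cap every log₂FC near zero, making a 2.75 gate
unreachable; this is why CPM was chosen.)

The test is a two-sided Wilcoxon rank-sum: exact enumeration when both
groups have ≤ 8 cells, otherwise the tie-corrected normal approximation,
vectorized across peaks; a peak with constant raw counts across all tested
cells gets p = 1 by convention; BH across peaks. Marker peaks per cluster
test the cluster against a bias-matched background: each group cell's
nearest non-group neighbour in the space of LSI coordinates concatenated
with standardized bias covariates (log₁₀ fragments, TSS enrichment),
deduplicated. For the group-1 (developmental + BO) vs group-2 (adult)
comparison feeding the GWAS cascade the explicit adult group is used
directly, since both groups are defined.

## GWAS cascade

Liftover uses a simplified block-offset chain (1-based inclusive source
blocks, per-block target offset); SNPs in no block are reported as unmapped
and excluded; SNPs already in the target build pass through with a warning.
The cascade selects peaks with (mean_diff > 0.03 OR FDR < 0.01) AND
log₂FC > 2.75 AND combined score ≥ 25 AND developmental-only score ≥ 10,
then intersects them with SNPs at P < 1 × 10⁻⁵. LD collapse builds a graph
with an edge wherever r² (squared Pearson correlation of allele dosages)
strictly exceeds 0.9 and reports connected components as loci — component
closure is the simplest rule consistent with pairs "marking" one locus;
missing genotype pairs count as r² = 0. The representative is the lowest-P
member; the genome-wide flag (P < 5 × 10⁻⁸) is annotation only and never
gates the cascade.

## Motif analysis

PWMs are parsed from JASPAR-format text (counts gain a +0.8 pseudocount per
cell; probability matrices are detected by unit column sums and taken
as-is). Scores are base-2 log-odds against the background, maximized over
all offsets on both strands. Two thresholds serve two different decisions:

* **Per-k-mer threshold** (stored on the PWM): the score of the top 0.1% of
  random background k-mers, estimated from 100,000 seeded draws. This is the
  threshold used for allele-effect calls, where the scan window is only
  2L − 1 bp around the SNP.
* **Per-peak threshold** (used by `motif_hits`): the exact score quantile at
  `0.001 / n_windows`, computed from the discretized exact score
  distribution (dynamic-programming convolution of per-position score
  distributions, grid 0.01, floor-rounded so thresholds are conservative).
  Scanning ~1000 windows of a 501 bp peak at the per-k-mer threshold would
  saturate (most random peaks would "hit"); the per-peak correction keeps
  the expected false-hit rate per peak near 0.1%.

An allele effect is *creates* iff the risk allele's best site reaches the
threshold while the reference's does not, *disrupts* for the reverse, and
the predicted regulatory direction combines the call with the TF's role:
creates×repressor and disrupts×activator → reduced activity. The shipped
role table assigns YY1, ZNF18 and ZNF708 as repressors and KLF5, NFIC and
TEAD as activators; roles are data, not code. Classification is
antisymmetric under allele swap.

Motif enrichment in marker peaks is the hypergeometric upper tail of k
motif-carrying markers given (N peaks, m carriers, K markers), BH-adjusted,
reported as −log₁₀(P_adj). Motif deviations follow the chromVAR recipe:
expected motif counts per cell from the cell's depth times the global
fraction of reads in the motif's peaks; raw deviation (obs − exp)/exp,
centred across cells; z against 50 background peak sets sampled without
replacement within GC-content × mean-accessibility decile strata (a
simplification of full Mahalanobis matching, documented as such).

## The synthetic study

Defaults: 3 chromosomes × 2 Mb, 6 clusters × 330 cells (two developmental,
two Barrett's, two adult), 40 planted 501 bp peak regions per cluster (40%
from a shared pool open in all clusters, 25% differential — open in all
developmental+Barrett's clusters and absent from adult — the rest
cluster-specific), background 2 × 10⁻⁴ fragments/bp/cell, 25-fold in-peak
enrichment, ~100 promoter insertions per cell, fragment lengths uniform in
[80, 300] bp, 4% doublets (union of two cells' draws), 5% low-quality cells
(quarter depth, a tenth of promoter signal), 300 genes (5% mitochondrial,
10% HVGs with biological log-variance 2.0, 10% planted below the 0.01-mean
filter), 40 GWAS SNPs (40% significant, half of those inside differential
peaks, 25% LD partners, 60% engineered alleles), 400 genotyped individuals.

Rationale for the two least obvious choices. *Enrichment fold 25*: typical
ATAC peaks are tens-fold enriched over background; after dilution by
fragment ends falling outside the peak and the CPM pseudo-count, a 25-fold
planted enrichment yields observed log₂FC ≈ 4, a comfortable margin over the
2.75 gate — at 10-fold the observed value sits at the gate and recovery
becomes a coin flip, which would test luck rather than the cascade.
*Fragment centres, not starts, uniform in the peak*: placing starts
uniformly skews the insertion cloud ~150 bp rightward, so called 501 bp
windows systematically miss SNPs near the left edge of the planted interval;
centre placement keeps summits near interval centres.

PWMs are engineered with one highly informative anchor position (p ≈ 0.997)
and moderate flanks (p = 0.55): a single base change at the anchor moves the
best-site score across the calibrated threshold in either direction, which
is what makes single-SNP creates/disrupts calls possible at all. With
uniformly sharp columns, a one-mismatch site still outscores the random
99.9th percentile and no single substitution could cross it. Engineered
sites are verified at plant time by exhaustive offset/strand scan against
the same thresholds the pipeline will calibrate, and re-planted elsewhere on
failure.

What the generator does **not** emulate — and what passing tests therefore
do not show: read-level artefacts (sequencing error, mapping bias, duplicate
structure), realistic LD decay along chromosomes (LD partners are engineered
column copies), chromatin-state correlation between neighbouring peaks,
batch effects across samples, GWAS P-values arising from actual association
tests (they are assigned), and real genome sequence composition (uniform
base frequencies). Recovery results certify the pipeline's logic under its
stated assumptions, not performance on patient data.

## Problem sizes

The default study (~2000 cells, 6 Mb genome, ~3 × 10⁶ fragments) runs end to
end in under a minute on one CPU; the test suite runs the full pipeline on
three seeds plus many scaled-down instances (30–60 cells per cluster) chosen
so each property is tested at the smallest size where its signal is
unambiguous.

## Known limitations

* The summit caller implements only the fixed-window/global-rate special
  case; model building, local background and broad peaks are out of scope.
* Deconvolution size-factor pools assume ≥ 61 cells at the default pool
  sizes; the pipeline skips RNA normalization below that.
* Bias-matched backgrounds use a plain nearest neighbour per group cell;
  duplicate matches are removed rather than re-matched, so the background
  can be smaller than the group.
* LD collapse treats missing r² as 0, which can split a true locus if
  genotypes are incomplete.
* The motif layer scores additive log-odds only; no energy models,
  dinucleotide dependencies or footprinting.
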