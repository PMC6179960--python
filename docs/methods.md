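# Methods

`epiprime` models the regulatory-element dynamics of a branching
differentiation system: a shared progenitor gives rise to two lineages
(here labelled astroglial — aNPC, eA, lA — and neuronal — nNPC, eN, lN), and
distal regulatory elements move through the chromatin-state sequence
*none → primed → active*, where priming (H3K4me1 without H3K27ac) precedes
transcriptional activation (H3K4me1 plus H3K27ac). This note records the
models, the defaults, the deliberately chosen numerical conventions, and
what the synthetic benchmark does and does not demonstrate.

## Coordinate and interval conventions

All coordinates are 0-based half-open, identical to native BED, in memory
and on disk. Two intervals that merely touch do not overlap; overlap
requires at least `min_overlap_bp` shared bases (default 1, the most
permissive criterion — a configurable choice, since peak-set algebra in the
literature rarely states its overlap rule). A region is reduced to a single
deterministic point — `floor((start + end) / 2)` — for annotation and
distance computations. All ties (equidistant genes, equal scores) break on
the lexicographically smallest identifier so results are platform-independent.

## Annotation and peak-to-gene assignment

Categories promoter > exon > intron > intergenic are assigned by midpoint
with that precedence. The promoter window is TSS −1000/+500 bp,
strand-aware; the value is a configuration field because annotation-tool
defaults vary and none is canonical. A peak inside a gene (promoter, exon or
intron) belongs to its host gene regardless of distance; an intergenic peak
is assigned to the nearest TSS on the same chromosome only when
|midpoint − TSS| < 50 kb (`max_tss_dist`), otherwise it stays unassigned.
The 50 kb figure is the standard distal-association radius for
enhancer-to-gene assignment in this kind of analysis.

## Signal model and the input-free peak caller

Read coverage is represented as fixed-width binned counts (default 200 bp).
Region quantification weights bin counts by fractional overlap, which makes
it additive over partitions and invariant to bin refinement. Enrichment is

    log2( (chip + p) / chip_lib ) − log2( (input + p) / input_lib ),

with pseudocount p = 1 on both counts; it is invariant to rescaling both
library sizes and finite for empty regions. A region is "marked" for one
histone modification when its enrichment is ≥ `mark_threshold` (default
1.0 log2 units, i.e. two-fold over input). The threshold is a free
parameter: with the default simulation folds (8× acetylation, 6×
methylation) marked regions sit far above it, so the calls are not
threshold-sensitive there, but on shallow real data this knob matters.

The peak caller is intentionally minimal and input-free: per bin, a
one-sided Poisson test against λ = max(global mean rate, local mean in
±5 kb) — the dynamic-lambda idea of standard callers — BH-corrected across
all bins, an additional fold floor log2(count/λ) ≥ 1, and merging of
significant bins separated by at most one bin. It is a defined, testable
stand-in for an external caller, not a reimplementation of one; on
homogeneous Poisson noise it returns zero peaks in ≥95% of runs.

## Chromatin states and trajectories

The state logic is the exhaustive 2×2 table of the two marks: primed =
K4me1 only, active = both, acetyl-only = K27ac only (kept separate rather
than folded into active, so the table stays lossless), none = neither. A
region is *primed-then-activated at stage s* iff it is primed at the stage
preceding s and active at s. States are deterministic threshold logic; no
probabilistic segmentation (HMM-style) is attempted, because the analyses
this package supports operate on exactly these binary calls.

Trajectory clustering is k-means on row-z-scored enrichment patterns
(stage × mark × lineage features), Euclidean distance, 25 restarts, fixed
seed, restricted to regions primed or active at the progenitor stage. k is
a parameter (`k_trajectory`); the pipeline default of 6 equals the number
of distinct planted archetypes among progenitor-primed classes in the
synthetic design. Zero-variance rows cannot be z-scored and are rejected.

## Differential expression

Normalisation is median-of-ratios: factor_j = median over genes positive in
all samples of count_gj / geometric-mean_g, rescaled to geometric mean 1
(total-count fallback with a warning when no gene is everywhere-positive).
Downstream expression is log2(count/size_factor + 1).

The two-group test is a negative-binomial Wald test with a **common
dispersion per contrast**: for each gene, a method-of-moments estimate
(s² − μ)/μ² with residuals pooled within the two groups; these estimates are
averaged over genes with mean ≥ 1 and floored at 0.01. With a common
dispersion the estimate is essentially noise-free at a few thousand genes,
so the Wald statistic log2FC / SE (delta-method SE under NB(μ, α)) can be
referred to the normal distribution and stays calibrated at 3-vs-3
replicates: the seeded null simulation yields a p < 0.05 fraction of
~0.05. A gene-wise plug-in dispersion would make the same statistic badly
anticonservative (~0.11) — with four residual degrees of freedom per gene
there is no calibrated-and-powerful gene-wise option without sharing
information, and this package deliberately uses the simplest sharing scheme
(complete pooling) rather than empirical-Bayes shrinkage. The model
consequently assumes dispersion is roughly constant across genes, which the
synthetic data satisfies by construction; on real data with strongly
gene-dependent dispersion the test would be anticonservative for
high-dispersion genes. FDR is Benjamini–Hochberg; the DE cutoff is
FDR < 0.1. Log-fold-changes use a 0.5 pseudocount on group means to remain
finite for zero groups; all-zero genes get p = 1.

Temporal clustering runs k-means (25 restarts, seeded) on per-gene z-scored
stage profiles of the union of genes DE in consecutive-stage contrasts, and
relabels clusters 1..k by the stage index of the centroid maximum so labels
follow temporal order. Sample PCA operates on gene-centred
log2-normalised counts with the full (deterministic) SVD solver; each
component's sign is fixed by making its largest-magnitude loading positive.

## Motif engine

PWMs are position probability matrices; log2-odds are taken against the
background composition after flooring probabilities at 1e-3, then quantized
to a 0.005-bit grid. The quantization is what makes threshold calibration
exact: the dynamic programme over per-position score distributions and the
scanner operate on the *same* discrete scores, so the DP null tail is the
true false-positive rate of the scan (per-position rounding inside the DP
alone would let probability lumps near the threshold flip sides, inflating
the realised rate several-fold). Per-motif thresholds are calibrated to an
exact null p-value (default 1e-4); when the requested p-value is below the
minimal attainable tail the threshold is placed just above the maximal
score (no sequence can reach it) with a warning. Scanning evaluates both
strands, takes the per-position maximum of forward and reverse-complement
scores, and skips windows containing N; region-level hits are therefore
exactly strand-symmetric.

Enrichment at a target region set uses a GC-matched background: bin edges
at the targets' GC deciles, and per decile the pool is sampled without
replacement at `ratio` × the target count (default 2×, seeded; capped at
availability with a warning). The statistic is a one-sided hypergeometric
test on region-level hit counts, BH-corrected across the motif library;
"enriched" means FDR < 0.05 with odds ratio > 1 (odds ratios are
Haldane-corrected). Background windows are length-matched to the targets,
because per-region hit probability grows with region length and a
length-mismatched background would bias every motif's odds ratio upward.
TF nomination intersects the per-stage enriched sets across lineages
(unique vs common), maps motifs to TF genes through a user-supplied table,
and keeps candidates whose TF gene is expressed (≥ `min_tf_expr` on the
log2-normalised scale, default 1.0 — a deliberately permissive "detected"
cut) at the stage, ranked by enrichment p.

## Expression coupling of stage-unique elements

Genes are assigned to each stage's unique active peaks with the standard
50 kb rule, genes claimed by more than one stage are discarded, and each
gene is reduced to a *stage-preference score*: its own-stage log2 expression
minus the mean of its other-stage expression, which cancels the gene's
baseline. The one-sided Mann–Whitney rank-sum test then compares the scores
of the stage's gene set against all remaining genes. The score reduction is
essential: comparing the raw own-stage sample against the other-stage sample
of the same genes puts correlated values (shared gene baseline) in both
samples, invalidating the rank-sum null for any data; with one independent
score per gene the test is a random-partition comparison whose analytic
null is exact, and with randomly permuted gene–region links its p-values
are uniform.

## Knockdown analysis

A knockdown experiment carries control and TF-depleted H3K27ac tracks plus
expression counts for both arms. The chromatin effect at a site set is the
per-site difference of log2-over-input enrichments (kd − control), tested
one-sided with a paired Wilcoxon signed-rank test (H1: Δ < 0); identical
arms short-circuit to p = 1 with a degenerate flag. Deregulated genes come
from the NB Wald test at FDR < 0.1, split by fold-change sign. For linkage,
sites are partitioned by the regulation direction of their nearest gene
(down / up / unchanged, where unchanged = FDR ≥ 0.5 and |log2FC| < 0.25 to
keep the classes well separated), and a one-sided rank-sum test asks
whether down-linked sites lost more acetylation than unchanged-linked ones;
classes under 5 sites skip the test. Two-TF co-regulation is the overlap of
the down-gene sets with a one-sided hypergeometric p against a universe of
genes detected in both experiments, plus the count of overlap genes whose
sites carry both TFs' motifs within the same peak.

## Synthetic study design

The generator is the package's benchmark instrument; its defaults are the
study conditions and are not tuned per analysis.

* **Genome**: 4 chromosomes × 2.5 Mb of i.i.d. uniform bases; 1000
  two-exon genes (250 per chromosome) on a 10 kb slot grid, random strand.
  The slot layout guarantees every planted enhancer's nearest TSS is its
  linked gene, so peak-to-gene recovery is well-defined; gene counts and
  slot geometry were chosen jointly so that 900 stage-unique enhancers each
  link to a distinct gene with room to spare.
* **Enhancers**: 8 classes × 150 (one stage-unique class per stage per
  lineage, plus constitutive and never-active), 600 bp wide, bin-aligned so
  each spans exactly three 200 bp bins. Stage-unique enhancers sit 4.4–5.4 kb
  downstream of their linked gene's TSS — close enough that the 50 kb
  nearest-TSS rule recovers the planted link even on this deliberately
  gene-dense toy genome; constitutive/never-active elements occupy a
  disjoint region of the slot. State trajectories follow the priming rule:
  each stage-unique class is primed (K4me1) at the stage before its
  activation stage, and classes that activate early are primed in both
  lineages' progenitors, giving six distinct progenitor-primed archetypes
  for clustering.
* **ChIP tracks**: per condition, Poisson bins with background rate set so
  the expected library is 2×10⁶; bins inside enhancers whose state implies
  the mark are elevated 8× (K27ac at active/acetyl-only) or 6× (K4me1 at
  primed/active). The genomic input is pure background at the same depth.
* **Expression**: NB counts (dispersion 0.1) over 6 stage-lineage
  conditions × 3 replicates; gene baselines LogNormal(log 200, 0.5);
  genes linked to an enhancer active at a stage get a 2.5× mean boost
  there; per-sample size factors jitter ±20%.
* **Motifs**: three planted 10-mer PWMs (consensus probability 0.88) plus
  20 shuffled-decoy PWMs. Two "remodeling" TFs target overlapping subsets
  of the eA-unique class — sharing exactly 47 target genes by construction —
  and one "non-remodeling" TF targets the lA-unique class. Planted
  instances are rejection-sampled from the PWM until they clear the
  calibrated threshold, so every planted site is scannable.
* **Knockdowns**: 3 replicates per arm. For a remodeling TF the kd track
  scales the H3K27ac rate at motif-bearing targets by 0.4 (expected site
  Δlog2 ≈ log2 0.4 ≈ −1.32, slightly attenuated by library renormalisation)
  and divides target-gene means by the 2.5× boost; a non-remodeling TF
  leaves chromatin untouched. A planted set of 40 indirectly upregulated
  genes (2× mean, chromatin untouched) exercises the "up" linkage class,
  mirroring the observation that upregulated genes' regulatory sites do not
  lose acetylation.

Every generator output is a pure function of (config, seed) through named
substreams, so datasets are bit-reproducible; truth tables ship with every
dataset.

**What passing does not show.** The synthetic data are far kinder than real
ChIP-seq/RNA-seq: uniform mappability, no GC bias, no replicate batch
effects beyond size-factor jitter, constant NB dispersion, bin-aligned
enhancers with large planted folds, and decoy motifs independent of the
planted ones. Perfect recovery here validates the logic and the statistics
of the pipeline, not its robustness to the noise structure of real data.

## Problem sizes and determinism

The default study (10 Mb genome, 1200 enhancers, 12 ChIP tracks, 18
expression samples, 23 PWMs, 3 knockdowns) runs end-to-end in well under a
minute on one CPU; the test suite's scaled variants use a 2 Mb genome with
30 enhancers per class. All stochastic steps draw from named substreams of
one root seed; k-means uses a fixed random_state and 25 restarts; PCA uses
the full SVD solver. Two runs with the same config produce byte-identical
reports.
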