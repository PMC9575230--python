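# Methods

`repliscape` re-implements the quantitative machinery used to study what
happens when the temporal programme of replication-origin firing in
budding yeast is collapsed — when limiting initiation factors (the
SSDDCS set: Sld2, Sld3, Dpb11, Dbf4, Cdc45, Sld7) are over-expressed so
that most origins fire at the start of S-phase. The package covers five
analysis stages plus the simulators that generate inputs with the
statistical structure each stage assumes.

## Replication timing (Trep)

**Model.** Copy number of a 1-kb bin at time *t* after G1 release is the
ratio of its read count to the G1 sample, rescaled per timepoint by one
multiplicative constant so the genome-wide mean equals the bulk
replicated fraction (a value between 1 and 2, treated as an external
input on the copy-number scale). Each bin's trajectory is fitted with a
bounded four-parameter logistic

r(t) = L + (U − L) / (1 + e^{−k (t − m)}),  L ∈ [0.8, 1.2], U ∈ [1.8, 2.2], k > 0,

and Trep is the exact solution of r(t) = 1.5 — the time of half-maximal
replication on the canonical 1→2 scale. Solving for 1.5 (rather than
reporting the midpoint *m*) guarantees the fitted curve evaluated at the
returned Trep is 1.5 regardless of where the floor and ceiling land.

**Fit failure.** A fit is rejected (Trep undefined, never an exception)
when the trajectory's last two points stay below ratio 1.4 (the bin has
not replicated within the timecourse; extrapolation would fabricate a
value), when residual RMS exceeds 0.25, when 1.5 is outside (L, U), or
when the crossing falls outside the sampled span. The fit uses bounded
least squares with three midpoint starts to dodge local minima.

**Smoothing and calling.** Profiles are smoothed with a centred,
mask-aware moving average (default 15 bins = 15 kb; the window is a
package default, not a published value) that never mixes chromosomes.
Origins are local minima and termination zones local maxima of the
smoothed profile, found with a prominence threshold (default 2 min) and
forced to alternate by keeping the extreme call within same-kind runs.

**Simulator.** Each origin fires at a Gaussian time (per-condition mean,
shared SD, truncated at 0); a bin is replicated by the first fork to
reach it at `fork_speed` (default 1.5 kb/min), which makes passive
replication implicit — an origin overrun by a neighbour's fork never
contributes. Expected copy number is 1 + P(replicated), counts are
Poisson around depth × copy number (or exact in noiseless mode), and the
genome-wide mean expected copy number is emitted as the bulk value. The
firing-time SD (default 4 min) is a free parameter chosen so 5-min
sampling sees a smooth sigmoid; it is not a published value. Ground
truth is emitted two ways: the median replication time (P = 0.5, solved
on a 0.25-min grid with linear interpolation) — what a sigmoid fit
estimates — and the deterministic min-over-origins time used by the
monotonicity and origin-deletion property tests. The control strain's
firing means increase with centromere distance (10 → 35 min), the
global-early condition advances every origin by up to 15 min with an
8-min floor, so early origins advance little and late origins a lot.

## Expression timecourse

Counts are modelled as NB with variance μ + αμ². Size factors are
median-of-ratios (cross-checked against pydeseq2 in the tests).
Dispersion is per-gene method-of-moments pooled across all
(strain, timepoint) replicate groups and floored at 1e-8; pooling is
essential with two replicates per group, and no empirical-Bayes
shrinkage is applied (a documented simplification — our tests quantify
its calibration directly rather than claiming bit-compatibility with
DESeq2).

* **Per-timepoint Wald:** log2 fold-change of normalized group means,
  delta-method SE under the NB model, two-sided normal p,
  Benjamini–Hochberg across genes, DE at FDR < 0.01.
* **Timecourse LRT:** full model with one normalized mean per
  (strain, timepoint) at post-G1 timepoints and a shared G1 mean,
  against a reduced per-timepoint-mean model; χ² with df = number of
  post-G1 timepoints. G1 is excluded from the strain contrast because
  the question is a difference *after* release. Group means are plug-in
  estimates (the NB mean MLE at fixed dispersion is approximated by the
  mean of normalized counts when size factors are near 1).
* **Clustering:** rows z-scored, seeded k-means++ (k = 6, max 50
  iterations, Euclidean); constant rows dropped with a warning. The
  initialization and metric are our choices; the published description
  fixes only k and the iteration cap.
* **Enrichment:** exact binomial tails for over/under-representation of
  an annotated set within a cluster; the smaller tail and its direction
  are reported.
* **Group comparisons:** each cluster versus a seeded random control of
  non-DE genes (default n = 300, configurable to 250/350) by two-sided
  Wilcoxon rank-sum (mid-ranks, continuity-corrected normal
  approximation), Holm step-down across clusters.

Marker genes that are artificially over-expressed by the induction
system can be excluded from all tests via `excluded_genes`.

## Nucleosome dynamics

Nucleosome-sized fragments (140–180 bp inclusive) contribute one dyad
count at their midpoint. The caller is a deliberately simple greedy
local-maxima algorithm on Gaussian-smoothed coverage (bandwidth 20 bp,
suppression window ±120 bp, both module defaults, not published
values) standing in for a full positioning caller. The +1 nucleosome is
the call within −20..+80 bp of the TSS in the transcription direction
(inclusive bounds; ties broken by occupancy then smaller |offset| — the
multiple-candidate rule is our choice). Offsets are positive into the
gene body for both strands.

Gene-body phasing is summarized by the autocorrelation of the
mean-centred dyad signal over [TSS, TSS + 700 bp) (four nucleosomes'
worth; genes ≤ 700 bp are excluded): the score is the maximum
autocorrelation over a nucleosome-repeat lag band (120–220 bp), with the
lag-ℓ covariance normalized by the overlap length so a perfectly
periodic signal scores ≈ 1. The lag-band-maximum summary is our
convention — the protocol this statistic descends from does not print
one — and it is invariant to scaling and shifting the signal.

The fragment simulator places regular arrays (+1 dyad 60 bp into the
gene, 165-bp repeat, 5 nucleosomes, Gaussian positional jitter) and TF
footprints (sub-nucleosomal fragments, lengths 30–99 bp, centred on
annotated sites with per-sample occupancy). Per-sample jitter and +1
shift schedules emulate the transient mid-S-phase chromatin
disorganization of the global-early strain.

## TF footprints

Fragments < 100 bp (strict) are selected; per fragment length, every
sample is down-sampled to the minimum count over samples so per-length
histograms match exactly; samples are pooled and candidate peaks are
maximal runs of coverage ≥ min_coverage with nearby runs merged. Peak
counts are fragment midpoints per peak, normalized to counts-per-million
per sample (the normalization basis and pseudocount 1 are our
documented stand-ins — the original pipeline's are not printed). A peak
is high confidence when Σ_samples log2(normalized count + pseudocount)
> 75 (strict); differential when its midpoint lies in the 1-kb
strand-aware promoter of a gene *and* |log2 treatment/control| ≥ 1 at
some post-G1 timepoint (two-sided — the direction of a "2-fold
difference" is not specified, and footprints can go either way). Peaks
are annotated to the nearest TF site within 200 bp (ties: smaller
distance, then lexical name) and summarized per TF as
x = changed/total peaks and y = changed-in-DE-promoters/changed, with
the all-peak baseline ratios emitted alongside.

Because per-sample normalization fixes total signal, a change affecting
a large fraction of all footprints is partially absorbed: ratios are
attenuated by the ratio of library totals. Recovery is therefore
benchmarked with the changed TF owning ~12% of sites; a genuinely
global footprint loss would need spike-in-style external calibration,
which is out of scope.

Motif sites come from log-odds scanning of both strands with PWMs read
from MEME minimal files (threshold on score; no p-value calibration).

## Compendium screen

For each mutant in a genes × mutants fold-change table, a tie-corrected
Kruskal–Wallis test compares its per-gene values across the reference
experiment's k-means clusters plus one control group of non-DE genes
(a seeded sample, default 300, mirroring the group-comparison design;
whether the original screen included such a control is not stated, so
it is configurable). Effect size is η² = (H − k + 1)/(n − k), clamped
to [0, 1]; a mutant is similar when Bonferroni-adjusted p < 0.001
(m = number of mutants) and η² ≥ 0.14. When reference averages are
supplied, per-cluster median sign agreement is reported as a
directionality check.

The compendium simulator draws similar mutants from the per-cluster
mean pattern plus Gaussian residuals, and null mutants from one global
mean; default effect magnitudes are ≥ 3 residual SDs so the η²
threshold separates cleanly at desk scale.

## What the simulations do and do not show

The generators reproduce the statistical structure each stage assumes —
sigmoidal per-bin copy-number trajectories with Poisson sequencing
noise, NB counts with cluster-structured log2 effects that vanish at
G1, phased dyad arrays with schedulable jitter, occupancy-controlled
sub-nucleosomal footprints, and a block-structured mutant compendium.
They do not emulate mappability or GC bias, MNase sequence preference,
replication-fork collisions and delayed termination topology, checkpoint
feedback, or real yeast sequence (genomes are coordinate systems;
small FASTA is generated only for motif-scan tests). Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated models, not robustness to every artefact of real sequencing
data.

## Problem sizes

Default test and demo scales are deliberately small: genomes of one to
two chromosomes (100–300 kb) at 1-kb bins, 13 × 5-min timepoints,
hundreds to 2,000 genes with 2 replicates, tens of TF sites, and
20-mutant compendia. These sizes make every stage's recovery measurable
in seconds while preserving the estimators' asymptotic behaviour;
everything scales linearly in bins, genes and fragments.
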