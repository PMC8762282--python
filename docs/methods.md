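# Methods

This note documents the models, defaults and numerical choices behind each
pipeline stage, what the synthetic generator does and does not emulate, and
the design decisions taken where the problem left the choice open.

## Expression integration

Per-species FPKM matrices are joined on a 1:1 ortholog table; an ortholog
group is retained only when its gene reaches max FPKM ≥ `min_fpkm`
(default 1) across samples in **every** species, so the integrated matrix
contains genes expressed everywhere. Non-1:1 groups are dropped rather
than resolved.

Batch effects are removed by a per-gene location–scale adjustment on
log2(FPKM + 1): within each batch the gene is centred and scaled to the
batch mean/SD, then the pooled mean/SD are restored. This is a
ComBat-style adjustment without empirical-Bayes shrinkage — adequate when
each batch has tens of samples, as here, and exactly removes additive
per-batch offsets. Batches default to species-of-origin because integrated
public sets arrive one per study, which confounds batch with species; the
adjustment therefore also removes genuine per-gene species differences in
level, by construction. Zero-variance gene/batch combinations get the
location step only; adjusted log values are clipped at zero before
back-transforming (log2(FPKM+1) cannot be negative), so the documented
moment-preservation identities hold wherever no clipping occurs. The
adjustment is idempotent. Note one intrinsic limit: for a gene with no
expression structure all variance is noise, and removing the batch-mean
sampling component necessarily costs a little correlation with the input
(≈ √(1−(B−1)/N)); genes with real structure are essentially untouched.

Sample clustering is agglomerative with average linkage on
1 − Pearson between z-scored columns (scipy implementation). Clusters are
named by the majority stage-group of the reference species' samples they
contain, ties resolved toward the earlier developmental group; clusters
with no reference sample are "unassigned".

## Stage alignment

Each species/compartment contributes one mean log2(FPKM+1) profile per
stage (replicate means, not per-replicate columns, since correspondence is
judged stage-to-stage). The cost matrix is 1 − Spearman; undefined
correlations (constant profiles) are set to the maximum cost 2. DTW uses
the symmetric step pattern (1,1), (1,0), (0,1) with unit weights, full
boundary constraints and no window; backtracking ties prefer diagonal,
then vertical, making the optimal path deterministic. The per-stage best
match is the reference stage with the minimal pair cost among optimal-path
pairs visiting that query stage, ties toward the earlier reference stage.
Alignment is pairwise against a designated reference species (cattle in
the default configuration), not a joint multi-species warp.

## Marker discovery and species-specific genes

Stage markers come from a one-vs-rest contrast per stage. The test is a
per-gene negative-binomial Wald test applied to FPKM treated as
pseudo-counts: dispersion by method of moments on the pooled within-group
variance, floored at 1e-8; the log2 fold change uses a continuity shift of
0.5; the delta-method variance of the log mean is (1/μ + α)/n. There is no
dispersion shrinkage — with the default three replicates and 16-fold
planted effects, power is ample, and the null positive rate stays within
its nominal bound (checked by a calibration test). P-values are BH
adjusted (statsmodels); markers need log2FC > 0, padj ≤ 0.05 and stage
mean FPKM ≥ 1.

Term enrichment uses the exact hypergeometric upper tail
P(X ≥ k) = Σ C(K,x)C(N−K,n−x)/C(N,n), evaluated in log space with gammaln
and logsumexp; terms are flat gene sets (no GO DAG propagation). A
species-specific biological process is significant (padj ≤ 0.05) in the
target species and in none of the others. From the top `top_k_bps`
(default 10, ordered by enrichment p) of the target's GC
differentiation-stage processes, those absent from the theca enrichment
yield candidate genes; candidates that are GC stage markers and appear in
no TC stage set form the final species-specific gene set. Significance is
α = 0.05 everywhere; the stricter 0.0001 that appears in reporting
contexts is echo only, not a different test.

Ectopically expressed genes are ortholog groups confined to one
compartment (GC-only vs TC-only at a stage) in the query species and the
opposite compartment in at least one other species; groups in both
compartments anywhere are excluded.

## Super-enhancer calling

Defaults follow ROSE conventions: stitch distance 12,500 bp, TSS exclusion
2,500 bp (peaks fully inside TSS ± 2,500 are removed before stitching),
assignment window ± 50,000 bp; all configurable. Region signal is the
interval-length-weighted sum of bedGraph values minus the optional control,
floored at 0. The cutoff sorts signals ascending, min–max-scales both axes,
and takes the signal at the first inter-rank segment whose discrete slope
strictly exceeds 1; regions strictly above it are super-enhancers.
Consequences of the strict rule: all-equal signals and an exactly linear
ramp produce no super-enhancers. Because the scaled curve's mean slope is
exactly 1, some crossing always exists for continuous non-linear inputs;
the rule is intended for genuinely hockey-stick-shaped data, where the
wide signal range keeps shelf slopes far below 1 and the crossing lands at
the elbow. On data with no high-signal tail the crossing is unstable and
the caller's output should not be over-interpreted.

## Core regulatory circuitry

Motif scanning is a log-odds scan of both strands against position weight
matrices (probabilities floored at 1e-9; uniform background by default); a
window is a hit at ≥ `motif_threshold` (default 0.9) of the maximal
attainable score, and windows containing non-ACGT characters are skipped.
An edge A → B requires ≥ 1 hit of A's motif in any SE constituent assigned
to B; self-edges are recorded but ignored for distances. Closeness is
harmonic — score(v) = Σ 1/d(v,u)/(n−1), unreachable nodes contributing 0 —
because the SE-derived digraphs are routinely disconnected and harmonic
closeness needs no reachability fix-ups; "out" measures regulatory reach,
"in" being regulated. Hubs exceed mean + 1 population SD of out-closeness
(multiplier configurable; zero variance means no hubs). Circuits are
maximal sets in which every ordered pair is connected — maximal cliques of
the mutual-edge graph — of size ≥ 2, reported largest first.

## Conservation

MAF blocks are parsed with Biopython; a whole block is reverse-complemented
when its reference row is minus-strand (MAF rows share one column space, so
per-row flipping is not meaningful). For a reference interval the homolog
slice keeps exactly the columns carrying a reference base inside the
interval; insertion columns (reference gapped) are dropped, which makes the
reference gap fraction identically 0 and the extraction invariant to block
splitting. Reference bases covered by no block count as gap columns for
every other species — absence of alignment is read as deletion, the
strongest divergence signal. The verdict for an interval at `max_gap`
(default 0.5): *clade-specific* when all clade members are ≤ max_gap and
all non-members are above it, *not-conserved* when no species besides the
reference is ≤ max_gap, else *shared*. The threshold is a parameter, not a
calibrated constant: no quantitative conservation criterion exists for
these regions, so verdicts should be read relative to the chosen max_gap.

## Auxiliary statistics

GSEA uses the classic running sum: hits add |score|^p normalized by the
total over hits (default weight p = 1; p = 0 supported), misses subtract
1/(N − Nh); the ES is the extremum of largest magnitude, first such point
on ties; when the set covers the whole list the miss term is absent and
ES = +1 at the last hit. The permutation null reshuffles set membership
with size preserved — a phenotype permutation is not supportable at three
replicates — and p = (1 + #{|ES*| ≥ |ES|})/(n_perm + 1), so p is never 0.
The egg-laying test is the exact lower-tail binomial CDF at the
pre-treatment rate. One-way ANOVA (F, p) is followed, when significant at
α, by Fisher's-LSD pairwise t-tests on the pooled MSE with a
compact-letter display: groups ordered by descending mean, each maximal
run of mutually non-different groups sharing a letter. All-constant input
is an error.

## Synthetic data and what passing tests mean

The generator emulates the *structure* of the real inputs, not their full
biology. Expression: per-ortholog baseline log2 FPKM ~ Normal(3, 2) shared
across species, per-sample noise Normal(0, 0.2), one batch per species
with additive per-gene offsets Normal(0, batch_sd = 1), three stages per
species mapped to a reference grid (selection, differentiation,
preovulation), 40 GC and 20 TC marker genes per reference stage up-shifted
by log2(effect_fold), default effect_fold 16 with n = 3 replicates, and 40
species-specific genes silenced everywhere (log2 ≈ −4) except in the
target species' GC differentiation block (one also planted in TC).
Annotation: the planted genes are split into 10-gene terms — the planted
enriched processes — plus 50 noise terms drawn from the non-planted
groups, so the planted term list is the exact enrichment truth. Epigenome:
typical-enhancer signal areas are log-normal (σ = 0.15 on the log scale);
planted SE clusters of 3 peaks within the stitch distance receive totals
of 30–60× the typical median — far above the ≥ 5× separation the method
assumes, reflecting the hockey-stick geometry (a long shelf and a sharp
elbow) and keeping the discrete-slope crossing at the shelf/tail junction;
SE entities are spaced beyond the assignment window so each SE belongs to
one gene. Motif plants are exact consensus strings of length-12 PWMs
(match probability 0.85, so at the 0.9 score threshold only exact matches
hit), and accidental consensus occurrences in the background are scrubbed,
making the planted edge list the exact regulatory graph. Alignment: 77
pseudo-species, gap-free reference, per-column gap probabilities 0.05
(clade) vs 0.6 (outgroup) inside planted intervals and 0.5 background
elsewhere; clade rows copy the reference base where ungapped so reference
motifs persist in the clade.

Not emulated: read-level noise, FPKM length biases, dispersion trends,
correlated genes, ChIP fragment coverage, indel structure within
alignments, or phylogenetic correlation among species. Passing recovery
tests therefore demonstrates that each operation implements its contract
and that the pipeline identifies planted structure at realistic effect
sizes — not that the thresholds are optimal for any particular real
dataset.

Problem sizes used by the default fixture and the acceptance script: 400
ortholog groups × 3 species × 2 compartments × 3 stages × 3 replicates;
420 stitched regions (400 typical, 20 SE) with 8 TFs; 77 alignment rows
over a 6 kb reference; 1,000 GSEA permutations. These sizes give stable
recovery while keeping a full run in seconds.

## Reproducibility

Every generator and every stochastic statistic takes an explicit seed;
fixture regeneration with the same seed is byte-identical, and two
pipeline runs with the same seed produce byte-identical reports. Stage
outputs are plain TSV/BED/JSON so any stage can be re-run standalone from
cached upstream files.

## Known limitations

- The NB Wald test's normal reference is anti-conservative at very small
  replicate numbers; BH across hundreds of genes absorbs this at the
  default fixture sizes, but shrinkage-based tools are preferable on real
  data with few replicates.
- The batch adjustment cannot distinguish species effects from study
  effects when each species comes from one study.
- The hockey-stick cutoff is meaningful only for signal distributions with
  a genuine high-signal tail (see above).
- Circuits are directed cliques; looser circuit notions (cycles through
  hubs) are not implemented.
- GO terms are flat sets; no term hierarchy or redundancy reduction.
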