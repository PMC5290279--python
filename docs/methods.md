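# Methods

`scint` re-implements, as a tested library, the computational analysis used
to parcellate developing Htr3a-GFP+ cortical interneurons into robust
transcriptomic types and to measure their migratory behaviour. This note
describes the models and procedures, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
numerical choices that affect reproducibility.

## Quality control

Five per-cell criteria are applied to raw counts and sequencing metadata,
before any normalization:

| criterion | rule | default |
|---|---|---|
| sequencing depth | `read_pairs >= min_read_pairs` | 5,000,000 |
| mapping rate | `frac_mapped > min_frac_mapped` | 0.80 |
| mitochondrial fraction | `frac_mito < max_frac_mito` | 0.05 |
| reporter detection | `egfp_reads >= min_egfp_reads` | 1 |
| interneuron identity | max raw reads over Dlx1/2/5/6, Gad1/2 `>= min_marker_reads` | 10 |

Inequality strictness follows the wording of each rule literally ("at
least" inclusive, "more than"/"less than" strict), so a cell at exactly 5%
mitochondrial reads fails and one at exactly 5,000,000 read-pairs passes.
`frac_mapped` and `frac_mito` are metadata recorded upstream by the
aligner; the package does not recompute them. A cell passes iff no
criterion fails; relaxing any single threshold can only grow the survivor
set (a property the tests check).

## Normalization and gene selection

Counts are scaled to reads per million: `count / mapped_reads * 1e6` per
cell, where `mapped_reads` is the cell's total reads on expressed genes
(so each cell's RPM values sum to 1e6 when that definition is used).
Clustering input is restricted to genes with RPM strictly above 10 in
strictly more than 5% of the cells of the analysis subset; the filter is
recomputed per stage for within-stage clustering and on the pooled cells
for cross-stage embedding. Downstream methods work on log2(RPM + 1); the
log transform is the package's choice (a config flag), adopted because
PCA and Euclidean distances on raw RPM are dominated by a handful of
high-expression genes.

## Consensus clustering and the stability score

The base operation projects cells onto the top 10 principal components of
the log expression (genes centered, not variance-scaled by default) and
applies agglomerative clustering (Ward linkage, Euclidean distance), cut
into k clusters. The number of components is a package default — exposed
in `ClusteringParams` — reduced automatically (with a warning) when the
matrix is too small.

Robustness is assessed by resampling: 100 runs, each drawing 80% of the
cells without replacement, recomputing the PCA on the subsample, and
clustering into k. For every pair of cells the **stability score** is

    s(i, j) = (# runs where i and j were both drawn and co-clustered)
              / (# runs where i and j were both drawn),

i.e. the denominator counts only runs in which co-membership was
observable; pairs never co-sampled are flagged NaN rather than zeroed
(at the default 80% sampling a pair is co-drawn in ~64 of 100 runs, so
flags only occur at much smaller sampling fractions). The final robust
assignment cuts an average-linkage hierarchy of the dissimilarity
`1 - s` into k clusters; the dendrogram leaf order is returned for the
consensus heatmap, and labels are renumbered 1..K in leaf order so output
is deterministic. Flagged pairs are imputed with the mean defined
dissimilarity before linkage. Ties in agglomeration are broken by scipy's
deterministic observation-index rule.

`suggest_k` is advisory (the published analysis fixed K = 3 by heatmap
inspection, which is the package default): it scans k = 2..k_max and
reports the mean silhouette width on `1 - s`. When even the best k gives
a silhouette below 0.5 the result is flagged "no structure", following
the standard silhouette interpretation scale on which values up to 0.5
indicate weak, possibly artificial structure. On resampled stability
matrices this bar cleanly separates planted types (silhouette ~0.9) from
structureless data (~0.15-0.26, inflated at large k by small spurious
clusters).

## Embedding and subtype parcellation

t-SNE (perplexity 30 for the all-cells map, 4 for within-type subtype
analysis) embeds cells in 2-D. The embedding is initialized from the
top-2 principal components scaled to the conventional 1e-4 spread — a
deterministic, spectral initialization — and cells are canonicalized by
sorting on identifier before the run, so coordinates are a function of
the data and the seed, not of row order. Subtypes are obtained by
average-linkage agglomeration of Euclidean distances in the embedding,
cut at an explicit k (the published hierarchy was cut manually; the
silhouette heuristic can propose a default).

## Dropout-aware differential expression

Single-cell counts mix biological absence with detection failure, so the
package models each group's counts per gene as **zero-inflated negative
binomial**. The NB component has RPM-scale mean mu and a group-level size
theta; counts enter the likelihood through per-cell size factors
`mapped_reads / 1e6`. Detection failure (dropout) zeroes an observation
with probability logistic in log mean, `pi(mu) = expit(a0 + a1 log mu)`,
with a1 < 0: dim transcripts drop out more.

Fitting, per group:

- **theta** by method of moments on nonzero normalized counts, restricted
  to well-detected genes (mean nonzero raw count >= 30, >= 10 nonzero
  cells) where zero-truncation bias is negligible; the count-level
  Poisson variance component is removed using the harmonic-mean size
  factor; the median across genes is used. Simulation recovery is within
  ~10% at 2,000 genes x 100 cells.
- **(a0, a1)** by maximum likelihood on the zero/nonzero indicators of
  all gene-cell pairs, with the NB zero probability accounted for;
  a0 is capped at +-20 (data with no zeros drive pi to ~0).
- **mu per gene** by the fixed point of `E[observed] = (1 - pi(mu)) mu`,
  i.e. the observed mean corrected upward for expected dropout.

The per-gene test profiles the log2 fold change f of the target type
against all other cells over a fixed grid, [-10, 10] in steps of 0.05.
The two group means are parametrized **symmetrically** around the pooled
baseline `mu0 = sqrt(mu_target * mu_rest)`: target mean `mu0 * 2^(f/2)`,
complement `mu0 * 2^(-f/2)`. This makes swapping target and complement
negate both outputs exactly, an invariant the tests assert. The MLE is
the grid argmax; the confidence score is the signed root of the
likelihood-ratio statistic,

    Z = sign(f_MLE) * sqrt(2 * (ll(f_MLE) - ll(0))),

which coincides with the curvature-based Wald z when the profile is
near-quadratic, remains finite and well-calibrated (~N(0,1) under the
null) when it is not, and is exactly antisymmetric under group exchange.
For genes detected in exactly one group the plug-in baseline is
meaningless, so mu0 is additionally profiled over a log-spaced grid
(`mu_detected * 2^[-9..3]`, 25 points); this attributes an all-zero group
to dropout when the expression level makes that likely, instead of
reading it as an infinite fold change — the dominant source of false
positives otherwise.

Enriched genes satisfy `MLE >= 2 and Z >= 2` (both inclusive; mirrored
for depletion). No multiple-testing correction enters selection — the
rule is threshold-based by design — though a Benjamini-Hochberg FDR
column is emitted for reference. Top-N tables rank up-enriched genes by
Z descending, ties by |MLE| descending then gene name, and carry the
model-based adjusted expressions (the fitted RPM-scale group means at the
MLE) used for heatmaps, violin-style summaries and time-course
trajectories. Time-course extraction reports the adjusted expression of
a gene in a type per stage and flags missing stages rather than
interpolating.

Measured operating characteristics (recomputed by the acceptance script):
a permutation null passes ~0.7-1.2% of genes at 30-vs-60 cells and 800
genes; power for planted log2FC-3 markers exceeds 95% at the same group
sizes.

## Cross-dataset shared enrichment

Given a query type's enriched gene set and a reference DE table (gene,
Z-score, subtype family), the shared-enrichment curve reports, at each
reference threshold z on a 0.1-step grid, the percentage of the query set
found among the reference family's genes with Z >= z. The denominator is
the fixed query-set size, which makes curves comparable across families;
an intersection-over-union variant would shrink the denominator with z
and is deliberately not the default. Gene symbols are harmonized by
uppercased exact match; unmatched query symbols are reported and retained
in the denominator. The curve is non-increasing by construction.

## Migration metrics

Tracks are time-stamped 2-D positions (minutes, micrometres). The first
60 minutes are removed before measurement (slices settle in the imaging
chamber); times are re-zeroed. Gaps of up to 2 missing frames (frame
interval = median sampling step, 10 min by default) are linearly bridged;
longer gaps split the track into independent segments — the movies
themselves give no guidance here, so the bridge/split rule is the
package's choice, chosen to avoid manufacturing displacement across long
occlusions. Per track:

- speed = total path length / observed duration (um/h), with duration
  the track's own span after burn-in rather than the nominal movie
  length, so partially tracked cells are not biased;
- directional persistence = net displacement / path length, in [0, 1]
  (0 for stationary tracks, flagged).

Groups are compared per metric with a two-sided unpaired Student's
t-test (pooled variance; Welch via a flag), reporting means +- s.e.m.,
t and p. Zero variance in both groups with equal means reports t = 0,
p = 1.

## Synthetic data

The generator emulates the study design so every stage of the pipeline
can be tested against known truth: K planted types (default 3) at three
developmental stages (E18/P2/P5), 25 cells per type per stage, 2,000
genes of which 50 per type are markers at log2 fold change 3. Counts are
NB (size theta = 1, a typical full-length single-cell value) with
baseline means `exp(U(0, 4))`, observed through logistic dropout with
midpoint 8 counts and slope 1. Six interneuron-identity genes
(Dlx1/2/5/6, Gad1/2) lead the gene list with high expression so the QC
marker criterion is exercised. Per-cell metadata are drawn consistent
with QC pass (depth lognormal around 1e7 read-pairs, the stated
sequencing depth), except a planted fraction of cells (default 8%,
matching the ~243-captured/223-passing attrition of the cohort this
emulates) that each violate exactly one named criterion. `mapped_reads`
equals the column sum of the counts, making RPM exact by construction.
An optional per-stage log-fold drift on 5% of genes (off by default)
supports time-course tests. Migration tracks are correlated random walks
(von Mises turning with concentration kappa, gamma step lengths, 10-min
frames); kappa = 0 gives an isotropic walk and large kappa a straight
path, so a persistence contrast between two "graft groups" can be
planted.

What the generator does **not** emulate: gene-gene correlation beyond
type structure, batch/chip effects, library-size-dependent dropout
differences between cells, UMI counting, doublets, or ambient RNA.
Passing tests therefore demonstrate the pipeline's correctness and its
operating characteristics under a clean generative model matching its own
assumptions — not robustness to every artifact of real data. The
dispersion and dropout magnitudes are conventional choices, not values
fitted to the original dataset (which does not report them).

## Problem sizes and determinism

All randomness flows through explicit integer seeds (NumPy Generator
seeds; scikit-learn `random_state` for t-SNE), and fixed seeds give
bit-identical generator output and stability matrices. The test suite and
the acceptance script run the clustering analyses at the study-scale
default (225 cells, 2,000 genes, 100 resampling runs), the null-structure
analysis at 20 replicates of 75 cells x 1,000 genes, the DE null at 20
permutations of 90 cells x 800 genes, the DE power analysis at 50
simulations of 90 cells x 300 genes, and the migration comparison at 20
replicates of 50 tracks per group — sizes chosen to make each operating
characteristic measurable with comfortable Monte-Carlo margins while the
whole suite stays fast.

## Known limitations

- The DE module reproduces the decision rule and output contract of the
  published analysis (MLE fold change, Z confidence, adjusted
  expressions) with its own ZINB profile-likelihood model; it does not
  numerically replicate the external tool the original analysis used.
- A single dispersion per group is assumed; strongly gene-specific
  overdispersion would be mis-calibrated at the extremes.
- `suggest_k` is a heuristic for an advisory quantity; the intended use
  is fixing k from the consensus heatmap, as the original analysis did.
- The grid bounds clamp |MLE| at 10 log2 units; genes beyond that report
  the bound.
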