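# scint

Single-cell transcriptomic typing of developing cortical interneurons.

During late embryonic and early postnatal development, 5-HT3A-receptor
(Htr3a)-expressing GABAergic interneurons migrate into the cortex and
diversify into molecularly distinct types. `scint` is a tested,
reusable implementation of the analysis used to parcellate such cells
from full-length single-cell RNA-seq: per-cell quality control, RPM
normalization, resampling-based consensus clustering into robust types,
t-SNE embedding and within-type subtype parcellation, dropout-aware
type-enriched gene identification, cross-dataset shared-enrichment
comparison, and migration metrics from time-lapse cell tracks. A
first-class synthetic-data module generates count matrices, QC metadata,
reference DE tables and migration tracks with known ground truth, so the
whole pipeline is exercisable and testable end to end without external
data.

It is intended for computational biologists who want the individual
steps of this analysis as library functions with explicit contracts, or
who need a ground-truthed sandbox for benchmarking clustering stability
and dropout-aware differential expression at small-cohort scale
(~10^2 cells, full-length chemistry).

## The core statistics

**Co-clustering stability.** Cells are projected on the top principal
components of log2(RPM+1) expression and clustered hierarchically (Ward);
the procedure is repeated 100 times on random 80% subsamples, and for
each pair of cells

s(i, j) = #\{runs: i, j both drawn and co-clustered\} / #\{runs: i, j both drawn\}.

Average-linkage clustering of 1 − s gives the final robust type
assignment; a silhouette scan over k is provided as an advisory k chooser
with a "no structure" flag.

**Dropout-aware differential expression.** Counts in each group are
modeled as zero-inflated negative binomial with RPM-scale mean mu,
group dispersion theta and dropout probability logistic in log mu. The
log2 fold change f of a type against all other cells is profiled on a
grid, parametrized symmetrically around the pooled baseline mu0:

L(f) = prod_target ZINB(c; mu0 2^{f/2} s_i, theta_t) * prod_rest ZINB(c; mu0 2^{-f/2} s_i, theta_r),

MLE = argmax L, Z = sign(MLE) * sqrt(2 (log L(MLE) − log L(0))).

Genes with MLE ≥ 2 and Z ≥ 2 (log2 units; mirrored for depletion) are
called type-enriched. Migration tracks yield speed (path length / time)
and directional persistence (net displacement / path length), compared
between groups with an unpaired Student's t-test.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np, scint
from scint.normalize import log_rpm, select_genes
from scint.cluster import ClusteringParams, stability_matrix, consensus_assign, suggest_k
from scint.diffexpr import de_test, top_n_table
from sklearn.metrics import adjusted_rand_score

params = scint.SyntheticParams(seed=0)          # 3 types x 3 stages, 2,000 genes
adata, truth = scint.generate_counts(params)
report = scint.apply_qc(adata)
print(f"QC: {report.n_pass}/{report.n_total} cells pass")

passed = adata[report.pass_mask].copy()
p2 = passed[passed.obs["stage"] == "P2"].copy()
log_rpm(p2)
genes = select_genes(p2)                        # >10 RPM in >5% of cells
X = np.asarray(p2[:, genes].layers["log_rpm"])
print(f"P2: {p2.n_obs} cells, {len(genes)} genes selected")

sm = stability_matrix(X, ClusteringParams(seed=7), cell_ids=list(p2.obs_names))
sk = suggest_k(sm)
assignment = consensus_assign(sm, sk.k)
ari = adjusted_rand_score(truth.type_labels.loc[p2.obs_names], assignment.labels)
print(f"suggest_k={sk.k} (silhouette {sk.silhouettes[sk.k]:.2f}), ARI vs truth {ari:.2f}")

de = de_test(p2, assignment.labels, target_type=1)
print(top_n_table(de, n=5)[["mle_log2fc", "z_score"]].round(2))
```

prints

```
QC: 207/225 cells pass
P2: 70 cells, 1948 genes selected
suggest_k=3 (silhouette 0.89), ARI vs truth 0.96
        mle_log2fc  z_score
gene
G00439        3.70    11.25
G01697        3.65    10.77
G00956        3.50    10.62
G00227        3.30     9.94
G00027        3.25     9.64
```

18 of 225 synthetic cells were planted to fail exactly one QC criterion
and exactly those are removed; the resampled consensus analysis of the
surviving P2 cells proposes k = 3 types matching the planted truth
(adjusted Rand index 0.96); and the top-ranked enriched genes of type 1
are all planted type-1 markers, with estimated log2 fold changes near
the planted value of 3.

The same pipeline is available from the shell:

```sh
scint synth counts --seed 0 --out data/
scint qc --counts data/ --out qc/
scint cluster --counts data/ --stage P2 --k 3 --seed 7 --out clust/
scint de --counts data/ --assignment clust/assignment.tsv --type 1 --out de.tsv
scint migrate --tracks tracks.tsv --burn-in 60 --out mig/
```

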