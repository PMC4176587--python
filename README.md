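# tempoclust

Analysis toolkit for two-strain time-course transcriptomics: it answers the
question "which genes respond over time, how do the two strains differ, and
how do those responses compare with other published stress or
acid-production experiments?" The typical user has a gene × sample log2
expression matrix from a producer strain and a control strain sampled at a
handful of time points with a few biological replicates — for example an
engineered organic-acid-producing yeast next to its parent — and wants
soft clusters of temporal profiles, statistically sound per-time-point
differential expression, annotation-term enrichment per cluster, and a
harmonised cross-study comparison matrix.

## What it computes

**Dual-view fuzzy c-means clustering.** Genes are clustered twice, from two
views of the same data:

* **NP** (normalized profile) — each gene's replicate-averaged trajectory,
  scaled to mean 0 / sd 1, so clustering captures the *shape* of the
  response over time in both strains;
* **FC** (fold-change profile) — the per-time log2 ratio of producer over
  control, so −1 means 2-fold down and +1 means 2-fold up in the producer.

Both views are clustered with fuzzy c-means, minimising
`J = Σ_g Σ_j u_gj^m ‖x_g − v_j‖²` with memberships
`u_gj = 1 / Σ_k (d_gj/d_gk)^{2/(m−1)}` summing to 1 per gene.  The
fuzziness exponent `m` is selected by running the algorithm on a
row-randomized copy of the data and taking the smallest `m` at which no
clusters are detected there (no more than a sliver of genes reaching
membership ≥ 0.5); `m = 1.35` is the classical operating point for
microarray time courses and is the package default.  The cluster count `c`
is selected as the largest value at which every cluster holds at least one
gene with membership ≥ 0.5 **and** repeated runs from different starts
produce matching centroids (greedy best-match Pearson r ≥ 0.9).  Genes are
hard-assigned to their argmax cluster only when the membership reaches
0.5; the two views are then cross-tabulated to show how each NP cluster
distributes over FC clusters.

**Moderated differential expression.** For each condition pair, a per-gene
one-way linear model is fitted by least squares and the residual variances
are shrunk by empirical Bayes: hyperparameters (d0, s0²) are estimated by
moment matching on log s² (digamma/trigamma identities), the posterior
variance is `s̃² = (d0·s0² + d·s²)/(d0 + d)`, and the moderated t has
`d0 + d` degrees of freedom.  P-values are Benjamini–Hochberg adjusted,
with default significance thresholds of adjusted p < 1e-05 and
|log2 ratio| ≥ 1.

**Cluster enrichment.** Annotation terms (GMT files) are tested per
cluster with the upper hypergeometric tail P(X ≥ k) over the measured-gene
universe.

**Cross-study integration.** Per-study log2-ratio columns (each study vs
its own control) are quantile-normalized (studies with complete data),
scaled to a common range by a sign-preserving piecewise-linear map
(default [−4.03, 4.07]; zero stays zero and within-study gene ranks are
unchanged), filtered to genes significant in ≥ 2 comparisons, and
clustered on both axes with complete-linkage hierarchical clustering for
ordered-matrix (heatmap) export with newick dendrograms.

**Synthetic data.** `tempoclust.simulate` generates every input with known
ground truth: two strains × 6 time points × 3 replicates, genes drawn from
planted temporal archetypes (steady up, steady down, transient, delayed,
producer-induced flat) with Gaussian log2 replicate noise; term sets
enriched in chosen archetypes; and panels of pseudo-studies sharing
planted response modules.

## Worked example

```python
import tempoclust as tc
from sklearn.metrics import adjusted_rand_score

cfg = tc.default_config(seed=7)               # 5 archetypes x 200 genes
ds, truth = tc.simulate_timecourse(cfg)
avg = tc.average_replicates(ds)
np_view = tc.normalized_profiles(avg)

m, _ = tc.select_m(np_view, [1.05, 1.15, 1.25, 1.35, 1.5, 2.0], c=5, seed=0)
c, _ = tc.select_c(np_view, range(2, 9), m=m, seed=0)
fit = tc.fcm_fit(np_view, c=c, m=m, seed=1)
ha = fit.hard_assignments()
print(f"selected m={m}, c={c}")
print(f"ARI vs planted archetypes: "
      f"{adjusted_rand_score(truth[ha.index][ha >= 0], ha[ha >= 0]):.3f}")
```

prints

```
selected m=1.35, c=5
ARI vs planted archetypes: 1.000
```

i.e. the randomized-data heuristic lands on the m = 1.35 operating point,
the occupancy + stability heuristic recovers the planted number of
archetypes, and the hard cluster assignments reproduce the planted
partition exactly (adjusted Rand index 1.0).  Continuing with
`tc.enrich_clusters` ranks the planted term of the up-regulated archetype
first in its cluster at `p = 4.8e-38` (50 of 50 term genes in a 200-gene
cluster from a 1000-gene universe).

The same stages are available from the shell:

```sh
tempoclust run --outdir runs/demo --seed 7         # end-to-end on synthetic data
tempoclust simulate --seed 7 --outdir data/
tempoclust preprocess --dataset data/expression.tsv --metadata data/samples.tsv \
    --view np --out np.tsv
tempoclust select-params --profiles np.tsv --out params.tsv
tempoclust cluster --profiles np.tsv --c 5 --m 1.35 --seed 1 \
    --out-memberships mem.tsv --out-centroids cent.tsv
tempoclust enrich --memberships mem.tsv --gmt data/terms.gmt --out enr.tsv
```

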