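# Methods

This note records the models implemented in `tempoclust`, the defaults and
their rationale, what the synthetic generator does and does not emulate,
and the numerical and design choices a maintainer would want explained.

## Data model

The unit of input is a gene × sample matrix of log2 intensities with
per-sample annotations (strain ∈ {producer, control}, time in hours,
replicate).  All noise models and all downstream arithmetic operate on the
log2 scale; a difference of log2 means *is* a log2 fold-change.  Replicates
are averaged before profile construction — clustering operates on one
profile per gene, while replicate variance is consumed separately by the
differential-expression model.

### The two clustering views

* **NP** — per gene, the concatenated producer + control trajectory is
  centred and scaled to mean 0, sd 1 (sample sd, n−1 denominator).
  Scaling the concatenated profile (rather than each strain separately)
  keeps both strains' shapes, and their relative levels, visible in a
  single vector; `per_strain=True` switches to separate scaling when pure
  within-strain shape is wanted.  Zero-variance rows have no defined
  z-score; they are excluded from the clustering input and reported in
  `ProfileMatrix.degenerate`.  No other gene filtering is applied.
* **FC** — per gene and time, producer log2 mean minus control log2 mean.
  No row scaling, so −1 means exactly 2-fold down in the producer.

### qPCR transform

Relative template abundance from threshold cycles is `2^(−Ct)` (exact
doubling per cycle; no amplification-efficiency correction), reported as a
percentage of the maximum over the conditions, so the most expressed
condition reads exactly 100.

## Fuzzy c-means

Objective `J = Σ_g Σ_j u_gj^m d_gj²` with Euclidean distance, alternating
the centroid update `v_j = Σ u^m x / Σ u^m` and the membership update
`u_gj = 1/Σ_k (d_gj/d_gk)^{2/(m−1)}`.  Numerical choices:

* Memberships are computed as a softmax of `−log(d²)/(m−1)`, which is the
  same formula evaluated in log space and is stable for the small m
  (sharp exponent ≈ 5.7 at m = 1.35) this domain uses.  A gene at exactly
  zero distance from one or more centroids takes the limit value:
  membership split equally over the zero-distance centroids.
* Convergence is declared when max |Δu| < 1e-6 (membership change is on a
  bounded scale, unlike the objective, so one tolerance fits all data
  magnitudes); iteration cap 500.  The per-iteration objective is recorded
  and is non-increasing by construction of the alternating minimisation.
* Initialization is k-means++ centroid seeding from the data
  (deterministic given the seed), with memberships derived from the
  membership formula.  Uniform-random membership initialization was tried
  first and produces initial centroids that all sit near the global data
  mean; on well-separated profile data it converges to a cluster-merging
  local optimum in roughly a third of runs, which destroys the run-to-run
  stability signal that c-selection depends on.  k-means++ seeding removes
  that failure mode while keeping runs seeded and reproducible.  Duplicate
  initial centroids (possible only with duplicated profiles) trigger a
  re-draw.

### Selecting m

The algorithm is run on a row-randomized copy of the data (each gene's
values permuted independently across columns, preserving per-gene
marginals while destroying temporal and cross-gene structure) over an
ascending m grid.  "Clusters detected" is operationalised as more than 1%
of genes reaching max membership ≥ 0.5 — the same 0.5 membership cut-off
used everywhere else.  The chosen m is the smallest grid value at which no
seed detects clusters.  On the default synthetic data this lands on 1.35:
smaller m (1.05–1.25) behaves like hard k-means and carves crisp clusters
out of pure noise, larger m flattens memberships toward 1/c.

### Selecting c

For each candidate c, `n_repeats` (default 3) seeded runs are fitted.  The
candidate passes if (1) in every run, every cluster contains at least one
gene with membership ≥ 0.5, and (2) the runs are mutually stable: matching
centroids greedily by Pearson correlation, every matched pair correlates
at ≥ 0.9.  The largest passing c wins.  Correlation (not Euclidean
distance) is used for matching because centroid *shape* is what a
practitioner compares across runs; 0.9 is deliberately strict so that an
extra cluster which splits a real group differently in different runs
fails the criterion.

### Comparing the two views

Genes are hard-assigned (argmax membership, threshold 0.5; below-threshold
genes stay unassigned rather than being forced) in each view and
cross-tabulated into a cluster × cluster count table, with unassigned
counts reported per view.

## Moderated differential expression

One-way group-means layout (every comparison in this setting is a pair of
conditions, so a general design matrix adds nothing): per gene, group
means are replicate means and `s²_g` pools residuals across groups with
`d = n − n_levels` degrees of freedom.  The variance prior is a scaled
inverse-chi-square with hyperparameters estimated from the ensemble of
genes by moment matching on `z = log s²`, using
`E[log(χ²_k/k)] = ψ(k/2) − log(k/2)` and `Var = ψ′(k/2)`:
`d0 = 2·ψ′⁻¹(Var(e) − ψ′(d/2))`, `s0² = exp(mean(e) + ψ(d0/2) − log(d0/2))`
with `e = z − ψ(d/2) + log(d/2)`.  The trigamma inversion is a Newton
iteration (tolerance 1e-8) started at `0.5 + 1/y`, with asymptotic
branches at both extremes; d0 above 1e6 is reported as +∞ (variances
underdispersed relative to chi-square sampling noise), in which case
`s̃² = s0²` and the reference distribution is normal.  Genes with `s² = 0`
are excluded from hyperparameter estimation (their log is undefined) but
still receive a posterior variance.  `prior_df=0` recovers the ordinary
pooled two-sample t — useful both as a limiting-case check and as an
escape hatch.

P-values are two-sided.  BH adjustment delegates to
`statsmodels.stats.multitest` and is applied across genes within each
contrast.  The default selection rule is adjusted p < 1e-05 and
|log2fc| ≥ 1; the p cut-off is applied to the BH-adjusted value (the
conventional reading when FDR control is named alongside the threshold),
with `use_adjusted=False` to apply it to raw p instead.

## Enrichment

Plain (unconditional) hypergeometric upper-tail test per (cluster, term),
via the exact survival function; no ontology-graph conditioning and no
annotation propagation — term files are taken at face value.  The universe
is the set of measured genes, matching the sampling frame the clusters
were drawn from.  Raw p is primary (BH across terms within each cluster is
supplied as supplementary output); terms smaller than 3 genes after
restriction to the universe are not tested.

## Cross-study integration

Each study is one column of per-gene log2 ratios vs its own control plus a
significance flag from the original study's criteria.  Pipeline order:
quantile normalization → range scaling → recurrent-significance selection
→ complete-linkage clustering of both axes.

* **Quantile normalization** is applied to the block of studies with
  complete data; partial studies bypass it and are only range-scaled.
  The reference distribution is the per-rank mean of column-sorted values;
  tied values within a column receive the mean of the reference values at
  the tied ranks, which makes the transform idempotent.
* **Range scaling** to [lo, hi] (default [−4.03, 4.07]) is a
  sign-preserving piecewise-linear map through zero: positive values ×
  hi/max, negative values × lo/min.  An affine min–max map would shift the
  zero point of a log2 ratio and corrupt up/down semantics; the piecewise
  map keeps signs, keeps zero at zero, and preserves within-study rank
  order.  An all-zero study is returned unchanged.
* **Selection**: genes flagged significant in ≥ `min_count` (default 2)
  comparisons; per-gene counts are returned for audit.  Alternative
  selection predicates (e.g. union with a stress-response gene list, or a
  fold-change-in-k-studies rule) can be applied by the caller before
  clustering, since selection is an explicit, separable step.
* **Clustering**: Euclidean complete linkage via
  `scipy.cluster.hierarchy.linkage`; merge heights are non-decreasing
  (ultrametric property).  Genes missing from a study are imputed to 0 for
  the distance computation with a logged warning and remain visible as
  missing in the export.  Dendrograms export as newick.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *design* of a two-strain bioreactor time
course: 2 strains × 6 time points (0, 7, 23, 47, 49, 71 h) × 3
replicates, ~1,000 genes drawn from five temporal archetypes, additive
Gaussian noise on log2 values.  Defaults:

* **Archetypes** (base profile = control-strain log2 means; strain effect
  = additive producer offset, i.e. the planted FC profile): steady up,
  steady down, transient (early peak), delayed (late onset), and
  flat-but-producer-induced.  Amplitudes span 2–3 log2 units, typical of
  strongly responding genes.  The shapes are chosen to be mutually
  distinguishable in both views — that separability is a stated
  calibration of the generator (clustering should recover the planted
  partition at ARI ≥ 0.8 for noise sd ≤ 0.25 and ≥ 100 genes per
  archetype), not an accident.  A truly flat, non-induced archetype would
  be degenerate in the NP view (its z-score is pure noise), which is why
  the flat archetype carries a producer induction.
* **Replicate noise sd = 0.2 log2 units** per measurement.  Replicate
  variability of well-measured genes on expression arrays is of the order
  of 10–25% CV; 0.2 log2 units (~15%) sits in that band.  This is a
  package choice, not a literature-fixed constant.
* **Term sets**: each planted term samples from one source archetype plus
  optional background genes; a background-only term provides the null.
* **Pseudo-studies**: 20 columns over a shared universe, planted modules
  (gene set, affected studies, common log2 effect), flags set where the
  |ratio| exceeds a truth threshold (default 1).

Ground truth is always returned separately from the dataset (never encoded
in gene identifiers), so tests cannot accidentally leak labels.

What the generator deliberately does **not** emulate: probe-level effects
and RMA summarisation, dye/batch effects, intensity-dependent variance,
missing values, correlated replicate structure, and ontology-structured
annotation.  Tests passing on this data therefore demonstrate correctness
of the algorithms and calibration under idealised noise — not robustness
to array artefacts, which an RMA-style upstream pipeline is expected to
have removed.

Row-wise independent permutation is used as the "randomized data" for
m-selection: it preserves each gene's value multiset (hence marginal
scale) while destroying temporal ordering and cross-gene correlation.

## Reproducibility

All generators and fits are pure functions of (config, seed).  The
pipeline expands one top-level seed into per-stage seeds via
`numpy.random.SeedSequence([seed, stage_offset])`, so every stage is
independently reproducible; two runs with the same config produce
byte-identical outputs.  Output tables carry a header comment with the
generating parameters and a config hash.

## Problem sizes used in the test and acceptance suites

The shipped suites run the default study conditions: 1,000 genes
(5 × 200), 36 samples, 10-seed clustering replicates, 20 trials for
c-selection and for the integration panel (20 studies × 1,000 genes), a
2,000-gene global-null calibration, and 5,000-gene × 20-seed
hyperparameter-recovery simulations.  These sizes give stable medians and
tight binomial bounds while keeping a full run to a few minutes of CPU.

## Known limitations

* The stability criterion in c-selection quantifies what is, in practice,
  a judgement call; the 0.9 correlation threshold is a reasonable but not
  canonical choice, and very elongated clusters can match above 0.9 while
  differing in extent.
* The hypergeometric test treats terms independently; nested terms will
  co-score.
* The range-scaling map is one defensible reading of "scaled to the same
  range"; any monotone sign-preserving alternative would also satisfy the
  stated invariants.
* d0 estimation assumes a common residual df across genes (true in the
  complete one-way layouts this package fits).
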