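# Methods

This note records the models, conventions, and numerical choices behind
`phagenet`, and what the synthetic-data checks do and do not establish.

## Data model

The universal input is an `AbundanceTable`: a taxa × samples matrix of
non-negative abundances on a fixed-total scale (a TPM analogue), a taxonomy
map (taxon → domain ∈ {bacteria, phage}, phylum, order, family), and sample
metadata (group, diet, host order, host family). Rows and columns are aligned
by id everywhere; taxa are rows, samples are columns, in memory and in the
tab-separated files. Validation is strict: duplicate ids, negative values,
and taxa/samples missing from taxonomy/metadata are hard errors that name the
offending entry.

## Synthetic community generator

The generator draws log abundances from a multivariate Gaussian and closes
each sample to `tpm_total`:

* latent `z ~ N(μ_g, Σ)` per sample of group *g*, abundance `exp(z)`,
  column-normalized. Closure and exponentiation distort Pearson correlations
  but largely preserve ranks, which is what the Spearman screen measures.
* **Group structure**: `μ_g = effect_size × ε`, with `ε` a fixed
  standard-normal draw per (taxon, group). `effect_size` is a log-scale mean
  shift; 0 gives exchangeable groups (the null used for calibration).
* **Correlated blocks**: members of a block with target ρ load `√|ρ|` on one
  shared factor (alternating loading signs when ρ < 0), giving latent
  pairwise correlation ρ (|ρ| between same-sign members of a negative block).
  A +0.9 latent block realizes mean pairwise Spearman ≈ 0.84 after closure at
  20 samples (Monte-Carlo, 50 seeds; minimum 0.70).
* **Hubs**: the hub loads 1.0 on its own factor, satellites ±√c with
  c = 0.5 by default, giving hub–satellite latent correlation ±0.71 and
  satellite–satellite correlation 0.5. Positive-definiteness makes mutually
  independent satellites impossible at this hub coupling (Σr² ≤ 1 would cap
  r at 1/√m); c = 0.5 is the weakest admissible mutual coupling, and it
  straddles the |ρ| ≥ 0.6 edge threshold so the hub, not the satellite
  clique, dominates degree.
* **Sparsity**: an optional fraction of structural zeros injected after
  normalization (default 0); a sample column is never fully zeroed.

One `numpy` generator seeded from the config drives all draws, so identical
configs produce byte-identical tables.

What the generator does **not** emulate: sequencing depth variation,
taxon-specific detection limits, phylogenetic correlation of abundances, and
the heavy taxon-richness tails of real metagenomes. Passing the recovery
tests therefore shows the estimators respond correctly to planted signal in
compositional log-normal data — not that real gut data satisfy those
assumptions.

## Diversity and effect attribution

* Shannon index with the natural logarithm, over positive entries of the
  per-sample relative composition.
* Bray–Curtis on abundances, Sørensen (`1 − 2a/(2a+b+c)`) on presence/absence
  with a strict detection threshold (`abundance > threshold`, default 0).
  Within the pipeline each domain is re-closed to sum 1 before its distance
  matrix is computed: whole-table closure would otherwise leak variation
  from one domain into the other (empirically this biased the
  bacteria–phage coupling slope upward on independent data).
* PERMANOVA is single-factor: for each factor, `R² = SS_between/SS_total`
  from the distance-based partition (`SS_total = Σ_{i<j} d²ᵢⱼ/n`,
  `SS_within = Σ_g Σ_{i<j∈g} d²ᵢⱼ/n_g`), pseudo-F with (g−1, n−g) degrees of
  freedom, and `p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)` under label
  permutation (999 by default, seeded). Perfectly separated groups give
  F = ∞; permutations reproducing the separation tie with it, so p stays
  honest. Cross-checked against `skbio.stats.distance.permanova` in tests.
* NMDS delegates to scikit-learn's non-metric SMACOF with a precomputed
  dissimilarity, k = 2, 20 random restarts, tol 1e-6, max 300 iterations,
  reporting Kruskal stress-1.
* Mann–Whitney is two-sided; small samples (min(n, m) ≤ 8) use the exact
  distribution — full permutation enumeration when ties are present — larger
  samples the normal approximation with tie correction. The tied small-n path
  matches brute-force enumeration over all label assignments exactly.
* The coupling regression treats sample pairs as observations; its OLS
  p-value ignores pair non-independence, so a Mantel permutation p is
  available and reported alongside where requested.

## Co-occurrence networks

Per (group, mode) screen: Spearman ρ with midranks for every eligible taxon
pair (bacteria-only, phage-only, or interdomain — both domains, all passing
edges; a cross-only restriction exists); two-sided p from the t
approximation, exact permutation null for tie-free pairs at n ≤ 9 samples;
constant taxa excluded with a logged count. Benjamini–Hochberg q-values are
computed over all pairs tested within the one screen (the FDR family is the
(group, mode) screen; a global family is possible by screening the
concatenated pair list). Edges are exactly the pairs with |ρ| ≥ 0.6 and
q ≤ 0.01, both inclusive; taxa with no passing edge are not nodes, so node
counts refer to connected taxa. Before screening, the pipeline keeps the
top-k (default 1000) bacterial taxa by mean abundance within the group's
samples (ties broken by taxon id) and all phage taxa.

Topology is unweighted and sign-blind: betweenness as raw shortest-path pair
counts; closeness with the Wasserman–Faust component-aware scaling (in
[0, 1]); eigenvector centrality by power iteration (tol 1e-10) on the largest
component, rescaled to max 1, zero elsewhere. The keystone z-score is
`(degree − mean)/sd + (closeness − mean)/sd` over the network's nodes
(population sd; a zero-sd term contributes 0) — standardization keeps the
integer degree from drowning the [0, 1] closeness; the raw sum is available
via the topology table columns. Top 10 z-scores per network are the keystone
taxa; ties break by degree, then taxon id.

Modularity uses Newman's fast-greedy agglomeration on the canonicalized
(id-sorted) graph — deterministic, unlike Louvain/Leiden — and the reported Q
is recomputed from the returned node→module map by `Q = Σᵢ(eᵢᵢ − aᵢ²)` and
asserted equal to the optimizer's value to 1e-12. On toys ≤ 8 nodes the
greedy Q is within 0.02 of the exhaustive-partition optimum (tested).

Summary rows report node/edge counts, positive/negative edge counts and
rates (percentages, rounded half-up to 2 decimals; they sum to 100.00% when
edges exist), average degree 2E/N, and Q.

## Cohesion

On the persistence-filtered (present in ≥ 10% of samples, configurable)
relative-abundance table: observed pairwise Pearson correlations
(Spearman optional), minus the mean null correlation from a **taxon-shuffle
null with re-closure**: shuffle the focal taxon's abundances across samples,
re-close every sample to its original total, recompute the focal taxon's
correlations, and average over 200 iterations (seeded). Re-closure is what
lets the null reproduce correlation that compositionality alone generates —
two taxa dominating the composition anti-correlate near −1 mechanically, and
the corrected value collapses toward 0 (tested) — whereas a plain shuffle
has expected null correlation −ρ/(n−1) and would slightly amplify instead.
The two shuffle directions of a pair are averaged, keeping the corrected
matrix symmetric.

Connectedness of a taxon is the mean of its positive (respectively negative)
corrected correlations, 0 if none — the mean, not the sum, so the statistic
is comparable across networks of different size. Cohesion of a sample is
`Σ_taxa abundance × connectedness`, computed separately for the positive and
negative parts; `total = positive + |negative|` holds exactly and is asserted
in the result container. The per-group pipeline runs
filter → close → correct → connect → cohere independently per group and
compares total cohesion between groups by Mann–Whitney.

## Problem sizes and calibration checks

Simulation-based checks use sizes chosen for tight Monte-Carlo error at
interactive runtimes: hub recovery uses 1 hub + 15 satellites among 60 taxa,
40 samples, 50 seeds (recovery ≈ 96–98%); coupling uses two 6-taxon
cross-domain blocks among 45 taxa, 40 samples, 50 seeds; the cohesion
gradient uses 0/2/4 five-taxon blocks among 42 taxa, 25 samples, 60 null
iterations, 50 seeds; PERMANOVA calibration uses 200 null datasets × 199
permutations; the false-edge check uses 200 null screens of 23 taxa ×
20 samples. Larger tables sharpen all of these; none of the estimators'
logic depends on size.

## Known limitations

* The interdomain network includes within-domain edges by design (the
  restriction to cross-domain edges is available); reported node counts mix
  domains accordingly.
* Spearman exact p-values with ties at n ≤ 9 fall back to the t
  approximation.
* The cohesion null corrects pairwise correlations for closure, not for
  shared group-mean structure; strongly grouped data will show nonzero
  cohesion even without taxon interactions — compute cohesion per group (as
  the pipeline does) to avoid conflating the two.
* NMDS stress depends on restarts; with few restarts the seeded best-of-k
  solution may be a local optimum.
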