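# phagenet

Diversity, co-occurrence network, and cohesion analysis of gut **bacteria–phage
communities** from taxon-abundance tables.

Bacteria and their phages are the two most abundant biological entities in the
gut, and the structure of their joint community reflects both host factors
(diet, phylogeny) and direct ecological interactions. `phagenet` implements the
statistical toolchain used to study such communities from finished metagenomic
abundance tables (TPM-scale taxa × samples matrices for two domains), for
microbial ecologists who want the whole analysis — from dissimilarities to
interdomain networks — reproducible from one seeded configuration:

* **Diversity** — Shannon alpha diversity (natural log); Bray–Curtis and
  Sørensen beta dissimilarities; non-metric multidimensional scaling (Kruskal
  stress-1); UPGMA dendrograms; Mann–Whitney group comparisons.
* **Effect attribution** — one-factor PERMANOVA (Adonis) on a distance matrix:
  pseudo-F, R² = SS_between/SS_total, and a permutation p-value, one row per
  factor (diet, host order, host family).
* **Composition coupling** — OLS regression of phage pairwise dissimilarity on
  bacterial pairwise dissimilarity over all sample pairs (optional Mantel
  permutation p-value for the non-independence of pairs).
* **Co-occurrence networks** — Spearman correlation screen per (group, mode)
  with Benjamini–Hochberg FDR; edges where |ρ| ≥ 0.6 and q ≤ 0.01 (inclusive);
  bacteria-only, phage-only, and interdomain modes; degree / betweenness /
  closeness / eigenvector centralities; keystone taxa ranked by the z-score
  `standardize(degree) + standardize(closeness)` (top 10 per network);
  Newman fast-greedy modularity `Q = Σᵢ(eᵢᵢ − aᵢ²)`; a summary table of node
  and edge counts, signed-edge rates, average degree 2E/N, and Q.
* **Cohesion** — per-taxon connectedness (mean positive / mean negative
  null-corrected correlation, taxon-shuffle null with per-sample re-closure)
  and per-sample cohesion `C±(s) = Σₜ aₜ(s) · connectednessₜ±`, with
  `total = positive + |negative|`.
* **Synthetic communities** — a seeded generator of two-domain TPM-like tables
  with known ground truth: group effects, correlated taxon blocks (either
  sign, within or across domains) realized through shared latent Gaussian
  factors, and planted hub taxa. Every downstream claim is testable against
  what was planted.

## Worked example

```python
import phagenet as pn

config = pn.SynthConfig(
    n_groups=2, samples_per_group=20, n_bacteria=40, n_phages=20,
    group_effect_size=0.8,
    block_specs=[pn.BlockSpec(("B0001", "B0002", "B0003", "B0004", "B0005"), 0.9)],
    hub_specs=[pn.HubSpec("B0010", tuple(f"B{i:04d}" for i in range(11, 26)))],
    seed=42,
)
table, truth = pn.generate_community(config)

alpha_b = pn.alpha_diversity(table.subset_domain("bacteria"))
alpha_p = pn.alpha_diversity(table.subset_domain("phage"))
U, p = pn.mann_whitney(alpha_b, alpha_p)

D = pn.bray_curtis(table)
res = pn.permanova(D, table.metadata["group"], n_permutations=999, seed=0)

screen = pn.spearman_screen(table, mode="interdomain")
net = pn.build_network(screen, rho_min=0.6, q_max=0.01)
summary = pn.network_summary(net, pn.modularity_partition(net))
keystones = pn.keystone_zscore(pn.topology(net), top_n=3)

_, coh = pn.cohesion_pipeline(table, n_iter=200, seed=0)
```

Output:

```
mean Shannon H: bacteria 3.126, phages 2.397 (Mann-Whitney U=1591, p=2.81e-14)
PERMANOVA group effect: F=6.70, R2=0.150, p=0.001
network: 18 nodes, 22 edges (81.82% positive), Q=0.590
top keystone taxa: B0010 (z=3.10), P0015 (z=2.93), B0001 (z=2.20)
median cohesion: positive 0.167, negative -0.121, total 0.288
```

Reading the numbers: bacterial alpha diversity exceeds phage alpha diversity
(the generator plants more bacterial than phage taxa); the planted group shift
is detected by PERMANOVA (R² = 0.15 of the Bray–Curtis variation, p at the
permutation floor); the network's top keystone is exactly the planted hub
`B0010`, with a planted block member (`B0001`) close behind; cohesion
summarizes the planted co-variation as positive/negative interaction strength
per sample.

## Command line

```sh
phagenet synth   --config synth.yaml --out data/          # tables + ground truth
phagenet run     --config run.yaml                        # the full bundle
phagenet network --abundance a.tsv --taxonomy t.tsv --metadata m.tsv \
                 --mode interdomain --out net.graphml
phagenet cohesion --abundance a.tsv --taxonomy t.tsv --metadata m.tsv \
                 --out cohesion.tsv
```

`phagenet run` emits, per group: alpha tables with Mann–Whitney tests,
Bray–Curtis matrices, NMDS coordinates, UPGMA Newick trees, a PERMANOVA table,
Sørensen coupling regressions, three networks (GraphML + edge lists + topology
+ keystones + modules), a network summary table, cohesion tables, and a JSON
manifest with versions, thresholds, and the per-stage seeds derived from the
one master seed (reruns are byte-identical).

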