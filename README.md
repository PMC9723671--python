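# nullnet

Null-model comparison of groups of microbial association networks.

Association networks inferred from microbiome count data are noisy: edges
are statistical associations, not verified interactions, and apparently
striking patterns — a large shared "core" of edges across hosts or time
points, a highly central taxon — can arise from nothing more than node
and edge counts. `nullnet` asks whether such patterns survive comparison
with randomized networks. Given a group of *n* undirected weighted
networks sharing a taxon namespace, it

* generates **negative-control ensembles** per observed network — fully
  randomized networks (same nodes, same edge count, edges uniform) and
  degree-preserving networks (edges rewired by double edge swaps, every
  node keeping its degree) — and **positive controls** in which a
  synthetic core (a fraction of the union of observed edges) is planted
  at a chosen prevalence;
* computes the **edge-set algebra** over the group: the *k*-intersection
  {e : prev(e) ≥ k} (edges present in at least *k* networks), the unique
  difference {e : prev(e) = 1}, and the difference of intersections
  *k*→*m* = {e : k ≤ prev(e) < m}, whose subgraph is a **core
  association network (CAN)**; thresholds may be counts or fractions of
  *n* (fractions round up: the 0.5-intersection of 20 networks means "in
  at least 10");
* tests observed set sizes with a **Z-score test** against the set-size
  distribution over replicate groups (with a D'Agostino–Pearson
  normality gate), compares node **centrality ranks** (degree,
  betweenness, closeness) with repeated Mann–Whitney *U* tests and an
  add-one-smoothed parameter-free p-value
  p = (c − s + 1)/(c + 1) for *s* rejections in *c* comparisons,
  Benjamini–Hochberg-corrected across taxa, and compares whole-network
  properties (assortativity, connectivity, diameter, radius, average
  shortest path length);
* supports **ordered groups** (Spearman correlation of properties with a
  gradient order) and **rarefaction curves** of set sizes over the
  number of networks subsampled.

## Worked example

Plant a 12-edge core in half of 10 synthetic networks (30 taxa, 50 edges
each) and test whether the toolbox finds it:

```python
from nullnet import (SyntheticSpec, generate_group, GroupComparison,
                     SetDefinition)

group, truth = generate_group(SyntheticSpec(
    n_networks=10, n_taxa=30, edges_per_network=50,
    core_size=12, core_prevalence=0.5, seed=42))

model = GroupComparison(
    group,
    set_definitions=[SetDefinition("difference"),
                     SetDefinition("intersection", 2),
                     SetDefinition("intersection", 0.5),
                     SetDefinition("diff_of_intersections", 2, 5)],
    n_replicates=10, n_sets=50,
    metrics=("degree",), properties=("diameter",))
results = model.fit(seed=1)
print(results.summary())
```

```
Null-model comparison of association networks
==============================================
group: synthetic   networks: 10   taxa (union): 30   edges (union): 293
shared nodes (descriptive): 30
null models: random, degree   replicates/network: 10   replicate groups: 50
seed: 1

set                 source           observed  null mean  null sd        z          p      p(BH)  normal
----------------------------------------------------------------------------------------------------
difference          random                166        168     9.36   -0.218      0.828      0.828  yes
intersection_2      random                127        140     4.95    -2.62     0.0088     0.0117  yes
intersection_0.5    random                 13       1.38     1.12     10.3   4.25e-25    1.7e-24  yes
2->5                random                114      138.6     5.25    -4.69   2.73e-06   5.46e-06  yes
difference          degree                166      163.9     10.1    0.204      0.838      0.838  yes
intersection_2      degree                127      137.9     5.67    -1.92     0.0545     0.0727  yes
intersection_0.5    degree                 13       2.34     1.29     8.28   1.23e-16   4.93e-16  yes
2->5                degree                114      135.6     6.11    -3.53   0.000416   0.000832  yes

centrality comparisons: 60 node tests, 0 significant at BH-adjusted p < 0.05
property diameter          random      obs=5.8 null=5.89 z=-0.337 p=0.7365
property diameter          degree      obs=5.8 null=5.802 z=-0.0101 p=0.992
```

The planted core is exactly what lights up: the 0.5-intersection holds
13 edges (the 12-edge core plus one coincidental background edge) where
random ensembles produce one or two (z ≈ 10 against the fully random
null, z ≈ 8 against the degree-preserving null). Sets dominated by
background edges (the unique difference; the 2→5 band) stay at or below
their null expectation, no taxon has a nonrandom centrality ranking, and
the diameter is unremarkable. `results.can(0.5)` extracts the CAN itself
as a network (edge weights are the mean over contributing networks) for
export via `nullnet.write_network`.

The same analysis runs from the shell on GraphML or TSV edge lists
(`source<TAB>target<TAB>weight`):

```bash
nullnet --graph net1.graphml,net2.graphml,net3.graphml --label gut \
        --perm 10 --nperm 50 --set difference --set 0.5 --set 2:5 \
        --centrality --network-properties --can 0.5 \
        --seed 1 --out results/
```

which writes `gut_setsizes.tsv`, `gut_comparisons.tsv`,
`gut_centralities.tsv`, `gut_properties.tsv`, `gut_can_0.5.graphml` and
a `run.log`; all tables are tab-delimited with `# key=value` provenance
headers. Outputs are byte-identical across runs with the same
configuration and seed.

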