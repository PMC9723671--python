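# Methods

## Problem setting

The unit of analysis is a *group* of n ≥ 2 undirected, weighted
association networks over a shared taxon namespace — one network per
host, time point, or position along a gradient. Edge identity is the
unordered taxon pair; weights never participate in edge matching. An
optional sign mode qualifies each edge with the arithmetic sign of its
weight, so that a positive and a negative association between the same
taxa count as different edges (the literature does not settle whether
matching should be sign-aware, so it is a flag, off by default). Taxon
identifiers are opaque strings; no taxonomy is parsed. Nodes without any
incident edge (orphans) are kept on input by default: including them
makes the fully random null draw associations from all taxa, which
lowers null set sizes and can overstate the significance of a core, so a
`strip_orphans` option removes them for analyses that prefer the
conservative choice.

## Null models

Two negative controls bracket the constraint spectrum:

* **Fully random** (`random`): a network with the source's node set and
  edge count, edges drawn uniformly without self-loops or duplicates.
  Only node identity and edge number are conserved. Weights (hence
  signs) of randomized edges are resampled with replacement from the
  source's weights, preserving its sign composition.
* **Degree-preserving** (`degree`): the source rewired by double edge
  swaps — (a, b), (c, d) → (a, c), (b, d) — rejecting swaps that would
  create a self-loop or duplicate. Every node keeps its degree exactly;
  betweenness and other non-degree properties are free to change. The
  number of successful swaps per replicate is max(100, 10·|E|); the
  mixing count is a convention (standard rewiring practice, exposed as
  `swaps_per_edge`) since no canonical value exists. A network admitting
  no valid swap (e.g. a triangle) is returned unchanged with a warning.
  After an attempt budget of 100 attempts per requested swap the
  replicate is returned as-is with a warning rather than looping
  forever.

Positive controls plant a **synthetic core**: ⌈fraction·|union|⌉ edges
sampled uniformly from the union of observed edge sets, carried by
⌈prevalence·n⌉ uniformly chosen network positions. Fractional sizes and
prevalences always round up, so a 10% prevalence among 20 networks means
2 carriers. One core assignment is sampled per ensemble and shared by
all replicates (the alternative — a fresh core per replicate — would
blur the prevalence signal the positive control exists to create). Under
the random model, core edges are placed first and the remainder filled
uniformly; a core larger than a network's edge count is a hard error.
Under the degree model, a degree-preserving replicate is generated
first; each missing core edge (a, b) is then created by a targeted swap
that removes (a, x) and (b, y) and adds (a, b) and (x, y), which
preserves all degrees, never sacrificing another core edge. When no
valid (x, y) exists — e.g. both endpoints' only neighbour is the same
node — a random non-core edge is deleted and the core edge inserted.
This fallback preserves the edge count but not the degrees of the four
touched nodes; fallback events are counted per replicate, and a
prominent warning fires when they exceed half the core, since the degree
distribution then deviates substantially (large cores or sparsely
connected core nodes). Core edges whose endpoints are absent from a
network are skipped with a warning rather than adding nodes, which would
change the node universe.

Growth-based models (preferential attachment and relatives) are
deliberately out of scope: they encode mechanisms that cannot be assumed
for association networks, and a null model with an unverified assumption
stops being a null.

An ensemble holds `n_replicates` randomizations per observed network
(default 10) and `n_sets` replicate groups (default 50), each picking
one replicate per position independently and uniformly. Seeding is
hierarchical: one master seed; per-(network, replicate) streams derived
through `numpy.random.SeedSequence` spawn keys, so ensembles are
reproducible and order-independent.

## Set algebra

All set operations reduce to per-edge prevalence counting — the number
of networks containing an edge — because the identity of the networks is
irrelevant to "present in at least k". The k-intersection is
{e : prev(e) ≥ k}; the unique difference {e : prev(e) = 1}; the
difference of intersections k→m is {e : k ≤ prev(e) < m} with k < m and
m = n+1 meaning no upper removal. These satisfy the partition identity
|prev=1| + Σ_{k=2..n−1} |k→k+1| + |prev≥n| = |union|, which is tested as
an invariant, and each operation is tested against an independent oracle
built from the literal union-over-combinations definitions. Fractional
thresholds convert with a ceiling (⌈fraction·n⌉); Python ints are counts
and floats are fractions, so the integer 1 (union) and the float 1.0
(full intersection) are distinct definitions. The CAN at threshold k is
the k-intersection as a network; its edge weights are the arithmetic
mean of the weights in the contributing networks (symmetric and
order-free; the median would be an equally defensible choice). Matching
*node* counts are reported only descriptively — the algebra is defined
on edge sets and no significance test is attached to shared nodes.

## Significance tests

**Set sizes.** For each set definition and each null source, the null
sample is the set size over that source's replicate groups; the test is
two-sided z = (observed − mean)/sd (sample sd, ddof 1) with p from the
standard normal — two-sided because deviations in either direction are
informative. The D'Agostino–Pearson omnibus test (scipy `normaltest`)
gates the normality assumption at α = 0.05; with fewer than 20 null
values the gate cannot run reliably, `normality_ok` is false, and a
warning tells the user to increase the number of sets. A zero-variance
null is degenerate: p = 1 if the observed value equals the constant,
else p = 0, flagged in the result's note.

**Centralities.** Degree, shortest-path betweenness (normalized by
(N−1)(N−2)/2) and classic closeness (per-component, scaled by component
size fraction) come from NetworkX — the standard implementations — and
are converted to average-tied ranks within each network so that
networks with different edge numbers are comparable. Orphan nodes are
excluded from scoring; a node absent or orphaned in a network
contributes no rank for that network rather than a rank of zero. A
node's observed rank sample (requiring presence in ≥ 2 observed
networks) is compared to its rank sample in each of c replicate groups
by a two-sided Mann–Whitney U test (normal approximation with tie
correction) at level α; with s rejections the parameter-free p is the
add-one-smoothed non-rejection fraction (c − s + 1)/(c + 1). The
smoothing keeps p off exactly zero (floor 1/(c+1) — with the default 50
comparisons the smallest attainable p is ≈ 0.0196) and makes it a valid
empirical p-value. Ranks are pooled across the networks of each group
rather than tested per network, matching the idea of comparing
distributions of ranks across groups. Benjamini–Hochberg correction
(statsmodels) is applied across taxa within each (metric, null source)
family; the same correction is applied across set definitions within a
null source for symmetry of the output table.

**Network properties.** Degree assortativity (Pearson correlation of
endpoint degrees; undefined for constant-degree graphs and recorded as
missing), connectivity, diameter, radius and average shortest path
length. "Connectivity" is implemented as average node connectivity on
the largest connected component, with edge connectivity behind a flag —
the scalar variant defined for any connected graph. Path-based
properties of disconnected graphs are computed on the largest connected
component and annotated; edge weights are ignored in all metrics, since
association weights are correlation-like quantities, not distances. The
observed statistic is the mean over observed networks; the null sample
is the per-replicate-group mean; the Z-score test applies as above.

**Ordered groups.** When the group order encodes a gradient, Spearman's
rho of each property against position 1..n is reported with its p-value
(average ranks for ties; constant properties are recorded as undefined).

## Rarefaction

The resampling option draws, per resample, a random permutation of the
group and evaluates each set definition on its nested prefixes of size
s = 2..n. Nesting the subsets within a draw makes the union curve
non-decreasing and the full-intersection curve non-increasing draw by
draw — the qualitative shape a rarefaction curve is read for — rather
than only in expectation; means and standard errors per subset size are
summarized separately. Integer thresholds larger than the current subset
size contribute no point at that depth; fractional thresholds re-resolve
against s.

## Synthetic fixtures

The generator emulates what a group of inferred networks looks like to
the toolbox: uniform random simple graphs on a shared taxon universe
with configurable per-network edge counts, signed weights (magnitude
uniform on [0.1, 1], negative with configurable probability), an
optional planted core inserted into exactly ⌈prevalence·n⌉ networks
(displacing random non-core edges so edge counts hold; non-carriers draw
only non-core pairs, so planted prevalence is exact and background
prevalence is very slightly depleted), hub taxa wired to a fixed high
degree in every network, and strict monotone edge-count trends for
ordered groups. Backgrounds are uniform random graphs on purpose: that
is exactly the fully random null, so calibration experiments compare
like with like by construction. The defaults (20 networks, 50 taxa, 100
edges, 20-edge core at prevalence 0.5) represent a mid-sized
comparative study. What the fixtures do *not* emulate: compositional
count data, the error structure of any particular inference method,
taxon-abundance-driven edge probability, or cross-network weight
correlation — so passing tests demonstrate correctness of the null-model
machinery, not robustness to inference artefacts in real data.

## Problem sizes and numerical choices

The test suite and the reproduction script run ensembles at the default
10 replicates × 50 sets on groups of 10–20 networks with 25–50 taxa and
40–100 edges — large enough for the asymptotic inner tests (network
counts ≥ 8 per Mann–Whitney sample) and for the normality gate, small
enough that the full suite completes in about a minute. The calibration
experiment uses 200 simulated runs and the k = 2 intersection of a
10-network group, whose null set-size distribution is comfortably
non-degenerate; its empirical false-positive rate lands near the nominal
0.05 (the Z-test on 50 discrete set sizes is approximate, so a band
rather than a point is the honest expectation). Determinism is exact:
identical configuration and seed give byte-identical output tables, with
timestamps confined to the run log.

## Known limitations

* The Z-score test assumes approximate normality of null set sizes;
  heavily discrete or skewed distributions (tiny groups, near-empty
  intersections) trip the normality gate, and the degenerate-null branch
  returns hard 0/1 p-values that should be read qualitatively.
* The degree-preserving positive control is only approximately
  degree-preserving when the fallback fires; the fallback count is the
  diagnostic to watch.
* Average node connectivity is O(|V|²) max-flow computations and is the
  slow path among the properties; it is excluded from the default
  property list and opt-in.
* p-values from the parameter-free procedure are bounded below by
  1/(c+1); with few replicate groups no taxon can clear a stringent
  multiple-testing threshold, by design rather than by accident.
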