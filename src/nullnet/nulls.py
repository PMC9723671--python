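"""Null models for association networks.

Two negative-control models are implemented:

* ``random`` — fully randomized: a network is initialized with the same
  nodes as the input and edges are added uniformly at random until the
  edge count matches.  Only node identity and edge number are conserved.
* ``degree`` — degree-preserving: edges are rewired by repeated double
  edge swaps, where two edges (a, b) and (c, d) become (a, c) and (b, d).
  Every node keeps exactly its original degree; other centralities (e.g.
  betweenness) are free to change.

Positive controls plant a synthetic core: a fraction of the union of
observed edges is fixed in a chosen fraction of the networks (the core
prevalence).  For the fully random model the core edges are placed first
and the remainder filled at random.  For the degree-preserving model a
negative-control replicate is generated first; then for each missing core
edge the algorithm searches for a double swap that creates it without
breaking simplicity.  If no such swap exists, a random non-core edge is
deleted and the core edge inserted — the documented fallback that
preserves edge count but not degree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .network import NEGATIVE, POSITIVE, EdgeKey, Network, NetworkGroup, edge_key

logger = logging.getLogger("nullnet")

MODELS = ("random", "degree")

#: successful swaps per degree-preserving replicate: max(MIN_SWAPS, SWAPS_PER_EDGE * |E|)
MIN_SWAPS = 100
SWAPS_PER_EDGE = 10
#: give up on a replicate after this many attempts per requested swap
ATTEMPTS_PER_SWAP = 100


@dataclass
class NullModelSpec:
    """Configuration of one null-model ensemble.

    ``core_fraction`` is the fraction of the union of observed edges fixed
    as a synthetic core (0 = negative control); ``core_prevalence`` the
    fraction of networks carrying it.  ``n_replicates`` randomized networks
    are generated per observed network (default 10) and ``n_sets`` replicate
    groups are sampled from them to build null set-size distributions
    (default 50).
    """

    model: str = "random"
    core_fraction: float = 0.0
    core_prevalence: Optional[float] = None
    n_replicates: int = 10
    n_sets: int = 50
    seed: int = 0
    swaps_per_edge: int = SWAPS_PER_EDGE

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must lie in [0, 1]")
        if self.core_fraction > 0 and self.core_prevalence is None:
            raise ValueError("core_fraction > 0 requires core_prevalence")
        if self.core_prevalence is not None and not 0.0 < self.core_prevalence <= 1.0:
            raise ValueError("core_prevalence must lie in (0, 1]")
        if self.n_replicates < 1 or self.n_sets < 1:
            raise ValueError("n_replicates and n_sets must be >= 1")

    @property
    def source_name(self) -> str:
        """Tag used in result tables: random / degree / random_core / degree_core."""
        return self.model + ("_core" if self.core_fraction > 0 else "")


@dataclass
class CoreAssignment:
    """A sampled synthetic core: fixed edges plus the carrier positions."""

    core_edges: Set[EdgeKey]
    carrier_indices: Set[int]


@dataclass
class NullEnsemble:
    """Replicate randomizations for one observed group under one spec."""

    source_group: NetworkGroup
    spec: NullModelSpec
    core: Optional[CoreAssignment]
    replicates: List[List[Network]]
    replicate_groups: List[NetworkGroup] = field(default_factory=list)
    fallback_counts: List[List[int]] = field(default_factory=list)

    @property
    def source_name(self) -> str:
        return self.spec.source_name


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _all_pairs(nodes: Iterable[str]) -> List[Tuple[str, str]]:
    return list(combinations(sorted(nodes), 2))


def _sample_weights(network: Network, rng: np.random.Generator,
                    size: int) -> List[float]:
    """Resample edge weights (hence signs) from the source's empirical
    weight distribution; keeps the sign composition of the input."""
    weights = list(network.edges.values())
    if not weights:
        return []
    idx = rng.integers(0, len(weights), size=size)
    return [weights[i] for i in idx]


def _build(network: Network, pairs: Sequence[Tuple[str, str]],
           weights: Sequence[float], name_suffix: str) -> Network:
    edges = {
        edge_key(a, b, weight=w, signed=network.signed): float(w)
        for (a, b), w in zip(pairs, weights)
    }
    return Network(name=f"{network.name}{name_suffix}",
                   nodes=set(network.nodes), edges=edges,
                   signed=network.signed)


def randomize_random(network: Network, seed=None) -> Network:
    """Fully randomized negative control: same nodes, same edge count,
    edges drawn uniformly among all node pairs without self-loops or
    duplicates."""
    if network.n_nodes < 2 and network.n_edges > 0:
        raise ValueError("cannot randomize a network with < 2 nodes")
    rng = _rng(seed)
    pairs = _all_pairs(network.nodes)
    m = network.n_edges
    if m > len(pairs):
        raise ValueError(
            f"{network.name}: {m} edges cannot be placed among "
            f"{len(pairs)} possible pairs")
    chosen = [pairs[i] for i in rng.choice(len(pairs), size=m, replace=False)] if m else []
    return _build(network, chosen, _sample_weights(network, rng, m), "_random")


def randomize_degree(network: Network, seed=None,
                     swaps_per_edge: int = SWAPS_PER_EDGE) -> Network:
    """Degree-preserving negative control via repeated double edge swaps.

    Performs ``max(100, swaps_per_edge * |E|)`` successful swaps; swaps
    that would create a self-loop or duplicate edge are rejected and
    redrawn.  A network admitting no valid swap (e.g. a triangle) is
    returned unchanged with a logged warning.
    """
    rng = _rng(seed)
    out = network.copy(name=f"{network.name}_degree")
    m = out.n_edges
    if m < 2:
        logger.warning("%s: fewer than 2 edges, degree model returns the "
                       "network unchanged", network.name)
        return out
    edge_list: List[EdgeKey] = list(out.edges)
    present: Set[Tuple[str, str]] = {k.pair for k in edge_list}
    weights: Dict[EdgeKey, float] = dict(out.edges)
    target = max(MIN_SWAPS, swaps_per_edge * m)
    max_attempts = ATTEMPTS_PER_SWAP * target
    successes = 0
    attempts = 0
    while successes < target and attempts < max_attempts:
        attempts += 1
        i = int(rng.integers(0, m))
        j = int(rng.integers(0, m))
        if i == j:
            continue
        a, b = edge_list[i].pair
        c, d = edge_list[j].pair
        if rng.integers(0, 2):
            c, d = d, c
        # proposed new edges (a, c) and (b, d)
        if a == c or b == d:
            continue
        p1 = (a, c) if a < c else (c, a)
        p2 = (b, d) if b < d else (d, b)
        if p1 in present or p2 in present:
            continue
        w1, w2 = weights.pop(edge_list[i]), weights.pop(edge_list[j])
        present.discard(edge_list[i].pair)
        present.discard(edge_list[j].pair)
        k1 = edge_key(*p1, weight=w1, signed=out.signed)
        k2 = edge_key(*p2, weight=w2, signed=out.signed)
        edge_list[i], edge_list[j] = k1, k2
        weights[k1], weights[k2] = w1, w2
        present.add(p1)
        present.add(p2)
        successes += 1
    if successes == 0:
        logger.warning("%s: no valid degree-preserving swap found in %d "
                       "attempts; returning the network unchanged",
                       network.name, attempts)
        return out
    if successes < target:
        logger.warning("%s: only %d/%d swaps achieved before the attempt "
                       "budget ran out", network.name, successes, target)
    out.edges = {k: weights[k] for k in edge_list}
    return out


def sample_core(group: NetworkGroup, core_fraction: float,
                core_prevalence: float, seed=None) -> CoreAssignment:
    """Sample a synthetic core: ``ceil(core_fraction * |union|)`` edges
    drawn uniformly from the union of all observed edge sets, carried by
    ``ceil(core_prevalence * n)`` uniformly chosen network positions."""
    if not 0.0 < core_fraction <= 1.0:
        raise ValueError("core_fraction must lie in (0, 1]")
    if not 0.0 < core_prevalence <= 1.0:
        raise ValueError("core_prevalence must lie in (0, 1]")
    union = sorted(group.edge_union())
    if not union:
        raise ValueError(f"group '{group.label}' has an empty edge union")
    rng = _rng(seed)
    n_core = math.ceil(core_fraction * len(union))
    n_carriers = math.ceil(core_prevalence * group.n)
    core_idx = rng.choice(len(union), size=n_core, replace=False)
    carriers = rng.choice(group.n, size=n_carriers, replace=False)
    return CoreAssignment(core_edges={union[i] for i in core_idx},
                          carrier_indices={int(i) for i in carriers})


def _placeable_core(network: Network, core_edges: Set[EdgeKey]
                    ) -> List[EdgeKey]:
    placeable, skipped = [], 0
    for key in sorted(core_edges):
        if key.taxon_a in network.nodes and key.taxon_b in network.nodes:
            placeable.append(key)
        else:
            skipped += 1
    if skipped:
        logger.warning("%s: skipped %d core edges with endpoints absent "
                       "from the network", network.name, skipped)
    return placeable


def randomize_random_with_core(network: Network, core_edges: Set[EdgeKey],
                               seed=None) -> Network:
    """Positive control under the fully random model: placeable core edges
    are added first, then random edges until the source edge count."""
    if not core_edges:
        return randomize_random(network, seed=seed)
    rng = _rng(seed)
    placeable = _placeable_core(network, core_edges)
    m = network.n_edges
    if len(placeable) > m:
        raise ValueError(
            f"{network.name}: core of {len(placeable)} edges exceeds the "
            f"network's edge count {m}; shrink the core fraction")
    core_pairs = {k.pair for k in placeable}
    pool = [p for p in _all_pairs(network.nodes) if p not in core_pairs]
    n_fill = m - len(placeable)
    if n_fill > len(pool):
        raise ValueError(f"{network.name}: not enough free pairs to place "
                         f"{n_fill} non-core edges")
    fill = [pool[i] for i in rng.choice(len(pool), size=n_fill, replace=False)] if n_fill else []
    pairs = [k.pair for k in placeable] + fill
    return _build(network, pairs, _sample_weights(network, rng, m), "_random_core")


def randomize_degree_with_core(network: Network, core_edges: Set[EdgeKey],
                               seed=None,
                               swaps_per_edge: int = SWAPS_PER_EDGE
                               ) -> Tuple[Network, int]:
    """Positive control under the degree-preserving model.

    Returns ``(replicate, n_fallbacks)``.  A degree-preserving replicate is
    generated first; each missing core edge (a, b) is then created by a
    targeted swap removing edges (a, x) and (b, y) and adding (a, b) and
    (x, y) — which keeps every degree — or, when no valid (x, y) exists, by
    the delete-and-insert fallback that keeps the edge count but not the
    degrees of the touched nodes.
    """
    if not core_edges:
        return randomize_degree(network, seed=seed,
                                swaps_per_edge=swaps_per_edge), 0
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    swap_seed, place_seed = ss.spawn(2)
    out = randomize_degree(network, seed=swap_seed,
                           swaps_per_edge=swaps_per_edge)
    out.name = f"{network.name}_degree_core"
    rng = _rng(place_seed)
    placeable = _placeable_core(network, core_edges)
    core_pairs = {k.pair for k in placeable}

    adjacency: Dict[str, Set[str]] = {v: set() for v in out.nodes}
    for k in out.edges:
        adjacency[k.taxon_a].add(k.taxon_b)
        adjacency[k.taxon_b].add(k.taxon_a)

    def remove(k: EdgeKey) -> float:
        w = out.edges.pop(k)
        adjacency[k.taxon_a].discard(k.taxon_b)
        adjacency[k.taxon_b].discard(k.taxon_a)
        return w

    def add(a: str, b: str, w: float) -> None:
        k = edge_key(a, b, weight=w, signed=out.signed)
        out.edges[k] = w
        adjacency[a].add(b)
        adjacency[b].add(a)

    def find_key(a: str, b: str) -> EdgeKey:
        pair = (a, b) if a < b else (b, a)
        for k in out.edges:
            if k.pair == pair:
                return k
        raise KeyError(pair)

    present = lambda a, b: (b in adjacency[a])
    fallbacks = 0
    order = rng.permutation(len(placeable))
    for idx in order:
        target = placeable[idx]
        a, b = target.pair
        if present(a, b):
            continue  # already there: no swap or fallback needed
        placed = False
        xs = [x for x in adjacency[a] if x != b]
        ys = [y for y in adjacency[b] if y != a]
        rng.shuffle(xs)
        rng.shuffle(ys)
        for x in xs:
            if placed:
                break
            pax = (a, x) if a < x else (x, a)
            if pax in core_pairs:
                continue  # never sacrifice another core edge
            for y in ys:
                if x == y or present(x, y):
                    continue
                pby = (b, y) if b < y else (y, b)
                if pby in core_pairs:
                    continue
                w1 = remove(find_key(a, x))
                w2 = remove(find_key(b, y))
                add(a, b, w1)
                add(x, y, w2)
                placed = True
                break
        if not placed:
            # fallback: delete a random non-core edge, insert the core edge
            candidates = [k for k in out.edges if k.pair not in core_pairs]
            if not candidates:
                logger.warning("%s: no non-core edge left to sacrifice for "
                               "core edge %s; skipping it", out.name, target)
                continue
            victim = candidates[int(rng.integers(0, len(candidates)))]
            w = remove(victim)
            add(a, b, w)
            fallbacks += 1
    if placeable and fallbacks > 0.5 * len(placeable):
        logger.warning(
            "%s: delete-and-insert fallback fired for %d of %d core edges; "
            "the degree distribution of this positive control deviates "
            "substantially from the source (core too large or core nodes "
            "too sparsely connected)", out.name, fallbacks, len(placeable))
    return out, fallbacks


def _replicate_seed(master: int, net_index: int, rep_index: int
                    ) -> np.random.SeedSequence:
    """Deterministic per-network, per-replicate seed stream."""
    return np.random.SeedSequence(entropy=master,
                                  spawn_key=(net_index, rep_index))


def generate_null_ensemble(group: NetworkGroup, spec: NullModelSpec
                           ) -> NullEnsemble:
    """Generate ``n_replicates`` randomizations per observed network under
    *spec* and sample ``n_sets`` replicate groups from them.

    With ``core_fraction > 0`` one :class:`CoreAssignment` is sampled for
    the whole ensemble; every replicate of a carrier network plants the
    same core.
    """
    spec.validate()
    group.require_comparable()
    core: Optional[CoreAssignment] = None
    if spec.core_fraction > 0:
        core = sample_core(group, spec.core_fraction, spec.core_prevalence,
                           seed=np.random.SeedSequence(
                               entropy=spec.seed, spawn_key=(1 << 20,)))
    replicates: List[List[Network]] = []
    fallback_counts: List[List[int]] = []
    for i, net in enumerate(group.networks):
        reps: List[Network] = []
        falls: List[int] = []
        carries = core is not None and i in core.carrier_indices
        for r in range(spec.n_replicates):
            seed = _replicate_seed(spec.seed, i, r)
            if spec.model == "random":
                if carries:
                    rep = randomize_random_with_core(net, core.core_edges,
                                                     seed=seed)
                else:
                    rep = randomize_random(net, seed=seed)
                nfall = 0
            else:
                if carries:
                    rep, nfall = randomize_degree_with_core(
                        net, core.core_edges, seed=seed,
                        swaps_per_edge=spec.swaps_per_edge)
                else:
                    rep = randomize_degree(net, seed=seed,
                                           swaps_per_edge=spec.swaps_per_edge)
                    nfall = 0
            reps.append(rep)
            falls.append(nfall)
        replicates.append(reps)
        fallback_counts.append(falls)
    ensemble = NullEnsemble(source_group=group, spec=spec, core=core,
                            replicates=replicates,
                            fallback_counts=fallback_counts)
    ensemble.replicate_groups = sample_replicate_groups(
        ensemble, spec.n_sets,
        seed=np.random.SeedSequence(entropy=spec.seed, spawn_key=(1 << 21,)))
    return ensemble


def sample_replicate_groups(ensemble: NullEnsemble, n_sets: int,
                            seed=None) -> List[NetworkGroup]:
    """Sample *n_sets* groups, each picking one replicate per observed
    network position independently and uniformly."""
    rng = _rng(seed)
    groups: List[NetworkGroup] = []
    n = ensemble.source_group.n
    n_rep = ensemble.spec.n_replicates
    for s in range(n_sets):
        picks = rng.integers(0, n_rep, size=n)
        nets = [ensemble.replicates[i][int(picks[i])] for i in range(n)]
        groups.append(NetworkGroup(
            label=f"{ensemble.source_group.label}_{ensemble.source_name}_{s}",
            networks=nets, ordered=ensemble.source_group.ordered))
    return groups
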