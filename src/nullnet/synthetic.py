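"""Synthetic groups of association networks with controlled structure.

The generator emulates what a group of inferred microbial association
networks looks like to the toolbox: a shared taxon universe, per-network
edge sets of configurable size drawn as uniform random simple graphs,
signed weights, and optionally

* a planted core — a fixed edge set inserted into a chosen fraction of
  the networks, displacing random non-core edges so edge counts hold;
* hub taxa wired to a fixed large number of partners in every network
  (degree heterogeneity without any planted edge identity);
* a strict monotone trend in edge count along the group order, for
  testing ordered-group correlations.

Background graphs are uniform random simple graphs on purpose: that is
exactly the fully random null model, so calibration experiments are
exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .network import EdgeKey, Network, NetworkGroup, edge_key
from .nulls import CoreAssignment


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic group.

    Defaults mirror a mid-sized comparative study: 20 networks on 50 taxa
    with 100 associations each, and (when a core is requested) a 20-edge
    core carried by half the networks.
    """

    n_networks: int = 20
    n_taxa: int = 50
    edges_per_network: Union[int, Tuple[int, int]] = 100
    core_size: int = 0
    core_prevalence: float = 0.5
    signed: bool = False
    negative_edge_fraction: float = 0.3
    hub_fraction: float = 0.0
    hub_degree: Optional[int] = None
    trend: Optional[str] = None  # "increasing" | "decreasing" | "flat"
    seed: int = 0
    label: str = "synthetic"

    def edge_counts(self) -> List[int]:
        """Per-network edge counts implied by the spec."""
        n = self.n_networks
        if isinstance(self.edges_per_network, int):
            return [self.edges_per_network] * n
        lo, hi = self.edges_per_network
        if self.trend in (None, "flat"):
            return [lo] * n
        counts = np.linspace(lo, hi, n)
        counts = [int(round(c)) for c in counts]
        if len(set(counts)) < n:
            raise ValueError(
                f"edge range {self.edges_per_network} too narrow for a "
                f"strictly monotone trend over {n} networks")
        if self.trend == "decreasing":
            counts = counts[::-1]
        return counts

    def validate(self) -> None:
        if self.n_networks < 2 or self.n_taxa < 2:
            raise ValueError("need at least 2 networks and 2 taxa")
        max_edges = self.n_taxa * (self.n_taxa - 1) // 2
        for m in self.edge_counts():
            if m > max_edges:
                raise ValueError(f"{m} edges cannot fit among "
                                 f"{self.n_taxa} taxa ({max_edges} pairs)")
        if self.core_size > min(self.edge_counts()):
            raise ValueError("core_size exceeds the per-network edge budget")
        if self.core_size > 0 and not 0.0 < self.core_prevalence <= 1.0:
            raise ValueError("core_prevalence must lie in (0, 1]")
        if not 0.0 <= self.negative_edge_fraction <= 1.0:
            raise ValueError("negative_edge_fraction must lie in [0, 1]")


def _taxa(spec: SyntheticSpec) -> List[str]:
    width = len(str(spec.n_taxa - 1))
    return [f"t{i:0{width}d}" for i in range(spec.n_taxa)]


def _weights(rng: np.random.Generator, size: int, spec: SyntheticSpec
             ) -> np.ndarray:
    """Signed association weights: magnitude uniform on [0.1, 1], sign
    negative with probability negative_edge_fraction (signed mode only)."""
    mags = rng.uniform(0.1, 1.0, size=size)
    if spec.signed:
        signs = np.where(rng.random(size) < spec.negative_edge_fraction,
                         -1.0, 1.0)
        return mags * signs
    return mags


def _network(name: str, taxa: Sequence[str],
             pairs: Sequence[Tuple[str, str]], weights: Sequence[float],
             signed: bool) -> Network:
    edges = {edge_key(a, b, weight=w, signed=signed): float(w)
             for (a, b), w in zip(pairs, weights)}
    return Network(name=name, nodes=set(taxa), edges=edges, signed=signed)


def generate_group(spec: SyntheticSpec
                   ) -> Tuple[NetworkGroup, CoreAssignment]:
    """Generate a group with an optional planted core; returns the group
    and the ground-truth :class:`CoreAssignment` (empty when core_size=0).

    Carrier networks contain every core edge; non-carriers draw only from
    non-core pairs, so each core edge appears in exactly
    ``ceil(core_prevalence * n)`` networks (the background prevalence of
    non-core pairs is very slightly depleted in carriers as a result).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    taxa = _taxa(spec)
    all_pairs = list(combinations(taxa, 2))
    counts = spec.edge_counts()
    core_pairs: List[Tuple[str, str]] = []
    carriers: Set[int] = set()
    if spec.core_size > 0:
        idx = rng.choice(len(all_pairs), size=spec.core_size, replace=False)
        core_pairs = [all_pairs[i] for i in idx]
        n_carriers = math.ceil(spec.core_prevalence * spec.n_networks)
        carriers = {int(i) for i in rng.choice(spec.n_networks,
                                               size=n_carriers,
                                               replace=False)}
    core_set = set(core_pairs)
    # in signed mode each core edge keeps one fixed sign across carriers,
    # so it is the same edge under sign-aware matching
    core_signs = np.where(
        rng.random(len(core_pairs)) < spec.negative_edge_fraction, -1.0, 1.0
    ) if spec.signed else np.ones(len(core_pairs))
    background = [p for p in all_pairs if p not in core_set]
    networks: List[Network] = []
    for i in range(spec.n_networks):
        m = counts[i]
        if i in carriers:
            n_bg = m - spec.core_size
            bg_idx = rng.choice(len(background), size=n_bg, replace=False)
            pairs = core_pairs + [background[j] for j in bg_idx]
            weights = _weights(rng, len(pairs), spec)
            weights[:len(core_pairs)] = (
                np.abs(weights[:len(core_pairs)]) * core_signs)
        else:
            bg_idx = rng.choice(len(background), size=m, replace=False)
            pairs = [background[j] for j in bg_idx]
            weights = _weights(rng, len(pairs), spec)
        networks.append(_network(f"{spec.label}_{i:02d}", taxa, pairs,
                                 weights, spec.signed))
    group = NetworkGroup(label=spec.label, networks=networks,
                         ordered=spec.trend is not None)
    core_keys = {edge_key(a, b, weight=s, signed=spec.signed)
                 for (a, b), s in zip(core_pairs, core_signs)}
    return group, CoreAssignment(core_edges=core_keys,
                                 carrier_indices=carriers)


def generate_hub_group(spec: SyntheticSpec) -> NetworkGroup:
    """Group whose designated hub taxa hold a fixed high degree in every
    network; all remaining edges are random among non-hub pairs."""
    spec.validate()
    if spec.hub_fraction <= 0:
        group, _ = generate_group(spec)
        return group
    rng = np.random.default_rng(spec.seed)
    taxa = _taxa(spec)
    n_hubs = math.ceil(spec.hub_fraction * spec.n_taxa)
    hubs = taxa[:n_hubs]
    others = taxa[n_hubs:]
    hub_degree = spec.hub_degree
    if hub_degree is None:
        hub_degree = math.ceil(0.5 * spec.n_taxa)
    if hub_degree > spec.n_taxa - 1:
        raise ValueError(f"hub degree {hub_degree} exceeds the "
                         f"{spec.n_taxa - 1} available partners")
    counts = spec.edge_counts()
    non_hub_pairs = list(combinations(others, 2))
    networks: List[Network] = []
    for i in range(spec.n_networks):
        m = counts[i]
        pairs: List[Tuple[str, str]] = []
        seen: Set[Tuple[str, str]] = set()
        for hub in hubs:
            partners = [t for t in taxa if t != hub]
            chosen = rng.choice(len(partners), size=hub_degree, replace=False)
            for j in chosen:
                pair = tuple(sorted((hub, partners[j])))
                if pair not in seen:
                    seen.add(pair)
                    pairs.append(pair)
        if len(pairs) > m:
            raise ValueError(
                f"hub edges ({len(pairs)}) exceed the edge budget {m}")
        n_bg = m - len(pairs)
        pool = [p for p in non_hub_pairs if p not in seen]
        if n_bg > len(pool):
            raise ValueError("not enough non-hub pairs for the edge budget")
        bg_idx = rng.choice(len(pool), size=n_bg, replace=False)
        pairs.extend(pool[j] for j in bg_idx)
        weights = _weights(rng, len(pairs), spec)
        networks.append(_network(f"{spec.label}_{i:02d}", taxa, pairs,
                                 weights, spec.signed))
    return NetworkGroup(label=spec.label, networks=networks)


def generate_ordered_group(spec: SyntheticSpec) -> NetworkGroup:
    """Ordered group whose edge count (hence density) follows a strict
    monotone trend along the group order."""
    if spec.trend not in ("increasing", "decreasing", "flat"):
        raise ValueError("trend must be 'increasing', 'decreasing' or 'flat'")
    if spec.trend != "flat" and isinstance(spec.edges_per_network, int):
        raise ValueError("a monotone trend needs an (lo, hi) edge range")
    group, _ = generate_group(spec)
    group.ordered = True
    return group
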