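"""Core containers: canonical edge keys, weighted undirected networks, and
groups of networks sharing a taxon namespace.

An association network is an undirected graph whose edges are statistically
inferred co-occurrence relationships between taxa.  Edge identity throughout
the package is the *unordered* taxon pair; weights never participate in
matching.  An optional sign mode additionally qualifies each edge with the
arithmetic sign of its weight, so that a positive and a negative association
between the same pair count as different edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Set, Tuple

logger = logging.getLogger("nullnet")

POSITIVE = "+"
NEGATIVE = "-"


class EdgeKey(NamedTuple):
    """Canonical unordered taxon pair, optionally sign-qualified.

    Invariants: ``taxon_a < taxon_b`` lexicographically, ``taxon_a != taxon_b``
    (no self-loops).  ``sign`` is ``None`` in sign-insensitive mode, else one
    of ``"+"`` / ``"-"``.
    """

    taxon_a: str
    taxon_b: str
    sign: Optional[str] = None

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.taxon_a, self.taxon_b)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        s = f"[{self.sign}]" if self.sign else ""
        return f"{self.taxon_a}--{self.taxon_b}{s}"


def edge_key(a: str, b: str, weight: Optional[float] = None,
             signed: bool = False) -> EdgeKey:
    """Build a canonical :class:`EdgeKey` from two endpoints.

    In signed mode the sign is derived from the arithmetic sign of *weight*;
    a zero weight is fatal because its sign is undefined.
    """
    a, b = str(a), str(b)
    if a == b:
        raise ValueError(f"self-loop edge ({a}, {b}) is not allowed")
    if a > b:
        a, b = b, a
    sign = None
    if signed:
        if weight is None:
            raise ValueError("signed edge keys require a weight")
        if weight == 0:
            raise ValueError(
                f"zero-weight edge ({a}, {b}): sign undefined in sign mode")
        sign = POSITIVE if weight > 0 else NEGATIVE
    return EdgeKey(a, b, sign)


@dataclass
class Network:
    """One observed or randomized association network.

    ``nodes`` may contain taxa with no incident edge (orphan nodes: taxa
    included in the input without significant associations).  ``edges`` maps
    canonical :class:`EdgeKey` to a nonzero real weight; at most one edge per
    unordered pair.
    """

    name: str
    nodes: Set[str]
    edges: Dict[EdgeKey, float] = field(default_factory=dict)
    signed: bool = False

    def validate(self) -> None:
        seen_pairs: Set[Tuple[str, str]] = set()
        for key, weight in self.edges.items():
            if key.taxon_a >= key.taxon_b:
                raise ValueError(f"non-canonical edge key {key}")
            if key.taxon_a not in self.nodes or key.taxon_b not in self.nodes:
                raise ValueError(f"edge {key} has endpoint outside node set")
            if key.pair in seen_pairs:
                raise ValueError(f"duplicate unordered pair {key.pair}")
            seen_pairs.add(key.pair)
            if weight == 0:
                raise ValueError(f"zero weight on edge {key}")
            if self.signed and key.sign is None:
                raise ValueError(f"unsigned key {key} in signed network")
            if not self.signed and key.sign is not None:
                raise ValueError(f"signed key {key} in unsigned network")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> Set[EdgeKey]:
        return set(self.edges)

    def degrees(self) -> Dict[str, int]:
        """Degree of every node, orphans included with degree 0."""
        deg = {v: 0 for v in self.nodes}
        for key in self.edges:
            deg[key.taxon_a] += 1
            deg[key.taxon_b] += 1
        return deg

    def orphans(self) -> Set[str]:
        connected = set()
        for key in self.edges:
            connected.add(key.taxon_a)
            connected.add(key.taxon_b)
        return self.nodes - connected

    def strip_orphans(self) -> None:
        self.nodes -= self.orphans()

    def copy(self, name: Optional[str] = None) -> "Network":
        return Network(name=name or self.name, nodes=set(self.nodes),
                       edges=dict(self.edges), signed=self.signed)

    def to_networkx(self, include_orphans: bool = True):
        """Convert to an undirected :mod:`networkx` graph with a ``weight``
        edge attribute.  Sign qualification is dropped (it is recoverable
        from the weight's sign)."""
        import networkx as nx

        g = nx.Graph()
        if include_orphans:
            g.add_nodes_from(sorted(self.nodes))
        for key, weight in sorted(self.edges.items()):
            g.add_edge(key.taxon_a, key.taxon_b, weight=float(weight))
        return g


@dataclass
class NetworkGroup:
    """An ordered collection of networks sharing a taxon namespace.

    When ``ordered`` is true, list position is the gradient rank used for
    Spearman correlations of network properties against the ordering.
    """

    label: str
    networks: List[Network]
    ordered: bool = False

    @property
    def n(self) -> int:
        return len(self.networks)

    @property
    def signed(self) -> bool:
        return bool(self.networks) and self.networks[0].signed

    def edge_sets(self) -> List[Set[EdgeKey]]:
        return [net.edge_set() for net in self.networks]

    def node_union(self) -> Set[str]:
        out: Set[str] = set()
        for net in self.networks:
            out |= net.nodes
        return out

    def edge_union(self) -> Set[EdgeKey]:
        out: Set[EdgeKey] = set()
        for net in self.networks:
            out |= net.edge_set()
        return out

    def require_comparable(self) -> None:
        if self.n < 2:
            raise ValueError(
                f"group '{self.label}' has {self.n} networks; "
                "comparisons require at least 2")

    def subset(self, indices: Sequence[int], label: Optional[str] = None
               ) -> "NetworkGroup":
        return NetworkGroup(label=label or self.label,
                            networks=[self.networks[i] for i in indices],
                            ordered=self.ordered)
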