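"""Node centralities and whole-network properties.

Centralities (degree, shortest-path betweenness, closeness) use the
NetworkX implementations and are reported together with their
average-tied rank within each network, because ranks — not raw scores —
are what the cross-network comparisons consume.  Edge weights are ignored
throughout: association weights are correlation-like quantities, not
distances, so weighted shortest paths would be meaningless.

Whole-network properties: degree assortativity, connectivity (average
node connectivity by default, edge connectivity behind a flag), diameter,
radius and average shortest path length.  Path-based properties of a
disconnected graph are computed on the largest connected component and
flagged in ``component_note``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .network import Network, NetworkGroup

logger = logging.getLogger("nullnet")

CENTRALITY_METRICS = ("degree", "betweenness", "closeness")
GRAPH_PROPERTIES = ("assortativity", "connectivity", "diameter", "radius",
                    "avg_shortest_path")


@dataclass
class CentralityRecord:
    """Centrality score and within-network rank for one connected node.
    Higher value -> higher rank; ties get average ranks."""

    network: str
    node: str
    metric: str
    value: float
    rank: float


@dataclass
class GraphPropertyRecord:
    network: str
    property: str
    value: float  # NaN when undefined
    component_note: str = ""


def _connected_subgraph(network: Network):
    """NetworkX view of the connected part only (orphans excluded)."""
    g = network.to_networkx(include_orphans=False)
    return g


def centralities(network: Network, metric: str) -> List[CentralityRecord]:
    """Centrality records for every connected node of *network*.

    Orphan nodes are excluded from scoring and ranking: a taxon with no
    associations carries no information about relative importance.
    Betweenness is normalized by (N-1)(N-2)/2; closeness is the classic
    per-component closeness scaled by the component's size fraction
    (Wasserman–Faust), so nodes in small fragments do not outscore nodes
    in the giant component.
    """
    if metric not in CENTRALITY_METRICS:
        raise ValueError(f"metric must be one of {CENTRALITY_METRICS}")
    g = _connected_subgraph(network)
    if g.number_of_nodes() == 0:
        return []
    if metric == "degree":
        values = {v: float(d) for v, d in g.degree()}
    elif metric == "betweenness":
        values = nx.betweenness_centrality(g, normalized=True)
    else:
        values = nx.closeness_centrality(g, wf_improved=True)
    nodes = sorted(values)
    scores = np.array([values[v] for v in nodes], dtype=float)
    ranks = rankdata(scores, method="average")
    return [CentralityRecord(network=network.name, node=v, metric=metric,
                             value=float(s), rank=float(r))
            for v, s, r in zip(nodes, scores, ranks)]


def centrality_rank_table(group: NetworkGroup, metric: str
                          ) -> Dict[str, List[float]]:
    """Per-node list of ranks across the group's networks.

    A node absent (or orphaned) in a network contributes no rank for that
    network, rather than a rank of 0.
    """
    table: Dict[str, List[float]] = {}
    for net in group.networks:
        for rec in centralities(net, metric):
            table.setdefault(rec.node, []).append(rec.rank)
    return table


def _largest_component(g):
    if g.number_of_nodes() == 0:
        return g, ""
    if nx.is_connected(g):
        return g, ""
    comp = max(nx.connected_components(g), key=len)
    note = (f"computed on largest connected component "
            f"({len(comp)}/{g.number_of_nodes()} nodes)")
    return g.subgraph(comp), note


def graph_property(network: Network, property: str,
                   connectivity_variant: str = "node") -> GraphPropertyRecord:
    """One whole-network property of *network*.

    Undefined values (no edges; assortativity of a constant-degree graph)
    are recorded as NaN with an explanatory note rather than raised.
    """
    if property not in GRAPH_PROPERTIES:
        raise ValueError(f"property must be one of {GRAPH_PROPERTIES}")
    g = _connected_subgraph(network)
    if g.number_of_edges() == 0:
        return GraphPropertyRecord(network=network.name, property=property,
                                   value=float("nan"),
                                   component_note="no edges; value undefined")
    if property == "assortativity":
        degrees = {d for _, d in g.degree()}
        if len(degrees) == 1:
            return GraphPropertyRecord(
                network=network.name, property=property, value=float("nan"),
                component_note="assortativity undefined (constant degree)")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            value = float(nx.degree_assortativity_coefficient(g))
        note = "" if np.isfinite(value) else "assortativity undefined"
        return GraphPropertyRecord(network=network.name, property=property,
                                   value=value, component_note=note)
    sub, note = _largest_component(g)
    if property == "connectivity":
        if connectivity_variant == "edge":
            value = float(nx.edge_connectivity(sub))
        else:
            value = float(nx.average_node_connectivity(sub))
        return GraphPropertyRecord(network=network.name, property=property,
                                   value=value, component_note=note)
    if property == "diameter":
        value = float(nx.diameter(sub))
    elif property == "radius":
        value = float(nx.radius(sub))
    else:
        value = float(nx.average_shortest_path_length(sub))
    return GraphPropertyRecord(network=network.name, property=property,
                               value=value, component_note=note)


def group_properties(group: NetworkGroup, property: str,
                     connectivity_variant: str = "node"
                     ) -> List[GraphPropertyRecord]:
    return [graph_property(net, property,
                           connectivity_variant=connectivity_variant)
            for net in group.networks]
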