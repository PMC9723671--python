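"""Reading and writing networks and result tables.

Two input formats are supported: GraphML (undirected, numeric ``weight``
edge attribute, missing weight defaults to 1.0) and tab-delimited edge
lists with a ``source<TAB>target<TAB>weight`` header.  All result tables
are exported tab-delimited with ``.`` as the decimal separator.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
import os
from typing import Dict, Iterable, List, Optional, Sequence, Set

import networkx as nx
import pandas as pd

from .network import EdgeKey, Network, NetworkGroup, edge_key

logger = logging.getLogger("nullnet")

FORMATS = ("graphml", "edgelist_tsv")


def _canonical_insert(nodes: Set[str], edges: Dict[EdgeKey, float],
                      pairs_seen: Dict, a: str, b: str, weight: float,
                      signed: bool, origin: str) -> None:
    """Insert one raw edge row, enforcing canonicalization rules.

    Self-loops are dropped with a warning; the first occurrence of a
    duplicate unordered pair wins (warning logged); zero weights are fatal
    only in sign mode, where the sign would be undefined.
    """
    if a == b:
        logger.warning("%s: dropping self-loop on node '%s'", origin, a)
        return
    if signed and weight == 0:
        raise ValueError(
            f"{origin}: zero-weight edge ({a}, {b}) — sign undefined")
    if weight == 0:
        raise ValueError(f"{origin}: zero-weight edge ({a}, {b})")
    pair = tuple(sorted((a, b)))
    if pair in pairs_seen:
        logger.warning("%s: duplicate undirected pair %s, keeping first "
                       "occurrence", origin, pair)
        return
    key = edge_key(a, b, weight=weight, signed=signed)
    pairs_seen[pair] = key
    edges[key] = float(weight)
    nodes.add(pair[0])
    nodes.add(pair[1])


def read_network(path: str, format: Optional[str] = None,
                 sign_mode: bool = False, name: Optional[str] = None
                 ) -> Network:
    """Read a single network from *path*.

    ``format`` is ``"graphml"`` or ``"edgelist_tsv"``; when omitted it is
    inferred from the file extension.  With ``sign_mode`` each edge key is
    qualified by the arithmetic sign of its weight.
    """
    if format is None:
        format = "graphml" if str(path).endswith(".graphml") else "edgelist_tsv"
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"network file not found: {path}")
    name = name or os.path.splitext(os.path.basename(path))[0]
    nodes: Set[str] = set()
    edges: Dict[EdgeKey, float] = {}
    pairs_seen: Dict = {}
    if format == "graphml":
        try:
            graph = nx.read_graphml(path)
        except Exception as exc:  # noqa: BLE001 - re-raise with path context
            raise ValueError(f"could not parse GraphML file {path}: {exc}") from exc
        for node in graph.nodes:
            nodes.add(str(node))
        for a, b, data in graph.edges(data=True):
            weight = data.get("weight", 1.0)
            try:
                weight = float(weight)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: non-numeric weight on edge ({a}, {b})") from exc
            _canonical_insert(nodes, edges, pairs_seen, str(a), str(b),
                              weight, sign_mode, str(path))
    else:
        with open(path, newline="", encoding="utf-8") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            required = {"source", "target", "weight"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(
                    f"{path}: edge list needs header columns source, target, "
                    f"weight (found {reader.fieldnames})")
            for row in reader:
                try:
                    weight = float(row["weight"])
                except (TypeError, ValueError) as exc:
                    raise ValueError(
                        f"{path}: non-numeric weight {row['weight']!r}") from exc
                _canonical_insert(nodes, edges, pairs_seen, row["source"],
                                  row["target"], weight, sign_mode, str(path))
    net = Network(name=name, nodes=nodes, edges=edges, signed=sign_mode)
    net.validate()
    return net


def read_group(paths: Sequence[str], label: str, ordered: bool = False,
               strip_orphans: bool = False, sign_mode: bool = False,
               format: Optional[str] = None) -> NetworkGroup:
    """Load an ordered group of networks from *paths*.

    With ``strip_orphans`` every degree-0 node is removed from each
    network's node set; orphan inclusion changes the fully random null
    (associations drawn from all taxa) and can overestimate core
    significance, so stripping is a common analysis choice.
    """
    if len(paths) < 2:
        raise ValueError(
            f"group '{label}' needs at least 2 networks, got {len(paths)}")
    networks = [read_network(p, format=format, sign_mode=sign_mode)
                for p in paths]
    if strip_orphans:
        for net in networks:
            net.strip_orphans()
    return NetworkGroup(label=label, networks=networks, ordered=ordered)


def write_network(network: Network, path: str,
                  format: Optional[str] = None) -> None:
    """Write *network* to *path*; round-trip safe up to canonical ordering."""
    if format is None:
        format = "graphml" if str(path).endswith(".graphml") else "edgelist_tsv"
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "graphml":
        nx.write_graphml(network.to_networkx(include_orphans=True), path)
        return
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target", "weight"])
        for key in sorted(network.edges):
            writer.writerow([key.taxon_a, key.taxon_b,
                             repr(float(network.edges[key]))])
    orphans = network.orphans()
    if orphans:
        logger.warning(
            "write_network(%s): %d orphan nodes cannot be represented in an "
            "edge list and were dropped; use GraphML to keep them",
            path, len(orphans))


def export_table(records: Sequence, path: str,
                 metadata: Optional[Dict[str, object]] = None,
                 columns: Optional[Sequence[str]] = None) -> None:
    """Export homogeneous result records as a tab-delimited UTF-8 file.

    Writes optional ``# key=value`` provenance lines, then a header row and
    one row per record.  Floats keep at least 6 significant digits and
    re-parse exactly under the "." decimal convention.  *columns* supplies
    the header when *records* is empty (header-only file).
    """
    frame = records_to_frame(records, columns=columns)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        for key, value in (metadata or {}).items():
            handle.write(f"# {key}={value}\n")
        frame.to_csv(handle, sep="\t", index=False, float_format="%.8g",
                     lineterminator="\n")


def records_to_frame(records: Sequence,
                     columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Convert a list of result dataclasses to a DataFrame; *columns* names
    the header for an empty list."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = [dataclasses.asdict(r) for r in records]
    if rows:
        types = {type(r) for r in records}
        if len(types) > 1:
            raise ValueError(f"heterogeneous record types: {types}")
        return pd.DataFrame(rows)
    return pd.DataFrame(rows, columns=list(columns) if columns else None)


def record_columns(record_type) -> List[str]:
    """Column names of a result dataclass, in declaration order."""
    return [f.name for f in dataclasses.fields(record_type)]
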