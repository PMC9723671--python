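"""Edge-set algebra over groups of networks.

For a group of n edge sets E_1..E_n the toolbox works with:

* the **k-intersection** — edges present in at least k networks (k = 1 is
  the union, k = n the full intersection);
* the **unique difference** — edges present in exactly one network;
* the **difference of intersections** k→m — edges present in at least k
  but fewer than m networks (k < m), isolating one band of conservation.

All three reduce to per-edge prevalence counting: the identity of the
networks containing an edge is irrelevant, only their number matters.  A
core association network (CAN) is the subgraph spanned by such a set.

Thresholds may be given as integer counts or as fractions of n; fractions
convert with a ceiling, so the 0.5-intersection of 20 networks means
"present in at least 10 networks".
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .network import EdgeKey, Network, NetworkGroup

logger = logging.getLogger("nullnet")

SET_KINDS = ("intersection", "difference", "diff_of_intersections")

Threshold = Union[int, float]


def resolve_threshold(value: Threshold, n: int) -> int:
    """Convert a threshold to an integer count of networks.

    Python ints are taken as counts; floats are fractions of n converted
    with a ceiling (so 0.5 of 20 networks -> 10).  A float above 1 is
    rejected to avoid silently mixing the two conventions.
    """
    if isinstance(value, float):
        if not 0.0 < value <= 1.0:
            raise ValueError(
                f"fractional threshold {value} must lie in (0, 1]")
        return math.ceil(value * n)
    return int(value)


@dataclass(frozen=True)
class SetDefinition:
    """One set of the algebra: kind plus threshold(s), count or fraction.

    For ``diff_of_intersections`` both ``k`` and ``m`` are required with
    k < m after conversion; m = n + 1 means "no upper removal".
    """

    kind: str
    k: Optional[Threshold] = None
    m: Optional[Threshold] = None

    def __post_init__(self) -> None:
        if self.kind not in SET_KINDS:
            raise ValueError(f"kind must be one of {SET_KINDS}")
        if self.kind == "intersection" and self.k is None:
            raise ValueError("intersection requires k")
        if self.kind == "diff_of_intersections" and (self.k is None or self.m is None):
            raise ValueError("diff_of_intersections requires k and m")

    def resolve(self, n: int) -> Tuple[Optional[int], Optional[int]]:
        """Concrete (k, m) counts for a group of *n* networks."""
        if self.kind == "difference":
            return None, None
        k = resolve_threshold(self.k, n)
        if not 1 <= k <= n:
            raise ValueError(f"k={k} out of range 1..{n}")
        if self.kind == "intersection":
            return k, None
        m = resolve_threshold(self.m, n)
        if not k < m <= n + 1:
            raise ValueError(
                f"diff_of_intersections needs k < m <= n+1, got k={k}, m={m}")
        return k, m

    @property
    def label(self) -> str:
        if self.kind == "difference":
            return "difference"
        if self.kind == "intersection":
            return f"intersection_{self.k}"
        return f"{self.k}->{self.m}"


@dataclass
class SetSizeRecord:
    """Size of one set in one (observed or replicate) group.

    ``replicate`` is 0 for the observed group; ``subset_size`` is only set
    by the resampling curve, where it is the number of networks drawn.
    """

    group: str
    source: str
    set_kind: str
    k: Optional[Threshold]
    m: Optional[Threshold]
    subset_size: Optional[int]
    replicate: int
    size: int


def edge_prevalence(group: NetworkGroup) -> Dict[EdgeKey, int]:
    """Number of networks containing each edge of the union (1..n)."""
    if group.n == 0:
        raise ValueError("empty group")
    counts: Counter = Counter()
    for edges in group.edge_sets():
        counts.update(edges)
    return dict(counts)


def k_intersection(group: NetworkGroup, k: Threshold) -> Set[EdgeKey]:
    """Edges present in at least k networks; k=1 is the union, k=n the
    full intersection."""
    kk = resolve_threshold(k, group.n)
    if not 1 <= kk <= group.n:
        raise ValueError(f"k={kk} out of range 1..{group.n}")
    return {e for e, c in edge_prevalence(group).items() if c >= kk}


def unique_difference(group: NetworkGroup) -> Set[EdgeKey]:
    """Edges present in exactly one network of the group."""
    group.require_comparable()
    return {e for e, c in edge_prevalence(group).items() if c == 1}


def diff_of_intersections(group: NetworkGroup, k: Threshold,
                          m: Threshold) -> Set[EdgeKey]:
    """k-intersection minus m-intersection: edges in at least k but fewer
    than m networks (k < m; m = n+1 removes nothing)."""
    kk = resolve_threshold(k, group.n)
    mm = resolve_threshold(m, group.n)
    if kk >= mm:
        raise ValueError(f"diff_of_intersections requires k < m, got "
                         f"k={kk}, m={mm}")
    if not 1 <= kk <= group.n or mm > group.n + 1:
        raise ValueError(f"thresholds k={kk}, m={mm} out of range for "
                         f"n={group.n}")
    return {e for e, c in edge_prevalence(group).items() if kk <= c < mm}


def compute_set(group: NetworkGroup, definition: SetDefinition
                ) -> Set[EdgeKey]:
    if definition.kind == "difference":
        return unique_difference(group)
    if definition.kind == "intersection":
        return k_intersection(group, definition.k)
    return diff_of_intersections(group, definition.k, definition.m)


def set_sizes(groups: Sequence[NetworkGroup],
              definitions: Sequence[SetDefinition],
              source: str = "observed",
              group_label: Optional[str] = None) -> List[SetSizeRecord]:
    """Set sizes for a sequence of groups sharing n (observed group first,
    replicate groups after); one record per (group, definition)."""
    records: List[SetSizeRecord] = []
    ns = {g.n for g in groups}
    if len(ns) > 1:
        raise ValueError(f"groups differ in size: {sorted(ns)}")
    for index, group in enumerate(groups):
        label = group_label or group.label
        for definition in definitions:
            records.append(SetSizeRecord(
                group=label, source=source, set_kind=definition.kind,
                k=definition.k, m=definition.m, subset_size=None,
                replicate=index, size=len(compute_set(group, definition))))
    return records


def resampling_curve(group: NetworkGroup,
                     definitions: Sequence[SetDefinition],
                     n_resamples: int, seed=None,
                     source: str = "observed") -> List[SetSizeRecord]:
    """Rarefaction of set sizes over the number of networks.

    Each resample draws a random permutation of the group's networks; the
    subset of size s is its first s elements, for s = 2..n.  Nesting the
    subsets within a resample makes the union curve non-decreasing and the
    full-intersection curve non-increasing draw by draw, not merely on
    average.  Flattening of the curve suggests enough networks have been
    collected to see every edge at the target prevalence.
    """
    group.require_comparable()
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    records: List[SetSizeRecord] = []
    for r in range(n_resamples):
        order = rng.permutation(group.n)
        for s in range(2, group.n + 1):
            sub = group.subset([int(i) for i in order[:s]])
            for definition in definitions:
                # integer thresholds above the subset size are infeasible
                # at this depth of the curve and contribute no point
                if definition.kind != "difference":
                    k = resolve_threshold(definition.k, s)
                    if k > s:
                        continue
                    if definition.kind == "diff_of_intersections":
                        m = min(resolve_threshold(definition.m, s), s + 1)
                        if m <= k:
                            continue
                        size = len(diff_of_intersections(sub, k, m))
                    else:
                        size = len(k_intersection(sub, k))
                else:
                    size = len(unique_difference(sub))
                records.append(SetSizeRecord(
                    group=group.label, source=source,
                    set_kind=definition.kind, k=definition.k,
                    m=definition.m, subset_size=s, replicate=r,
                    size=size))
    return records


def resampling_summary(records: Sequence[SetSizeRecord]):
    """Per subset-size mean and standard error of the resampled sizes."""
    import pandas as pd

    from .io import records_to_frame

    frame = records_to_frame(records)
    grouped = frame.groupby(
        ["group", "source", "set_kind", "k", "m", "subset_size"],
        dropna=False, sort=True)["size"]
    out = grouped.agg(mean_size="mean", se_size="sem",
                      n_resamples="count").reset_index()
    return out


def extract_can(group: NetworkGroup, k: Threshold,
                name: str = "CAN") -> Network:
    """Build the core association network at threshold k.

    Edges are the k-intersection; each edge's weight is the arithmetic
    mean of its weights over the networks containing it; nodes are the
    edge endpoints only.
    """
    edges = k_intersection(group, k)
    if not edges:
        logger.warning("group '%s': CAN at k=%s is empty", group.label, k)
    weights: Dict[EdgeKey, float] = {}
    for key in edges:
        values = [net.edges[key] for net in group.networks
                  if key in net.edges]
        weights[key] = float(np.mean(values))
    nodes: Set[str] = set()
    for key in edges:
        nodes.add(key.taxon_a)
        nodes.add(key.taxon_b)
    return Network(name=name, nodes=nodes, edges=weights,
                   signed=group.signed)


def shared_node_count(group: NetworkGroup) -> int:
    """Descriptive count of node identifiers present in every network; the
    set algebra applies to edges only, so no significance test is attached."""
    nets = group.networks
    if not nets:
        return 0
    shared = set(nets[0].nodes)
    for net in nets[1:]:
        shared &= net.nodes
    return len(shared)
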