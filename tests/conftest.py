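"""Shared fixtures: hand-built toy groups and random network factories."""

import logging

import numpy as np
import pytest

from nullnet import Network, NetworkGroup, edge_key


@pytest.fixture(autouse=True)
def _propagate_logging(caplog):
    # record package warnings for tests asserting on the log
    caplog.set_level(logging.WARNING, logger="nullnet")
    yield


def build_network(name, pairs, weights=None, extra_nodes=(), signed=False):
    """Network from a list of (a, b) pairs; default weight 1.0."""
    if weights is None:
        weights = [1.0] * len(pairs)
    edges = {edge_key(a, b, weight=w, signed=signed): float(w)
             for (a, b), w in zip(pairs, weights)}
    nodes = set(extra_nodes)
    for a, b in pairs:
        nodes.add(a)
        nodes.add(b)
    return Network(name=name, nodes=nodes, edges=edges, signed=signed)


def random_network(rng, n_nodes, n_edges, name="net", signed=False):
    """Uniform random simple graph with signed weights."""
    from itertools import combinations

    nodes = [f"n{i:03d}" for i in range(n_nodes)]
    pairs = list(combinations(nodes, 2))
    idx = rng.choice(len(pairs), size=n_edges, replace=False)
    weights = rng.uniform(0.1, 1.0, size=n_edges)
    if signed:
        weights *= np.where(rng.random(n_edges) < 0.5, -1.0, 1.0)
    return build_network(name, [pairs[i] for i in idx], weights,
                         extra_nodes=nodes, signed=signed)


def random_group(rng, n_networks, n_nodes, max_edges, label="grp",
                 signed=False):
    nets = []
    cap = min(max_edges, n_nodes * (n_nodes - 1) // 2)
    for i in range(n_networks):
        m = int(rng.integers(1, cap + 1))
        nets.append(random_network(rng, n_nodes, m, name=f"{label}_{i}",
                                   signed=signed))
    return NetworkGroup(label=label, networks=nets)


@pytest.fixture
def toy_group():
    """Three networks with edge sets E1={ab,bc}, E2={ab,cd}, E3={ab,bc}:
    prevalences ab:3, bc:2, cd:1."""
    e1 = build_network("E1", [("a", "b"), ("b", "c")], [0.4, 1.0])
    e2 = build_network("E2", [("a", "b"), ("c", "d")], [0.6, 1.0])
    e3 = build_network("E3", [("a", "b"), ("b", "c")], [0.5, 1.0])
    return NetworkGroup(label="toy", networks=[e1, e2, e3])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
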