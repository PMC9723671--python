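"""Null-model randomizers: conservation laws, swaps, synthetic cores."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from nullnet import (NetworkGroup, NullModelSpec, edge_key,
                     generate_null_ensemble, randomize_degree,
                     randomize_degree_with_core, randomize_random,
                     randomize_random_with_core, sample_core,
                     sample_replicate_groups)

from conftest import build_network, random_group, random_network


class TestRandomizeRandom:
    def test_zero_edges(self):
        net = build_network("z", [], extra_nodes=["a", "b", "c"])
        rep = randomize_random(net, seed=0)
        assert rep.n_edges == 0 and rep.nodes == net.nodes

    def test_complete_graph_forced(self):
        pairs = list(itertools.combinations("abcd", 2))
        net = build_network("k4", pairs)
        rep = randomize_random(net, seed=0)
        assert rep.edge_set() == net.edge_set()

    def test_conservation_over_replicates(self, rng):
        net = random_network(rng, 10, 20)
        for seed in range(1000):
            rep = randomize_random(net, seed=seed)
            assert rep.n_edges == 20
            assert rep.nodes == net.nodes
            rep.validate()

    def test_too_many_edges_fatal(self):
        from nullnet import Network

        # 2 requested edges cannot fit among C(2,2)=1 node pair
        bad = Network("bad", nodes={"a", "b"},
                      edges={edge_key("a", "b"): 1.0,
                             edge_key("a", "c"): 1.0})
        with pytest.raises(ValueError, match="cannot be placed"):
            randomize_random(bad, seed=0)

    def test_uniformity_over_possible_edge_sets(self, rng):
        """Empirical distribution over the C(10,3)=120 possible 3-edge sets
        on 5 nodes is uniform within chi-squared tolerance at 12000 draws."""
        net = random_network(rng, 5, 3)
        counts = {}
        for seed in range(12000):
            rep = randomize_random(net, seed=seed)
            key = frozenset(k.pair for k in rep.edges)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 120
        stat, p = chisquare(list(counts.values()))
        assert p > 0.001

    def test_sign_frequencies_resampled(self, rng):
        net = random_network(rng, 12, 30, signed=True)
        src_neg = sum(1 for k in net.edges if k.sign == "-") / net.n_edges
        negs = []
        for seed in range(200):
            rep = randomize_random(net, seed=seed)
            negs.append(sum(1 for k in rep.edges if k.sign == "-")
                        / rep.n_edges)
        assert np.mean(negs) == pytest.approx(src_neg, abs=0.05)


class TestRandomizeDegree:
    def test_triangle_unchanged_with_warning(self, caplog):
        net = build_network("tri", list(itertools.combinations("abc", 2)))
        rep = randomize_degree(net, seed=0)
        assert rep.edge_set() == net.edge_set()
        assert "no valid degree-preserving swap" in caplog.text

    def test_four_cycle_swap_outcomes(self):
        """On the 4-cycle a-b-c-d-a the swap (a,b),(c,d)->(a,c),(b,d) maps
        between hamiltonian cycles; every replicate keeps all degrees 2 and
        is one of the three 2-regular simple graphs on 4 nodes."""
        cycle = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")]
        net = build_network("c4", cycle)
        valid = set()
        for perm in itertools.permutations("abcd"):
            edges = frozenset(tuple(sorted(p)) for p in
                              zip(perm, perm[1:] + perm[:1]))
            valid.add(edges)
        for seed in range(30):
            rep = randomize_degree(net, seed=seed)
            assert rep.degrees() == net.degrees()
            assert frozenset(k.pair for k in rep.edges) in valid

    def test_degree_sequence_preserved_100_inputs(self, rng):
        for _ in range(100):
            net = random_network(rng, 12, int(rng.integers(5, 30)))
            rep = randomize_degree(net, seed=int(rng.integers(2**31)))
            assert rep.degrees() == net.degrees()
            rep.validate()

    def test_mixing_changes_edges(self, rng):
        net = random_network(rng, 20, 40)
        rep = randomize_degree(net, seed=1)
        assert rep.edge_set() != net.edge_set()


class TestSampleCore:
    def test_arithmetic(self, rng):
        group = random_group(rng, 10, 8, 5)
        union = group.edge_union()
        core = sample_core(group, core_fraction=0.2, core_prevalence=0.5,
                           seed=0)
        assert len(core.core_edges) == math.ceil(0.2 * len(union))
        assert len(core.carrier_indices) == 5
        assert core.core_edges <= union

    def test_full_core(self, rng):
        group = random_group(rng, 4, 8, 5)
        core = sample_core(group, 1.0, 1.0, seed=0)
        assert core.core_edges == group.edge_union()
        assert core.carrier_indices == set(range(4))

    def test_ceiling_prevalence(self, rng):
        """10% prevalence of 20 networks means 2 carrier networks."""
        group = random_group(rng, 20, 8, 5)
        core = sample_core(group, 0.2, 0.1, seed=0)
        assert len(core.carrier_indices) == 2

    def test_empty_union_fatal(self):
        nets = [build_network(f"e{i}", [], extra_nodes=["a", "b"])
                for i in range(2)]
        with pytest.raises(ValueError, match="empty"):
            sample_core(NetworkGroup("e", nets), 0.5, 0.5, seed=0)


class TestRandomWithCore:
    def test_empty_core_matches_plain(self, rng):
        net = random_network(rng, 10, 15)
        assert (randomize_random_with_core(net, set(), seed=5).edge_set()
                == randomize_random(net, seed=5).edge_set())

    def test_core_present_and_count_kept(self, rng):
        net = random_network(rng, 15, 20)
        core = set(list(net.edge_set())[:2])
        rep = randomize_random_with_core(net, core, seed=3)
        assert core <= rep.edge_set()
        assert rep.n_edges == 20

    def test_core_equal_to_edge_count(self, rng):
        net = random_network(rng, 10, 6)
        core = net.edge_set()
        rep = randomize_random_with_core(net, core, seed=1)
        assert rep.edge_set() == core

    def test_oversized_core_fatal(self, rng):
        net = random_network(rng, 10, 3)
        big = random_network(rng, 10, 10).edge_set()
        with pytest.raises(ValueError, match="core"):
            randomize_random_with_core(net, big, seed=0)


class TestDegreeWithCore:
    def test_empty_core_matches_plain(self, rng):
        net = random_network(rng, 10, 15)
        rep, nfall = randomize_degree_with_core(net, set(), seed=5)
        assert nfall == 0
        assert rep.edge_set() == randomize_degree(net, seed=5).edge_set()

    def test_star_core_edge_needs_fallback(self):
        """Star z-{a..e} with core edge (a,b): no swap can create (a,b)
        while preserving degrees (exhaustively, both endpoints' only
        neighbour is z), so the delete-and-insert fallback must fire."""
        star = build_network("star", [("z", leaf) for leaf in "abcde"])
        core = {edge_key("a", "b")}
        rep, nfall = randomize_degree_with_core(star, core, seed=0)
        assert nfall == 1
        assert edge_key("a", "b") in rep.edge_set()
        assert rep.n_edges == star.n_edges

    def test_swap_path_preserves_degrees(self, rng):
        """With a small core on a dense network the targeted swap usually
        succeeds; whenever no fallback fired the degrees are exact."""
        exact = 0
        for seed in range(20):
            net = random_network(rng, 20, 60)
            core = set(list(random_network(rng, 20, 4).edge_set()))
            rep, nfall = randomize_degree_with_core(net, core, seed=seed)
            assert core <= rep.edge_set()
            assert rep.n_edges == net.n_edges
            if nfall == 0:
                assert rep.degrees() == net.degrees()
                exact += 1
        assert exact > 0

    def test_absent_endpoints_skipped(self, rng, caplog):
        net = random_network(rng, 8, 10)
        core = {edge_key("missing1", "missing2")}
        rep, _ = randomize_degree_with_core(net, core, seed=0)
        assert edge_key("missing1", "missing2") not in rep.edge_set()
        assert "skipped" in caplog.text


class TestEnsemble:
    def test_default_shapes(self, rng):
        group = random_group(rng, 5, 10, 12)
        spec = NullModelSpec(model="random", n_replicates=10, n_sets=50,
                             seed=1)
        ens = generate_null_ensemble(group, spec)
        assert len(ens.replicates) == 5
        assert all(len(reps) == 10 for reps in ens.replicates)
        assert len(ens.replicate_groups) == 50
        assert all(g.n == 5 for g in ens.replicate_groups)

    def test_single_replicate_groups_identical(self, rng):
        group = random_group(rng, 4, 10, 12)
        spec = NullModelSpec(model="random", n_replicates=1, n_sets=5, seed=1)
        ens = generate_null_ensemble(group, spec)
        first = [n.edge_set() for n in ens.replicate_groups[0].networks]
        for g in ens.replicate_groups[1:]:
            assert [n.edge_set() for n in g.networks] == first

    def test_carriers_receive_core_in_every_replicate(self, rng):
        group = NetworkGroup("fixed", [
            random_network(rng, 12, 20, name=f"f{i}") for i in range(6)])
        spec = NullModelSpec(model="random", core_fraction=0.2,
                             core_prevalence=0.5, n_replicates=4, n_sets=5,
                             seed=2)
        ens = generate_null_ensemble(group, spec)
        assert len(ens.core.carrier_indices) == 3
        for i in ens.core.carrier_indices:
            placeable = {e for e in ens.core.core_edges
                         if e.taxon_a in group.networks[i].nodes
                         and e.taxon_b in group.networks[i].nodes}
            for rep in ens.replicates[i]:
                assert placeable <= rep.edge_set()

    def test_seeded_determinism(self, rng):
        group = random_group(rng, 4, 10, 12)
        spec = NullModelSpec(model="degree", n_replicates=3, n_sets=8, seed=9)
        e1 = generate_null_ensemble(group, spec)
        e2 = generate_null_ensemble(group, spec)
        for g1, g2 in zip(e1.replicate_groups, e2.replicate_groups):
            assert ([n.edge_set() for n in g1.networks]
                    == [n.edge_set() for n in g2.networks])

    def test_invalid_spec(self):
        with pytest.raises(ValueError, match="core_prevalence"):
            NullModelSpec(model="random", core_fraction=0.5).validate()
        with pytest.raises(ValueError, match="model"):
            NullModelSpec(model="barabasi").validate()
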