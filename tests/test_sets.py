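"""Edge-set algebra: examples, brute-force oracle, invariants."""

import itertools
import math

import numpy as np
import pytest

from nullnet import (EdgeKey, NetworkGroup, SetDefinition, diff_of_intersections,
                     edge_prevalence, extract_can, k_intersection,
                     resampling_curve, resampling_summary, set_sizes,
                     unique_difference)
from nullnet.sets import resolve_threshold

from conftest import build_network, random_group

AB, BC, CD = EdgeKey("a", "b"), EdgeKey("b", "c"), EdgeKey("c", "d")


# ---------------------------------------------------------------------------
# independent oracles built from the set-theoretic definitions (unions of
# per-combination intersections), not from prevalence counting
# ---------------------------------------------------------------------------

def oracle_k_intersection(edge_sets, k):
    out = set()
    for combo in itertools.combinations(range(len(edge_sets)), k):
        inter = set(edge_sets[combo[0]])
        for i in combo[1:]:
            inter &= edge_sets[i]
        out |= inter
    return out


def oracle_unique_difference(edge_sets):
    out = set()
    for i, edges in enumerate(edge_sets):
        rest = set()
        for j, other in enumerate(edge_sets):
            if j != i:
                rest |= other
        out |= edges - rest
    return out


def oracle_diff_of_intersections(edge_sets, k, m):
    upper = (oracle_k_intersection(edge_sets, m)
             if m <= len(edge_sets) else set())
    return oracle_k_intersection(edge_sets, k) - upper


class TestToyExamples:
    def test_prevalence_counts(self, toy_group):
        assert edge_prevalence(toy_group) == {AB: 3, BC: 2, CD: 1}

    def test_identical_networks_prevalence(self):
        nets = [build_network(f"n{i}", [("a", "b"), ("b", "c")])
                for i in range(5)]
        group = NetworkGroup("id", nets)
        assert set(edge_prevalence(group).values()) == {5}

    def test_k_intersections(self, toy_group):
        assert k_intersection(toy_group, 1) == {AB, BC, CD}
        assert k_intersection(toy_group, 2) == {AB, BC}
        assert k_intersection(toy_group, 3) == {AB}
        with pytest.raises(ValueError):
            k_intersection(toy_group, 4)

    def test_unique_difference(self, toy_group):
        assert unique_difference(toy_group) == {CD}

    def test_unique_difference_disjoint_and_identical(self):
        disjoint = NetworkGroup("d", [build_network("1", [("a", "b")]),
                                      build_network("2", [("c", "d")])])
        assert unique_difference(disjoint) == {EdgeKey("a", "b"),
                                               EdgeKey("c", "d")}
        identical = NetworkGroup("i", [build_network(str(i), [("a", "b")])
                                       for i in range(3)])
        assert unique_difference(identical) == set()

    def test_diff_of_intersections(self, toy_group):
        assert diff_of_intersections(toy_group, 2, 3) == {BC}
        assert diff_of_intersections(toy_group, 1, 4) == {AB, BC, CD}
        with pytest.raises(ValueError, match="k < m"):
            diff_of_intersections(toy_group, 3, 2)

    def test_fraction_thresholds_use_ceiling(self):
        assert resolve_threshold(0.5, 20) == 10
        assert resolve_threshold(0.5, 3) == 2
        assert resolve_threshold(0.2, 10) == 2
        assert resolve_threshold(1.0, 7) == 7
        assert resolve_threshold(3, 20) == 3  # ints are counts


class TestOracleEquivalence:
    def test_exhaustive_small_groups(self, rng):
        """All four operations agree with the union-of-combination-
        intersections oracle on random groups with n <= 6, <= 15 nodes."""
        for trial in range(40):
            n = int(rng.integers(2, 7))
            group = random_group(rng, n, int(rng.integers(4, 16)), 12,
                                 label=f"o{trial}")
            sets = group.edge_sets()
            assert unique_difference(group) == oracle_unique_difference(sets)
            for k in range(1, n + 1):
                assert (k_intersection(group, k)
                        == oracle_k_intersection(sets, k))
                for m in range(k + 1, n + 2):
                    assert (diff_of_intersections(group, k, m)
                            == oracle_diff_of_intersections(sets, k, m))


class TestInvariants:
    def test_partition_identity(self, rng):
        """|prevalence=1| + sum of band sizes + |full intersection| covers
        the union exactly, over 100 random groups."""
        for trial in range(100):
            n = int(rng.integers(2, 11))
            group = random_group(rng, n, 10, 15, label=f"p{trial}")
            total = len(unique_difference(group))
            for k in range(2, n):
                total += len(diff_of_intersections(group, k, k + 1))
            if n >= 2:
                total += len(k_intersection(group, n))
            assert total == len(group.edge_union())

    def test_nesting(self, rng):
        group = random_group(rng, 6, 10, 15)
        for k in range(1, 6):
            assert k_intersection(group, k + 1) <= k_intersection(group, k)

    def test_order_permutation_invariance(self, rng):
        group = random_group(rng, 5, 10, 15)
        perm = NetworkGroup("perm", [group.networks[i]
                                     for i in (3, 1, 4, 0, 2)])
        assert edge_prevalence(group) == edge_prevalence(perm)
        assert unique_difference(group) == unique_difference(perm)
        for k in range(1, 6):
            assert k_intersection(group, k) == k_intersection(perm, k)


class TestSetSizes:
    def test_record_counts(self, rng):
        observed = random_group(rng, 4, 10, 12, label="obs")
        replicates = [random_group(rng, 4, 10, 12, label="rep")
                      for _ in range(50)]
        defs = [SetDefinition("difference"),
                SetDefinition("intersection", 2),
                SetDefinition("intersection", 0.5),
                SetDefinition("diff_of_intersections", 2, 4)]
        records = (set_sizes([observed], defs, source="observed")
                   + set_sizes(replicates, defs, source="random"))
        assert len(records) == 204
        assert records[0].source == "observed" and records[0].replicate == 0

    def test_empty_definitions(self, toy_group):
        assert set_sizes([toy_group], []) == []

    def test_sizes_non_increasing_in_k(self, rng):
        group = random_group(rng, 8, 10, 15)
        sizes = [len(k_intersection(group, k)) for k in range(1, 9)]
        assert sizes == sorted(sizes, reverse=True)


class TestResampling:
    def test_identical_networks_flat_curve(self):
        nets = [build_network(f"n{i}", [("a", "b"), ("b", "c"), ("c", "d")])
                for i in range(10)]
        group = NetworkGroup("id", nets)
        records = resampling_curve(group, [SetDefinition("intersection", 1.0)],
                                   n_resamples=5, seed=0)
        assert {r.size for r in records} == {3}
        summary = resampling_summary(records)
        assert (summary["mean_size"] == 3).all()
        assert (summary["se_size"].fillna(0) == 0).all()

    def test_union_monotone_per_draw(self, rng):
        group = random_group(rng, 8, 10, 15)
        records = resampling_curve(group, [SetDefinition("intersection", 1)],
                                   n_resamples=10, seed=1)
        by_draw = {}
        for rec in records:
            by_draw.setdefault(rec.replicate, []).append(
                (rec.subset_size, rec.size))
        for draws in by_draw.values():
            sizes = [s for _, s in sorted(draws)]
            assert sizes == sorted(sizes)

    def test_full_intersection_monotone_per_draw(self, rng):
        group = random_group(rng, 8, 10, 15)
        records = resampling_curve(group, [SetDefinition("intersection", 1.0)],
                                   n_resamples=10, seed=2)
        by_draw = {}
        for rec in records:
            by_draw.setdefault(rec.replicate, []).append(
                (rec.subset_size, rec.size))
        for draws in by_draw.values():
            sizes = [s for _, s in sorted(draws)]
            assert sizes == sorted(sizes, reverse=True)


class TestExtractCan:
    def test_toy_can(self, toy_group):
        can = extract_can(toy_group, 2, name="can")
        assert can.edge_set() == {AB, BC}
        assert can.nodes == {"a", "b", "c"}

    def test_weight_is_mean_of_contributors(self, toy_group):
        # ab has weights 0.4, 0.6, 0.5 over three networks
        can = extract_can(toy_group, 3)
        assert can.edges[AB] == pytest.approx(0.5)

    def test_two_network_mean(self):
        g = NetworkGroup("w", [build_network("1", [("a", "b")], [0.4]),
                               build_network("2", [("a", "b")], [0.6])])
        can = extract_can(g, 2)
        assert can.edges[AB] == pytest.approx(0.5)

    def test_empty_can_warns(self, toy_group, caplog):
        nets = [build_network("1", [("a", "b")]),
                build_network("2", [("c", "d")])]
        can = extract_can(NetworkGroup("dj", nets), 2)
        assert can.n_edges == 0
        assert "empty" in caplog.text
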