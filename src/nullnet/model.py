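"""Model/Results interface over the full comparison workflow.

:class:`GroupComparison` is built from an observed :class:`NetworkGroup`
plus the analysis configuration (set definitions, null-model settings,
synthetic-core specifications, centrality metrics, network properties);
``fit()`` generates the null ensembles, computes observed and null set
sizes, and runs every requested significance test, returning a
:class:`GroupComparisonResults` carrying the tables, a text ``summary()``
and tab-delimited export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as nio
from .metrics import (CENTRALITY_METRICS, GRAPH_PROPERTIES, CentralityRecord,
                      GraphPropertyRecord, centralities, group_properties)
from .network import NetworkGroup
from .nulls import (NullEnsemble, NullModelSpec, generate_null_ensemble)
from .sets import (SetDefinition, SetSizeRecord, extract_can,
                   resampling_curve, set_sizes, shared_node_count)
from .stats import (ComparisonResult, compare_centralities,
                    compare_graph_properties, compare_set_sizes,
                    ordered_correlation)

logger = logging.getLogger("nullnet")


def default_set_definitions(n: int) -> List[SetDefinition]:
    """Unique difference plus every integer intersection 2..n."""
    defs = [SetDefinition("difference")]
    defs.extend(SetDefinition("intersection", k) for k in range(2, n + 1))
    return defs


class GroupComparison:
    """Null-model comparison of one group of association networks.

    Parameters
    ----------
    group
        Observed networks sharing a taxon namespace (n >= 2).
    set_definitions
        Edge sets to size and test; defaults to the unique difference plus
        all integer intersections.
    n_replicates, n_sets
        Randomized networks per observed network (default 10) and sampled
        replicate groups per null model (default 50).
    core_specs
        ``(core_fraction, core_prevalence)`` pairs; each adds a
        positive-control variant of both null models.
    metrics, properties
        Node centralities and whole-network properties to compare; pass
        empty sequences to disable.
    alpha
        Level of the inner Mann–Whitney tests and the significance level
        reported by ``summary()``.
    n_resamples
        When > 0, compute the set-size rarefaction curve with this many
        resamples.
    """

    def __init__(self, group: NetworkGroup,
                 set_definitions: Optional[Sequence[SetDefinition]] = None,
                 n_replicates: int = 10, n_sets: int = 50,
                 core_specs: Sequence[Tuple[float, float]] = (),
                 metrics: Sequence[str] = CENTRALITY_METRICS,
                 properties: Sequence[str] = ("assortativity", "diameter",
                                              "radius", "avg_shortest_path"),
                 alpha: float = 0.05,
                 n_comparisons: Optional[int] = None,
                 n_resamples: int = 0,
                 swaps_per_edge: int = 10,
                 connectivity_variant: str = "node"):
        group.require_comparable()
        self.group = group
        self.set_definitions = (list(set_definitions)
                                if set_definitions is not None
                                else default_set_definitions(group.n))
        for definition in self.set_definitions:
            definition.resolve(group.n)  # fail fast on bad thresholds
        self.n_replicates = n_replicates
        self.n_sets = n_sets
        self.core_specs = list(core_specs)
        self.metrics = list(metrics)
        self.properties = list(properties)
        self.alpha = alpha
        self.n_comparisons = n_comparisons
        self.n_resamples = n_resamples
        self.swaps_per_edge = swaps_per_edge
        self.connectivity_variant = connectivity_variant

    @classmethod
    def from_files(cls, paths: Sequence[str], label: str,
                   ordered: bool = False, strip_orphans: bool = False,
                   sign_mode: bool = False, **kwargs) -> "GroupComparison":
        group = nio.read_group(paths, label=label, ordered=ordered,
                               strip_orphans=strip_orphans,
                               sign_mode=sign_mode)
        return cls(group, **kwargs)

    def _null_specs(self, seed: int) -> List[NullModelSpec]:
        specs = [NullModelSpec(model=m, n_replicates=self.n_replicates,
                               n_sets=self.n_sets, seed=seed + offset,
                               swaps_per_edge=self.swaps_per_edge)
                 for offset, m in enumerate(("random", "degree"))]
        offset = 2
        for fraction, prevalence in self.core_specs:
            for m in ("random", "degree"):
                specs.append(NullModelSpec(
                    model=m, core_fraction=fraction,
                    core_prevalence=prevalence,
                    n_replicates=self.n_replicates, n_sets=self.n_sets,
                    seed=seed + offset, swaps_per_edge=self.swaps_per_edge))
                offset += 1
        return specs

    def fit(self, seed: int = 0) -> "GroupComparisonResults":
        """Run the full analysis under a master seed."""
        group = self.group
        ensembles: Dict[str, NullEnsemble] = {}
        for spec in self._null_specs(seed):
            ensemble = generate_null_ensemble(group, spec)
            name = ensemble.source_name
            if name in ensembles:  # several core specs of the same model
                name = f"{name}_{spec.core_fraction}_{spec.core_prevalence}"
            ensembles[name] = ensemble

        observed_sizes = set_sizes([group], self.set_definitions,
                                   source="observed")
        null_sizes: Dict[str, List[SetSizeRecord]] = {}
        for name, ensemble in ensembles.items():
            null_sizes[name] = set_sizes(
                ensemble.replicate_groups, self.set_definitions,
                source=name, group_label=group.label)

        set_comparisons = compare_set_sizes(
            observed_sizes, {name: recs for name, recs in null_sizes.items()})

        negative_controls = {name: ens for name, ens in ensembles.items()
                             if ens.spec.core_fraction == 0}
        centrality_records: List[CentralityRecord] = []
        for metric in self.metrics:
            for net in group.networks:
                centrality_records.extend(centralities(net, metric))
        centrality_comparisons: List[ComparisonResult] = []
        for metric in self.metrics:
            for name, ensemble in negative_controls.items():
                centrality_comparisons.extend(compare_centralities(
                    group, ensemble.replicate_groups, metric,
                    alpha=self.alpha, n_comparisons=self.n_comparisons,
                    null_source=f"{name}/{metric}"))

        property_records: List[GraphPropertyRecord] = []
        property_comparisons: List[ComparisonResult] = []
        for prop in self.properties:
            property_records.extend(group_properties(
                group, prop, connectivity_variant=self.connectivity_variant))
            for name, ensemble in negative_controls.items():
                res = compare_graph_properties(
                    group, ensemble.replicate_groups, prop, null_source=name,
                    connectivity_variant=self.connectivity_variant)
                if res is not None:
                    property_comparisons.append(res)

        ordered_results: List[ComparisonResult] = []
        if group.ordered:
            for prop in self.properties:
                ordered_results.append(ordered_correlation(
                    group, prop,
                    connectivity_variant=self.connectivity_variant))

        resampling_records: List[SetSizeRecord] = []
        if self.n_resamples > 0:
            resampling_records = resampling_curve(
                group, self.set_definitions, self.n_resamples,
                seed=seed + 10_000)

        return GroupComparisonResults(
            model=self, seed=seed, ensembles=ensembles,
            observed_set_sizes=observed_sizes, null_set_sizes=null_sizes,
            set_comparisons=set_comparisons,
            centrality_records=centrality_records,
            centrality_comparisons=centrality_comparisons,
            property_records=property_records,
            property_comparisons=property_comparisons,
            ordered_results=ordered_results,
            resampling_records=resampling_records)


@dataclass
class GroupComparisonResults:
    """Fitted results: observed statistics, null distributions, tests."""

    model: GroupComparison
    seed: int
    ensembles: Dict[str, NullEnsemble]
    observed_set_sizes: List[SetSizeRecord]
    null_set_sizes: Dict[str, List[SetSizeRecord]]
    set_comparisons: List[ComparisonResult]
    centrality_records: List[CentralityRecord]
    centrality_comparisons: List[ComparisonResult]
    property_records: List[GraphPropertyRecord]
    property_comparisons: List[ComparisonResult]
    ordered_results: List[ComparisonResult]
    resampling_records: List[SetSizeRecord]

    # ----- tabular views -------------------------------------------------
    @property
    def set_size_table(self) -> pd.DataFrame:
        records = list(self.observed_set_sizes)
        for recs in self.null_set_sizes.values():
            records.extend(recs)
        return nio.records_to_frame(
            records, columns=nio.record_columns(SetSizeRecord))

    @property
    def comparison_table(self) -> pd.DataFrame:
        records = (list(self.set_comparisons)
                   + list(self.centrality_comparisons)
                   + list(self.property_comparisons)
                   + list(self.ordered_results))
        return nio.records_to_frame(
            records, columns=nio.record_columns(ComparisonResult))

    @property
    def centrality_table(self) -> pd.DataFrame:
        return nio.records_to_frame(
            self.centrality_records,
            columns=nio.record_columns(CentralityRecord))

    @property
    def property_table(self) -> pd.DataFrame:
        return nio.records_to_frame(
            self.property_records,
            columns=nio.record_columns(GraphPropertyRecord))

    @property
    def resampling_table(self) -> pd.DataFrame:
        return nio.records_to_frame(
            self.resampling_records,
            columns=nio.record_columns(SetSizeRecord))

    def can(self, k, name: Optional[str] = None):
        """Core association network of the observed group at threshold k."""
        return extract_can(self.model.group, k,
                           name=name or f"{self.model.group.label}_CAN_{k}")

    # ----- reporting -----------------------------------------------------
    def summary(self) -> str:
        group = self.model.group
        alpha = self.model.alpha
        lines = [
            "Null-model comparison of association networks",
            "=" * 46,
            f"group: {group.label}   networks: {group.n}   "
            f"taxa (union): {len(group.node_union())}   "
            f"edges (union): {len(group.edge_union())}",
            f"shared nodes (descriptive): {shared_node_count(group)}",
            f"null models: {', '.join(self.ensembles)}   "
            f"replicates/network: {self.model.n_replicates}   "
            f"replicate groups: {self.model.n_sets}",
            f"seed: {self.seed}",
            "",
            f"{'set':<20}{'source':<16}{'observed':>9}{'null mean':>11}"
            f"{'null sd':>9}{'z':>9}{'p':>11}{'p(BH)':>11}  normal",
            "-" * 100,
        ]
        for res in self.set_comparisons:
            lines.append(
                f"{res.entity:<20}{res.null_source:<16}"
                f"{res.observed:>9.4g}{res.null_mean:>11.4g}"
                f"{res.null_sd:>9.3g}{res.statistic:>9.3g}"
                f"{res.p_raw:>11.3g}{res.p_adjusted:>11.3g}"
                f"  {'yes' if res.normality_ok else 'no'}")
        sig_nodes = [r for r in self.centrality_comparisons
                     if np.isfinite(r.p_adjusted) and r.p_adjusted < alpha]
        if self.model.metrics:
            lines += ["", f"centrality comparisons: "
                          f"{len(self.centrality_comparisons)} node tests, "
                          f"{len(sig_nodes)} significant at "
                          f"BH-adjusted p < {alpha}"]
            for res in sig_nodes:
                lines.append(f"  {res.entity:<12}{res.null_source:<24}"
                             f"rejections={res.statistic:.2f}  "
                             f"p={res.p_raw:.4g}  p(BH)={res.p_adjusted:.4g}")
        for res in self.property_comparisons:
            lines.append(f"property {res.entity:<18}{res.null_source:<12}"
                         f"obs={res.observed:.4g} null={res.null_mean:.4g} "
                         f"z={res.statistic:.3g} p={res.p_raw:.4g}")
        for res in self.ordered_results:
            lines.append(f"order correlation {res.entity:<18}"
                         f"rho={res.statistic:.3g} p={res.p_raw:.4g} "
                         f"{res.note}")
        return "\n".join(lines)

    def save_tables(self, outdir: str, prefix: Optional[str] = None) -> List[str]:
        """Write all result tables as tab-delimited files; returns paths.

        Every table starts with ``# key=value`` provenance lines that
        include the master seed.
        """
        import os

        os.makedirs(outdir, exist_ok=True)
        prefix = prefix or self.model.group.label
        metadata = {"group": self.model.group.label, "seed": self.seed,
                    "n_networks": self.model.group.n,
                    "n_replicates": self.model.n_replicates,
                    "n_sets": self.model.n_sets}
        written = []

        def write(name: str, frame_or_records, columns=None):
            path = os.path.join(outdir, f"{prefix}_{name}.tsv")
            nio.export_table(frame_or_records, path, metadata=metadata,
                             columns=columns)
            written.append(path)

        write("setsizes", self.set_size_table)
        write("comparisons", self.comparison_table)
        if self.centrality_records or self.model.metrics:
            write("centralities", self.centrality_table)
        if self.property_records or self.model.properties:
            write("properties", self.property_table)
        if self.resampling_records:
            write("resampling", self.resampling_table)
        return written
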