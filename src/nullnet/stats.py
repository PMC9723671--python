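"""Significance machinery for observed-versus-null comparisons.

Set sizes and whole-network properties are tested with a Z-score test
against the null distribution formed by the replicate groups; the
D'Agostino–Pearson omnibus test gates the normality assumption and the
result is flagged when the null sample is too small for the gate (fewer
than 20 observations) or non-normal.

Node centralities are first rank-transformed within each network and then
compared with repeated two-sided Mann–Whitney U tests: the observed rank
sample of a node is tested against its rank sample in each replicate
group, and an add-one-smoothed parameter-free p-value is computed from
the number of rejections — p = (n_comparisons − successes + 1) /
(n_comparisons + 1), which can never reach exactly 0.
Benjamini–Hochberg correction is applied across taxa (and, for symmetry,
across set definitions and properties within a family).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .metrics import centrality_rank_table, group_properties
from .network import NetworkGroup
from .sets import SetDefinition, SetSizeRecord

logger = logging.getLogger("nullnet")

NORMALITY_MIN_N = 20


@dataclass
class ComparisonResult:
    """One observed-vs-null comparison row.

    ``statistic`` is the z score (set sizes, properties), the rejection
    fraction of the repeated Mann–Whitney tests (centralities), or
    Spearman's rho (ordered groups).
    """

    entity: str
    entity_kind: str  # "set" | "node" | "property"
    null_source: str
    observed: float
    null_mean: float
    null_sd: float
    statistic: float
    p_raw: float
    p_adjusted: float
    normality_ok: bool
    note: str = ""


def zscore_test(observed: float, null_values: Sequence[float],
                entity: str = "", entity_kind: str = "set",
                null_source: str = "") -> ComparisonResult:
    """Two-sided Z-score test of *observed* against a null sample.

    z = (observed − mean) / sd of the null values, with the two-sided p
    from the standard normal.  A zero-variance null is degenerate: p = 1
    if the observed value equals the constant, else p = 0.  The normality
    flag is false whenever fewer than 20 null values are available (the
    omnibus test is unreliable below that) or the omnibus test rejects at
    α = 0.05.
    """
    values = np.asarray(list(null_values), dtype=float)
    if values.size < 2:
        raise ValueError("zscore_test needs at least 2 null values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    note = ""
    normality_ok = False
    if values.size < NORMALITY_MIN_N:
        logger.warning(
            "null sample of %d set-size observations is below %d: the "
            "normality test is not reliable; increase the number of "
            "random network sets", values.size, NORMALITY_MIN_N)
        note = f"null sample < {NORMALITY_MIN_N}; normality not assessed"
    if sd == 0.0:
        p = 1.0 if observed == mean else 0.0
        z = 0.0 if observed == mean else math.copysign(math.inf,
                                                       observed - mean)
        note = (note + "; " if note else "") + "degenerate null (sd = 0)"
        return ComparisonResult(entity=entity, entity_kind=entity_kind,
                                null_source=null_source, observed=float(observed),
                                null_mean=mean, null_sd=sd, statistic=z,
                                p_raw=p, p_adjusted=float("nan"),
                                normality_ok=False, note=note)
    if values.size >= NORMALITY_MIN_N:
        try:
            _, p_norm = sps.normaltest(values)
            normality_ok = bool(p_norm > 0.05)
            if not normality_ok:
                note = "null sample fails omnibus normality test"
        except ValueError:
            normality_ok = False
            note = "normality test failed"
    z = (float(observed) - mean) / sd
    p = 2.0 * sps.norm.sf(abs(z))
    return ComparisonResult(entity=entity, entity_kind=entity_kind,
                            null_source=null_source, observed=float(observed),
                            null_mean=mean, null_sd=sd, statistic=float(z),
                            p_raw=float(min(p, 1.0)), p_adjusted=float("nan"),
                            normality_ok=normality_ok, note=note)


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return [float(p) for p in adjusted]


def _apply_bh(results: Sequence[ComparisonResult]) -> None:
    """Fill p_adjusted in place, one BH family per null_source."""
    by_source: Dict[str, List[ComparisonResult]] = {}
    for res in results:
        by_source.setdefault(res.null_source, []).append(res)
    for family in by_source.values():
        adjusted = bh_adjust([r.p_raw for r in family])
        for res, p_adj in zip(family, adjusted):
            res.p_adjusted = p_adj


def compare_set_sizes(observed_records: Sequence[SetSizeRecord],
                      null_records_by_source: Dict[str, Sequence[SetSizeRecord]],
                      adjust: bool = True) -> List[ComparisonResult]:
    """Z-score tests of each observed set size against each null source.

    The null sample for one (definition, source) pair is the set size over
    that source's replicate groups.
    """
    results: List[ComparisonResult] = []
    for source, null_records in null_records_by_source.items():
        nulls: Dict[Tuple, List[int]] = {}
        # repr-keyed so the integer count 1 (union) and the fraction 1.0
        # (full intersection) stay distinct definitions
        for rec in null_records:
            nulls.setdefault((rec.set_kind, repr(rec.k), repr(rec.m)),
                             []).append(rec.size)
        for rec in observed_records:
            key = (rec.set_kind, repr(rec.k), repr(rec.m))
            entity = SetDefinition(rec.set_kind, rec.k, rec.m).label
            if key not in nulls:
                logger.warning("set %s missing from null source %s; skipped",
                               entity, source)
                results.append(ComparisonResult(
                    entity=entity, entity_kind="set", null_source=source,
                    observed=float(rec.size), null_mean=float("nan"),
                    null_sd=float("nan"), statistic=float("nan"),
                    p_raw=float("nan"), p_adjusted=float("nan"),
                    normality_ok=False, note="missing from null source"))
                continue
            results.append(zscore_test(rec.size, nulls[key], entity=entity,
                                       entity_kind="set", null_source=source))
    if adjust:
        _apply_bh([r for r in results if np.isfinite(r.p_raw)])
    return results


def _mwu_p(observed: Sequence[float], null: Sequence[float]) -> float:
    """Two-sided Mann–Whitney U p-value (normal approximation with tie
    correction); degenerate all-tied samples count as non-rejections."""
    obs = np.asarray(observed, dtype=float)
    nul = np.asarray(null, dtype=float)
    pooled = np.concatenate([obs, nul])
    if np.all(pooled == pooled[0]):
        return 1.0
    res = sps.mannwhitneyu(obs, nul, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def compare_centralities(observed_group: NetworkGroup,
                         replicate_groups: Sequence[NetworkGroup],
                         metric: str, alpha: float = 0.05,
                         n_comparisons: Optional[int] = None,
                         null_source: str = "random",
                         adjust: bool = True) -> List[ComparisonResult]:
    """Repeated rank comparison of node centralities against a null.

    For each node, the observed sample is its centrality rank across the
    observed networks (networks where the node is connected); the null
    samples are its ranks across each replicate group.  Each of the
    ``n_comparisons`` groups contributes one two-sided Mann–Whitney U test
    at level *alpha*; with s rejections out of c performed comparisons the
    smoothed parameter-free p is (c − s + 1)/(c + 1).
    """
    observed_group.require_comparable()
    if n_comparisons is None:
        n_comparisons = len(replicate_groups)
    if n_comparisons > len(replicate_groups):
        raise ValueError(
            f"n_comparisons={n_comparisons} exceeds the "
            f"{len(replicate_groups)} available replicate groups")
    observed_ranks = centrality_rank_table(observed_group, metric)
    null_tables = [centrality_rank_table(g, metric)
                   for g in replicate_groups[:n_comparisons]]
    results: List[ComparisonResult] = []
    for node in sorted(observed_ranks):
        obs = observed_ranks[node]
        if len(obs) < 2:
            continue  # node connected in < 2 observed networks
        null_samples = [t[node] for t in null_tables if node in t and t[node]]
        if not null_samples:
            logger.warning("node %s absent from every replicate group for "
                           "metric %s / source %s; skipped",
                           node, metric, null_source)
            continue
        successes = 0
        performed = 0
        pooled: List[float] = []
        for sample in null_samples:
            performed += 1
            pooled.extend(sample)
            if _mwu_p(obs, sample) < alpha:
                successes += 1
        p_raw = (performed - successes + 1) / (performed + 1)
        note = ""
        if performed < n_comparisons:
            note = (f"only {performed}/{n_comparisons} replicate groups "
                    f"contained the node")
        results.append(ComparisonResult(
            entity=node, entity_kind="node", null_source=null_source,
            observed=float(np.mean(obs)), null_mean=float(np.mean(pooled)),
            null_sd=float(np.std(pooled, ddof=1)) if len(pooled) > 1 else 0.0,
            statistic=successes / performed, p_raw=float(p_raw),
            p_adjusted=float("nan"), normality_ok=False, note=note))
    if adjust:
        _apply_bh(results)
    return results


def compare_graph_properties(observed_group: NetworkGroup,
                             replicate_groups: Sequence[NetworkGroup],
                             property: str, null_source: str = "random",
                             connectivity_variant: str = "node"
                             ) -> Optional[ComparisonResult]:
    """Z-score test of the mean network property against per-replicate-group
    means; undefined per-network values are skipped within each mean."""

    def group_mean(group: NetworkGroup) -> float:
        values = [r.value for r in group_properties(
            group, property, connectivity_variant=connectivity_variant)]
        finite = [v for v in values if np.isfinite(v)]
        return float(np.mean(finite)) if finite else float("nan")

    observed = group_mean(observed_group)
    if not np.isfinite(observed):
        logger.warning("property %s undefined on every observed network; "
                       "comparison skipped", property)
        return None
    null_means = [group_mean(g) for g in replicate_groups]
    null_means = [v for v in null_means if np.isfinite(v)]
    if len(null_means) < 2:
        logger.warning("property %s undefined in the null ensemble; "
                       "comparison skipped", property)
        return None
    result = zscore_test(observed, null_means, entity=property,
                         entity_kind="property", null_source=null_source)
    result.p_adjusted = result.p_raw
    return result


def ordered_correlation(group: NetworkGroup, property: str,
                        connectivity_variant: str = "node"
                        ) -> ComparisonResult:
    """Spearman correlation of a network property with the group order.

    Position 1..n along the (user-supplied) gradient is the ordering
    variable; ties in the property values get average ranks.
    """
    if not group.ordered:
        raise ValueError(f"group '{group.label}' is not ordered")
    if group.n < 3:
        raise ValueError("ordered correlation needs at least 3 networks")
    values = [r.value for r in group_properties(
        group, property, connectivity_variant=connectivity_variant)]
    positions = list(range(1, group.n + 1))
    finite = [(p, v) for p, v in zip(positions, values) if np.isfinite(v)]
    note = ""
    if len(finite) < len(values):
        note = f"{len(values) - len(finite)} undefined values dropped"
    if len(finite) < 3 or len({v for _, v in finite}) == 1:
        return ComparisonResult(
            entity=property, entity_kind="property",
            null_source="order", observed=float("nan"),
            null_mean=float("nan"), null_sd=float("nan"),
            statistic=float("nan"), p_raw=float("nan"),
            p_adjusted=float("nan"), normality_ok=False,
            note=(note + "; " if note else "") +
                 "correlation undefined (constant or too few values)")
    pos, vals = zip(*finite)
    rho, p = sps.spearmanr(pos, vals)
    return ComparisonResult(entity=property, entity_kind="property",
                            null_source="order",
                            observed=float(np.mean(vals)),
                            null_mean=float("nan"), null_sd=float("nan"),
                            statistic=float(rho), p_raw=float(p),
                            p_adjusted=float(p), normality_ok=False,
                            note=note)
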