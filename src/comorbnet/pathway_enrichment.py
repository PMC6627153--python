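"""Pathway over-representation in disease subnetworks.

Each pathway gene set overlapping a cluster is tested with the
hypergeometric upper tail P(X >= overlap) for X ~ Hypergeom(universe,
pathway size, cluster size) — the one-sided Fisher test on the implied 2x2
table. Raw p-values are adjusted per cluster with the Holm (Bonferroni
step-down) procedure; note some tools label this adjustment "FDR", but it
controls the family-wise error rate, hence the column name
``adjusted_p_holm``. A significant pathway is flagged *shared* when its
overlap with the cluster contains at least one shared protein of the
cluster's significant comorbid disease(s).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .disease_enrichment import DiseaseEnrichmentResult
from .mcode import Cluster
from .network_io import PathwaySet

__all__ = [
    "PathwayEnrichmentResult",
    "hypergeom_test",
    "holm_adjust",
    "enrich_pathways",
    "flag_shared_pathways",
]


@dataclasses.dataclass(frozen=True)
class PathwayEnrichmentResult:
    cluster_id: int
    pathway: str
    overlap_count: int
    cluster_size: int
    pathway_size: int
    universe_size: int
    raw_p: float
    adjusted_p: float
    significant: bool
    overlap_proteins: frozenset
    shared: bool = False


def hypergeom_test(overlap: int, cluster_size: int, pathway_size: int,
                   universe: int) -> float:
    """Upper-tail P(X >= overlap), X ~ Hypergeom(universe, pathway, cluster)."""
    if not (0 <= overlap <= min(cluster_size, pathway_size)
            and max(cluster_size, pathway_size) <= universe):
        raise ValueError(
            f"invalid hypergeometric bounds: overlap={overlap}, "
            f"cluster={cluster_size}, pathway={pathway_size}, "
            f"universe={universe}")
    if overlap == 0:
        return 1.0
    p = stats.hypergeom.sf(overlap - 1, universe, pathway_size, cluster_size)
    return float(min(p, 1.0))


def holm_adjust(raw_ps: Sequence[float]) -> list:
    """Holm step-down adjusted p-values, returned in input order.

    adjusted_(i) = max_{j<=i} min(1, (m - j + 1) * p_(j)) over ascending
    raw p-values.
    """
    p = np.asarray(raw_ps, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adjusted_sorted = np.maximum.accumulate(stepped)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted.tolist()


def enrich_pathways(cluster: Cluster, pathways: PathwaySet,
                    universe_nodes: Iterable[str],
                    alpha: float = 0.05) -> list:
    """Over-representation of each overlapping pathway in one cluster.

    The family for Holm adjustment is the set of pathways tested for this
    cluster (those with overlap >= 1 within the universe). Results are
    sorted by adjusted then raw p-value.
    """
    universe = set(universe_nodes)
    if not universe:
        raise ValueError("empty enrichment universe")
    members = set(cluster.members) & universe
    tested = []
    for name, gene_set in pathways.items():
        in_universe = gene_set & universe
        overlap = members & in_universe
        if not overlap:
            continue
        raw_p = hypergeom_test(len(overlap), len(members), len(in_universe),
                               len(universe))
        tested.append((name, overlap, len(in_universe), raw_p))
    adjusted = holm_adjust([t[3] for t in tested])
    results = [
        PathwayEnrichmentResult(
            cluster_id=cluster.rank,
            pathway=name,
            overlap_count=len(overlap),
            cluster_size=len(members),
            pathway_size=size,
            universe_size=len(universe),
            raw_p=raw_p,
            adjusted_p=adj,
            significant=adj < alpha,
            overlap_proteins=frozenset(overlap),
        )
        for (name, overlap, size, raw_p), adj in zip(tested, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.raw_p, r.pathway))
    return results


def flag_shared_pathways(pathway_results: Iterable[PathwayEnrichmentResult],
                         disease_results: Iterable[DiseaseEnrichmentResult]
                         ) -> list:
    """Mark significant pathways carrying a comorbid disease's shared protein."""
    shared_by_cluster: dict = {}
    for r in disease_results:
        if r.significant and r.comorbid:
            shared_by_cluster.setdefault(r.cluster_id, set()).update(
                r.shared_proteins)
    out = []
    for r in pathway_results:
        pool = shared_by_cluster.get(r.cluster_id, set())
        shared = bool(r.significant and (r.overlap_proteins & pool))
        out.append(dataclasses.replace(r, shared=shared))
    return out
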