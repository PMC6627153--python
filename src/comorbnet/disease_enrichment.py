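"""Per-cluster disease enrichment and the comorbidity filter.

For every detected subnetwork and every disease annotating at least one of
its members, a 2x2 contingency table is built over the network universe:

====================  =================  =====================
..                     annotated          not annotated
====================  =================  =====================
inside the cluster     a                  b
outside the cluster    c                  d
====================  =================  =====================

with ``a + b`` the cluster size and ``a + b + c + d = n`` the number of
proteins in the filtered network. Fisher's exact test on this table (by
default one-sided, "greater": over-representation of annotated proteins
inside the cluster) yields the p-value; diseases with p below ``alpha``
(default 0.01) are flagged significant. The a-cell membership — cluster
members annotated to the disease — is reported as the shared proteins.

The comorbidity filter then restricts significant results to diseases on a
user-supplied comorbid list (case-insensitive exact label match after
trimming); clusters retaining at least one comorbid result are the disease
subnetworks carried into pathway enrichment.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, NamedTuple

import networkx as nx
from scipy import stats

from .mcode import Cluster
from .network_io import DiseaseAnnotation

__all__ = [
    "ContingencyTable",
    "DiseaseEnrichmentResult",
    "contingency_table",
    "fisher_exact",
    "enrich_clusters",
    "comorbidity_filter",
    "disease_subnetwork_ids",
]


class ContingencyTable(NamedTuple):
    a: int  # annotated, inside cluster
    b: int  # not annotated, inside cluster
    c: int  # annotated, outside cluster
    d: int  # not annotated, outside cluster

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclasses.dataclass(frozen=True)
class DiseaseEnrichmentResult:
    cluster_id: int
    disease: str
    table: ContingencyTable
    p_value: float
    significant: bool
    shared_proteins: frozenset
    comorbid: bool = False


def contingency_table(cluster: Cluster, disease: str,
                      annotation: DiseaseAnnotation,
                      network: nx.Graph) -> ContingencyTable:
    """Counts over the network universe; off-network annotations ignored."""
    universe = set(network.nodes)
    members = set(cluster.members)
    if not members <= universe:
        raise ValueError("cluster members must be network nodes")
    annotated = annotation.proteins_for(disease) & universe
    a = len(members & annotated)
    b = len(members) - a
    c = len(annotated) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def fisher_exact(table: ContingencyTable,
                 alternative: str = "greater") -> float:
    """Exact hypergeometric tail p-value for a 2x2 table.

    ``greater`` sums P(X >= a) under the hypergeometric law with the
    table's margins; ``two_sided`` sums every table with point probability
    at most that of the observed one. Degenerate margins give p = 1.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if min(table) < 0:
        raise ValueError("contingency counts must be nonnegative")
    scipy_alt = "greater" if alternative == "greater" else "two-sided"
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative=scipy_alt)
    return float(min(p, 1.0))


def enrich_clusters(clusters: Iterable[Cluster],
                    annotation: DiseaseAnnotation,
                    network: nx.Graph,
                    alpha: float = 0.01,
                    alternative: str = "greater") -> list:
    """Test every (cluster, disease) pair with a nonempty a-cell.

    Diseases with no annotated protein inside a cluster are trivially
    p = 1 and are not reported. Results are ordered by (cluster rank,
    p-value, disease label).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    universe = set(network.nodes)
    results = []
    for cluster in clusters:
        members = set(cluster.members)
        candidates = set()
        for protein in members:
            candidates |= annotation.diseases_for(protein)
        for disease in sorted(candidates):
            table = contingency_table(cluster, disease, annotation, network)
            if table.a == 0:
                continue
            p = fisher_exact(table, alternative)
            shared = frozenset(members
                               & annotation.proteins_for(disease) & universe)
            results.append(DiseaseEnrichmentResult(
                cluster_id=cluster.rank,
                disease=disease,
                table=table,
                p_value=p,
                significant=p < alpha,
                shared_proteins=shared,
            ))
    results.sort(key=lambda r: (r.cluster_id, r.p_value, r.disease))
    return results


def _normalize(label: str) -> str:
    return label.strip().casefold()


def comorbidity_filter(results: Iterable[DiseaseEnrichmentResult],
                       comorbid_diseases: Iterable[str]) -> list:
    """Restrict significant results to diseases on the comorbid list.

    Matching is case-insensitive after whitespace trimming. With an empty
    list a warning is emitted and every significant result is kept, but
    none is tagged comorbid — so no cluster qualifies as a disease
    subnetwork without actual comorbidity evidence.
    """
    comorbid = {_normalize(d) for d in comorbid_diseases if d.strip()}
    significant = [r for r in results if r.significant]
    if not comorbid:
        warnings.warn(
            "empty comorbid-disease list: keeping all significant results, "
            "none tagged comorbid", stacklevel=2)
        return [dataclasses.replace(r, comorbid=False) for r in significant]
    return [dataclasses.replace(r, comorbid=True) for r in significant
            if _normalize(r.disease) in comorbid]


def disease_subnetwork_ids(filtered_results: Iterable[DiseaseEnrichmentResult]
                           ) -> list:
    """Cluster ids retaining >= 1 significant comorbid disease, sorted."""
    return sorted({r.cluster_id for r in filtered_results
                   if r.significant and r.comorbid})
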