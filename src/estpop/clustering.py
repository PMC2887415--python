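"""Best-hit association graphs and connected-component clusters.

Unigenes are clustered aggressively through shared sequence similarity:
every unigene becomes a node, as does every reference protein it best-hits.
Each unigene contributes at most one undirected edge per relation — to its
best same-species unigene match (the trivial self-match excluded), and to its
best protein hit in each reference database (below the e-value cutoff).
Unigenes in the same connected component form a cluster; for example, if
unigene A best-hits unigene B while B and C both best-hit protein X, then
{A, B, C} is one cluster.  Protein nodes connect components but are not
counted as cluster members.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .ortholog_annotation import SpeciesHitProfile

UNIGENE = "unigene"
PROTEIN = "protein"


def _unigene_node(uid: str) -> tuple[str, str]:
    return (UNIGENE, uid)


def _protein_node(db: str, pid: str) -> tuple[str, str, str]:
    return (PROTEIN, db, pid)


def build_graph(
    unigene_ids: Sequence[str],
    unigene_best_hits: Mapping[str, str] | None = None,
    protein_best_hits: Mapping[str, Mapping[str, str]] | None = None,
) -> nx.Graph:
    """Assemble the association graph.

    ``unigene_best_hits`` maps unigene -> best same-species unigene;
    ``protein_best_hits`` maps database label -> {unigene -> best protein}.
    Both maps are assumed to be already filtered at the e-value cutoff (they
    come from :func:`estpop.ortholog_annotation.best_hit`).  Unigenes with no
    hits anywhere become isolated nodes; self-best-hits are suppressed.
    """
    graph = nx.Graph()
    universe = set(unigene_ids)
    for uid in unigene_ids:
        graph.add_node(_unigene_node(uid))

    for uid, target in (unigene_best_hits or {}).items():
        if uid not in universe:
            raise ValueError(f"best-hit source '{uid}' not in unigene set")
        if target not in universe:
            raise ValueError(
                f"best-hit target '{target}' (from '{uid}') not in unigene set"
            )
        if uid == target:
            continue
        graph.add_edge(
            _unigene_node(uid), _unigene_node(target), relation="unigene"
        )

    for db, hits in (protein_best_hits or {}).items():
        for uid, pid in hits.items():
            if uid not in universe:
                raise ValueError(f"best-hit source '{uid}' not in unigene set")
            graph.add_edge(
                _unigene_node(uid), _protein_node(db, pid), relation=db
            )
    return graph


@dataclass
class ClusterReport:
    """Connected-component clusters over the unigene set.

    ``clusters`` partition the unigenes (largest first, then lexicographic
    for determinism); protein nodes act as connectors only.
    """

    clusters: list[set[str]]
    n_clusters: int
    n_singleton_clusters: int

    @property
    def largest(self) -> set[str]:
        return self.clusters[0] if self.clusters else set()


def connected_components(graph: nx.Graph) -> ClusterReport:
    """Clusters = unigene members of each connected component; components
    containing only protein nodes are dropped."""
    clusters: list[set[str]] = []
    for comp in nx.connected_components(graph):
        members = {node[1] for node in comp if node[0] == UNIGENE}
        if members:
            clusters.append(members)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return ClusterReport(
        clusters=clusters,
        n_clusters=len(clusters),
        n_singleton_clusters=sum(1 for c in clusters if len(c) == 1),
    )


@dataclass
class ClusterComposition:
    """Breakdown of one cluster by unigene class and database exclusivity."""

    size: int
    n_contigs: int
    n_singletons: int
    only_db: dict[str, int]  # members hitting exactly one database


def cluster_composition(
    cluster: set[str],
    kinds: Mapping[str, str],
    profiles: Mapping[str, SpeciesHitProfile],
) -> ClusterComposition:
    """Count contigs vs singletons and members hitting only one database."""
    n_contigs = sum(1 for u in cluster if kinds.get(u) == "contig")
    n_singletons = sum(1 for u in cluster if kinds.get(u) == "singleton")
    only_db: dict[str, int] = {}
    for u in cluster:
        p = profiles.get(u)
        if p is not None and p.n_databases_hit == 1:
            (db,) = p.hit_set
            only_db[db] = only_db.get(db, 0) + 1
    return ClusterComposition(
        size=len(cluster),
        n_contigs=n_contigs,
        n_singletons=n_singletons,
        only_db=only_db,
    )


def write_cluster_report(
    report: ClusterReport,
    kinds: Mapping[str, str],
    prefix: str | Path,
) -> None:
    """Write ``<prefix>.clusters.tsv`` (cluster id, member, class) and
    ``<prefix>.summary.json``."""
    prefix = Path(prefix)
    with open(f"{prefix}.clusters.tsv", "w") as fh:
        fh.write("cluster_id\tmember\tkind\n")
        for i, cluster in enumerate(report.clusters):
            for member in sorted(cluster):
                fh.write(f"{i}\t{member}\t{kinds.get(member, 'contig')}\n")
    summary = {
        "n_clusters": report.n_clusters,
        "n_singleton_clusters": report.n_singleton_clusters,
        "largest_cluster_size": len(report.largest),
    }
    with open(f"{prefix}.summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
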