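"""Greedy identity clustering, BSR cluster graphs, minimum spanning forest.

Unique flagellin sequences are grouped by single-pass greedy set-cover
clustering (longest sequence first, later sequences join the first
representative they match at the identity/coverage thresholds).  Clusters
are then linked by the maximum BSR between any cross-cluster member pair,
and a minimum spanning forest over distance 1 - similarity exposes the
supercluster structure (connected components), which in the curated corpus
separates the bacterial from the archaeal superkingdom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .pairwise_align import DEFAULT_SCHEME, ScoringScheme, align_local, bsr
from .sequence_model import UniqueSequenceSet


@dataclass
class Cluster:
    cluster_id: str
    representative: str            # unique-sequence key (residue string)
    members: set[str] = field(default_factory=set)
    phylum_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = set(self.members)
        self.members.add(self.representative)


@dataclass
class ClusterGraph:
    """BSR-weighted cluster network with optional spanning-forest annotation."""

    clusters: list[Cluster]
    edge_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    mst_edges: list[tuple[str, str]] = field(default_factory=list)
    components: list[set[str]] = field(default_factory=list)

    def cluster(self, cluster_id: str) -> Cluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)


def _identity_coverage(a: str, b: str, scheme: ScoringScheme) -> tuple[float, float]:
    """Identity over aligned columns and coverage of the shorter sequence."""
    res = align_local(a, b, scheme)
    if not res.path:
        return 0.0, 0.0
    cov = res.query_cov if len(a) <= len(b) else res.subject_cov
    return res.identity, cov


def greedy_cluster(uniques: UniqueSequenceSet, min_identity: float = 0.3,
                   min_coverage: float = 0.8,
                   scheme: ScoringScheme = DEFAULT_SCHEME) -> list[Cluster]:
    """Single-pass greedy set-cover clustering of unique sequences.

    Sequences are visited longest-first (ties by representative record id);
    each visits the existing representatives in creation order and joins
    the first whose local alignment reaches both thresholds, otherwise it
    founds a new cluster.  Every sequence is assigned exactly once.
    """
    if not (0 < min_identity <= 1 and 0 < min_coverage <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    reps = uniques.representatives()
    order = sorted(reps, key=lambda s: (-len(s), reps[s]))
    clusters: list[Cluster] = []
    for seq in order:
        placed = False
        for cl in clusters:
            ident, cov = _identity_coverage(seq, cl.representative, scheme)
            if ident >= min_identity and cov >= min_coverage:
                cl.members.add(seq)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(cluster_id=f"C{len(clusters) + 1:03d}",
                                    representative=seq))
    return clusters


def attach_phyla(clusters: list[Cluster],
                 phylum_by_key: dict[str, str]) -> None:
    """Fill ``phylum_counts`` from a unique-key -> phylum mapping (in place)."""
    for cl in clusters:
        counts: dict[str, int] = {}
        for key in cl.members:
            ph = phylum_by_key.get(key, "Unknown")
            counts[ph] = counts.get(ph, 0) + 1
        cl.phylum_counts = counts


def cluster_similarity(ci: Cluster, cj: Cluster,
                       scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Maximum BSR over all cross-cluster member pairs.

    The spanning forest minimises distance 1 - this similarity.
    """
    if ci.cluster_id == cj.cluster_id:
        raise ValueError("cluster_similarity requires two distinct clusters")
    best = 0.0
    for a in sorted(ci.members):
        for b in sorted(cj.members):
            val = bsr(a, b, scheme)
            if val > best:
                best = val
                if best >= 1.0:
                    return 1.0
    return best


def build_cluster_graph(clusters: list[Cluster],
                        scheme: ScoringScheme = DEFAULT_SCHEME) -> ClusterGraph:
    """All-vs-all max-BSR edge weights between clusters."""
    weights: dict[tuple[str, str], float] = {}
    for ci, cj in combinations(sorted(clusters, key=lambda c: c.cluster_id), 2):
        pair = (ci.cluster_id, cj.cluster_id)
        weights[pair] = cluster_similarity(ci, cj, scheme)
    return ClusterGraph(clusters=list(clusters), edge_weights=weights)


def minimum_spanning_forest(graph: ClusterGraph,
                            link_threshold: float = 0.1) -> ClusterGraph:
    """Kruskal spanning forest minimising 1 - similarity per component.

    Edges with similarity <= ``link_threshold`` are removed first; the
    surviving connected components are the superclusters.  Ties are broken
    by lexicographic cluster-id pair, making the forest deterministic.
    The default threshold is a noise floor: unrelated proteins produce
    small positive local-alignment scores, so truly unlinked clusters sit
    at BSR ~0.02-0.05, not exactly 0.
    """
    if link_threshold < 0:
        raise ValueError("link_threshold must be >= 0")
    ids = sorted(c.cluster_id for c in graph.clusters)
    g = nx.Graph()
    g.add_nodes_from(ids)
    kept = [(pair, sim) for pair, sim in graph.edge_weights.items()
            if sim > link_threshold]
    kept.sort(key=lambda item: (1.0 - item[1], item[0]))
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst: list[tuple[str, str]] = []
    for (u, v), sim in kept:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            mst.append((u, v))
            g.add_edge(u, v, similarity=sim)
    components = [set(comp) for comp in nx.connected_components(g)]
    components.sort(key=lambda s: sorted(s)[0])
    return ClusterGraph(clusters=graph.clusters, edge_weights=graph.edge_weights,
                        mst_edges=mst, components=components)


def summarize_composition(clusters: list[Cluster]) -> tuple[pd.DataFrame, float]:
    """Per-cluster phylum proportions and the multi-phylum cluster fraction.

    Returns a long-form table (cluster_id, phylum, count, proportion) and
    the fraction of clusters containing two or more phyla.  Display the
    fraction with :func:`multi_phylum_percent` to the nearest percent.
    """
    rows = []
    n_multi = 0
    for cl in clusters:
        total = sum(cl.phylum_counts.values())
        if len([p for p in cl.phylum_counts if cl.phylum_counts[p] > 0]) >= 2:
            n_multi += 1
        for ph, cnt in sorted(cl.phylum_counts.items()):
            rows.append({"cluster_id": cl.cluster_id, "phylum": ph,
                         "count": cnt,
                         "proportion": cnt / total if total else 0.0})
    table = pd.DataFrame(rows, columns=["cluster_id", "phylum", "count",
                                        "proportion"])
    fraction = n_multi / len(clusters) if clusters else 0.0
    return table, fraction


def multi_phylum_percent(n_multi: int, n_clusters: int) -> int:
    """Multi-phylum cluster share to the nearest percent (e.g. 46/135 -> 34)."""
    if n_clusters <= 0:
        raise ValueError("n_clusters must be positive")
    return round(100.0 * n_multi / n_clusters)


def write_cluster_table(clusters: list[Cluster],
                        uniques: UniqueSequenceSet, path) -> None:
    reps = uniques.representatives()
    with open(path, "w") as fh:
        fh.write("cluster_id\trepresentative\tn_members\tmember_ids\tphylum_counts\n")
        for cl in clusters:
            ids = sorted(i for key in cl.members for i in uniques.members.get(key, []))
            counts = ";".join(f"{p}:{c}" for p, c in sorted(cl.phylum_counts.items()))
            fh.write(f"{cl.cluster_id}\t{reps.get(cl.representative, '')}\t"
                     f"{len(cl.members)}\t{','.join(ids)}\t{counts}\n")


def to_networkx(graph: ClusterGraph, mst_only: bool = True) -> nx.Graph:
    g = nx.Graph()
    for cl in graph.clusters:
        g.add_node(cl.cluster_id, n_members=len(cl.members),
                   phyla=";".join(sorted(cl.phylum_counts)))
    edges = (set(graph.mst_edges) if mst_only
             else {p for p, s in graph.edge_weights.items() if s > 0})
    for u, v in edges:
        sim = graph.edge_weights.get((u, v), graph.edge_weights.get((v, u), 0.0))
        g.add_edge(u, v, similarity=sim, distance=1.0 - sim)
    return g


def write_graph(graph: ClusterGraph, edge_list_path=None,
                graphml_path=None, mst_only: bool = True) -> None:
    """Export as edge-list TSV and/or GraphML (Cytoscape-ready)."""
    g = to_networkx(graph, mst_only=mst_only)
    if edge_list_path is not None:
        with open(edge_list_path, "w") as fh:
            fh.write("source\ttarget\tsimilarity\tdistance\n")
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data['similarity']:.4f}\t"
                         f"{data['distance']:.4f}\n")
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
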