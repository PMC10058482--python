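"""Walktrap community detection and partition comparison.

Walktrap exploits the fact that short random walks tend to stay inside
densely connected groups: it agglomerates nodes bottom-up by the similarity
of their t-step random-walk distributions (t = 4 by default) and cuts the
resulting dendrogram at maximum modularity.  Communities of exposure
biomarkers are the analysis's candidate "real-life chemical mixtures".

Edge weights, where present, enter the walk transition probabilities through
their absolute value (negative partial correlations are rare and small in
biomonitoring networks); the sign is preserved for display only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict

import igraph as ig
import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .datatypes import DataError

WALKTRAP_STEPS = 4


@dataclass
class CommunityPartition:
    """Node -> community assignment with quality diagnostics.

    Community ids are contiguous integers starting at 1; isolated nodes form
    singleton communities.
    """

    assignment: Dict[object, int]
    modularity: float
    merge_sequence: list = field(default_factory=list)
    edge_classes: Dict[tuple, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment.values()))
        if ids and ids != list(range(1, len(ids) + 1)):
            raise DataError("community ids must be contiguous integers from 1")
        if not -0.5 - 1e-9 <= self.modularity <= 1.0 + 1e-9:
            raise DataError("modularity out of [-0.5, 1]")

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> Dict[int, list]:
        out: Dict[int, list] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, []).append(node)
        return out

    def labels_for(self, nodes) -> np.ndarray:
        return np.array([self.assignment[n] for n in nodes])


def _abs_weights(G: nx.Graph):
    return [abs(d.get("weight", 1.0)) for _, _, d in G.edges(data=True)]


def modularity(G: nx.Graph, assignment: Dict[object, int]) -> float:
    """Newman-Girvan modularity on absolute edge weights.

    Q = sum_c [ e_c / m  -  (d_c / 2m)^2 ]

    where m is the total (absolute) edge weight, e_c the weight inside
    community c and d_c the total degree of its nodes.  Returns 0 for an
    empty graph.
    """
    missing = set(G.nodes) - set(assignment)
    if missing:
        raise DataError(f"assignment missing nodes: {sorted(map(str, missing))}")
    m = sum(_abs_weights(G))
    if m == 0:
        return 0.0
    e = {}
    d = {}
    for u, v, data in G.edges(data=True):
        w = abs(data.get("weight", 1.0))
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            e[cu] = e.get(cu, 0.0) + w
        d[cu] = d.get(cu, 0.0) + w
        d[cv] = d.get(cv, 0.0) + w
    return float(
        sum(e.get(c, 0.0) / m - (d.get(c, 0.0) / (2 * m)) ** 2 for c in set(assignment.values()))
    )


def walktrap(G: nx.Graph, steps: int = WALKTRAP_STEPS) -> CommunityPartition:
    """Walktrap community detection, dendrogram cut at maximum modularity.

    Weighted graphs use |weight| for the walk transition matrix.  An empty
    graph (no edges) yields all-singleton communities with modularity 0 and
    a warning.  Deterministic: walktrap involves no randomness beyond fixed
    tie-breaking.
    """
    nodes = list(G.nodes)
    if G.number_of_edges() == 0:
        warnings.warn("graph has no edges; every node is its own community")
        assignment = {n: i + 1 for i, n in enumerate(nodes)}
        part = CommunityPartition(assignment, 0.0)
        part.edge_classes = {}
        return part

    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in G.edges()]
    g = ig.Graph(n=len(nodes), edges=edges)
    w = _abs_weights(G)
    weighted = any(abs(x - 1.0) > 1e-12 for x in w)
    dendrogram = g.community_walktrap(weights=w if weighted else None, steps=steps)
    clustering = dendrogram.as_clustering()  # cut maximising modularity

    # contiguous ids from 1, numbered by first appearance in node order
    raw = clustering.membership
    relabel: Dict[int, int] = {}
    assignment = {}
    for n in nodes:
        r = raw[index[n]]
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        assignment[n] = relabel[r]

    part = CommunityPartition(
        assignment,
        modularity(G, assignment),
        merge_sequence=[tuple(m) for m in dendrogram.merges],
    )
    part.edge_classes = classify_edges(G, part)
    return part


def classify_edges(G: nx.Graph, partition: CommunityPartition) -> Dict[tuple, str]:
    """Label every edge intra- or inter-community.

    Intra-community edges are drawn black (green when weighted positive),
    inter-community edges red, matching the reporting convention.
    """
    out = {}
    for u, v in G.edges():
        same = partition.assignment[u] == partition.assignment[v]
        out[(u, v)] = "intra" if same else "inter"
    return out


def compare_partitions(p1: CommunityPartition, p2: CommunityPartition) -> dict:
    """Quantitative agreement between two partitions on their shared nodes.

    Strata may retain different biomarkers, so the comparison is restricted
    to the node intersection.  Reports the adjusted Rand index, normalised
    mutual information, the shared-node count and, per community of the
    first partition, the best Jaccard overlap with any community of the
    second.
    """
    shared = sorted(set(p1.assignment) & set(p2.assignment), key=str)
    if len(shared) < 2:
        raise DataError("need at least 2 shared nodes to compare partitions")
    a = [p1.assignment[n] for n in shared]
    b = [p2.assignment[n] for n in shared]
    ari = float(adjusted_rand_score(a, b))
    nmi = float(normalized_mutual_info_score(a, b))
    members2 = {}
    for n, c in zip(shared, b):
        members2.setdefault(c, set()).add(n)
    jaccard = {}
    members1 = {}
    for n, c in zip(shared, a):
        members1.setdefault(c, set()).add(n)
    for c, nodes1 in members1.items():
        best = 0.0
        for nodes2 in members2.values():
            inter = len(nodes1 & nodes2)
            union = len(nodes1 | nodes2)
            best = max(best, inter / union if union else 0.0)
        jaccard[c] = best
    return {
        "adjusted_rand": ari,
        "normalized_mutual_information": nmi,
        "n_shared_nodes": len(shared),
        "community_jaccard": jaccard,
    }
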