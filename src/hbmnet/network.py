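"""Network construction and export.

A fitted precision matrix (or bootstrap median structure) becomes an
undirected :class:`networkx.Graph`: one node per biomarker, one edge per
conditionally dependent pair.  Unweighted networks carry only the edge set;
weighted networks carry the signed partial correlation as the edge weight.
Node labels are annotated with the sample matrix, e.g. ``"Pb (CB)"`` for
lead in cord blood.
"""

from __future__ import annotations

from typing import Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .glasso import PrecisionEstimate
from .selection import BootstrapNetwork


def to_network(
    obj: Union[PrecisionEstimate, BootstrapNetwork],
    weighted: bool = False,
    labels: Optional[list] = None,
    matrix_annotation: Optional[dict] = None,
) -> nx.Graph:
    """Build the biomarker network from an estimate.

    Unweighted: an edge wherever the precision off-diagonal is nonzero
    (median weight nonzero for a bootstrap structure).  Weighted: the same
    edges with the signed partial correlation as weight.  The sign of every
    weight equals the sign of ``-theta_ij``.
    """
    if isinstance(obj, PrecisionEstimate):
        weights = obj.partial_corr * obj.adjacency
        labels = labels if labels is not None else obj.labels
    elif isinstance(obj, BootstrapNetwork):
        weights = obj.median_weights
        labels = labels if labels is not None else obj.labels
    else:
        raise TypeError(f"cannot build a network from {type(obj).__name__}")
    p = weights.shape[0]
    if labels is None:
        labels = [f"bm{i+1:02d}" for i in range(p)]

    G = nx.Graph(weighted=weighted)
    for i, name in enumerate(labels):
        attrs = {"index": i}
        if matrix_annotation and name in matrix_annotation:
            attrs["display"] = matrix_annotation[name]
        G.add_node(name, **attrs)
    for i in range(p):
        for j in range(i + 1, p):
            w = weights[i, j]
            if abs(w) > 1e-12:
                if weighted:
                    G.add_edge(labels[i], labels[j], weight=float(w),
                               sign=int(np.sign(w)))
                else:
                    G.add_edge(labels[i], labels[j])
    return G


def edge_list(G: nx.Graph, partition=None) -> pd.DataFrame:
    """Tidy edge list with optional community annotations."""
    rows = []
    for u, v, data in G.edges(data=True):
        w = data.get("weight", 1.0)
        row = {
            "source": u,
            "target": v,
            "weight": float(w),
            "sign": int(np.sign(w)) if w else 0,
        }
        if partition is not None:
            cu = partition.assignment[u]
            cv = partition.assignment[v]
            row.update(
                community_source=cu,
                community_target=cv,
                intra_community=bool(cu == cv),
            )
        rows.append(row)
    cols = ["source", "target", "weight", "sign"]
    if partition is not None:
        cols += ["community_source", "community_target", "intra_community"]
    return pd.DataFrame(rows, columns=cols)


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, path)


def adjacency_frame(G: nx.Graph) -> pd.DataFrame:
    nodes = list(G.nodes)
    A = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    return pd.DataFrame(A, index=nodes, columns=nodes)
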