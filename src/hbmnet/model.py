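"""Model/Results interface for exposure-biomarker network estimation.

:class:`ExposureNetwork` is built from a processed (standardised residual
log-concentration) matrix and fitted with either penalty-selection route;
:meth:`ExposureNetwork.fit` returns an :class:`ExposureNetworkResults`
carrying the precision estimate, the selection diagnostics, the derived
network and its walktrap communities, with a ``summary()`` table.

    >>> model = ExposureNetwork(processed)            # doctest: +SKIP
    >>> res = model.fit(method="stars", seed=1)       # doctest: +SKIP
    >>> print(res.summary())                          # doctest: +SKIP
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .communities import CommunityPartition, walktrap, WALKTRAP_STEPS
from .datatypes import DataError, ProcessedMatrix
from .glasso import empirical_covariance, lambda_path
from .network import edge_list, to_network
from .selection import (
    BOOTSTRAP_ITERATIONS,
    EBIC_GAMMA,
    STARS_THRESHOLD,
    bootstrap_median_network,
    ebic_select,
    stars_select,
)


class ExposureNetwork:
    """Gaussian graphical model of an exposure-biomarker panel.

    Parameters
    ----------
    data : ProcessedMatrix or DataFrame or ndarray
        Subjects x biomarkers, already preprocessed (each column mean 0,
        SD 1; no censored or missing cells).
    labels : list, optional
        Biomarker names; taken from the columns when ``data`` is tabular.
    """

    def __init__(self, data, labels: Optional[list] = None):
        if isinstance(data, ProcessedMatrix):
            self.data = data.to_numpy()
            self.labels = list(data.values.columns)
            self.provenance = list(data.provenance)
        elif isinstance(data, pd.DataFrame):
            self.data = data.to_numpy(dtype=float)
            self.labels = list(data.columns)
            self.provenance = []
        else:
            self.data = np.asarray(data, dtype=float)
            self.labels = list(labels) if labels is not None else [
                f"bm{i+1:02d}" for i in range(self.data.shape[1])
            ]
            self.provenance = []
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise DataError("need a 2-D matrix with at least 2 biomarkers")
        self.n, self.p = self.data.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExposureNetwork":
        return cls(df)

    def covariance(self) -> np.ndarray:
        return empirical_covariance(self.data)

    def penalty_path(self) -> np.ndarray:
        return lambda_path(self.covariance())

    def fit(
        self,
        method: str = "stars",
        seed: int = 0,
        weighted: Optional[bool] = None,
        walktrap_steps: int = WALKTRAP_STEPS,
        stars_threshold: float = STARS_THRESHOLD,
        ebic_gamma: float = EBIC_GAMMA,
        bootstrap_iterations: int = BOOTSTRAP_ITERATIONS,
        **kwargs,
    ) -> "ExposureNetworkResults":
        """Estimate the network.

        method : "stars" (unweighted network, stability selection),
        "ebic" (weighted network, EBIC selection) or "bootstrap"
        (EBIC selection followed by the parametric-bootstrap median
        structure).
        """
        if method == "stars":
            sel = stars_select(self.data, threshold=stars_threshold, seed=seed, **kwargs)
            est = sel.estimate
            weighted = False if weighted is None else weighted
            graph_source = est
        elif method == "ebic":
            sel = ebic_select(self.data, gamma=ebic_gamma, **kwargs)
            est = sel.estimate
            weighted = True if weighted is None else weighted
            graph_source = est
        elif method == "bootstrap":
            sel = ebic_select(self.data, gamma=ebic_gamma, **kwargs)
            est = sel.estimate
            boot = bootstrap_median_network(
                self.data,
                n_iterations=bootstrap_iterations,
                gamma=ebic_gamma,
                seed=seed,
                base_estimate=est,
            )
            boot.labels = self.labels
            weighted = True if weighted is None else weighted
            graph_source = boot
        else:
            raise DataError(f"unknown fitting method {method!r}")

        est.labels = self.labels
        graph = to_network(graph_source, weighted=weighted, labels=self.labels)
        partition = walktrap(graph, steps=walktrap_steps)
        return ExposureNetworkResults(
            model=self,
            method=method,
            estimate=est,
            selection=sel,
            bootstrap=graph_source if method == "bootstrap" else None,
            graph=graph,
            partition=partition,
            weighted=weighted,
            seed=seed,
        )


class ExposureNetworkResults:
    """Fitted network, its communities and diagnostics."""

    def __init__(self, model, method, estimate, selection, bootstrap, graph,
                 partition: CommunityPartition, weighted: bool, seed: int):
        self.model = model
        self.method = method
        self.estimate = estimate
        self.selection = selection
        self.bootstrap = bootstrap
        self.graph = graph
        self.partition = partition
        self.weighted = weighted
        self.seed = seed

    # -- derived quantities ---------------------------------------------------

    @property
    def precision(self) -> np.ndarray:
        return self.estimate.theta

    @property
    def partial_corr(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.estimate.partial_corr, index=self.model.labels,
            columns=self.model.labels,
        )

    @property
    def selected_lambda(self) -> float:
        return self.estimate.lam

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def density(self) -> float:
        possible = self.model.p * (self.model.p - 1) / 2
        return self.n_edges / possible if possible else 0.0

    def edge_list(self) -> pd.DataFrame:
        return edge_list(self.graph, partition=self.partition)

    def communities(self) -> dict:
        return self.partition.members()

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Exposure-biomarker network".center(62),
            "=" * 62,
            f"{'No. subjects:':<28}{self.model.n:>10}",
            f"{'No. biomarkers:':<28}{self.model.p:>10}",
            f"{'Selection method:':<28}{self.method:>10}",
            f"{'Network type:':<28}{'weighted' if self.weighted else 'unweighted':>10}",
            f"{'Selected lambda:':<28}{self.selected_lambda:>10.4f}",
            f"{'Edges:':<28}{self.n_edges:>10}",
            f"{'Density:':<28}{self.density:>10.3f}",
            f"{'Communities:':<28}{self.partition.n_communities:>10}",
            f"{'Modularity:':<28}{self.partition.modularity:>10.3f}",
            "-" * 62,
        ]
        members = self.partition.members()
        multi = {c: m for c, m in sorted(members.items()) if len(m) > 1}
        singletons = [m[0] for c, m in members.items() if len(m) == 1]
        for c, m in multi.items():
            lines.append(f"community {c}: {', '.join(map(str, sorted(m, key=str)))}")
        if singletons:
            lines.append(
                f"not part of a community: {', '.join(map(str, sorted(singletons, key=str)))}"
            )
        edges = self.edge_list()
        if len(edges) and self.weighted:
            top = edges.reindex(
                edges["weight"].abs().sort_values(ascending=False).index
            ).head(5)
            lines.append("-" * 62)
            lines.append("strongest edges (partial correlation):")
            for _, r in top.iterrows():
                lines.append(f"  {r.source} -- {r.target}: {r.weight:+.3f}")
        lines.append("=" * 62)
        return "\n".join(lines)

    def plot(self, path=None, ax=None, seed: int = 0):
        """Draw the network: nodes coloured by community; intra-community
        edges black (green for positive weighted edges), inter-community red."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        import networkx as nx

        if ax is None:
            fig, ax = plt.subplots(figsize=(7, 7))
        else:
            fig = ax.figure
        G = self.graph
        pos = nx.spring_layout(G, seed=seed)
        comm = self.partition.assignment
        cmap = plt.get_cmap("tab10")
        node_colors = [cmap((comm[n] - 1) % 10) for n in G.nodes]
        edge_colors = []
        widths = []
        for u, v, d in G.edges(data=True):
            intra = comm[u] == comm[v]
            w = d.get("weight", 1.0)
            if not intra:
                edge_colors.append("red")
            elif self.weighted:
                edge_colors.append("green" if w > 0 else "red")
            else:
                edge_colors.append("black")
            widths.append(1.0 + (3.0 * abs(w) if self.weighted else 0.0))
        nx.draw_networkx(
            G, pos=pos, ax=ax, node_color=node_colors, edge_color=edge_colors,
            width=widths, font_size=8, node_size=400,
        )
        ax.set_axis_off()
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return ax
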