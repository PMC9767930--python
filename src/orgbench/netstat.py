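"""Hub sub-network export and node centrality analysis.

Path-based centralities (closeness, betweenness) use the distance transform
``d = 1 / w``, the standard choice for similarity weights that are bounded
away from zero by the minimum-edge threshold.  Betweenness is unnormalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from orgbench.coexpr import CoexpressionNetwork

logger = logging.getLogger(__name__)

__all__ = ["WeightedGraph", "hub_subnetwork", "centralities"]


@dataclass
class WeightedGraph:
    """Undirected weighted graph without self-loops."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w, dist=1.0 / w)
        return g

    def write_edges(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(self.edges, columns=["source", "target", "weight"])
        df.to_csv(path, sep="\t", index=False)


def hub_subnetwork(
    network: CoexpressionNetwork, module: int, top_n: int = 75, min_edge: float = 0.2
) -> WeightedGraph:
    """Top-``top_n`` module genes by intramodular connectivity, with edges
    from the adjacency matrix at weight >= ``min_edge``.

    Ties in connectivity are broken by ascending gene id.  Modules smaller
    than ``top_n`` are taken whole (with a warning).
    """
    if network.adjacency is None:
        raise ValueError("network has no adjacency matrix")
    members = network.module_genes(module)
    if len(members) == 0:
        raise ValueError(f"module {module} does not exist")
    if len(members) < top_n:
        logger.warning("module %d has only %d genes (< top_n=%d)", module, len(members), top_n)
    kim = network.kim.loc[members]
    ranked = sorted(members, key=lambda g: (-kim[g], g))[:top_n]
    pos = {g: i for i, g in enumerate(network.genes)}
    edges = []
    for i, u in enumerate(ranked):
        for v in ranked[i + 1 :]:
            w = float(network.adjacency[pos[u], pos[v]])
            if w >= min_edge:
                edges.append((u, v, w))
    return WeightedGraph(nodes=list(ranked), edges=edges)


def centralities(graph: WeightedGraph, tol: float = 1e-10, max_iter: int = 1000) -> pd.DataFrame:
    """Per-node degree, closeness, betweenness, and eigenvector centrality.

    - degree: weighted degree, sum of incident edge weights;
    - closeness: ``(n_c - 1) / sum(d)`` over the node's connected component
      (``n_c`` = component size), 0 for isolates; distances ``d = 1/w``;
    - betweenness: unnormalized shortest-path betweenness with ``d = 1/w``;
    - eigenvector: principal eigenvector of the weight matrix by power
      iteration, L2-normalized and non-negative.
    """
    if not graph.nodes:
        raise ValueError("empty graph")
    g = graph.to_networkx()
    nodes = graph.nodes

    degree = {n: sum(d["weight"] for _, _, d in g.edges(n, data=True)) for n in nodes}

    closeness = {}
    for component in nx.connected_components(g):
        comp = g.subgraph(component)
        n_c = comp.number_of_nodes()
        for n in component:
            if n_c == 1:
                closeness[n] = 0.0
                continue
            dist = nx.single_source_dijkstra_path_length(comp, n, weight="dist")
            total = sum(dist.values())
            closeness[n] = (n_c - 1) / total if total > 0 else 0.0

    betweenness = nx.betweenness_centrality(g, weight="dist", normalized=False)

    # power iteration on the dense weight matrix
    idx = {n: i for i, n in enumerate(nodes)}
    w_mat = np.zeros((len(nodes), len(nodes)))
    for u, v, w in graph.edges:
        w_mat[idx[u], idx[v]] = w
        w_mat[idx[v], idx[u]] = w
    vec = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    converged = False
    # positive diagonal shift: preserves eigenvectors and breaks the +/-lambda
    # tie on bipartite graphs, where unshifted power iteration oscillates
    shift = float(w_mat.max()) if w_mat.max() > 0 else 1.0
    for _ in range(max_iter):
        nxt = w_mat @ vec + shift * vec
        norm = np.linalg.norm(nxt)
        if norm == 0:
            nxt = vec  # edgeless graph: keep the uniform vector
            converged = True
            break
        nxt /= norm
        if np.linalg.norm(nxt - vec) < tol:
            vec = nxt
            converged = True
            break
        vec = nxt
    if not converged:
        logger.warning("eigenvector power iteration did not converge in %d steps", max_iter)
    vec = np.abs(vec)
    vec /= np.linalg.norm(vec) or 1.0

    return pd.DataFrame(
        {
            "degree": [degree[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "eigenvector": vec,
        },
        index=pd.Index(nodes, name="gene"),
    )
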