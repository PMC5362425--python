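"""The six node-topology measures used by the two-stage target filter.

For a simple undirected graph G and node v with neighbor set N(v):

- ``dc`` degree centrality, |N(v)|.
- ``bc`` betweenness centrality, unnormalized: the sum over unordered node
  pairs (s, t), s != v != t, of the fraction of shortest s-t paths through
  v. Pairs in different components contribute 0.
- ``cc`` closeness centrality, (n_c - 1) / sum of distances from v within
  its component of size n_c; 0 for isolated nodes. Lies in [0, 1].
- ``ec`` eigenvector centrality: v's entry of the nonnegative principal
  eigenvector of the adjacency matrix, computed independently per connected
  component and scaled to unit Euclidean norm within the component.
  Isolated nodes get 0.
- ``nc`` "network centrality": the sum over edges (v, u) of the edge
  clustering coefficient ECC(v, u) = z / min(dc(v) - 1, dc(u) - 1), where z
  is the number of triangles containing the edge; ECC is 0 when the
  denominator is 0 (a degree-1 endpoint cannot close a triangle).
- ``lac`` local average connectivity: the mean, over u in N(v), of u's
  degree inside the subgraph induced by N(v); 0 when N(v) is empty.

These match the raw (unnormalized) conventions of the CytoNCA family of
essential-protein measures, which is what the median thresholds of the
target filter are defined over.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .networks import PPINetwork

MEASURES = ("dc", "bc", "cc", "ec", "nc", "lac")

_EIG_TOL = 1e-12
_EIG_MAX_ITER = 100_000


def median_of(values) -> float:
    """Standard median: middle element (odd n) or mean of the two middle
    elements (even n). The filter thresholds below are medians, so the
    convention is pinned here once."""
    vals = sorted(values)
    n = len(vals)
    if n == 0:
        raise ValueError("median of empty list")
    mid = n // 2
    if n % 2 == 1:
        return float(vals[mid])
    return (float(vals[mid - 1]) + float(vals[mid])) / 2.0


@dataclass
class CentralityTable:
    """Per-node values of the six measures, as a DataFrame indexed by node."""

    values: pd.DataFrame  # columns exactly MEASURES

    def __post_init__(self) -> None:
        missing = [m for m in MEASURES if m not in self.values.columns]
        if missing:
            raise ValueError(f"centrality table missing columns: {missing}")

    def medians(self) -> dict[str, float]:
        return {m: median_of(self.values[m].tolist()) for m in MEASURES}

    def to_tsv(self, path) -> None:
        out = self.values.loc[sorted(self.values.index), list(MEASURES)]
        out.to_csv(path, sep="\t", index_label="node", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "CentralityTable":
        return cls(pd.read_csv(path, sep="\t", index_col="node"))


def _eigenvector_per_component(g: nx.Graph) -> dict[str, float]:
    """Nonnegative unit-norm principal eigenvector, one component at a time.

    Power iteration on A + I from the all-ones vector: the shift leaves the
    eigenvectors untouched but makes the principal eigenvalue strictly
    dominant, which plain iteration on A lacks on bipartite components
    (whose spectrum is symmetric about 0).
    """
    ec: dict[str, float] = {}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            ec[nodes[0]] = 0.0
            continue
        a = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr", dtype=float)
        x = np.ones(len(nodes)) / np.sqrt(len(nodes))
        for _ in range(_EIG_MAX_ITER):
            y = a @ x + x
            y /= np.linalg.norm(y)
            if np.linalg.norm(y - x) < _EIG_TOL:
                x = y
                break
            x = y
        x = np.abs(x)  # sign fixed nonnegative (Perron vector)
        x /= np.linalg.norm(x)
        for node, val in zip(nodes, x):
            ec[node] = float(val)
    return ec


def compute_centralities(net: PPINetwork) -> CentralityTable:
    """Compute all six measures for every node of a simple graph."""
    if net.n_nodes == 0:
        raise ValueError("no nodes: cannot compute centralities on an empty graph")
    g = net.to_networkx()
    nodes = sorted(g.nodes())
    adj = {n: set(g.neighbors(n)) for n in nodes}
    deg = {n: len(adj[n]) for n in nodes}

    bc = nx.betweenness_centrality(g, normalized=False)
    cc = nx.closeness_centrality(g, wf_improved=False)
    ec = _eigenvector_per_component(g)

    nc = {n: 0.0 for n in nodes}
    for u, v in g.edges():
        denom = min(deg[u] - 1, deg[v] - 1)
        if denom <= 0:
            continue
        z = len(adj[u] & adj[v])  # triangles containing edge (u, v)
        ecc = z / denom
        nc[u] += ecc
        nc[v] += ecc

    lac = {}
    for n in nodes:
        nbrs = adj[n]
        if not nbrs:
            lac[n] = 0.0
            continue
        # degree of each neighbor within the neighbor-induced subgraph
        internal = sum(len(adj[u] & nbrs) for u in nbrs)
        lac[n] = internal / len(nbrs)

    df = pd.DataFrame(
        {
            "dc": [float(deg[n]) for n in nodes],
            "bc": [float(bc[n]) for n in nodes],
            "cc": [float(cc[n]) for n in nodes],
            "ec": [ec[n] for n in nodes],
            "nc": [nc[n] for n in nodes],
            "lac": [lac[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return CentralityTable(df)
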