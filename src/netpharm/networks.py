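"""Graph containers: undirected PPI networks and compound-target bipartite networks.

Both are thin immutable-ish wrappers over node/edge sets with conversion to
:mod:`networkx` graphs for algorithms and serialization. Edges of a
:class:`PPINetwork` are stored as sorted 2-tuples so the edge set is
canonical regardless of input orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

Edge = tuple[str, str]

#: Namespace prefixes applied when compound and target nodes share one graph,
#: so the two node sets can never collide.
COMPOUND_PREFIX = "cpd:"
TARGET_PREFIX = "tgt:"


def _canon_edge(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class PPINetwork:
    """Simple undirected graph over normalized gene symbols.

    Invariants: no self-loops, no parallel edges, every edge endpoint is a
    node. Construct via :meth:`from_edges` which enforces all three.
    """

    nodes: frozenset[str]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u > v:
                raise ValueError(f"edge {(u, v)!r} not canonically ordered")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge {(u, v)!r} has an endpoint outside the node set")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "PPINetwork":
        """Build a simple graph: self-loops dropped, duplicates collapsed."""
        edge_set: set[Edge] = set()
        nodes: set[str] = set(extra_nodes)
        for u, v in edges:
            nodes.add(u)
            nodes.add(v)
            if u != v:
                edge_set.add(_canon_edge(u, v))
        return cls(frozenset(nodes), frozenset(edge_set))

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "PPINetwork":
        return cls.from_edges(((str(u), str(v)) for u, v in g.edges()),
                              extra_nodes=(str(n) for n in g.nodes()))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def neighbors(self, node: str) -> set[str]:
        out: set[str] = set()
        for u, v in self.edges:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        return out

    def induced_subgraph(self, keep: Iterable[str]) -> "PPINetwork":
        keep_set = set(keep) & self.nodes
        kept_edges = {(u, v) for u, v in self.edges if u in keep_set and v in keep_set}
        return PPINetwork(frozenset(keep_set), frozenset(kept_edges))

    def has_edge(self, u: str, v: str) -> bool:
        return _canon_edge(u, v) in self.edges


@dataclass(frozen=True)
class BipartiteNetwork:
    """Compound-target bipartite graph.

    Compound ids and target symbols live in distinct node sets; when both
    appear in one exported graph they are namespaced with
    :data:`COMPOUND_PREFIX` / :data:`TARGET_PREFIX`.
    """

    compound_nodes: frozenset[str]
    target_nodes: frozenset[str]
    edges: frozenset[Edge]  # (compound_id, target_symbol)

    def __post_init__(self) -> None:
        seen: set[Edge] = set()
        for c, t in self.edges:
            if c not in self.compound_nodes:
                raise ValueError(f"edge compound {c!r} not a compound node")
            if t not in self.target_nodes:
                raise ValueError(f"edge target {t!r} not a target node")
            if (c, t) in seen:
                raise ValueError(f"duplicate edge {(c, t)!r}")
            seen.add((c, t))

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        compounds: Iterable[str] = (),
        targets: Iterable[str] = (),
    ) -> "BipartiteNetwork":
        edge_set = set(edges)
        cpds = set(compounds) | {c for c, _ in edge_set}
        tgts = set(targets) | {t for _, t in edge_set}
        return cls(frozenset(cpds), frozenset(tgts), frozenset(edge_set))

    def to_networkx(self) -> nx.Graph:
        """Namespaced networkx view with a ``role`` node attribute."""
        g = nx.Graph()
        for c in sorted(self.compound_nodes):
            g.add_node(COMPOUND_PREFIX + c, role="compound")
        for t in sorted(self.target_nodes):
            g.add_node(TARGET_PREFIX + t, role="target")
        for c, t in sorted(self.edges):
            g.add_edge(COMPOUND_PREFIX + c, TARGET_PREFIX + t)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "BipartiteNetwork":
        cpds, tgts = set(), set()
        for n, data in g.nodes(data=True):
            name = str(n)
            if data.get("role") == "compound" or name.startswith(COMPOUND_PREFIX):
                cpds.add(name.removeprefix(COMPOUND_PREFIX))
            else:
                tgts.add(name.removeprefix(TARGET_PREFIX))
        edges = set()
        for u, v in g.edges():
            u, v = str(u), str(v)
            if u.startswith(TARGET_PREFIX):
                u, v = v, u
            edges.add((u.removeprefix(COMPOUND_PREFIX), v.removeprefix(TARGET_PREFIX)))
        return cls(frozenset(cpds), frozenset(tgts), frozenset(edges))

    @property
    def n_nodes(self) -> int:
        return len(self.compound_nodes) + len(self.target_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def compound_degrees(self) -> dict[str, int]:
        deg = {c: 0 for c in self.compound_nodes}
        for c, _ in self.edges:
            deg[c] += 1
        return deg

    def target_degrees(self) -> dict[str, int]:
        deg = {t: 0 for t in self.target_nodes}
        for _, t in self.edges:
            deg[t] += 1
        return deg
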