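"""Seed-expanded PPI subnetworks and their intersection.

A gene list is mapped onto a background PPI graph, expanded to its direct
interactors, and the induced subgraph taken. Two such networks (e.g. drug
putative targets vs disease-associated targets) are then intersected
node-wise and edge-wise; because both are induced subgraphs of the same
background PPI, edge-set intersection coincides with the induced subgraph
on the common nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .networks import PPINetwork
from .records import normalize_symbol

EXPANSIONS = ("none", "neighbors")


@dataclass
class SeedNetworkResult:
    network: PPINetwork
    #: seeds found in the PPI (whether or not they survived as nodes)
    mapped_seeds: frozenset[str]
    #: seeds absent from the background PPI
    missing_seeds: frozenset[str]
    #: seeds present in the PPI but with no interaction partner; dropped
    isolated_seeds: frozenset[str] = field(default_factory=frozenset)


def build_seed_network(
    seeds: Iterable[str], ppi: PPINetwork, expansion: str = "neighbors"
) -> SeedNetworkResult:
    """Induced subgraph on the seeds (plus their PPI neighbors by default).

    With ``expansion="neighbors"`` the node set is (seeds ∩ PPI nodes) and
    every direct interactor of those seeds; edges are all PPI edges with
    both endpoints inside. Seeds missing from the PPI are reported, not
    fatal; seeds with no partner at all are dropped from the network but
    listed. Raises if no seed maps into the PPI.
    """
    if expansion not in EXPANSIONS:
        raise ValueError(f"unknown expansion {expansion!r}; supported: {EXPANSIONS}")
    seed_set = frozenset(normalize_symbol(s) for s in seeds)
    mapped = seed_set & ppi.nodes
    if not mapped:
        raise ValueError("no seeds mapped into the PPI network")
    missing = seed_set - ppi.nodes

    neighbor_map: dict[str, set[str]] = {s: set() for s in mapped}
    for u, v in ppi.edges:
        if u in neighbor_map:
            neighbor_map[u].add(v)
        if v in neighbor_map:
            neighbor_map[v].add(u)
    isolated = frozenset(s for s, nbrs in neighbor_map.items() if not nbrs)

    keep: set[str] = set(mapped) - isolated
    if expansion == "neighbors":
        for nbrs in neighbor_map.values():
            keep.update(nbrs)
    net = ppi.induced_subgraph(keep)
    return SeedNetworkResult(
        network=net, mapped_seeds=mapped, missing_seeds=missing, isolated_seeds=isolated
    )


def intersect_networks(a: PPINetwork, b: PPINetwork) -> PPINetwork:
    """Node-wise and edge-wise intersection of two networks.

    Commutative and idempotent; the result is a subgraph of both inputs.
    An empty intersection is a valid (empty) network.
    """
    return PPINetwork(nodes=a.nodes & b.nodes, edges=a.edges & b.edges)
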