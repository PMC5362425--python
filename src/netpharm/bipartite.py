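"""Compound–putative-target bipartite network construction and statistics."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .centrality import median_of
from .networks import BipartiteNetwork
from .records import CompoundRecord, normalize_symbol

log = logging.getLogger(__name__)


@dataclass
class BipartiteBuildResult:
    network: BipartiteNetwork
    #: kept compounds with no mapped target — excluded from the graph but reported
    unmapped: list[str]


def build_bipartite(
    kept: Sequence[CompoundRecord], ct_map: Mapping[str, Iterable[str]]
) -> BipartiteBuildResult:
    """Link each kept compound to its mapped targets.

    Compounds with no targets are left out of the graph and listed in
    ``unmapped``. Map entries for unknown compound ids are ignored with a
    logged warning. Target symbols are normalized; duplicate pairs collapse.
    """
    known = {r.compound_id for r in kept}
    stray = set(ct_map) - known
    if stray:
        log.warning("ct_map references unknown compound ids: %s", ", ".join(sorted(stray)))

    edges: set[tuple[str, str]] = set()
    unmapped: list[str] = []
    for rec in kept:
        targets = {normalize_symbol(t) for t in ct_map.get(rec.compound_id, ())}
        if not targets:
            unmapped.append(rec.compound_id)
            continue
        for t in targets:
            edges.add((rec.compound_id, t))
    return BipartiteBuildResult(BipartiteNetwork.from_edges(edges), unmapped)


def bipartite_stats(net: BipartiteNetwork) -> dict:
    """Headline statistics of a compound-target network.

    ``median_compound_degree`` is the standard median (mean of middle two
    for even counts), ``None`` for an empty network. The histogram counts
    compounds by their target out-degree.
    """
    degrees = net.compound_degrees()
    histogram = dict(sorted(Counter(degrees.values()).items()))
    return {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_compounds": len(net.compound_nodes),
        "n_targets": len(net.target_nodes),
        "median_compound_degree": median_of(list(degrees.values())) if degrees else None,
        "compound_degree_histogram": histogram,
    }
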