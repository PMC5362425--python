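"""Hypergeometric over-representation analysis with kappa term grouping.

For a query gene set inside a finite universe, each annotation term is
scored with the upper-tail hypergeometric probability

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

where N is the universe size, K the term size in the universe, n the query
size and k the observed overlap. P-values are Benjamini-Hochberg adjusted
within each term category (functional vocabularies are reported per
category). Enriched terms are then linked when the Cohen kappa agreement
of their gene memberships over a reference set reaches a threshold, and
connected components of the link graph form term groups, each labeled by
its most significant ("leading") term — the ClueGO-style grouping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .records import GeneSetCollection

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    category: str
    k: int  # overlap count
    K: int  # term size within the universe
    n: int  # query size within the universe
    N: int  # universe size
    p: float
    p_adj: float
    enriched: bool

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(f"{self.term_id}: k={self.k} outside [0, min(K, n)]")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.term_id}: p={self.p} outside (0, 1]")


@dataclass
class TermGroup:
    members: tuple[str, ...]
    links: list[tuple[str, str, float]] = field(default_factory=list)
    leading_term: str = ""

    def __post_init__(self) -> None:
        if self.leading_term and self.leading_term not in self.members:
            raise ValueError("leading_term must be a group member")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query: set[str],
    sets: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
    by_category: bool = True,
) -> list[EnrichmentResult]:
    """Score every term against the query; BH-adjust within category.

    Query genes outside the universe are dropped (count logged). Terms
    empty after restriction to the universe are skipped. The full table is
    returned, sorted by (category, p, term_id), with ``enriched`` flagging
    p_adj <= alpha.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if len(set(query)) > len(set(universe)):
        raise ValueError("universe smaller than query")
    uni = frozenset(universe)
    q = frozenset(query) & uni
    dropped = len(frozenset(query)) - len(q)
    if dropped:
        log.info("hypergeom_enrich: dropped %d query gene(s) outside the universe", dropped)

    N, n = len(uni), len(q)
    raw: list[tuple[str, str, int, int, float]] = []
    for term in sets:
        term_genes = term.genes & uni
        K = len(term_genes)
        if K == 0:
            log.info("term %s has no genes in the universe; skipped", term.term_id)
            continue
        k = len(term_genes & q)
        raw.append((term.term_id, term.category, k, K, hypergeom_pvalue(k, K, n, N)))

    results: list[EnrichmentResult] = []
    groups = sorted({cat for _, cat, _, _, _ in raw}) if by_category else [None]
    for cat in groups:
        block = [r for r in raw if cat is None or r[1] == cat]
        if not block:
            continue
        pvals = [r[4] for r in block]
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        for (term_id, category, k, K, p), pa in zip(block, p_adj):
            results.append(
                EnrichmentResult(
                    term_id=term_id, category=category, k=k, K=K, n=n, N=N,
                    p=p, p_adj=float(pa), enriched=pa <= alpha,
                )
            )
    results.sort(key=lambda r: (r.category, r.p, r.term_id))
    return results


def kappa_statistic(set_a: frozenset[str], set_b: frozenset[str], reference: frozenset[str]) -> float:
    """Cohen's kappa between two gene-set memberships over a reference set.

    Memberships are binary vectors over the reference; kappa compares
    observed agreement with chance agreement, and is defined as 1 when
    chance agreement is already perfect.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    a_set, b_set = set_a & reference, set_b & reference
    total = len(reference)
    a = len(a_set & b_set)
    b = len(a_set - b_set)
    c = len(b_set - a_set)
    d = total - a - b - c
    po = (a + d) / total
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / total**2
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def kappa_group_terms(
    results: list[EnrichmentResult],
    sets: GeneSetCollection,
    reference: set[str],
    kappa_min: float = 0.4,
) -> list[TermGroup]:
    """Group enriched terms by kappa agreement of their gene memberships.

    Terms with pairwise kappa >= ``kappa_min`` are linked; groups are the
    connected components of the link graph (singletons included). The
    leading term of a group is the member with the smallest adjusted
    p-value, ties broken by lexicographically smallest term id.
    """
    ref = frozenset(reference)
    if results and not ref:
        raise ValueError("reference must be non-empty")
    term_ids = [r.term_id for r in results]
    p_adj = {r.term_id: r.p_adj for r in results}
    genes = {tid: sets[tid].genes for tid in term_ids}

    link_graph = nx.Graph()
    link_graph.add_nodes_from(term_ids)
    links: dict[frozenset[str], float] = {}
    for ti, tj in combinations(term_ids, 2):
        kappa = kappa_statistic(genes[ti], genes[tj], ref)
        if kappa >= kappa_min:
            link_graph.add_edge(ti, tj)
            links[frozenset((ti, tj))] = kappa

    groups: list[TermGroup] = []
    for comp in nx.connected_components(link_graph):
        members = tuple(sorted(comp))
        leading = min(members, key=lambda t: (p_adj[t], t))
        comp_links = [
            (min(ti, tj), max(ti, tj), kappa)
            for pair, kappa in links.items()
            for ti, tj in [tuple(sorted(pair))]
            if ti in comp
        ]
        comp_links.sort()
        groups.append(TermGroup(members=members, links=comp_links, leading_term=leading))
    groups.sort(key=lambda g: (p_adj[g.leading_term], g.leading_term))
    return groups
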