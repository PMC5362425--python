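"""Two-stage median-threshold topological filter for candidate targets.

Stage 1 keeps nodes whose degree strictly exceeds twice the median degree
of the intersected network ("significant" targets) and induces the
subgraph on them. Stage 2 recomputes all six centrality measures on that
denser subgraph and keeps nodes strictly exceeding the per-measure medians
simultaneously ("candidate" targets). Both cuts are strict, so on any
graph where every node sits at the median of some measure (e.g. a
vertex-transitive graph) the filter returns nothing — the filter is
hub-seeking by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .centrality import MEASURES, CentralityTable, compute_centralities, median_of
from .networks import PPINetwork

log = logging.getLogger(__name__)

MEDIAN_CONVENTION = "mean_of_middle_two_for_even_counts"


@dataclass
class FilterThresholds:
    """Record of every cutoff the two-stage filter applied."""

    stage1_median_degree: float | None = None
    stage1_cut: float | None = None  # = 2 * stage1_median_degree
    stage2_medians: dict[str, float] = field(default_factory=dict)
    median_convention: str = MEDIAN_CONVENTION

    def __post_init__(self) -> None:
        if self.stage1_median_degree is not None and self.stage1_cut is not None:
            if self.stage1_cut != 2 * self.stage1_median_degree:
                raise ValueError("stage1_cut must equal 2 * stage1_median_degree")
        if self.stage2_medians and set(self.stage2_medians) != set(MEASURES):
            raise ValueError(f"stage2_medians must be keyed by exactly {MEASURES}")


def stage1_filter(net: PPINetwork) -> tuple[PPINetwork, FilterThresholds]:
    """Degree filter: keep nodes with DC > 2 * median DC, induce the subgraph."""
    if net.n_nodes == 0:
        raise ValueError("stage-1 filter needs a non-empty network")
    deg = net.degree()
    m = median_of(deg.values())
    cut = 2 * m
    kept = {v for v, d in deg.items() if d > cut}
    if not kept:
        log.warning("stage-1 filter kept no nodes (median degree %s, cut %s)", m, cut)
    significant = net.induced_subgraph(kept)
    thresholds = FilterThresholds(stage1_median_degree=m, stage1_cut=cut)
    return significant, thresholds


def stage2_filter(
    significant_net: PPINetwork, thresholds: FilterThresholds | None = None
) -> tuple[frozenset[str], FilterThresholds, CentralityTable]:
    """Six-measure median filter on the significant subnetwork.

    Measures are recomputed on the induced significant subgraph, not
    inherited from the parent network; a candidate must strictly exceed
    the median of every measure. Returns the candidate set, the completed
    threshold record, and the centrality table for auditability.
    """
    if significant_net.n_nodes == 0:
        raise ValueError("empty significant network")
    table = compute_centralities(significant_net)
    medians = table.medians()
    mask = None
    for m in MEASURES:
        col = table.values[m] > medians[m]
        mask = col if mask is None else (mask & col)
    candidates = frozenset(table.values.index[mask])
    out = FilterThresholds(
        stage1_median_degree=thresholds.stage1_median_degree if thresholds else None,
        stage1_cut=thresholds.stage1_cut if thresholds else None,
        stage2_medians=medians,
    )
    return candidates, out, table
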