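"""End-to-end orchestration: screen → networks → filter → enrichment.

``run_pipeline`` executes the stages in the canonical order, records every
parameter, threshold and output count in a machine-readable run report,
and (optionally) writes each stage's artifacts to an output directory.
Inputs come either from files named in the config or from the synthetic
generator (a ``simulate`` block). Fixed inputs and config give an
identical report, candidate set and thresholds on rerun.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import netio
from .bipartite import bipartite_stats, build_bipartite
from .disease import merge_disease_targets, overlap_targets
from .enrichment import EnrichmentResult, TermGroup, hypergeom_enrich, kappa_group_terms
from .filtering import stage1_filter, stage2_filter
from .networks import PPINetwork
from .ppi import build_seed_network, intersect_networks
from .records import CompoundRecord, GeneSetCollection
from .screening import herb_target_sets, per_herb_summary, screen_compounds
from .simulate import SyntheticBundle, SyntheticConfig, simulate_bundle

log = logging.getLogger(__name__)

DEFAULT_PARAMS: dict[str, Any] = {
    "ob_min": 30.0,
    "dl_min": 0.18,
    "ob_min_no_dl": 35.0,
    "expansion": "neighbors",
    "alpha": 0.05,
    "kappa_min": 0.4,
    "bh_by_category": True,
}

STAGE_ORDER = (
    "screen",
    "ct_network",
    "disease_merge",
    "ppi_putative",
    "ppi_disease",
    "intersect",
    "stage1_filter",
    "stage2_filter",
    "enrichment",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the run report."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineInputs:
    compounds: list[CompoundRecord]
    whitelist: frozenset[str]
    ct_map: dict[str, set[str]]
    ppi: PPINetwork
    disease_lists: dict[str, list[str]]
    gene_sets: GeneSetCollection
    bundle: SyntheticBundle | None = None  # set when inputs were simulated


@dataclass
class PipelineResult:
    report: dict
    candidates: frozenset[str]
    thresholds: Any
    significant_net: PPINetwork
    intersected_net: PPINetwork
    centrality_table: Any
    enrichment: list[EnrichmentResult]
    groups: list[TermGroup]
    inputs: PipelineInputs
    screen: Any = None


def load_config(path: str | Path) -> dict:
    with Path(path).open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _preflight(cfg: dict) -> None:
    """Fail before any stage runs if a named input file is missing."""
    if "simulate" in cfg:
        return
    inputs = cfg.get("inputs")
    if not isinstance(inputs, dict):
        raise FileNotFoundError("config has neither an 'inputs' nor a 'simulate' block")
    required = ("compounds", "ct_map", "ppi", "disease", "gene_sets")
    for key in required:
        if key not in inputs:
            raise FileNotFoundError(f"config inputs missing required entry {key!r}")
    paths = [inputs[k] for k in ("compounds", "ct_map", "ppi", "gene_sets")]
    paths += list(inputs["disease"].values())
    if "whitelist" in inputs:
        paths.append(inputs["whitelist"])
    for p in paths:
        if not Path(p).is_file():
            raise FileNotFoundError(f"input file not found: {p}")


def _load_inputs(cfg: dict) -> PipelineInputs:
    if "simulate" in cfg:
        sim = dict(cfg["simulate"] or {})
        for key in ("ob_distribution", "dl_distribution", "disease_source_sizes"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(
                    tuple(x) if isinstance(x, list) else x for x in sim[key]
                )
        bundle = simulate_bundle(SyntheticConfig(**sim))
        return PipelineInputs(
            compounds=bundle.compounds,
            whitelist=bundle.whitelist,
            ct_map=bundle.ct_map,
            ppi=bundle.ppi,
            disease_lists=bundle.disease_lists,
            gene_sets=bundle.gene_sets,
            bundle=bundle,
        )
    inputs = cfg["inputs"]
    whitelist = (
        netio.read_whitelist(inputs["whitelist"]) if "whitelist" in inputs else frozenset()
    )
    return PipelineInputs(
        compounds=netio.read_compound_table(inputs["compounds"]),
        whitelist=whitelist,
        ct_map=netio.read_ct_map(inputs["ct_map"]),
        ppi=netio.read_ppi_edges(inputs["ppi"]),
        disease_lists={
            src: netio.read_symbol_list(path) for src, path in inputs["disease"].items()
        },
        gene_sets=netio.read_gmt(inputs["gene_sets"]),
    )


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> PipelineResult:
    """Run all stages; return the result object (report under ``.report``)."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    params = {**DEFAULT_PARAMS, **(cfg.get("params") or {})}
    _preflight(cfg)
    inputs = _load_inputs(cfg)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stages: list[dict] = []
    current = "load"

    def record(name: str, **counts: Any) -> None:
        stages.append({"stage": name, "counts": counts})

    try:
        current = "screen"
        screen = screen_compounds(
            inputs.compounds,
            ob_min=params["ob_min"],
            dl_min=params["dl_min"],
            ob_min_no_dl=params["ob_min_no_dl"],
            whitelist=inputs.whitelist,
        )
        record(
            "screen",
            n_input=len(inputs.compounds),
            n_kept=len(screen.kept),
            n_excluded=len(screen.excluded),
            per_herb_counts=dict(sorted(per_herb_summary(screen).items())),
        )
        if out is not None:
            _write_screen(screen, out)

        current = "ct_network"
        build = build_bipartite(screen.kept_records, inputs.ct_map)
        ct_stats = bipartite_stats(build.network)
        putative = set(build.network.target_nodes)
        record("ct_network", n_unmapped=len(build.unmapped), **ct_stats)
        if out is not None:
            netio.write_network(build.network, out / "ct_network.graphml", format="graphml")
            (out / "ct_stats.json").write_text(json.dumps(ct_stats, indent=2, sort_keys=True))

        current = "disease_merge"
        disease = merge_disease_targets(inputs.disease_lists)
        shared = overlap_targets(putative, disease)
        record(
            "disease_merge",
            n_sources=len(disease.by_source),
            per_source={s: len(v) for s, v in sorted(disease.by_source.items())},
            n_merged=len(disease.merged),
            n_shared_with_putative=len(shared),
        )
        if out is not None:
            _write_disease(disease, shared, out)

        current = "ppi_putative"
        put_net = build_seed_network(putative, inputs.ppi, expansion=params["expansion"])
        record(
            "ppi_putative",
            n_seeds=len(putative),
            n_missing_seeds=len(put_net.missing_seeds),
            n_isolated_seeds=len(put_net.isolated_seeds),
            n_nodes=put_net.network.n_nodes,
            n_edges=put_net.network.n_edges,
        )

        current = "ppi_disease"
        dis_net = build_seed_network(
            disease.merged_symbols, inputs.ppi, expansion=params["expansion"]
        )
        record(
            "ppi_disease",
            n_seeds=len(disease.merged_symbols),
            n_missing_seeds=len(dis_net.missing_seeds),
            n_isolated_seeds=len(dis_net.isolated_seeds),
            n_nodes=dis_net.network.n_nodes,
            n_edges=dis_net.network.n_edges,
        )

        current = "intersect"
        inter = intersect_networks(put_net.network, dis_net.network)
        record("intersect", n_nodes=inter.n_nodes, n_edges=inter.n_edges)
        if out is not None:
            netio.write_network(inter, out / "intersected_network.graphml", format="graphml")

        current = "stage1_filter"
        significant, thresholds1 = stage1_filter(inter)
        record(
            "stage1_filter",
            median_degree=thresholds1.stage1_median_degree,
            cut=thresholds1.stage1_cut,
            n_nodes=significant.n_nodes,
            n_edges=significant.n_edges,
        )
        if out is not None:
            netio.write_network(significant, out / "significant_network.graphml", format="graphml")

        current = "stage2_filter"
        candidates, thresholds, table = stage2_filter(significant, thresholds1)
        record(
            "stage2_filter",
            medians={k: v for k, v in sorted(thresholds.stage2_medians.items())},
            n_candidates=len(candidates),
        )
        if out is not None:
            netio.write_symbol_list(candidates, out / "candidate_targets.tsv")
            table.to_tsv(out / "centrality.tsv")
            (out / "thresholds.json").write_text(
                json.dumps(dataclasses.asdict(thresholds), indent=2, sort_keys=True)
            )

        current = "enrichment"
        universe = set(inputs.gene_sets.all_genes() & inter.nodes)
        query = set(candidates)
        results = hypergeom_enrich(
            query,
            inputs.gene_sets,
            universe,
            alpha=params["alpha"],
            by_category=params["bh_by_category"],
        )
        enriched = [r for r in results if r.enriched]
        groups = kappa_group_terms(
            enriched, inputs.gene_sets, universe, kappa_min=params["kappa_min"]
        )
        record(
            "enrichment",
            n_universe=len(universe),
            n_query_in_universe=len(query & universe),
            n_terms_tested=len(results),
            n_enriched=len(enriched),
            n_groups=len(groups),
        )
        if out is not None:
            _write_enrichment(results, groups, out)
    except Exception as exc:  # record the failing stage, then propagate
        raise PipelineError(current, str(exc)) from exc

    report = {
        "params": params,
        "stages": stages,
        "thresholds": dataclasses.asdict(thresholds),
        "candidates": sorted(candidates),
        "herb_target_sets": {
            h: len(s)
            for h, s in sorted(herb_target_sets(screen.kept_records, inputs.ct_map).items())
        },
    }
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return PipelineResult(
        report=report,
        candidates=candidates,
        thresholds=thresholds,
        significant_net=significant,
        intersected_net=inter,
        centrality_table=table,
        enrichment=results,
        groups=groups,
        inputs=inputs,
        screen=screen,
    )


def _write_screen(screen, out: Path) -> None:
    with (out / "kept_compounds.tsv").open("w", encoding="utf-8") as fh:
        fh.write("compound_id\tname\treason\n")
        for rec, reason in screen.kept:
            fh.write(f"{rec.compound_id}\t{rec.name}\t{reason}\n")
    with (out / "excluded_compounds.tsv").open("w", encoding="utf-8") as fh:
        fh.write("compound_id\tname\n")
        for rec in screen.excluded:
            fh.write(f"{rec.compound_id}\t{rec.name}\n")


def _write_disease(disease, shared, out: Path) -> None:
    with (out / "merged_disease_targets.tsv").open("w", encoding="utf-8") as fh:
        fh.write("symbol\tsources\n")
        for rec in disease.merged:
            fh.write(f"{rec.symbol}\t{'|'.join(sorted(rec.sources))}\n")
    netio.write_symbol_list(shared, out / "shared_targets.tsv")


def _write_enrichment(results, groups, out: Path) -> None:
    group_of: dict[str, int] = {}
    leading: set[str] = set()
    for gi, g in enumerate(groups, start=1):
        leading.add(g.leading_term)
        for t in g.members:
            group_of[t] = gi
    with (out / "enrichment.tsv").open("w", encoding="utf-8") as fh:
        fh.write("term_id\tcategory\tk\tK\tn\tN\tp\tp_adj\tenriched\tgroup\tleading\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.category}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p:.6g}\t{r.p_adj:.6g}\t{str(r.enriched).lower()}\t"
                f"{group_of.get(r.term_id, '')}\t{str(r.term_id in leading).lower()}\n"
            )
    (out / "term_groups.json").write_text(
        json.dumps(
            [
                {
                    "members": list(g.members),
                    "leading_term": g.leading_term,
                    "links": [[a, b, round(k, 6)] for a, b, k in g.links],
                }
                for g in groups
            ],
            indent=2,
        )
    )


def explain_thresholds(report: dict) -> list[dict]:
    """One row per cutoff the run applied, with its provenance."""
    params = report["params"]
    rows = [
        {"threshold": "ob_min", "value": params["ob_min"], "provenance": "config"},
        {"threshold": "dl_min", "value": params["dl_min"], "provenance": "config"},
        {"threshold": "ob_min_no_dl", "value": params["ob_min_no_dl"], "provenance": "config"},
        {
            "threshold": "stage1_cut (2 x median degree)",
            "value": report["thresholds"]["stage1_cut"],
            "provenance": "computed-median",
        },
    ]
    for m, v in sorted(report["thresholds"]["stage2_medians"].items()):
        rows.append(
            {"threshold": f"stage2_median_{m}", "value": v, "provenance": "computed-median"}
        )
    rows.append({"threshold": "alpha", "value": params["alpha"], "provenance": "config"})
    rows.append({"threshold": "kappa_min", "value": params["kappa_min"], "provenance": "config"})
    return rows


def format_thresholds(rows: list[dict]) -> str:
    width = max(len(r["threshold"]) for r in rows)
    lines = [f"{'threshold':<{width}}  value       provenance"]
    for r in rows:
        val = r["value"]
        sval = f"{val:.6g}" if isinstance(val, float) else str(val)
        lines.append(f"{r['threshold']:<{width}}  {sval:<10}  {r['provenance']}")
    return "\n".join(lines)
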