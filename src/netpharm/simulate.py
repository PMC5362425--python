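"""Synthetic input bundles with known ground truth.

The generator emulates the statistical shape of a real herbal-formula
target-identification study so the full pipeline can be exercised and
verified without any database export:

- a compound table spread over several herbs with cross-herb sharing, OB
  and DL values sampled from configurable distributions, a fraction of
  missing DL predictions, and a small literature-rescue whitelist;
- a hub-skewed compound→target map (a few promiscuous compounds hit many
  targets, most hit few);
- a scale-free (preferential-attachment) background PPI graph with a
  dense module planted on its highest-degree nodes — the "true targets".
  Disease proteins concentrate on network hubs, and planting the module
  there puts it in the regime the hub-seeking two-stage filter assumes;
- several overlapping disease-target source lists enriched for the module;
- a GMT annotation file with terms planted inside the module plus random
  background terms.

Everything is driven by one integer seed; the same config yields
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .netio import (
    write_compound_table,
    write_ct_map,
    write_gmt,
    write_network,
    write_symbol_list,
)
from .records import (
    CATEGORY_MFBP,
    CATEGORY_PATHWAY,
    CompoundRecord,
    GeneSetCollection,
    GeneSetTerm,
)
from .networks import PPINetwork

DISEASE_SOURCE_NAMES = ("DRUGBANK", "OMIM", "GAD", "KEGG", "TTD")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs. Defaults define the standard benchmark bundle."""

    seed: int = 42
    # compound table
    n_herbs: int = 8
    compounds_per_herb: int = 20
    herb_sharing_prob: float = 0.15
    ob_distribution: tuple = ("uniform", (0.0, 80.0))  # percent
    dl_distribution: tuple = ("beta", (2.0, 4.0))  # unitless in [0, 1]
    missing_dl_fraction: float = 0.05
    n_rescued: int = 4
    # compound -> target map
    n_targets: int = 120
    bipartite_attachment_exponent: float = 1.0
    unmapped_fraction: float = 0.15
    mean_targets_per_compound: float = 11.0
    # background PPI with planted module
    ppi_n_nodes: int = 300
    ppi_attachment_m: int = 3
    planted_module_size: int = 15
    planted_module_density: float = 0.9
    # disease-target sources
    n_disease_sources: int = 5
    disease_source_sizes: tuple = (10, 10, 60, 25, 15)
    disease_overlap_with_module: float = 0.8
    # annotations
    n_terms: int = 30
    planted_term_count: int = 3

    def validate(self) -> None:
        sizes = (
            self.n_herbs, self.compounds_per_herb, self.n_rescued, self.n_targets,
            self.ppi_n_nodes, self.ppi_attachment_m, self.planted_module_size,
            self.n_disease_sources, self.n_terms, self.planted_term_count,
        )
        if any(s < 0 for s in sizes):
            raise ValueError("all sizes must be >= 0")
        probs = (
            self.herb_sharing_prob, self.missing_dl_fraction, self.unmapped_fraction,
            self.planted_module_density, self.disease_overlap_with_module,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.planted_module_size > self.ppi_n_nodes:
            raise ValueError("planted module larger than the PPI graph")
        if self.n_targets > self.ppi_n_nodes:
            raise ValueError("target universe larger than the PPI graph")
        if self.ppi_n_nodes and self.ppi_attachment_m >= self.ppi_n_nodes:
            raise ValueError("attachment parameter m must be < ppi_n_nodes")


@dataclass
class GroundTruthManifest:
    true_threshold_survivors: frozenset[str]
    planted_module: frozenset[str]
    planted_terms: frozenset[str]
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "true_threshold_survivors": sorted(self.true_threshold_survivors),
            "planted_module": sorted(self.planted_module),
            "planted_terms": sorted(self.planted_terms),
            "params": self.params,
        }


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    compounds: list[CompoundRecord]
    whitelist: frozenset[str]
    ct_map: dict[str, set[str]]
    ppi: PPINetwork
    disease_lists: dict[str, list[str]]
    gene_sets: GeneSetCollection
    manifest: GroundTruthManifest

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the bundle in the exact formats the readers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "compounds": out / "compounds.tsv",
            "whitelist": out / "whitelist.txt",
            "ct_map": out / "ct_map.tsv",
            "ppi": out / "ppi_edges.sif",
            "gene_sets": out / "gene_sets.gmt",
            "manifest": out / "manifest.json",
        }
        write_compound_table(self.compounds, paths["compounds"])
        with paths["whitelist"].open("w", encoding="utf-8") as fh:
            fh.write("# literature-rescue whitelist (synthetic)\n")
            for cid in sorted(self.whitelist):
                fh.write(f"{cid}\n")
        write_ct_map(self.ct_map, paths["ct_map"])
        write_network(self.ppi, paths["ppi"], format="sif")
        write_gmt(self.gene_sets, paths["gene_sets"])
        for src, symbols in self.disease_lists.items():
            p = out / f"disease_{src}.tsv"
            write_symbol_list(symbols, p)
            paths[f"disease_{src}"] = p
        with paths["manifest"].open("w", encoding="utf-8") as fh:
            json.dump(self.manifest.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _sample(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    family, params = dist
    if family == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size)
    if family == "beta":
        a, b = params
        return rng.beta(a, b, size)
    if family == "constant":
        return np.full(size, float(params[0]))
    raise ValueError(f"unknown distribution family {family!r}")


def _weighted_sample_without_replacement(
    rng: np.random.Generator, items: list[str], weights: np.ndarray, k: int
) -> list[str]:
    """Efraimidis-Spirakis reservoir keys; deterministic given the rng state."""
    k = min(k, len(items))
    keys = rng.random(len(items)) ** (1.0 / weights)
    order = np.argsort(-keys)
    return [items[i] for i in order[:k]]


def _passes_screen(rec: CompoundRecord, whitelist: frozenset[str]) -> bool:
    # the generator's own straightforward reading of the screening rules
    if rec.dl is not None and rec.ob is not None and rec.ob >= 30.0 and rec.dl >= 0.18:
        return True
    if rec.dl is None and rec.ob is not None and rec.ob >= 35.0:
        return True
    return rec.compound_id in whitelist


def simulate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate a complete, internally consistent input bundle."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- background PPI: preferential attachment + planted dense module ---
    base = nx.barabasi_albert_graph(cfg.ppi_n_nodes, cfg.ppi_attachment_m, seed=int(cfg.seed))
    name = {i: f"G{i:04d}" for i in base.nodes()}
    degree = dict(base.degree())
    by_degree = sorted(base.nodes(), key=lambda i: (-degree[i], i))
    module_idx = by_degree[: cfg.planted_module_size]
    module = frozenset(name[i] for i in module_idx)
    edges = {(name[u], name[v]) for u, v in base.edges()}
    for pos, u in enumerate(module_idx):
        for v in module_idx[pos + 1:]:
            if rng.random() < cfg.planted_module_density:
                edges.add((name[u], name[v]))
    ppi = PPINetwork.from_edges(edges, extra_nodes=name.values())
    ppi_degree = ppi.degree()

    # --- target universe: the module plus degree-weighted background genes ---
    background = sorted(ppi.nodes - module)
    n_extra = max(0, cfg.n_targets - len(module))
    weights = np.array(
        [ (ppi_degree[g] + 1.0) ** cfg.bipartite_attachment_exponent for g in background ]
    )
    extra = _weighted_sample_without_replacement(rng, background, weights, n_extra)
    target_universe = sorted(module | set(extra))
    tu_weights = np.array(
        [ (ppi_degree[g] + 1.0) ** cfg.bipartite_attachment_exponent for g in target_universe ]
    )

    # --- compound table ---
    herbs = [f"H{j + 1}" for j in range(cfg.n_herbs)]
    n_compounds = cfg.n_herbs * cfg.compounds_per_herb
    ob = _sample(rng, cfg.ob_distribution, n_compounds)
    dl = _sample(rng, cfg.dl_distribution, n_compounds)
    dl_missing = rng.random(n_compounds) < cfg.missing_dl_fraction
    records: list[CompoundRecord] = []
    idx = 0
    for j, herb in enumerate(herbs):
        for _ in range(cfg.compounds_per_herb):
            membership = {herb}
            while len(membership) < cfg.n_herbs and rng.random() < cfg.herb_sharing_prob:
                membership.add(herbs[int(rng.integers(cfg.n_herbs))])
            records.append(
                CompoundRecord(
                    compound_id=f"C{idx + 1:03d}",
                    name=f"compound-{idx + 1:03d}",
                    herbs=frozenset(membership),
                    ob=round(float(ob[idx]), 4),
                    dl=None if dl_missing[idx] else round(float(dl[idx]), 4),
                )
            )
            idx += 1

    # literature rescue: whitelist a few compounds that fail both rules
    failing = [r for r in records if not _passes_screen(r, frozenset())]
    n_rescue = min(cfg.n_rescued, len(failing))
    rescue_pick = sorted(
        _weighted_sample_without_replacement(
            rng, [r.compound_id for r in failing], np.ones(len(failing)), n_rescue
        )
    )
    whitelist = frozenset(rescue_pick)
    records = [
        dataclasses.replace(
            r, rescued=True, rescue_note="documented activity; retained despite screen (synthetic)"
        )
        if r.compound_id in whitelist
        else r
        for r in records
    ]
    survivors = [r for r in records if _passes_screen(r, whitelist)]

    # --- hub-skewed compound -> target map for the surviving compounds ---
    p_geom = min(1.0, 1.0 / cfg.mean_targets_per_compound)
    ct_map: dict[str, set[str]] = {}
    for rec in survivors:
        if rng.random() < cfg.unmapped_fraction:
            continue
        n_t = int(rng.geometric(p_geom))
        chosen = _weighted_sample_without_replacement(rng, target_universe, tu_weights, n_t)
        ct_map[rec.compound_id] = set(chosen)

    # --- disease-target source lists, enriched for the module ---
    n_src = cfg.n_disease_sources
    src_names = [
        DISEASE_SOURCE_NAMES[i] if i < len(DISEASE_SOURCE_NAMES) else f"SRC{i + 1}"
        for i in range(n_src)
    ]
    sizes = [
        cfg.disease_source_sizes[i % len(cfg.disease_source_sizes)] for i in range(n_src)
    ]
    bg_weights = np.array([ppi_degree[g] + 1.0 for g in background])
    disease_lists: dict[str, list[str]] = {}
    for src, size in zip(src_names, sizes):
        picked = {
            g for g in sorted(module) if rng.random() < cfg.disease_overlap_with_module
        }
        n_fill = max(0, size - len(picked))
        picked |= set(_weighted_sample_without_replacement(rng, background, bg_weights, n_fill))
        disease_lists[src] = sorted(picked)

    # --- gene-set annotations: planted module terms + random background ---
    gene_sets = GeneSetCollection()
    module_sorted = sorted(module)
    planted_ids = []
    for t in range(cfg.planted_term_count):
        size = max(3, min(10, len(module_sorted)))
        genes = set(
            _weighted_sample_without_replacement(
                rng, module_sorted, np.ones(len(module_sorted)), size
            )
        )
        # one background gene per planted term keeps terms imperfect
        genes |= set(_weighted_sample_without_replacement(rng, background, bg_weights, 1))
        tid = f"PT{t + 1:02d}"
        planted_ids.append(tid)
        cat = CATEGORY_PATHWAY if t % 2 == 0 else CATEGORY_MFBP
        gene_sets.add(GeneSetTerm(tid, f"planted module process {t + 1}", cat, frozenset(genes)))
    all_nodes = sorted(ppi.nodes)
    for t in range(cfg.n_terms):
        size = int(rng.integers(8, 31))
        genes = frozenset(
            _weighted_sample_without_replacement(rng, all_nodes, np.ones(len(all_nodes)), size)
        )
        cat = CATEGORY_PATHWAY if t % 2 == 0 else CATEGORY_MFBP
        gene_sets.add(GeneSetTerm(f"T{t + 1:03d}", f"background process {t + 1}", cat, genes))

    manifest = GroundTruthManifest(
        true_threshold_survivors=frozenset(r.compound_id for r in survivors),
        planted_module=module,
        planted_terms=frozenset(planted_ids),
        params={
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
    )
    return SyntheticBundle(
        config=cfg,
        compounds=records,
        whitelist=whitelist,
        ct_map=ct_map,
        ppi=ppi,
        disease_lists=disease_lists,
        gene_sets=gene_sets,
        manifest=manifest,
    )


def recount_oracle(bundle: SyntheticBundle) -> dict:
    """Naive independent recount of every headline statistic.

    Deliberately avoids the pipeline modules: plain loops and set algebra
    over the bundle's raw content, usable as an equivalence oracle.
    """
    kept_ids = set()
    for rec in bundle.compounds:
        ok = False
        if rec.ob is not None and rec.dl is not None:
            ok = rec.ob >= 30.0 and rec.dl >= 0.18
        if not ok and rec.dl is None and rec.ob is not None:
            ok = rec.ob >= 35.0
        if not ok:
            ok = rec.compound_id in bundle.whitelist
        if ok:
            kept_ids.add(rec.compound_id)

    per_herb: dict[str, int] = {}
    for rec in bundle.compounds:
        if rec.compound_id in kept_ids:
            for h in rec.herbs:
                per_herb[h] = per_herb.get(h, 0) + 1

    mapped = {c: ts for c, ts in bundle.ct_map.items() if c in kept_ids and ts}
    putative = set()
    n_edges = 0
    for ts in mapped.values():
        putative |= set(ts)
        n_edges += len(set(ts))

    merged_disease = set()
    for symbols in bundle.disease_lists.values():
        merged_disease |= {s.strip().upper() for s in symbols}

    # seed-expanded networks by raw adjacency scan
    adjacency: dict[str, set[str]] = {n: set() for n in bundle.ppi.nodes}
    for u, v in bundle.ppi.edges:
        adjacency[u].add(v)
        adjacency[v].add(u)

    def seed_net(seeds: set[str]) -> tuple[set[str], set[frozenset]]:
        present = {s for s in seeds if s in adjacency and adjacency[s]}
        nodes = set(present)
        for s in present:
            nodes |= adjacency[s]
        edges = {
            frozenset((u, v))
            for u in nodes
            for v in adjacency[u]
            if v in nodes
        }
        return nodes, edges

    put_nodes, put_edges = seed_net(putative)
    dis_nodes, dis_edges = seed_net(merged_disease)

    return {
        "n_compounds": len(bundle.compounds),
        "n_kept": len(kept_ids),
        "kept_ids": sorted(kept_ids),
        "per_herb_counts": per_herb,
        "n_mapped_compounds": len(mapped),
        "n_unmapped_kept": len(kept_ids) - len(mapped),
        "n_putative_targets": len(putative),
        "n_ct_edges": n_edges,
        "n_merged_disease": len(merged_disease),
        "n_overlap": len(putative & merged_disease),
        "putative_net_nodes": len(put_nodes),
        "putative_net_edges": len(put_edges),
        "disease_net_nodes": len(dis_nodes),
        "disease_net_edges": len(dis_edges),
        "intersection_nodes": len(put_nodes & dis_nodes),
        "intersection_edges": len(put_edges & dis_edges),
    }
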