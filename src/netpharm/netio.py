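"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: TSV tables with a header row (UTF-8), SIF interaction lines with
the relation token ``interacts``, GraphML, GMT gene-set files, and
one-symbol-per-line lists. Every writer has a reader that round-trips the
node/edge or record content exactly.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .records import (
    CATEGORIES,
    CATEGORY_OTHER,
    CompoundRecord,
    GeneSetCollection,
    GeneSetTerm,
    normalize_symbol,
)
from .networks import BipartiteNetwork, PPINetwork

log = logging.getLogger(__name__)

SIF_RELATION = "interacts"
NETWORK_FORMATS = ("sif", "graphml", "tsv")

COMPOUND_COLUMNS = ("compound_id", "name", "herbs", "ob", "dl", "rescued", "rescue_note")


class TableFormatError(ValueError):
    """A file-level format violation (missing column, bad header, ...)."""


class RowError(ValueError):
    """A row/line-level parse failure; message carries the 1-based location."""


def _parse_optional_float(cell: str, column: str, row_index: int) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise RowError(f"row {row_index}: non-numeric {column} value {cell!r}") from None


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound TSV into records, preserving row order.

    Expected header columns: compound_id, name, herbs (semicolon-separated),
    ob, dl, rescued, rescue_note. Empty ob/dl cells mean "absent".
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in COMPOUND_COLUMNS:
            if col not in header:
                raise TableFormatError(f"{path.name}: missing mandatory column {col!r}")
        records: list[CompoundRecord] = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            herbs = frozenset(h.strip() for h in row["herbs"].split(";") if h.strip())
            if not herbs:
                raise RowError(f"row {i}: empty herbs cell")
            records.append(
                CompoundRecord(
                    compound_id=row["compound_id"].strip(),
                    name=row["name"].strip(),
                    herbs=herbs,
                    ob=_parse_optional_float(row["ob"], "ob", i),
                    dl=_parse_optional_float(row["dl"], "dl", i),
                    rescued=row["rescued"].strip().lower() in ("true", "1", "yes"),
                    rescue_note=row["rescue_note"].strip(),
                )
            )
    return records


def write_compound_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COMPOUND_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.compound_id,
                    r.name,
                    ";".join(sorted(r.herbs)),
                    "" if r.ob is None else f"{r.ob:.4f}",
                    "" if r.dl is None else f"{r.dl:.4f}",
                    "true" if r.rescued else "false",
                    r.rescue_note,
                ]
            )


def read_ppi_edges(path: str | Path) -> PPINetwork:
    """Read a PPI edge list (2-column TSV or SIF) into a simple graph.

    Symbols are normalized on read; self-loops are dropped (count logged);
    duplicate pairs collapse. An empty file yields an empty network.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    nodes: set[str] = set()
    dropped_loops = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and [f.lower() for f in fields[:2]] in (
                ["source", "target"],
                ["node_a", "node_b"],
                ["symbol_a", "symbol_b"],
            ):
                continue  # optional header row
            if len(fields) == 2:
                a, b = fields
            elif len(fields) == 3:
                a, _rel, b = fields
            else:
                raise RowError(f"{path.name}: malformed line {lineno}: {line!r}")
            a, b = normalize_symbol(a), normalize_symbol(b)
            nodes.add(a)
            nodes.add(b)
            if a == b:
                dropped_loops += 1
                continue
            edges.append((a, b))
    if dropped_loops:
        log.info("read_ppi_edges(%s): dropped %d self-loop(s)", path.name, dropped_loops)
    return PPINetwork.from_edges(edges, extra_nodes=nodes)


def write_network(
    net: PPINetwork | BipartiteNetwork, path: str | Path, format: str = "sif"
) -> None:
    """Write a network as SIF, GraphML, or a 2-column TSV edge list.

    Round-trip guarantee: :func:`read_network` on the written file
    reconstructs identical node and edge sets. Isolated nodes survive only
    GraphML (SIF/TSV are edge lists; isolated nodes are appended as
    single-token lines in SIF, the SIF convention for orphan nodes).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown format {format!r}; supported: {', '.join(NETWORK_FORMATS)}")
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
        return
    if isinstance(net, BipartiteNetwork):
        pairs = sorted(net.edges)
        connected = {c for c, _ in pairs} | {t for _, t in pairs}
        isolated = sorted((net.compound_nodes | net.target_nodes) - connected)
    else:
        pairs = sorted(net.edges)
        connected = {u for e in pairs for u in e}
        isolated = sorted(net.nodes - connected)
    with path.open("w", encoding="utf-8") as fh:
        if fmt == "tsv":
            fh.write("source\ttarget\n")
            for u, v in pairs:
                fh.write(f"{u}\t{v}\n")
        else:
            for u, v in pairs:
                fh.write(f"{u}\t{SIF_RELATION}\t{v}\n")
            for n in isolated:
                fh.write(f"{n}\n")


def read_network(path: str | Path, format: str = "sif", bipartite: bool = False):
    """Inverse of :func:`write_network`; set ``bipartite=True`` to recover
    a :class:`BipartiteNetwork` from GraphML role attributes."""
    path = Path(path)
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown format {format!r}; supported: {', '.join(NETWORK_FORMATS)}")
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return BipartiteNetwork.from_networkx(g) if bipartite else PPINetwork.from_networkx(g)
    edges: list[tuple[str, str]] = []
    nodes: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").strip()
            if not line:
                continue
            fields = line.split("\t")
            if fmt == "tsv" and lineno == 1 and fields[:2] == ["source", "target"]:
                continue
            if len(fields) == 1 and fmt == "sif":
                nodes.add(fields[0])
            elif len(fields) == 2 and fmt == "tsv":
                edges.append((fields[0], fields[1]))
            elif len(fields) == 3 and fmt == "sif":
                edges.append((fields[0], fields[2]))
            else:
                raise RowError(f"{path.name}: malformed line {lineno}: {line!r}")
    if bipartite:
        return BipartiteNetwork.from_edges(edges, compounds=(), targets=())
    return PPINetwork.from_edges(edges, extra_nodes=nodes)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file.

    Each line: ``term_id TAB description TAB gene ...``. A category suffix
    may ride on the description after a ``|`` (e.g.
    ``apoptosis|signaling_pathway``); without one the term is "other".
    Duplicate genes within a term collapse; duplicate term ids are an error.
    """
    path = Path(path)
    collection = GeneSetCollection()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RowError(f"{path.name}: line {lineno}: expected >= 3 fields")
            term_id, description = fields[0], fields[1]
            category = CATEGORY_OTHER
            if "|" in description:
                description, suffix = description.rsplit("|", 1)
                if suffix in CATEGORIES:
                    category = suffix
                else:
                    description = f"{description}|{suffix}"
            genes = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
            if term_id in collection:
                raise TableFormatError(f"{path.name}: duplicate term id {term_id!r}")
            collection.add(GeneSetTerm(term_id, description, category, genes))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for term_id in sorted(collection.terms):
            term = collection[term_id]
            desc = f"{term.description}|{term.category}"
            genes = "\t".join(sorted(term.genes))
            fh.write(f"{term.term_id}\t{desc}\t{genes}\n")


def read_whitelist(path: str | Path) -> frozenset[str]:
    """One compound id per line; ``#`` comments and blank lines ignored."""
    ids: set[str] = set()
    with Path(path).open(encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                ids.add(line)
    return frozenset(ids)


def read_symbol_list(path: str | Path) -> list[str]:
    """Read a one-column TSV of gene symbols (header ``symbol`` optional).

    Returns raw symbols in file order; normalization is the consumer's job
    (merging keeps provenance of pre-normalization duplicates).
    """
    out: list[str] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").strip()
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower() == "symbol":
                continue
            out.append(line)
    return out


def write_symbol_list(symbols: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("symbol\n")
        for s in sorted(symbols):
            fh.write(f"{s}\n")


def read_ct_map(path: str | Path) -> dict[str, set[str]]:
    """Read a compound→target map: 2-column TSV (compound_id, symbol)."""
    mapping: dict[str, set[str]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise RowError(f"{Path(path).name}: line {lineno}: expected 2 fields")
            if lineno == 1 and [f.lower() for f in fields] == ["compound_id", "target"]:
                continue
            cid, sym = fields[0].strip(), normalize_symbol(fields[1])
            mapping.setdefault(cid, set()).add(sym)
    return mapping


def write_ct_map(mapping: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("compound_id\ttarget\n")
        for cid in sorted(mapping):
            for sym in sorted(mapping[cid]):
                fh.write(f"{cid}\t{sym}\n")
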