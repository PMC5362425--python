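"""Merging disease-target lists from multiple sources with provenance."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .records import TargetRecord, normalize_symbol


@dataclass
class DiseaseTargetSet:
    """Per-source symbol sets plus the deduplicated union with provenance."""

    by_source: dict[str, frozenset[str]]
    merged: list[TargetRecord]

    @property
    def merged_symbols(self) -> frozenset[str]:
        return frozenset(r.symbol for r in self.merged)


def merge_disease_targets(lists: Mapping[str, Iterable[str]]) -> DiseaseTargetSet:
    """Normalize, union, and deduplicate disease-target lists.

    Each merged record carries exactly the set of sources that contained
    its symbol. Merging is order-independent and idempotent; an empty
    union is an error.
    """
    by_source = {
        src: frozenset(normalize_symbol(s) for s in symbols if s.strip())
        for src, symbols in lists.items()
    }
    union: dict[str, set[str]] = {}
    for src, symbols in by_source.items():
        for sym in symbols:
            union.setdefault(sym, set()).add(src)
    if not union:
        raise ValueError("no disease targets: all source lists empty")
    merged = [
        TargetRecord(symbol=sym, sources=frozenset(srcs))
        for sym, srcs in sorted(union.items())
    ]
    return DiseaseTargetSet(by_source=by_source, merged=merged)


def overlap_targets(putative: Iterable[str], disease: DiseaseTargetSet) -> frozenset[str]:
    """Symbols shared between the putative-target set and the merged
    disease-target set (both normalized first)."""
    put = frozenset(normalize_symbol(s) for s in putative)
    return put & disease.merged_symbols
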