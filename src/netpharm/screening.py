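"""ADME screening of herbal compounds by oral bioavailability and drug-likeness.

A compound passes when OB >= 30% and DL >= 0.18 (the TCMSP-convention
thresholds, inclusive). Compounds lacking a DL prediction pass on OB alone
at a stricter 35% floor. A literature whitelist rescues compounds that fail
both rules but have documented pharmacological activity.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .records import CompoundRecord

log = logging.getLogger(__name__)

REASON_THRESHOLD = "threshold"
REASON_NO_DL = "no_dl_rule"
REASON_RESCUED = "rescued"


@dataclass
class ScreenResult:
    """Partition of the input table into kept (with reason) and excluded."""

    kept: list[tuple[CompoundRecord, str]]
    excluded: list[CompoundRecord]
    per_herb_counts: dict[str, int] = field(default_factory=dict)

    @property
    def kept_records(self) -> list[CompoundRecord]:
        return [r for r, _ in self.kept]

    @property
    def kept_ids(self) -> frozenset[str]:
        return frozenset(r.compound_id for r, _ in self.kept)


def screen_compounds(
    records: Sequence[CompoundRecord],
    ob_min: float = 30.0,
    dl_min: float = 0.18,
    ob_min_no_dl: float = 35.0,
    whitelist: Iterable[str] = (),
) -> ScreenResult:
    """Partition compounds into kept and excluded.

    Keep rules, applied in order, first match recorded as the reason:

    1. ``threshold`` — DL present, OB >= ob_min and DL >= dl_min.
    2. ``no_dl_rule`` — DL absent, OB present and OB >= ob_min_no_dl.
    3. ``rescued`` — compound id is whitelisted (kept regardless of values).

    Whitelist ids that match no input record are logged, not fatal.
    A record missing both OB and DL is excluded unless whitelisted.
    """
    if min(ob_min, dl_min, ob_min_no_dl) < 0:
        raise ValueError("screening thresholds must be >= 0")
    wl = set(whitelist)
    known_ids = {r.compound_id for r in records}
    stray = wl - known_ids
    if stray:
        log.warning("whitelist ids absent from input: %s", ", ".join(sorted(stray)))

    kept: list[tuple[CompoundRecord, str]] = []
    excluded: list[CompoundRecord] = []
    for rec in records:
        if rec.dl is not None and rec.ob is not None and rec.ob >= ob_min and rec.dl >= dl_min:
            kept.append((rec, REASON_THRESHOLD))
        elif rec.dl is None and rec.ob is not None and rec.ob >= ob_min_no_dl:
            kept.append((rec, REASON_NO_DL))
        elif rec.compound_id in wl:
            kept.append((rec, REASON_RESCUED))
        else:
            if rec.ob is None and rec.dl is None:
                log.warning(
                    "compound %s has neither OB nor DL and is not whitelisted; excluded",
                    rec.compound_id,
                )
            excluded.append(rec)

    result = ScreenResult(kept=kept, excluded=excluded)
    result.per_herb_counts = per_herb_summary(result)
    return result


def per_herb_summary(result: ScreenResult) -> dict[str, int]:
    """Count kept compounds per herb.

    A compound in several herbs counts once in each, so the column sum is
    at least the number of kept compounds — matching how multi-herb
    formulas report per-herb contributions.
    """
    counts: Counter[str] = Counter()
    for rec, _ in result.kept:
        counts.update(rec.herbs)
    return dict(counts)


def herb_target_sets(
    kept: Sequence[CompoundRecord], ct_map: Mapping[str, Iterable[str]]
) -> dict[str, frozenset[str]]:
    """Per-herb putative target sets: the union of targets of kept compounds
    containing that herb (herbs share compounds, so these overlap heavily)."""
    out: dict[str, set[str]] = {}
    for rec in kept:
        targets = set(ct_map.get(rec.compound_id, ()))
        for herb in rec.herbs:
            out.setdefault(herb, set()).update(targets)
    return {h: frozenset(s) for h, s in out.items()}
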