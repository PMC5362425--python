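"""Core domain records shared by every pipeline stage.

The pipeline operates on three kinds of entities: chemical compounds
(annotated with oral bioavailability and drug-likeness), protein targets
(normalized gene symbols with source provenance), and gene-set annotation
terms used for enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: whitespace-trimmed and upper-cased.

    Idempotent by construction; no alias mapping is attempted (identifier
    reconciliation across databases is out of scope for this pipeline).
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class CompoundRecord:
    """One chemical, with its herb memberships and screening annotations.

    Parameters
    ----------
    compound_id : opaque identifier, unique within a table.
    name : human-readable compound name.
    herbs : non-empty set of herb identifiers the compound occurs in
        (herbal formulas share many constituents across herbs).
    ob : predicted oral bioavailability in percent, ``None`` when the
        prediction is unavailable.
    dl : drug-likeness index in [0, 1], ``None`` when unavailable.
    rescued : literature-rescue flag; a rescued compound must carry a
        non-empty ``rescue_note`` justifying its retention.
    """

    compound_id: str
    name: str
    herbs: frozenset[str]
    ob: float | None = None
    dl: float | None = None
    rescued: bool = False
    rescue_note: str = ""

    def __post_init__(self) -> None:
        if not self.herbs:
            raise ValueError(f"compound {self.compound_id!r}: herbs must be non-empty")
        if self.ob is not None and self.ob < 0:
            raise ValueError(f"compound {self.compound_id!r}: ob must be >= 0")
        if self.dl is not None and not (0.0 <= self.dl <= 1.0):
            raise ValueError(f"compound {self.compound_id!r}: dl must lie in [0, 1]")
        if self.rescued and not self.rescue_note:
            raise ValueError(
                f"compound {self.compound_id!r}: rescued records need a rescue_note"
            )


@dataclass(frozen=True)
class TargetRecord:
    """A disease-associated protein target with source provenance."""

    symbol: str
    sources: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.symbol != normalize_symbol(self.symbol):
            raise ValueError(f"symbol {self.symbol!r} is not in normalized form")


#: Enrichment term categories. Annotation vocabularies are split into
#: molecular-function/biological-process terms and signaling pathways;
#: anything else falls into "other".
CATEGORY_MFBP = "molecular_function_biological_process"
CATEGORY_PATHWAY = "signaling_pathway"
CATEGORY_OTHER = "other"
CATEGORIES = (CATEGORY_MFBP, CATEGORY_PATHWAY, CATEGORY_OTHER)


@dataclass(frozen=True)
class GeneSetTerm:
    term_id: str
    description: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id!r}: gene set must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(f"term {self.term_id!r}: unknown category {self.category!r}")


@dataclass
class GeneSetCollection:
    """A GMT-style collection of annotation terms keyed by term id."""

    terms: dict[str, GeneSetTerm] = field(default_factory=dict)

    def add(self, term: GeneSetTerm) -> None:
        if term.term_id in self.terms:
            raise ValueError(f"duplicate term id {term.term_id!r}")
        self.terms[term.term_id] = term

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __getitem__(self, term_id: str) -> GeneSetTerm:
        return self.terms[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for term in self.terms.values():
            out |= term.genes
        return frozenset(out)
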