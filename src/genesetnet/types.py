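"""Domain types shared across all pipeline stages.

Records are plain frozen dataclasses; tabular collections of them are carried
as lists (or pandas DataFrames at the I/O boundary, see :mod:`genesetnet.tables`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence


class GenesetnetError(Exception):
    """Base class for all package errors."""


@dataclass(frozen=True)
class Gene:
    """A gene identified by an opaque string id within one organism."""

    gene_id: str
    taxon: str = "human"
    symbol: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


class GeneList:
    """A named, ordered, duplicate-free list of gene identifiers.

    Order is preserved from the input; duplicates are removed keeping the
    first occurrence and the number dropped is recorded.
    """

    def __init__(self, name: str, members: Sequence[str], taxon: str = "human"):
        seen: dict[str, None] = {}
        dropped = 0
        for m in members:
            if m in seen:
                dropped += 1
            else:
                seen[m] = None
        self.name = name
        self.members: list[str] = list(seen)
        self.taxon = taxon
        self.n_duplicates_dropped = dropped

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: object) -> bool:
        return gene_id in set(self.members)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneList):
            return NotImplemented
        return (self.name, self.members, self.taxon) == (
            other.name,
            other.members,
            other.taxon,
        )

    def __repr__(self) -> str:
        return f"GeneList({self.name!r}, n={len(self)}, taxon={self.taxon!r})"


#: category tags accepted for annotation themes
THEME_CATEGORIES = ("pathway", "go", "go_slim", "ipc", "custom")


@dataclass
class Theme:
    theme_id: str
    theme_name: str
    category: str
    genes: set[str]


class AnnotationSet:
    """Mapping from biological themes (pathways, GO slim terms, IPC clusters)
    to the sets of genes annotated with them; defines the enrichment universe.
    """

    def __init__(self, themes: Mapping[str, Theme] | Sequence[Theme]):
        if not isinstance(themes, Mapping):
            themes = {t.theme_id: t for t in themes}
        for t in themes.values():
            if not t.genes:
                raise ValueError(f"theme {t.theme_id!r} has no genes")
            if t.category not in THEME_CATEGORIES:
                raise ValueError(f"unknown category {t.category!r}")
        self.themes: dict[str, Theme] = dict(themes)

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[str, str, str]], category: str = "custom"
    ) -> "AnnotationSet":
        """Build from (theme_id, theme_name, gene_id) triples."""
        themes: dict[str, Theme] = {}
        for theme_id, theme_name, gene_id in pairs:
            t = themes.setdefault(theme_id, Theme(theme_id, theme_name, category, set()))
            t.genes.add(gene_id)
        return cls(themes)

    @property
    def universe(self) -> set[str]:
        """All genes carrying at least one theme annotation."""
        out: set[str] = set()
        for t in self.themes.values():
            out |= t.genes
        return out

    def __len__(self) -> int:
        return len(self.themes)

    def __iter__(self) -> Iterator[Theme]:
        return iter(self.themes.values())


@dataclass(frozen=True)
class ExpressionRecord:
    """One Barcode expression score: the fraction of samples of a tissue
    (on one microarray platform) in which the gene was judged expressed."""

    gene_id: str
    tissue: str
    platform: str
    barcode_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.barcode_score <= 1.0:
            raise ValueError(
                f"barcode_score {self.barcode_score} outside [0, 1] "
                f"for gene {self.gene_id}"
            )


@dataclass(frozen=True)
class MTIRecord:
    """A miRNA→target-gene interaction with its evidence class."""

    mirna_id: str
    gene_id: str
    evidence_class: str
    pmid: str = ""


@dataclass(frozen=True)
class TFTargetRecord:
    """A transcription-factor→target-gene regulatory edge."""

    tf_gene_id: str
    target_gene_id: str
    source_db: str


@dataclass(frozen=True)
class AlignmentHit:
    """One similarity-search hit between proteomes of two organisms."""

    query_id: str
    subject_id: str
    evalue: float
    query_taxon: str
    subject_taxon: str

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.query_taxon == self.subject_taxon:
            raise ValueError("query and subject taxa must differ")


@dataclass(frozen=True)
class OrthologuePair:
    """A mutual-best-hit orthologue pair between two organisms."""

    id_a: str
    id_b: str
    taxon_a: str
    taxon_b: str
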