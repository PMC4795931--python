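"""Merging PPI evidence from multiple source databases and classifying
high-confidence and high-confidence direct-physical interaction subsets.

Interactions are stored as unordered gene–gene pairs.  A pair is
*high-confidence* when supported by at least two distinct experimental
methods or at least two independent publications.  The *direct-physical*
subset additionally requires the pair to be (i) annotated as a direct
physical interaction by a source repository, or (ii) detected by at least
one method capable of detecting direct physical contact (yeast two-hybrid,
FRET, atomic force microscopy, ...); the capable-method list is a
user-editable whitelist shipped as package data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered unordered pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PPIEvidence:
    """One experimental support item for a gene–gene interaction."""

    gene_a: str
    gene_b: str
    method_id: str
    pmid: str
    source_db: str
    direct_flag: bool = False
    method_direct_capable: bool = False

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.gene_a, self.gene_b)

    @property
    def is_self_loop(self) -> bool:
        return self.gene_a == self.gene_b


@dataclass
class PPIClassified:
    pair: tuple[str, str]
    n_methods: int
    n_pubs: int
    high_confidence: bool
    direct_physical: bool = False


@dataclass
class AggregatedEvidence:
    """Deduplicated evidence per canonical pair; self-loops quarantined."""

    by_pair: dict[tuple[str, str], list[PPIEvidence]] = field(default_factory=dict)
    self_loops: list[PPIEvidence] = field(default_factory=list)


def load_direct_method_whitelist(path: Optional[Union[str, Path]] = None) -> set[str]:
    """Method ids considered capable of detecting direct physical contact.

    With no path, the default whitelist shipped with the package is used.
    The file is TSV with a ``method_id`` column; extra columns are ignored.
    """
    if path is None:
        ref = importlib.resources.files("genesetnet") / "data" / "direct_methods.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    header = lines[0].split("\t")
    idx = header.index("method_id")
    return {l.split("\t")[idx] for l in lines[1:]}


def evidence_from_frame(
    df: pd.DataFrame, direct_methods: Optional[set[str]] = None
) -> list[PPIEvidence]:
    """Build evidence records from a PPI table, tagging direct-capable methods."""
    if direct_methods is None:
        direct_methods = load_direct_method_whitelist()
    return [
        PPIEvidence(
            gene_a=r[0], gene_b=r[1], method_id=r[2], pmid=r[3], source_db=r[4],
            direct_flag=bool(r[5]), method_direct_capable=r[2] in direct_methods,
        )
        for r in zip(df["gene_a"], df["gene_b"], df["method_id"], df["pmid"],
                     df["source_db"], df["direct_flag"])
    ]


def aggregate_evidence(evidence: Iterable[PPIEvidence]) -> AggregatedEvidence:
    """Group evidence by canonical pair, deduplicating on
    (pair, method_id, pmid, source_db); self-loops are excluded and kept
    aside for reporting."""
    agg = AggregatedEvidence()
    seen: set[tuple] = set()
    for ev in evidence:
        if ev.is_self_loop:
            agg.self_loops.append(ev)
            continue
        key = (ev.pair, ev.method_id, ev.pmid, ev.source_db)
        if key in seen:
            continue
        seen.add(key)
        agg.by_pair.setdefault(ev.pair, []).append(ev)
    return agg


def classify_high_confidence(agg: AggregatedEvidence) -> list[PPIClassified]:
    """High-confidence = supported by >= 2 distinct experimental methods OR
    >= 2 independent publications (distinctness on the id strings)."""
    out = []
    for pair in sorted(agg.by_pair):
        evs = agg.by_pair[pair]
        n_methods = len({e.method_id for e in evs})
        n_pubs = len({e.pmid for e in evs})
        out.append(
            PPIClassified(
                pair=pair,
                n_methods=n_methods,
                n_pubs=n_pubs,
                high_confidence=(n_methods >= 2 or n_pubs >= 2),
            )
        )
    return out


def classify_direct_physical(
    classified: Iterable[PPIClassified], agg: AggregatedEvidence
) -> list[PPIClassified]:
    """Mark the direct-physical subset of the high-confidence pairs.

    A high-confidence pair is direct-physical if any of its evidence is
    source-annotated as direct (condition i) or comes from a direct-capable
    method (condition ii).  Non-high-confidence pairs are never marked.
    """
    out = []
    for c in classified:
        evs = agg.by_pair.get(c.pair, [])
        direct = c.high_confidence and any(
            e.direct_flag or e.method_direct_capable for e in evs
        )
        out.append(
            PPIClassified(c.pair, c.n_methods, c.n_pubs, c.high_confidence, direct)
        )
    return out


def classify(evidence: Iterable[PPIEvidence]) -> list[PPIClassified]:
    """Aggregate and fully classify evidence in one call."""
    agg = aggregate_evidence(evidence)
    return classify_direct_physical(classify_high_confidence(agg), agg)


def classified_to_frame(classified: Iterable[PPIClassified]) -> pd.DataFrame:
    rows = [
        (c.pair[0], c.pair[1], c.n_methods, c.n_pubs, c.high_confidence, c.direct_physical)
        for c in classified
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "n_methods", "n_pubs", "high_confidence", "direct_physical"],
    )
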