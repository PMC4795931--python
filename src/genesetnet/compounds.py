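"""InChIKey validation, compound unification by skeleton, and bioactivity
filtering into protein–compound interaction (PCI) edges.

An InChIKey is a 27-character hashed chemical identifier in three
hyphen-separated blocks; the first, 14-character block hashes the molecular
skeleton (connectivity).  Compounds from different source databases sharing a
skeleton are unified into one :class:`CompoundGroup`, the package's notion of
a single chemical entity.  Binding activities are kept only when they meet
the standard curation filter (confidence_score >= 4, assay type 'B' for
binding, single-protein target, IC50/Kd/Ki <= 10 000 nM).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import GenesetnetError

SKELETON_LEN = 14
_BLOCK_LENS = (14, 10, 1)


class InChIKeyError(GenesetnetError):
    """An InChIKey string failing validation; ``reason`` says why."""

    def __init__(self, key: str, reason: str):
        super().__init__(f"invalid InChIKey {key!r}: {reason}")
        self.key = key
        self.reason = reason


def parse_inchikey(s: str) -> str:
    """Validate an InChIKey and return its 14-character skeleton block.

    The expected shape is ``XXXXXXXXXXXXXX-YYYYYYYYSA-N``: 14 uppercase
    letters (skeleton), hyphen, 10 uppercase letters (proton/flag block),
    hyphen, one uppercase letter.  The flag characters are validated for
    shape only, never interpreted.

    Raises
    ------
    InChIKeyError
        with ``reason`` one of "missing hyphens", "block length", "case",
        "invalid characters".
    """
    blocks = s.split("-")
    if len(blocks) != 3:
        raise InChIKeyError(s, "missing hyphens")
    if tuple(len(b) for b in blocks) != _BLOCK_LENS:
        raise InChIKeyError(s, "block length")
    joined = "".join(blocks)
    if not joined.isalpha():
        raise InChIKeyError(s, "invalid characters")
    if not joined.isupper():
        raise InChIKeyError(s, "case")
    return blocks[0]


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    source_db: str
    inchikey: str
    name: Optional[str] = None

    @property
    def skeleton(self) -> str:
        return parse_inchikey(self.inchikey)


@dataclass
class CompoundGroup:
    """All compound records sharing one InChIKey skeleton — one chemical
    entity regardless of stereochemistry, protonation or source database."""

    skeleton: str
    members: list[CompoundRecord] = field(default_factory=list)

    @property
    def compound_ids(self) -> set[str]:
        return {m.compound_id for m in self.members}


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    protein_id: str
    confidence_score: int
    assay_type: str
    target_type: str
    standard_type: str
    standard_value_nM: float
    source_db: str = "chembl"

    def __post_init__(self) -> None:
        if self.standard_value_nM < 0:
            raise ValueError("standard_value_nM must be non-negative")


@dataclass
class PCIEdge:
    """One protein–compound-group interaction edge.

    ``best_activity_nM`` is the most potent (minimum) surviving assay value
    across the group's members; absent for edges supported only by curated
    drug-annotation pairs (DrugBank/PDB style).
    """

    skeleton: str
    protein_id: str
    best_activity_nM: Optional[float] = None
    source_dbs: set[str] = field(default_factory=set)
    drug_annotation: bool = False


def group_compounds(records: Iterable[CompoundRecord]) -> list[CompoundGroup]:
    """Partition compound records into groups by InChIKey skeleton.

    Records must already have valid InChIKeys; groups are returned in order
    of first appearance of their skeleton.
    """
    groups: dict[str, CompoundGroup] = {}
    for rec in records:
        sk = rec.skeleton
        groups.setdefault(sk, CompoundGroup(sk)).members.append(rec)
    return list(groups.values())


# filter predicates, checked in order; the first failure is the reported reason
BINDING_ASSAY = "B"
SINGLE_PROTEIN = "SINGLE PROTEIN"
BINDING_STANDARD_TYPES = frozenset({"IC50", "Kd", "Ki"})
MIN_CONFIDENCE = 4
DEFAULT_MAX_NM = 10_000.0


def filter_binding_activities(
    acts: Iterable[ActivityRecord],
    max_value_nM: float = DEFAULT_MAX_NM,
) -> tuple[list[ActivityRecord], Counter]:
    """Keep activities meeting the binding-evidence filter.

    A record survives iff confidence_score >= 4, assay_type == 'B',
    target_type == 'SINGLE PROTEIN', standard_type in {IC50, Kd, Ki} and
    standard_value_nM <= max_value_nM (both boundaries inclusive).  Values
    must already be in nM.  Returns the survivors (input order preserved)
    and a Counter of rejection reasons.
    """
    kept: list[ActivityRecord] = []
    reasons: Counter = Counter()
    for a in acts:
        if a.confidence_score < MIN_CONFIDENCE:
            reasons["confidence_score"] += 1
        elif a.assay_type != BINDING_ASSAY:
            reasons["assay_type"] += 1
        elif a.target_type != SINGLE_PROTEIN:
            reasons["target_type"] += 1
        elif a.standard_type not in BINDING_STANDARD_TYPES:
            reasons["standard_type"] += 1
        elif a.standard_value_nM > max_value_nM:
            reasons["standard_value"] += 1
        else:
            kept.append(a)
    return kept, reasons


def build_pci_edges(
    groups: Sequence[CompoundGroup],
    acts: Iterable[ActivityRecord],
    extra_pairs: Iterable[tuple[str, str, str]] = (),
) -> tuple[list[PCIEdge], list[str]]:
    """Merge filtered assay activities and curated drug–target pairs into
    PCI edges keyed by (skeleton, protein_id).

    ``extra_pairs`` are (compound_id, protein_id, source_db) triples without
    activity values (drug-annotation evidence).  Compound ids that resolve to
    no group are skipped and returned as orphans.
    """
    by_compound: dict[str, str] = {}
    for g in groups:
        for cid in g.compound_ids:
            by_compound[cid] = g.skeleton

    edges: dict[tuple[str, str], PCIEdge] = {}
    orphans: list[str] = []

    def edge_for(cid: str, protein_id: str) -> Optional[PCIEdge]:
        sk = by_compound.get(cid)
        if sk is None:
            orphans.append(cid)
            return None
        return edges.setdefault((sk, protein_id), PCIEdge(sk, protein_id))

    for a in acts:
        e = edge_for(a.compound_id, a.protein_id)
        if e is None:
            continue
        e.source_dbs.add(a.source_db)
        if e.best_activity_nM is None or a.standard_value_nM < e.best_activity_nM:
            e.best_activity_nM = a.standard_value_nM
    for cid, protein_id, source_db in extra_pairs:
        e = edge_for(cid, protein_id)
        if e is None:
            continue
        e.source_dbs.add(source_db)
        e.drug_annotation = True
    return list(edges.values()), orphans


def compounds_from_frame(df: pd.DataFrame) -> tuple[list[CompoundRecord], list[tuple[str, str]]]:
    """Turn a compound table into records, rejecting invalid InChIKeys.

    Returns (valid records, [(compound_id, reason), ...]) for the rejects.
    """
    ok: list[CompoundRecord] = []
    bad: list[tuple[str, str]] = []
    names = df["name"] if "name" in df.columns else [None] * len(df)
    for cid, src, key, nm in zip(df["compound_id"], df["source_db"], df["inchikey"], names):
        try:
            parse_inchikey(key)
        except InChIKeyError as e:
            bad.append((cid, e.reason))
            continue
        ok.append(CompoundRecord(cid, src, key, nm))
    return ok, bad


def activities_from_frame(df: pd.DataFrame) -> list[ActivityRecord]:
    return [
        ActivityRecord(
            r.compound_id, r.protein_id, int(r.confidence_score), r.assay_type,
            r.target_type, r.standard_type, float(r.standard_value_nM),
        )
        for r in df.itertuples(index=False)
    ]


def pci_edges_to_frame(edges: Sequence[PCIEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "skeleton": [e.skeleton for e in edges],
            "protein_id": [e.protein_id for e in edges],
            "best_activity_nM": [e.best_activity_nM for e in edges],
            "source_dbs": [";".join(sorted(e.source_dbs)) for e in edges],
            "drug_annotation": [e.drug_annotation for e in edges],
        }
    )
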