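"""Mutual-best-hit (MBH) orthology from reciprocal similarity-hit tables,
and cross-species conversion of gene lists.

A pair (a, b) between two organisms is an orthologue pair iff b is a's
unique minimum-e-value subject and a is b's unique minimum-e-value subject,
with both hits at e-value <= 1e-3 (threshold inclusive).  Ties for best hit
disqualify the gene: "best" is undefined under ties and a false pairing is
worse than an omission.  MBH output is one-to-one by construction, so list
conversion never maps two genes onto the same target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import AlignmentHit, GeneList, GenesetnetError, OrthologuePair

DEFAULT_MAX_EVALUE = 1e-3


@dataclass
class MBHReport:
    pairs: list[OrthologuePair]
    near_misses: list[tuple[str, str, str]]  # (id, its best hit, reason)


def _best_hits(
    hits: Sequence[AlignmentHit], max_evalue: float
) -> dict[str, Optional[str]]:
    """query_id -> unique best subject under the threshold, or None on ties."""
    best: dict[str, tuple[float, Optional[str]]] = {}
    for h in hits:
        if h.evalue > max_evalue:
            continue
        cur = best.get(h.query_id)
        if cur is None or h.evalue < cur[0]:
            best[h.query_id] = (h.evalue, h.subject_id)
        elif h.evalue == cur[0] and h.subject_id != cur[1]:
            best[h.query_id] = (h.evalue, None)  # tie: disqualified
    return {q: s for q, (_, s) in best.items()}


def mutual_best_hits(
    hits: Iterable[AlignmentHit], max_evalue: float = DEFAULT_MAX_EVALUE
) -> MBHReport:
    """Derive orthologue pairs by mutual best hit over all taxon pairs present.

    One-directional best hits (a's best is b, but b's best is elsewhere or
    undefined) are reported as near-misses rather than silently dropped.
    """
    hits = list(hits)
    taxon_pairs = sorted(
        {tuple(sorted((h.query_taxon, h.subject_taxon))) for h in hits}
    )
    pairs: list[OrthologuePair] = []
    near: list[tuple[str, str, str]] = []
    for ta, tb in taxon_pairs:
        fwd = _best_hits(
            [h for h in hits if h.query_taxon == ta and h.subject_taxon == tb],
            max_evalue,
        )
        rev = _best_hits(
            [h for h in hits if h.query_taxon == tb and h.subject_taxon == ta],
            max_evalue,
        )
        for a in sorted(fwd):
            b = fwd[a]
            if b is None:
                near.append((a, "", "tie for best hit"))
                continue
            back = rev.get(b)
            if back == a:
                pairs.append(OrthologuePair(a, b, ta, tb))
            elif back is None and b in rev:
                near.append((a, b, "reciprocal best is tied"))
            elif back is None:
                near.append((a, b, "no reciprocal hit under threshold"))
            else:
                near.append((a, b, f"reciprocal best is {back}"))
    return MBHReport(pairs=pairs, near_misses=near)


def hits_from_frame(
    df: pd.DataFrame,
    query_taxon: Optional[str] = None,
    subject_taxon: Optional[str] = None,
) -> list[AlignmentHit]:
    """Build hits from a table; taxa come from columns or the arguments."""
    has_taxa = "query_taxon" in df.columns and "subject_taxon" in df.columns
    if not has_taxa and (query_taxon is None or subject_taxon is None):
        raise GenesetnetError(
            "hit table lacks taxon columns; pass query_taxon and subject_taxon"
        )
    out = []
    for r in df.itertuples(index=False):
        out.append(
            AlignmentHit(
                query_id=r.query_id,
                subject_id=r.subject_id,
                evalue=float(r.evalue),
                query_taxon=r.query_taxon if has_taxa else query_taxon,
                subject_taxon=r.subject_taxon if has_taxa else subject_taxon,
            )
        )
    return out


def convert_list(
    genes: GeneList,
    pairs: Iterable[OrthologuePair],
    target_taxon: str,
) -> tuple[GeneList, list[str]]:
    """Convert a gene list to its orthologues in another organism.

    Returns the converted list (deduplicated, input order) and the input
    genes with no orthologue pair.
    """
    mapping: dict[str, str] = {}
    for p in pairs:
        if p.taxon_a == genes.taxon and p.taxon_b == target_taxon:
            mapping[p.id_a] = p.id_b
        elif p.taxon_b == genes.taxon and p.taxon_a == target_taxon:
            mapping[p.id_b] = p.id_a
    if not mapping:
        raise GenesetnetError(
            f"no orthologue pairs connect {genes.taxon!r} to {target_taxon!r}"
        )
    converted, unmapped = [], []
    for g in genes:
        if g in mapping:
            converted.append(mapping[g])
        else:
            unmapped.append(g)
    out = GeneList(f"{genes.name}:{target_taxon}", converted, taxon=target_taxon)
    # MBH pairs are one-to-one, so conversion can never collapse two genes
    assert out.n_duplicates_dropped == 0 or len(set(mapping.values())) < len(mapping)
    return out, unmapped


def pairs_to_frame(pairs: Sequence[OrthologuePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id_a": [p.id_a for p in pairs],
            "id_b": [p.id_b for p in pairs],
            "taxon_a": [p.taxon_a for p in pairs],
            "taxon_b": [p.taxon_b for p in pairs],
        }
    )
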