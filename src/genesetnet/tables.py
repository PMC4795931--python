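"""Readers and writers for the delimited input tables, plus the Barcode
expression filter.

All tables are tab-delimited with a mandatory header row (CSV via
``sep=","``).  Identifier matching throughout the package is case-sensitive
exact string comparison; no identifier translation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Union

import pandas as pd

from .types import GeneList, GenesetnetError

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class SchemaError(GenesetnetError):
    """Input table does not conform to the expected schema."""


def _coerce_bool(v: str) -> bool:
    s = str(v).strip().lower()
    if s in ("1", "true", "t", "yes", "y"):
        return True
    if s in ("0", "false", "f", "no", "n"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


def _coerce_score(v: str) -> float:
    x = float(v)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"barcode_score {x} outside [0, 1]")
    return x


def _coerce_nonneg(v: str) -> float:
    x = float(v)
    if x < 0:
        raise ValueError(f"negative value {x}")
    return x


#: required column -> coercion function (None = keep as string)
SCHEMAS: dict[str, dict[str, Optional[Callable]]] = {
    "annotation": {"theme_id": None, "theme_name": None, "gene_id": None},
    "ppi": {
        "gene_a": None,
        "gene_b": None,
        "method_id": None,
        "pmid": None,
        "source_db": None,
        "direct_flag": _coerce_bool,
    },
    "mti": {"mirna_id": None, "gene_id": None, "evidence_class": None, "pmid": None},
    "tf": {"tf_gene_id": None, "target_gene_id": None, "source_db": None},
    "compound": {"compound_id": None, "source_db": None, "inchikey": None, "name": None},
    "activity": {
        "compound_id": None,
        "protein_id": None,
        "confidence_score": int,
        "assay_type": None,
        "target_type": None,
        "standard_type": None,
        "standard_value_nM": _coerce_nonneg,
    },
    "expression": {
        "gene_id": None,
        "tissue": None,
        "platform": None,
        "barcode_score": _coerce_score,
    },
    "hits": {
        "query_id": None,
        "subject_id": None,
        "evalue": _coerce_nonneg,
        "query_taxon": None,
        "subject_taxon": None,
    },
}

#: columns that may be absent from the file (hit tables may carry one
#: direction per file, with taxa supplied by the caller instead)
OPTIONAL_COLUMNS: dict[str, set[str]] = {"hits": {"query_taxon", "subject_taxon"}}


def read_gene_list(path: PathLike, taxon: str = "human", name: Optional[str] = None) -> GeneList:
    """Read a plain-text gene list, one identifier per line.

    Lines starting with ``#`` are comments; duplicates are dropped keeping the
    first occurrence (the number dropped is logged and recorded on the list).
    """
    path = Path(path)
    ids = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ids.append(line)
    if not ids:
        raise GenesetnetError(f"empty gene list: {path}")
    gl = GeneList(name or path.stem, ids, taxon=taxon)
    if gl.n_duplicates_dropped:
        log.info("%s: dropped %d duplicate ids", path, gl.n_duplicates_dropped)
    return gl


def write_gene_list(genes: GeneList, path: PathLike) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_table(path: PathLike, schema: str, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited table and coerce it to the named schema.

    Rows failing type coercion are rejected; their 1-based data-row numbers
    and reasons are logged and stored in ``df.attrs["rejected"]``.

    Raises
    ------
    SchemaError
        If the schema name is unknown or a required column is missing.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    cols = SCHEMAS[schema]
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#", keep_default_na=False)
    optional = OPTIONAL_COLUMNS.get(schema, set())
    missing = [c for c in cols if c not in df.columns and c not in optional]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} for schema {schema!r}")

    rejected: list[tuple[int, str]] = []
    converted: dict[str, list] = {c: [] for c in df.columns}
    colnames = list(df.columns)
    for i, row in enumerate(df.itertuples(index=False, name=None), start=1):
        vals = {}
        try:
            for c, raw in zip(colnames, row):
                fn = cols.get(c)
                vals[c] = fn(raw) if fn is not None else raw
        except (ValueError, TypeError) as e:
            rejected.append((i, str(e)))
            continue
        for c, v in vals.items():
            converted[c].append(v)
    out = pd.DataFrame(converted, columns=list(df.columns))
    out.attrs["rejected"] = rejected
    out.attrs["schema"] = schema
    if rejected:
        log.warning(
            "%s: rejected %d row(s): %s", path, len(rejected),
            "; ".join(f"row {i}: {r}" for i, r in rejected[:5]),
        )
    return out


def write_table(df: pd.DataFrame, path: PathLike, sep: str = "\t") -> None:
    """Write a table with header, no index; floats in repr-round-trip form."""
    df.to_csv(path, sep=sep, index=False)


@dataclass
class ExpressionFilterResult:
    """Outcome of the reliable-expression filter for one tissue."""

    kept: GeneList
    below_threshold: list[str] = field(default_factory=list)
    no_data: list[str] = field(default_factory=list)
    platform_disagreements: list[str] = field(default_factory=list)


def filter_reliably_expressed(
    genes: GeneList,
    expr: pd.DataFrame,
    tissue: str,
    threshold: float = 0.5,
) -> ExpressionFilterResult:
    """Keep genes 'reliably expressed' in a tissue: Barcode score >= threshold.

    The Barcode score is the fraction of samples of the tissue in which the
    gene was judged expressed; >= 0.5 is the conventional reliability cut.
    A gene passes if ANY of its records for the tissue (across microarray
    platforms) passes; platforms disagreeing across the threshold are noted.
    Genes with no record in the tissue are reported separately from genes
    failing the threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    tissues = set(expr["tissue"])
    if tissue not in tissues:
        raise GenesetnetError(
            f"tissue {tissue!r} absent from expression table; "
            f"available: {sorted(tissues)}"
        )
    sub = expr[expr["tissue"] == tissue]
    scores: dict[str, list[float]] = {}
    for g, s in zip(sub["gene_id"], sub["barcode_score"]):
        scores.setdefault(g, []).append(float(s))

    kept, below, nodata, disagree = [], [], [], []
    for g in genes:
        if g not in scores:
            nodata.append(g)
        elif max(scores[g]) >= threshold:
            kept.append(g)
            if min(scores[g]) < threshold:
                disagree.append(g)
        else:
            below.append(g)
    if disagree:
        log.info("platforms disagree across threshold %.3g for: %s", threshold, disagree)
    return ExpressionFilterResult(
        kept=GeneList(f"{genes.name}:{tissue}", kept, taxon=genes.taxon),
        below_threshold=below,
        no_data=nodata,
        platform_disagreements=disagree,
    )
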