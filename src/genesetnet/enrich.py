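"""Fisher's exact over-representation test of biological themes in a gene
list, with Bonferroni / Holm / Benjamini–Hochberg correction, plus optional
query-list extension by PPI partners.

For a theme annotating K of the N background genes, with k of the n
foreground genes annotated, the one-sided p-value is the upper
hypergeometric tail

    p = sum_{j=k..min(n,K)} C(K,j) C(N-K,n-j) / C(N,n),

evaluated in log-space via the hypergeometric survival function.  The
default background is the annotation universe (every gene with at least one
theme), the default correction Benjamini–Hochberg at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ppi import PPIClassified
from .types import AnnotationSet, GeneList, GenesetnetError

CorrectionMethod = Literal["bonferroni", "holm", "bh"]
_SM_METHOD = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh"}


@dataclass(frozen=True)
class ContingencyCounts:
    """Hypergeometric counts: k of n foreground and K of N background genes
    annotated to the theme."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.k <= min(self.n, self.K)
            and self.n <= self.N
            and self.K <= self.N
        )
        if not ok:
            raise ValueError(f"inconsistent contingency counts {self}")


@dataclass
class EnrichmentResult:
    theme_id: str
    theme_name: str
    counts: ContingencyCounts
    p_raw: float
    p_adj: float
    method: str
    genes: list[str]

    @property
    def significant(self) -> bool:  # against the alpha recorded by the run
        return bool(self._significant)

    _significant: bool = False


def fisher_one_sided(c: ContingencyCounts) -> float:
    """Over-representation (upper-tail) Fisher's exact p-value."""
    return float(stats.hypergeom.sf(c.k - 1, c.N, c.K, c.n))


def adjust_pvalues(ps: Sequence[float], method: CorrectionMethod = "bh") -> list[float]:
    """Adjusted p-values, original order preserved.

    bonferroni: min(1, m p); holm: step-down running max of (m-j+1) p_(j);
    bh: step-up running min of m p_(j) / j.
    """
    ps = list(ps)
    if not ps:
        return []
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _SM_METHOD:
        raise ValueError(f"unknown correction method {method!r}")
    _, adj, _, _ = multipletests(ps, method=_SM_METHOD[method])
    return [float(p) for p in adj]


def extend_with_partners(
    genes: GeneList,
    ppi: Iterable[PPIClassified],
    mode: Literal["none", "high_confidence", "direct_physical"] = "none",
) -> tuple[GeneList, dict[str, str]]:
    """Extend a query list with its PPI partners of the selected confidence
    class.  Returns the extended list and a provenance map
    (gene -> "seed" | "partner")."""
    provenance = {g: "seed" for g in genes}
    if mode == "none":
        return GeneList(genes.name, list(genes), taxon=genes.taxon), provenance
    if mode not in ("high_confidence", "direct_physical"):
        raise ValueError(f"unknown extension mode {mode!r}")
    seed = set(genes)
    extra: list[str] = []
    for c in ppi:
        keep = c.direct_physical if mode == "direct_physical" else c.high_confidence
        if not keep:
            continue
        a, b = c.pair
        if a in seed and b not in seed:
            extra.append(b)
        elif b in seed and a not in seed:
            extra.append(a)
    out = GeneList(f"{genes.name}+partners", list(genes) + sorted(set(extra)),
                   taxon=genes.taxon)
    for g in out:
        provenance.setdefault(g, "partner")
    return out, provenance


@dataclass
class EnrichmentRun:
    """Full enrichment outcome: per-theme results plus run bookkeeping."""

    results: list[EnrichmentResult]
    alpha: float
    method: str
    m_tested: int
    foreground_used: list[str]
    foreground_dropped: list[str]  # query genes outside the background/universe

    @property
    def significant(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r._significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theme_id": [r.theme_id for r in self.results],
                "theme_name": [r.theme_name for r in self.results],
                "k": [r.counts.k for r in self.results],
                "n": [r.counts.n for r in self.results],
                "K": [r.counts.K for r in self.results],
                "N": [r.counts.N for r in self.results],
                "p_raw": [r.p_raw for r in self.results],
                "p_adj": [r.p_adj for r in self.results],
                "method": [r.method for r in self.results],
                "significant": [r._significant for r in self.results],
                "genes": [";".join(r.genes) for r in self.results],
            }
        )


def run_enrichment(
    genes: GeneList,
    ann: AnnotationSet,
    background: Optional[GeneList] = None,
    method: CorrectionMethod = "bh",
    alpha: float = 0.05,
    m_mode: Literal["tested", "all"] = "tested",
) -> EnrichmentRun:
    """Test every theme with at least one foreground gene for
    over-representation.

    The background defaults to the annotation universe (all genes with >= 1
    theme); an explicit background list is intersected with the universe.
    Foreground genes outside the background are dropped and reported, never
    silently kept.  Results are sorted by adjusted p ascending, ties by
    theme_id; a result is flagged significant iff p_adj <= alpha.

    ``m_mode`` controls the number of tests m used by the correction:
    "tested" (default) counts only themes with k >= 1, "all" counts every
    theme in the annotation set.
    """
    universe = ann.universe
    bg = universe if background is None else (set(background) & universe)
    if not bg:
        raise GenesetnetError("background is empty after universe intersection")
    fg = [g for g in genes if g in bg]
    dropped = [g for g in genes if g not in bg]
    if not fg:
        raise GenesetnetError("foreground is empty after background intersection")
    n, N = len(fg), len(bg)
    fg_set = set(fg)

    rows = []
    for t in sorted(ann, key=lambda t: t.theme_id):
        tg = t.genes & bg
        hit = sorted(fg_set & tg)
        if not hit:
            continue
        c = ContingencyCounts(k=len(hit), n=n, K=len(tg), N=N)
        rows.append((t, c, hit, fisher_one_sided(c)))

    m_extra = len(ann) - len(rows) if m_mode == "all" else 0
    praw = [r[3] for r in rows] + [1.0] * m_extra
    padj = adjust_pvalues(praw, method)[: len(rows)] if rows else []

    results = []
    for (t, c, hit, p), pa in zip(rows, padj):
        r = EnrichmentResult(t.theme_id, t.theme_name, c, p, pa, method, hit)
        r._significant = pa <= alpha
        results.append(r)
    results.sort(key=lambda r: (r.p_adj, r.theme_id))
    return EnrichmentRun(
        results=results,
        alpha=alpha,
        method=method,
        m_tested=len(rows) + m_extra,
        foreground_used=fg,
        foreground_dropped=dropped,
    )
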