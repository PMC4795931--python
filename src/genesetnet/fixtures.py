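"""Deterministic generator of synthetic input bundles with planted ground
truth, so every pipeline stage is testable without external downloads.

The generator emulates the shapes of the real inputs — annotation tables,
PPI evidence, miRNA-target and TF-target tables, compound/activity tables,
Barcode expression scores and reciprocal similarity hits — with known
planted structure: an over-represented theme in the foreground list, PPI
pairs with known confidence classes, orthologue pairs ranked strictly best
in both directions, a known number of InChIKey skeletons, and records
sitting exactly on every filter boundary (confidence score 4, 10 000 nM,
Barcode 0.5, e-value 1e-3) to pin inclusive/exclusive semantics.  A single
integer seed drives one pseudo-random stream; the emitted bundle is
byte-identical across runs.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class FixtureSpec:
    """Knobs of the synthetic bundle; defaults give the 'small' preset."""

    seed: int = 0
    n_genes: int = 60
    n_themes: int = 10
    n_mirnas: int = 8
    n_compounds: int = 20
    n_skeletons: int = 12
    foreground_size: int = 15
    planted_theme: tuple[str, float] = ("T0001", 0.8)  # (theme_id, intensity)
    planted_orthologues: int = 8
    ppi_density: float = 0.08
    fraction_direct: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_themes", "n_mirnas", "n_compounds",
                     "n_skeletons", "foreground_size", "planted_orthologues"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.ppi_density <= 1 or not 0 <= self.fraction_direct <= 1:
            raise ValueError("densities must be in [0, 1]")
        if not 0 < self.planted_theme[1] <= 1:
            raise ValueError("enrichment intensity must be in (0, 1]")


PRESETS = {
    "small": {},
    "medium": {"n_genes": 200, "n_themes": 25, "n_mirnas": 20, "n_compounds": 60,
               "n_skeletons": 35, "foreground_size": 40, "planted_orthologues": 25},
}


def spec_for_preset(preset: str, seed: int = 0) -> FixtureSpec:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}")
    return FixtureSpec(seed=seed, **PRESETS[preset])


# the whitelist tag used for planted direct-capable evidence
_DIRECT_METHOD = "Y2H"
_PLAIN_METHODS = ["MI:0006", "MI:0007", "MI:0019", "MI:0096", "MI:0114"]

_UPPER = np.array(list(string.ascii_uppercase))


def _skeleton(rng: np.random.Generator) -> str:
    return "".join(rng.choice(_UPPER, size=14))


def _inchikey(rng: np.random.Generator, skeleton: str) -> str:
    block2 = "".join(rng.choice(_UPPER, size=8)) + "SA"
    return f"{skeleton}-{block2}-N"


def generate_random_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdős–Rényi G(n, p) simple graph, deterministic under the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    return nx.gnp_random_graph(n, p, seed=seed)


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def generate_bundle(spec: FixtureSpec, outdir: Union[str, Path]) -> dict:
    """Emit all input tables plus a ground-truth manifest; returns the
    manifest (also written to ``manifest.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genes = [f"g{i:04d}" for i in range(1, spec.n_genes + 1)]
    mouse = [f"m{i:04d}" for i in range(1, spec.n_genes + 1)]

    # ---- annotation themes, one planted -------------------------------
    theme_ids = [f"T{i:04d}" for i in range(1, spec.n_themes + 1)]
    planted_id, intensity = spec.planted_theme
    if planted_id not in theme_ids:
        theme_ids[0] = planted_id
    ann_rows = []
    theme_genes: dict[str, list[str]] = {}
    for tid in theme_ids:
        size = int(rng.integers(5, 13))
        members = sorted(rng.choice(genes, size=size, replace=False))
        theme_genes[tid] = list(members)
        for g in members:
            ann_rows.append((tid, f"theme {tid}", g))
    _write_tsv(pd.DataFrame(ann_rows, columns=["theme_id", "theme_name", "gene_id"]),
               outdir / "annotation.tsv")

    # ---- foreground list over-sampling the planted theme --------------
    planted_genes = theme_genes[planted_id]
    n_fromtheme = min(len(planted_genes), max(1, round(intensity * spec.foreground_size)))
    fg = list(rng.choice(planted_genes, size=n_fromtheme, replace=False))
    others = [g for g in genes if g not in set(fg)]
    n_rest = spec.foreground_size - len(fg)
    fg += list(rng.choice(others, size=n_rest, replace=False))
    fg = list(dict.fromkeys(fg))
    (outdir / "genes.txt").write_text(
        "# synthetic foreground gene list\n" + "".join(f"{g}\n" for g in fg)
    )

    # ---- PPI evidence with known confidence classes -------------------
    base = generate_random_graph(spec.n_genes, spec.ppi_density, seed=spec.seed + 1)
    ppi_rows = []
    hc_pairs, direct_pairs, all_pairs = [], [], []
    for i, j in sorted(base.edges()):
        a, b = genes[i], genes[j]
        all_pairs.append((a, b))
        profile = rng.choice(["single", "two_methods", "two_pubs"],
                             p=[0.4, 0.3, 0.3])
        pmid = str(10_000_000 + int(rng.integers(0, 9_000_000)))
        m1, m2 = rng.choice(_PLAIN_METHODS, size=2, replace=False)
        if profile == "single":
            ppi_rows.append((a, b, m1, pmid, "dbA", False))
            continue
        hc_pairs.append((a, b))
        direct = bool(rng.random() < spec.fraction_direct)
        if direct:
            direct_pairs.append((a, b))
        if profile == "two_methods":
            second = _DIRECT_METHOD if direct else m2
            ppi_rows.append((a, b, m1, pmid, "dbA", False))
            ppi_rows.append((a, b, second, pmid, "dbB", False))
        else:  # two publications, same method
            pmid2 = str(20_000_000 + int(rng.integers(0, 9_000_000)))
            ppi_rows.append((a, b, m1, pmid, "dbA", direct))
            ppi_rows.append((a, b, m1, pmid2, "dbB", False))
    # a quarantined self-loop and a reversed duplicate are always planted
    ppi_rows.append((genes[0], genes[0], _PLAIN_METHODS[0], "99999999", "dbA", True))
    if hc_pairs:
        a, b = hc_pairs[0]
        ppi_rows.append((b, a, _PLAIN_METHODS[0], "88888888", "dbC", False))
    _write_tsv(
        pd.DataFrame(ppi_rows,
                     columns=["gene_a", "gene_b", "method_id", "pmid",
                              "source_db", "direct_flag"]),
        outdir / "ppi.tsv",
    )

    # ---- miRNA-target and TF-target tables ----------------------------
    mirnas = [f"mir-{i:03d}" for i in range(1, spec.n_mirnas + 1)]
    mti_rows = []
    for mir in mirnas:
        for g in rng.choice(fg, size=min(2, len(fg)), replace=False):
            mti_rows.append((mir, g, "luciferase assay",
                             str(15_000_000 + int(rng.integers(0, 9_000_000)))))
    _write_tsv(pd.DataFrame(mti_rows,
                            columns=["mirna_id", "gene_id", "evidence_class", "pmid"]),
               outdir / "mti.tsv")

    tf_rows = []
    tfs = list(rng.choice([g for g in genes if g not in set(fg)], size=3, replace=False))
    for tf in tfs:
        for g in rng.choice(fg, size=min(3, len(fg)), replace=False):
            tf_rows.append((tf, g, "tf_db"))
    _write_tsv(pd.DataFrame(tf_rows,
                            columns=["tf_gene_id", "target_gene_id", "source_db"]),
               outdir / "tf.tsv")

    # ---- compounds: known number of skeletons, one invalid key --------
    skeletons = sorted({_skeleton(rng) for _ in range(spec.n_skeletons)})
    comp_rows = []
    for i in range(spec.n_compounds):
        sk = skeletons[i % len(skeletons)]
        comp_rows.append((f"CPD{i + 1:04d}",
                          "chembl" if i % 3 else "pubchem",
                          _inchikey(rng, sk), f"compound-{i + 1}"))
    comp_rows.append(("CPD_BAD", "chembl", "AAAA-BB-N", "broken key"))
    _write_tsv(pd.DataFrame(comp_rows,
                            columns=["compound_id", "source_db", "inchikey", "name"]),
               outdir / "compound.tsv")

    # ---- activities: boundary rows pin the filter semantics -----------
    targets = list(rng.choice(fg, size=min(5, len(fg)), replace=False))
    act_rows = [
        # (compound, protein, score, assay, target_type, std_type, value) kept?
        ("CPD0001", targets[0], 4, "B", "SINGLE PROTEIN", "IC50", 10000.0),  # yes
        ("CPD0001", targets[0], 4, "B", "SINGLE PROTEIN", "Kd", 5000.0),     # yes
        ("CPD0002", targets[1], 3, "B", "SINGLE PROTEIN", "Kd", 10.0),       # score
        ("CPD0003", targets[2], 5, "F", "SINGLE PROTEIN", "Ki", 10.0),       # assay
        ("CPD0004", targets[3], 5, "B", "PROTEIN COMPLEX", "Ki", 10.0),      # target
        ("CPD0005", targets[4], 5, "B", "SINGLE PROTEIN", "EC50", 10.0),     # type
        ("CPD0006", targets[0], 5, "B", "SINGLE PROTEIN", "Ki", 10001.0),    # value
    ]
    n_boundary_kept = 2
    n_random_kept = 0
    for i in range(8):
        cid = f"CPD{int(rng.integers(1, spec.n_compounds + 1)):04d}"
        prot = targets[int(rng.integers(0, len(targets)))]
        val = float(np.round(rng.uniform(1, 9000), 1))
        act_rows.append((cid, prot, 4, "B", "SINGLE PROTEIN", "IC50", val))
        n_random_kept += 1
    _write_tsv(pd.DataFrame(act_rows,
                            columns=["compound_id", "protein_id", "confidence_score",
                                     "assay_type", "target_type", "standard_type",
                                     "standard_value_nM"]),
               outdir / "activity.tsv")

    # drug-annotation pairs without assay values (DrugBank style)
    drug_rows = [("CPD0007", targets[0], "drugbank"),
                 ("CPD0008", targets[1], "drugbank")]
    _write_tsv(pd.DataFrame(drug_rows,
                            columns=["compound_id", "protein_id", "source_db"]),
               outdir / "drug_pairs.tsv")

    # ---- Barcode expression straddling 0.5 ----------------------------
    expr_rows = []
    kept_expr = []
    for idx, g in enumerate(fg):
        score = [0.5, 0.49, 0.51, 0.0, 1.0][idx % 5]
        if idx % 7 == 6:
            continue  # no liver record at all
        expr_rows.append((g, "liver", "GPL570", score))
        if score >= 0.5:
            kept_expr.append(g)
        if idx % 4 == 0:  # second platform that may disagree
            expr_rows.append((g, "liver", "GPL96", 0.2))
    expr_rows.append((fg[0], "kidney", "GPL570", 0.9))
    _write_tsv(pd.DataFrame(expr_rows,
                            columns=["gene_id", "tissue", "platform", "barcode_score"]),
               outdir / "expression.tsv", float_format="%.2f")

    # ---- reciprocal similarity hits with planted MBH pairs ------------
    hit_rows = []
    planted_pairs = []
    n_orth = min(spec.planted_orthologues, spec.n_genes)
    for i in range(n_orth):
        a, b = genes[i], mouse[i]
        ev = 1e-30 if i else 1e-3  # one boundary pair exactly at the threshold
        planted_pairs.append((a, b))
        hit_rows.append((a, b, ev, "human", "mouse"))
        hit_rows.append((b, a, ev, "mouse", "human"))
        # decoys strictly worse, still under threshold
        decoy = mouse[(i + 1) % spec.n_genes]
        if ev < 1e-4:
            hit_rows.append((a, decoy, 1e-6, "human", "mouse"))
    # a tied query: two equally best subjects -> disqualified
    tie_q = genes[n_orth] if n_orth < spec.n_genes else "g_tie"
    hit_rows.append((tie_q, mouse[-1], 1e-20, "human", "mouse"))
    hit_rows.append((tie_q, mouse[-2], 1e-20, "human", "mouse"))
    hit_rows.append((mouse[-1], tie_q, 1e-20, "mouse", "human"))
    # a pair excluded by the e-value threshold
    excl_q = genes[min(n_orth + 1, spec.n_genes - 1)]
    hit_rows.append((excl_q, mouse[-3], 2e-3, "human", "mouse"))
    hit_rows.append((mouse[-3], excl_q, 2e-3, "mouse", "human"))
    _write_tsv(pd.DataFrame(hit_rows,
                            columns=["query_id", "subject_id", "evalue",
                                     "query_taxon", "subject_taxon"]),
               outdir / "hits.tsv", float_format="%g")

    manifest = {
        "spec": {
            "seed": spec.seed, "n_genes": spec.n_genes, "n_themes": spec.n_themes,
            "n_mirnas": spec.n_mirnas, "n_compounds": spec.n_compounds,
            "n_skeletons": spec.n_skeletons, "foreground_size": spec.foreground_size,
            "planted_theme": list(spec.planted_theme),
            "planted_orthologues": n_orth,
            "ppi_density": spec.ppi_density, "fraction_direct": spec.fraction_direct,
        },
        "foreground": fg,
        "planted_theme_id": planted_id,
        "planted_theme_genes": planted_genes,
        "ppi_all_pairs": [list(p) for p in all_pairs],
        "ppi_high_confidence": [list(p) for p in sorted(hc_pairs)],
        "ppi_direct_physical": [list(p) for p in sorted(direct_pairs)],
        "ppi_self_loops": 1,
        "orthologue_pairs": [list(p) for p in planted_pairs],
        "orthology_tie_query": tie_q,
        "orthology_excluded_query": excl_q,
        "n_compound_skeletons": len(skeletons),
        "n_valid_compounds": spec.n_compounds,
        "n_invalid_compounds": 1,
        "n_activity_survivors": n_boundary_kept + n_random_kept,
        "expression_kept": kept_expr,
        "files": sorted(p.name for p in outdir.iterdir() if p.suffix in (".tsv", ".txt")),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
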