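"""Chained analysis workflow: query list → optional PPI-partner extension →
optional orthologue conversion → enrichment → association heatmap →
composite interaction network.

Every artifact is written with a provenance header (tool version, stage
parameters, input checksums) as ``#`` comment lines, so re-running an
identical configuration reproduces byte-identical TSV outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .compounds import (activities_from_frame, build_pci_edges, compounds_from_frame,
                        filter_binding_activities, group_compounds, pci_edges_to_frame)
from .enrich import EnrichmentRun, extend_with_partners, run_enrichment
from .heatmap import build_binary_matrix, cluster_rows, export_matrix
from .network import build_network, export_network, filter_activity
from .orthology import convert_list, hits_from_frame, mutual_best_hits, pairs_to_frame
from .ppi import classify, classified_to_frame, evidence_from_frame
from .tables import read_gene_list, read_table
from .types import AnnotationSet, GeneList, GenesetnetError, MTIRecord, TFTargetRecord

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one workflow run."""

    genes: str
    annotation: str
    outdir: str
    taxon: str = "human"
    ppi: Optional[str] = None
    mti: Optional[str] = None
    tf: Optional[str] = None
    compound: Optional[str] = None
    activity: Optional[str] = None
    drug_pairs: Optional[str] = None
    hits: Optional[str] = None
    extend: str = "none"  # none | high_confidence | direct_physical
    convert_to: Optional[str] = None
    correction: str = "bh"
    alpha: float = 0.05
    max_nm: Optional[float] = None
    network_format: str = "graphml"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**cfg)

    def validate(self) -> None:
        for attr in ("genes", "annotation"):
            p = getattr(self, attr)
            if p is None or not Path(p).exists():
                raise GenesetnetError(f"required input {attr!r} missing: {p}")
        if self.extend != "none" and self.ppi is None:
            raise GenesetnetError("extension by PPI partners requires a ppi table")
        if self.convert_to is not None and self.hits is None:
            raise GenesetnetError("orthologue conversion requires a hits table")
        if not 0 <= self.alpha <= 1:
            raise GenesetnetError("alpha must be in [0, 1]")


def _sha256(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def provenance_header(stage: str, params: dict, inputs: dict[str, str]) -> str:
    lines = [f"# genesetnet {__version__}", f"# stage: {stage}"]
    lines.append("# params: " + " ".join(f"{k}={v}" for k, v in sorted(params.items())))
    for name, p in sorted(inputs.items()):
        lines.append(f"# input {name}={Path(p).name} sha256={_sha256(p)}")
    return "".join(l + "\n" for l in lines)


def write_artifact(df: pd.DataFrame, path: Path, stage: str, params: dict,
                   inputs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, params, inputs))
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class WorkflowResult:
    artifacts: dict[str, Path] = field(default_factory=dict)
    enrichment: Optional[EnrichmentRun] = None
    final_genes: Optional[GeneList] = None


def run_workflow(cfg: RunConfig) -> WorkflowResult:
    """Execute the full chained analysis; raises GenesetnetError naming the
    failing stage."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = WorkflowResult()
    stage = "load"
    try:
        genes = read_gene_list(cfg.genes, taxon=cfg.taxon)
        ann_df = read_table(cfg.annotation, "annotation")
        ann = AnnotationSet.from_pairs(
            list(zip(ann_df["theme_id"], ann_df["theme_name"], ann_df["gene_id"]))
        )

        classified = None
        if cfg.ppi:
            stage = "ppi-classify"
            ev = evidence_from_frame(read_table(cfg.ppi, "ppi"))
            classified = classify(ev)
            path = outdir / "ppi_classified.tsv"
            write_artifact(classified_to_frame(classified), path, stage,
                           {}, {"ppi": cfg.ppi})
            res.artifacts["ppi_classified"] = path

        stage = "extend"
        if cfg.extend != "none":
            genes, _prov = extend_with_partners(genes, classified, cfg.extend)

        stage = "convert"
        if cfg.convert_to is not None:
            hits = hits_from_frame(read_table(cfg.hits, "hits"))
            mbh = mutual_best_hits(hits)
            path = outdir / "orthologue_pairs.tsv"
            write_artifact(pairs_to_frame(mbh.pairs), path, stage,
                           {}, {"hits": cfg.hits})
            res.artifacts["orthologue_pairs"] = path
            genes, unmapped = convert_list(genes, mbh.pairs, cfg.convert_to)
            if unmapped:
                log.info("%d genes had no orthologue", len(unmapped))

        stage = "enrich"
        run = run_enrichment(genes, ann, method=cfg.correction, alpha=cfg.alpha)
        res.enrichment = run
        res.final_genes = genes
        path = outdir / "enrichment.tsv"
        write_artifact(run.to_frame(), path, stage,
                       {"alpha": cfg.alpha, "correction": cfg.correction,
                        "extend": cfg.extend, "m": run.m_tested},
                       {"genes": cfg.genes, "annotation": cfg.annotation})
        res.artifacts["enrichment"] = path

        stage = "heatmap"
        sig = run.significant
        pairs = [(g, r.theme_id) for r in sig for g in r.genes]
        if pairs:
            m = build_binary_matrix(pairs)
            dg = cluster_rows(m) if len(m) >= 2 else None
            path = outdir / "association_matrix.tsv"
            with open(path, "w") as fh:
                fh.write(provenance_header(stage, {"sort": "cluster"},
                                           {"genes": cfg.genes}))
                export_matrix(m, dg, sort="cluster" if dg else "none").to_csv(
                    fh, sep="\t", index_label="gene_id")
            res.artifacts["association_matrix"] = path
            if dg is not None:
                npath = outdir / "dendrogram.nwk"
                npath.write_text(dg.to_newick() + "\n")
                res.artifacts["dendrogram"] = npath

        stage = "network"
        mti = []
        if cfg.mti:
            mti = [MTIRecord(*r) for r in read_table(cfg.mti, "mti").itertuples(index=False)]
        tf = []
        if cfg.tf:
            tf = [TFTargetRecord(*r) for r in read_table(cfg.tf, "tf").itertuples(index=False)]
        pci = []
        if cfg.compound and cfg.activity:
            comps, _bad = compounds_from_frame(read_table(cfg.compound, "compound"))
            groups = group_compounds(comps)
            acts, _reasons = filter_binding_activities(
                activities_from_frame(read_table(cfg.activity, "activity")))
            extra = []
            if cfg.drug_pairs:
                dp = pd.read_csv(cfg.drug_pairs, sep="\t", dtype=str, comment="#")
                extra = list(zip(dp["compound_id"], dp["protein_id"], dp["source_db"]))
            pci, _orphans = build_pci_edges(groups, acts, extra)
            ppath = outdir / "pci_edges.tsv"
            write_artifact(pci_edges_to_frame(pci), ppath, "compounds", {},
                           {"compound": cfg.compound, "activity": cfg.activity})
            res.artifacts["pci_edges"] = ppath
        net = build_network(genes, classified or [], mti, pci, tf)
        if cfg.max_nm is not None:
            net = filter_activity(net, cfg.max_nm)
        ext = {"graphml": "graphml", "sif": "sif", "json": "json"}[cfg.network_format]
        npath = outdir / f"network.{ext}"
        export_network(net, npath, cfg.network_format)
        res.artifacts["network"] = npath
    except GenesetnetError as e:
        raise GenesetnetError(f"stage {stage!r} failed: {e}") from e
    return res
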