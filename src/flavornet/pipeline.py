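"""End-to-end orchestration: DE -> profiles -> network -> traits.

The stage order mirrors the study workflow: pairwise DE screens between
consecutive and flanking stages, four-group profile classification,
expression filtering (mean FPKM > 1), unsigned network construction and
module detection, eigengene-trait association, and candidate/hub
selection with a Cytoscape-ready edge export.  Every intermediate table
is written as TSV and a manifest JSON records parameters, seed and
per-stage row counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpr, detest, profiles, traits as trait_assoc
from .datatypes import CountMatrix
from .io import write_table

logger = logging.getLogger("flavornet")


@dataclass
class PipelineConfig:
    """All stage thresholds, defaulting to the study's printed
    parameters: FDR < 0.001, |log2 ratio| >= 1, 32-fold profile cap,
    mean FPKM > 1 network filter, soft power 16, min module size 30,
    merge cut height 0.25, candidate |r| > 0.91, hub kME >= 0.9."""

    fdr_threshold: float = 0.001
    min_abs_log2: float = 1.0
    log2_epsilon: float = 0.01
    fold_cap_log2: float = 5.0
    min_mean_fpkm: float = 1.0
    beta: float = 16.0
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    cut_quantile: float = 0.99
    min_kme_to_stay: float = 0.85
    module_p_threshold: float = 0.001
    r_threshold: float = 0.91
    kme_threshold: float = 0.9
    top_k_per_module: int = 5
    edge_weight_threshold: float = 0.1
    stages: tuple = ("S1", "S2", "S3")
    seed: int = 0
    outdir: str = "flavornet_out"

    def validate(self) -> None:
        checks = [
            ("fdr_threshold", 0 < self.fdr_threshold <= 1),
            ("min_abs_log2", self.min_abs_log2 >= 0),
            ("log2_epsilon", self.log2_epsilon > 0),
            ("min_mean_fpkm", self.min_mean_fpkm >= 0),
            ("beta", self.beta > 0),
            ("min_module_size", self.min_module_size >= 2),
            ("merge_cut_height", 0 <= self.merge_cut_height < 2),
            ("cut_quantile", 0 < self.cut_quantile <= 1),
            ("r_threshold", 0 <= self.r_threshold < 1),
            ("kme_threshold", 0 <= self.kme_threshold <= 1),
            ("edge_weight_threshold", 0 <= self.edge_weight_threshold <= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"config field {name} out of range: {getattr(self, name)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        if "stages" in known:
            known["stages"] = tuple(known["stages"])
        return cls(**known)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    counts: CountMatrix,
    traits: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every stage in order, writing all outputs under
    ``config.outdir``.  Returns a result bundle (dict of DataFrames and
    paths); deterministic for a fixed seed."""
    cfg = config or PipelineConfig()
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    written: list[str] = []
    counts_rows: dict[str, int] = {}

    def _stage(name):
        logger.info("stage %s: start", name)
        return name

    def _done(name, df):
        logger.info("stage %s: done (%d rows)", name, len(df))
        counts_rows[name] = int(len(df))

    s1, s2, s3 = cfg.stages

    try:
        name = _stage("fpkm")
        fpkm = profiles.compute_fpkm(counts)
        write_table(fpkm, out / "fpkm.tsv")
        written.append("fpkm.tsv")
        results["fpkm"] = fpkm
        _done(name, fpkm)

        name = _stage("detest")
        de = {}
        for a, b in [(s1, s2), (s2, s3), (s1, s3)]:
            tab = detest.run_pairwise_de(
                counts,
                a,
                b,
                fdr_threshold=cfg.fdr_threshold,
                min_abs_log2=cfg.min_abs_log2,
                epsilon=cfg.log2_epsilon,
            )
            fname = f"de_{a}_vs_{b}.tsv"
            write_table(tab, out / fname)
            written.append(fname)
            de[(a, b)] = tab
            logger.info("  %s vs %s: %d DEGs / %d genes", a, b, int(tab.is_deg.sum()), len(tab))
        results["de"] = de
        _done(name, de[(s1, s2)])

        name = _stage("profiles")
        prof = profiles.classify_profiles(
            de[(s1, s2)], de[(s2, s3)], fold_cap_log2=cfg.fold_cap_log2
        )
        write_table(prof, out / "profiles.tsv")
        written.append("profiles.tsv")
        results["profiles"] = prof
        _done(name, prof)

        name = _stage("network")
        kept = coexpr.filter_expressed(fpkm, min_mean=cfg.min_mean_fpkm)
        expr = np.log2(fpkm.loc[kept] + 1.0)
        adj = coexpr.soft_adjacency(expr, beta=cfg.beta)
        tom = coexpr.tom_similarity(adj)
        partition = coexpr.detect_modules(
            tom, min_module_size=cfg.min_module_size, cut_quantile=cfg.cut_quantile
        )
        if (partition > 0).any():
            partition = coexpr.prune_membership(
                expr, partition, min_kme=cfg.min_kme_to_stay,
                min_module_size=cfg.min_module_size,
            )
        if (partition > 0).any():
            partition = coexpr.merge_modules(
                expr, partition, merge_cut_height=cfg.merge_cut_height
            )
        else:
            logger.warning("no module reached min size %d", cfg.min_module_size)
        write_table(partition.to_frame(), out / "modules.tsv")
        written.append("modules.tsv")
        results["modules"] = partition
        results["adjacency"] = adj
        results["tom"] = tom
        _done(name, partition)

        name = _stage("traits")
        if (partition > 0).any():
            eig, varexp = coexpr.module_eigengenes(expr, partition)
            write_table(eig, out / "eigengenes.tsv", index_label="library_id")
            mt_r, mt_p = trait_assoc.module_trait_matrix(eig, traits.loc[eig.index])
            sig = trait_assoc.significant_modules(mt_r, mt_p, cfg.module_p_threshold)
        else:
            eig = pd.DataFrame(index=fpkm.columns)
            varexp = pd.Series(dtype=float)
            write_table(eig, out / "eigengenes.tsv", index_label="library_id")
            mt_r = pd.DataFrame()
            mt_p = pd.DataFrame()
            sig = []
        written.append("eigengenes.tsv")
        write_table(mt_r, out / "module_trait_r.tsv", index_label="module")
        write_table(mt_p, out / "module_trait_p.tsv", index_label="module")
        written += ["module_trait_r.tsv", "module_trait_p.tsv"]
        results["eigengenes"] = eig
        results["variance_explained"] = varexp
        results["module_trait_r"] = mt_r
        results["module_trait_p"] = mt_p
        results["significant_modules"] = sig
        _done(name, mt_r)

        name = _stage("candidates")
        if sig:
            cand = trait_assoc.select_candidate_genes(
                fpkm.loc[kept], traits.loc[fpkm.columns], partition, sig,
                r_threshold=cfg.r_threshold,
            )
            hubs = trait_assoc.identify_hubs(
                expr, eig[sig], partition, adj,
                kme_threshold=cfg.kme_threshold, top_k_per_module=cfg.top_k_per_module,
            )
            net_genes = sorted(set(cand.index) | set(hubs.index[hubs.is_hub]))
            edges = trait_assoc.export_network_edges(
                tom, net_genes, cfg.edge_weight_threshold, fmt="tsv"
            )
        else:
            logger.warning("no trait-significant module; candidates empty")
            cand = pd.DataFrame(columns=["module", "best_trait", "gene_trait_r"])
            hubs = pd.DataFrame(columns=["module", "kME", "intramodular_k", "is_hub"])
            edges = pd.DataFrame(columns=["source", "target", "weight"])
        write_table(cand, out / "candidates.tsv")
        write_table(hubs, out / "hubs.tsv")
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        written += ["candidates.tsv", "hubs.tsv", "edges.tsv"]
        results["candidates"] = cand
        results["hubs"] = hubs
        results["edges"] = edges
        _done(name, cand)
    except Exception as exc:  # annotate failures with the stage name
        raise StageError(name, exc) from exc

    manifest = {
        "package": "flavornet",
        "parameters": {k: v for k, v in asdict(cfg).items() if k != "outdir"},
        "seed": cfg.seed,
        "outputs": written,
        "rows": counts_rows,
        "n_genes": int(counts.counts.shape[0]),
        "n_libraries": int(counts.counts.shape[1]),
        "n_modules": int(partition.max()) if len(partition) else 0,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    results["manifest"] = manifest
    results["outdir"] = out
    return results
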