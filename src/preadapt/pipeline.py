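"""End-to-end pipeline driver over synthetic data.

Runs the stages in dependency order — simulate, qc, cna, grn, overlap, pa,
score — writing every output as TSV/MTX/JSON under one output directory and
recording a manifest (config snapshot, per-stage seeds, file hashes). One
global seed governs all stage seeds through a stage-name hash offset, so a
rerun with the same config reproduces identical outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cna as cna_mod
from . import ctc as ctc_mod
from . import grn as grn_mod
from . import overlap as overlap_mod
from . import pa as pa_mod
from . import signatures as sig_mod
from .containers import CountMatrix, GeneSet, NormalizedMatrix
from .io import read_10x_mtx, write_10x_mtx, write_gene_annotation
from .preprocess import (
    QcConfig,
    filter_by_housekeeping,
    filter_cells,
    filter_genes,
    find_variable_genes,
    lognormalize,
    remove_mito,
)
from .simulate import SimConfig, generate_gene_annotation, simulate_counts

log = logging.getLogger("preadapt.pipeline")

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    out_dir: str = "preadapt_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QcConfig | None = None
    n_chromosomes: int = 10
    cna_window: int = 100
    cna_step: int = 10
    grn_top_genes: int = 30
    grn_top_k_edges: int = 150
    community_min_size: int = 10
    n_null: int = 200
    nmf_k: int = 3
    pa_threshold: float = 0.75
    pa_train_fraction: float = 0.10
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        qc = QcConfig(**raw["qc"]) if "qc" in raw else None
        return cls(sim=sim, qc=qc, **raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed by a stage-name hash."""
    return int((global_seed + zlib.crc32(stage.encode())) % (2**31 - 1))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": VERSION, "seed": config.seed, "stages": {}, "files": {}}

    # --- simulate -----------------------------------------------------------
    sim_cfg = config.sim
    sim_cfg.seed = stage_seed(config.seed, "simulate")
    counts, truth = simulate_counts(sim_cfg)
    annotation = generate_gene_annotation(
        sim_cfg.n_genes, config.n_chromosomes, seed=stage_seed(config.seed, "annotation")
    )
    write_10x_mtx(counts, out / "raw")
    write_gene_annotation(annotation, out / "annotation.tsv")
    truth.cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
    pd.Series(truth.signature_genes, name="gene_id").to_csv(
        out / "truth_signature.tsv", sep="\t", index=False
    )
    manifest["stages"]["simulate"] = {"seed": sim_cfg.seed, "n_cells": counts.n_cells}

    # --- qc -----------------------------------------------------------------
    counts = read_10x_mtx(out / "raw")
    qc_cfg = config.qc or QcConfig(hk_genes=_auto_hk_genes(counts))
    report = []
    step = filter_cells(counts, qc_cfg)
    report.append(("filter_cells", counts.n_cells - step.n_cells, 0))
    counts2 = remove_mito(step, annotation)
    report.append(("remove_mito", 0, step.n_genes - counts2.n_genes))
    step = filter_by_housekeeping(counts2, qc_cfg)
    report.append(("filter_by_housekeeping", counts2.n_cells - step.n_cells, 0))
    filtered = filter_genes(step, qc_cfg.min_cells_per_gene)
    report.append(("filter_genes", 0, step.n_genes - filtered.n_genes))
    write_10x_mtx(filtered, out / "filtered")
    pd.DataFrame(report, columns=["rule", "cells_removed", "genes_removed"]).to_csv(
        out / "qc_report.tsv", sep="\t", index=False
    )
    manifest["stages"]["qc"] = {
        "hk_genes": list(qc_cfg.hk_genes),
        "n_cells": filtered.n_cells,
        "n_genes": filtered.n_genes,
    }

    cell_info = truth.cells.set_index("cell_id").loc[filtered.cell_ids]
    populations = [p.name for p in sim_cfg.populations]
    naive, treated = populations[0], populations[-1]

    # --- cna ----------------------------------------------------------------
    cna_cfg = cna_mod.CnaConfig(window=config.cna_window, step=config.cna_step)
    ref = filtered.subset_cells((cell_info["population"] == naive).to_numpy())
    cna = cna_mod.infer_cna(filtered, ref, annotation, cna_cfg)
    linkage, labels = cna_mod.cluster_cna_profiles(cna, n_clusters=len(populations))
    pd.DataFrame(cna.residuals, columns=cna.cell_ids).to_csv(out / "cna_residuals.tsv", sep="\t", index=False)
    cna.windows.to_csv(out / "cna_windows.tsv", sep="\t", index=False)
    pd.DataFrame({"cell_id": cna.cell_ids, "cluster": labels}).to_csv(
        out / "cna_clusters.tsv", sep="\t", index=False
    )
    manifest["stages"]["cna"] = {"n_windows": int(cna.residuals.shape[0])}

    # --- grn + overlap ------------------------------------------------------
    norm = lognormalize(filtered, qc_cfg.scale_factor, qc_cfg.pseudocount)
    naive_mask = (cell_info["population"] == naive).to_numpy()
    naive_norm = norm.subset_cells(naive_mask)
    variable = find_variable_genes(naive_norm)
    ranked = sorted(
        variable,
        key=lambda g: -naive_norm.values[naive_norm.gene_ids.index(g)].var(),
    )[: config.grn_top_genes]
    grn_cfg = grn_mod.GrnConfig(top_k_edges=config.grn_top_k_edges)
    marker_high = cell_info.loc[naive_mask, "marker_high"].to_numpy()
    nets = {}
    for name, mask in [("marker_high", marker_high), ("marker_low", ~marker_high)]:
        sub = naive_norm.subset_cells(mask)
        sub = sub.subset_genes(np.array([sub.gene_ids.index(g) for g in ranked]))
        net = grn_mod.infer_network(sub, grn_cfg, condition=name)
        net.edges.to_csv(out / f"grn_{name}.tsv", sep="\t", index=False)
        nets[name] = net
    overlay = overlap_mod.overlay_networks(nets["marker_high"], nets["marker_low"])
    communities = overlap_mod.detect_communities(
        overlay, min_size=config.community_min_size, seed=stage_seed(config.seed, "overlap")
    )
    stats_df = overlap_mod.score_communities(
        communities,
        nets["marker_high"],
        nets["marker_low"],
        n_null=config.n_null,
        seed=stage_seed(config.seed, "null"),
    )
    pd.DataFrame(
        [(c.community_id, ";".join(c.nodes)) for c in communities],
        columns=["community_id", "nodes"],
    ).to_csv(out / "communities.tsv", sep="\t", index=False)
    stats_df.to_csv(out / "community_stats.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(a, b, lab) for (a, b), lab in sorted(overlay.labels.items())],
        columns=["gene_a", "gene_b", "label"],
    ).to_csv(out / "overlap_edges.tsv", sep="\t", index=False)
    manifest["stages"]["overlap"] = {
        "n_communities": len(communities),
        "edge_labels": overlay.label_counts(),
    }

    # --- pa -----------------------------------------------------------------
    var_idx = np.array([norm.gene_ids.index(g) for g in variable])
    embed_input = norm.subset_genes(var_idx)
    emb_cfg = pa_mod.EmbeddingConfig(k=config.nmf_k, seed=stage_seed(config.seed, "nmf"))
    embedding, emb_info = pa_mod.embed_nmf(embed_input, emb_cfg)
    thr_call = pa_mod.pa_by_threshold(
        embedding,
        norm.cell_ids,
        threshold=config.pa_threshold,
        eligible=(cell_info["population"] == naive).to_numpy(),
    )
    clf_call, model = pa_mod.pa_by_classifier(
        norm.subset_cells((cell_info["population"] == naive).to_numpy()),
        norm.subset_cells((cell_info["population"] == treated).to_numpy()),
        train_fraction=config.pa_train_fraction,
        seed=stage_seed(config.seed, "classifier"),
    )
    calls = pd.merge(
        thr_call.cells.rename(columns={"score": "threshold_score", "is_pa": "pa_threshold"}),
        clf_call.cells.rename(columns={"score": "classifier_score", "is_pa": "pa_classifier"}),
        on="cell_id",
        how="outer",
    )
    for col in ("pa_threshold", "pa_classifier"):
        calls[col] = calls[col].map(lambda v: bool(v) if v == v else False)
    calls.to_csv(out / "pa_calls.tsv", sep="\t", index=False)
    with open(out / "pa_model.json", "w") as fh:
        json.dump(
            {
                "oob_error": model["oob_error"],
                "n_features": len(model["features"]),
                "features": model["features"],
                "seed": model["seed"],
                "embedding": {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in emb_info.items()},
            },
            fh,
            indent=1,
        )
    manifest["stages"]["pa"] = {
        "n_pa_threshold": int(thr_call.cells["is_pa"].sum()),
        "n_pa_classifier": int(clf_call.cells["is_pa"].sum()),
        "oob_error": model["oob_error"],
    }

    # --- score --------------------------------------------------------------
    present = [g for g in truth.signature_genes if g in norm.gene_ids]
    gs = GeneSet("planted_signature", present)
    sums = sig_mod.score_signature_sum(norm, gs)
    aucell = sig_mod.aucell_score(norm, gs, sig_mod.AucellConfig())
    scores = aucell.assign(sum_score=sums.to_numpy())
    scores.to_csv(out / "signature_scores.tsv", sep="\t", index=False)
    manifest["stages"]["score"] = {"signature_size": len(gs)}

    # --- manifest -----------------------------------------------------------
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    manifest["config"] = json.loads(json.dumps(asdict(config), default=_jsonable))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _auto_hk_genes(counts: CountMatrix, n: int = 3) -> tuple[str, ...]:
    """Stand-in housekeeping panel for simulated data: the most ubiquitously
    detected high-expression genes."""
    detected = np.asarray((counts.matrix > 0).sum(axis=1)).ravel()
    totals = np.asarray(counts.matrix.sum(axis=1)).ravel()
    order = np.lexsort((-totals, -detected))
    return tuple(counts.gene_ids[i] for i in order[:n])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)
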