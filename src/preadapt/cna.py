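"""Copy-number alteration inference from expression.

Per-cell log-normalised expression is averaged over genome-ordered sliding
windows of genes, regressed (OLS) on the matching windowed reference
pseudo-bulk profile, and the residuals are kept as the CNA proxy. Cells are
then hierarchically clustered (Ward linkage, Euclidean distance) on their
residual vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp

from .containers import CountMatrix
from .io import sort_annotation


@dataclass
class CnaConfig:
    min_cells_expressed: int = 25
    window: int = 100
    step: int = 10
    scale_factor: float = 10_000.0
    pseudocount: float = 1.0
    span_chromosomes: bool = True
    include_intercept: bool = True

    def __post_init__(self) -> None:
        if not (self.window >= self.step >= 1):
            raise ValueError("require window >= step >= 1")


@dataclass
class CnaMatrix:
    """Windows x cells residual matrix with window metadata and fit
    coefficients (slope/intercept per cell)."""

    residuals: np.ndarray
    windows: pd.DataFrame  # chromosomes, first/last gene, genomic midpoint
    coefficients: pd.DataFrame  # cell_id, slope, intercept
    cell_ids: list[str]


def _log_transform(vec: np.ndarray, scale_factor: float, pseudocount: float) -> np.ndarray:
    total = vec.sum(axis=0, keepdims=True)
    if np.any(total == 0):
        raise ValueError("profile with zero total counts")
    return np.log2(vec / total * scale_factor + pseudocount)


def build_reference_pseudobulk(
    ref_counts: CountMatrix, scale_factor: float = 10_000.0, pseudocount: float = 1.0
) -> pd.Series:
    """Mean of depth-normalised reference cells, re-normalised and log2-scaled.

    Each reference cell is scaled to ``scale_factor`` total counts, the
    per-gene mean across cells is taken, and the mean profile is itself
    re-normalised to ``scale_factor`` and log2(x + pseudocount)-transformed so
    it matches the transform applied to test cells.
    """
    dense = ref_counts.dense().astype(float)
    totals = dense.sum(axis=0, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("reference cells with zero total counts")
    mean_profile = (dense / totals * scale_factor).mean(axis=1)
    logged = _log_transform(mean_profile[:, None], scale_factor, pseudocount).ravel()
    return pd.Series(logged, index=ref_counts.gene_ids)


def windowed_profile(
    logvalues: np.ndarray | pd.DataFrame,
    annotation: pd.DataFrame,
    cfg: CnaConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sliding-window means over genome-ordered genes.

    ``logvalues`` rows must already be sorted by (chromosome, start) and
    aligned with the sorted ``annotation``. Window ``i`` covers genes
    ``[i*step, i*step + window)``; trailing genes not filling a window are
    dropped. With ``span_chromosomes=False`` the scan restarts on every
    chromosome. Returns (windows x cells means, window metadata).
    """
    if isinstance(logvalues, pd.DataFrame):
        logvalues = logvalues.to_numpy()
    logvalues = np.atleast_2d(np.asarray(logvalues, dtype=float))
    if logvalues.shape[0] == 1 and len(annotation) != 1 and logvalues.shape[1] == len(annotation):
        logvalues = logvalues.T
    n_genes = logvalues.shape[0]
    if len(annotation) != n_genes:
        raise ValueError("annotation rows must match gene rows")

    segments: list[tuple[int, int]] = []  # gene index ranges to scan
    if cfg.span_chromosomes:
        segments.append((0, n_genes))
    else:
        chroms = annotation["chromosome"].to_numpy()
        start = 0
        for i in range(1, n_genes + 1):
            if i == n_genes or chroms[i] != chroms[start]:
                segments.append((start, i))
                start = i

    rows, meta = [], []
    for seg_start, seg_end in segments:
        seg_len = seg_end - seg_start
        if seg_len < cfg.window:
            continue
        n_windows = (seg_len - cfg.window) // cfg.step + 1
        for w in range(n_windows):
            a = seg_start + w * cfg.step
            b = a + cfg.window
            # direct per-window mean: bit-identical to the naive computation
            rows.append(logvalues[a:b].mean(axis=0))
            first, last = a, b - 1
            chrom_span = pd.unique(annotation["chromosome"].iloc[first : last + 1])
            midpoint = 0.5 * (annotation["start"].iloc[first] + annotation["end"].iloc[last])
            meta.append(
                {
                    "window": len(meta),
                    "chromosomes": ",".join(map(str, chrom_span)),
                    "first_gene": annotation["gene_id"].iloc[first],
                    "last_gene": annotation["gene_id"].iloc[last],
                    "midpoint": midpoint,
                }
            )
    if not rows:
        raise ValueError("fewer genes than one window")
    return np.vstack([r[None, :] for r in rows]).reshape(len(rows), -1), pd.DataFrame(meta)


def estimate_cna(
    cell_windows: np.ndarray,
    reference_windows: np.ndarray,
    cfg: CnaConfig,
    cell_ids: list[str] | None = None,
    window_meta: pd.DataFrame | None = None,
) -> CnaMatrix:
    """OLS of each cell's window vector on the reference; residuals are the
    CNA proxy."""
    y = np.asarray(cell_windows, dtype=float)
    r = np.asarray(reference_windows, dtype=float).ravel()
    if y.shape[0] != r.shape[0]:
        raise ValueError("cell and reference window sets differ")
    if np.var(r) == 0:
        raise ValueError("reference window vector has zero variance")
    if cfg.include_intercept:
        rc = r - r.mean()
        slope = (rc @ (y - y.mean(axis=0))) / (rc @ rc)
        intercept = y.mean(axis=0) - slope * r.mean()
        fitted = r[:, None] * slope[None, :] + intercept[None, :]
    else:
        slope = (r @ y) / (r @ r)
        intercept = np.zeros(y.shape[1])
        fitted = r[:, None] * slope[None, :]
    residuals = y - fitted
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(y.shape[1])]
    coef = pd.DataFrame({"cell_id": cell_ids, "slope": slope, "intercept": intercept})
    if window_meta is None:
        window_meta = pd.DataFrame({"window": np.arange(y.shape[0])})
    return CnaMatrix(residuals=residuals, windows=window_meta, coefficients=coef, cell_ids=list(cell_ids))


def infer_cna(
    test_counts: CountMatrix,
    ref_counts: CountMatrix,
    annotation: pd.DataFrame,
    cfg: CnaConfig | None = None,
) -> CnaMatrix:
    """End-to-end CNA estimation for test cells against a reference population.

    The minimum-detection gene filter is applied jointly on the union of test
    and reference cells so both share one gene set; genes are then genome
    ordered, windowed, and each test cell is regressed on the windowed
    reference pseudo-bulk.
    """
    cfg = cfg or CnaConfig()
    common = [g for g in test_counts.gene_ids if g in set(ref_counts.gene_ids)]
    test = test_counts.subset_genes(np.array([test_counts.gene_ids.index(g) for g in common]))
    ref = ref_counts.subset_genes(np.array([ref_counts.gene_ids.index(g) for g in common]))

    detected = (
        np.asarray((test.matrix > 0).sum(axis=1)).ravel()
        + np.asarray((ref.matrix > 0).sum(axis=1)).ravel()
    )
    keep = detected >= cfg.min_cells_expressed
    test, ref = test.subset_genes(keep), ref.subset_genes(keep)

    ann = sort_annotation(annotation[annotation["gene_id"].isin(test.gene_ids)])
    order = [test.gene_ids.index(g) for g in ann["gene_id"]]
    test = test.subset_genes(np.array(order))
    ref = ref.subset_genes(np.array([ref.gene_ids.index(g) for g in ann["gene_id"]]))

    test_log = _log_transform(test.dense().astype(float), cfg.scale_factor, cfg.pseudocount)
    ref_profile = build_reference_pseudobulk(ref, cfg.scale_factor, cfg.pseudocount)

    cell_windows, meta = windowed_profile(test_log, ann, cfg)
    ref_windows, _ = windowed_profile(ref_profile.to_numpy()[:, None], ann, cfg)
    return estimate_cna(cell_windows, ref_windows.ravel(), cfg, test.cell_ids, meta)


def cluster_cna_profiles(cna: CnaMatrix, n_clusters: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Ward-linkage hierarchical clustering of cells on residual vectors.

    Returns (linkage matrix, flat labels obtained by cutting at
    ``n_clusters``).
    """
    profiles = cna.residuals.T  # cells x windows
    linkage = sch.linkage(profiles, method="ward", metric="euclidean")
    labels = sch.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return linkage, labels
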