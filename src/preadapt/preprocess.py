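"""Cell/gene quality filters, log-normalisation, variable-gene selection and
the two-part (hurdle) differential-expression test.

The QC defaults reproduce a stringent droplet-protocol setup: >=1500 detected
genes and >=5000 UMIs per cell, exclusion of mitochondrial genes, removal of
cells in the bottom 1% of a housekeeping-gene score (GAPDH, RPL26, RPL36),
and exclusion of genes detected in fewer than 20 cells. Normalisation is
library-size scaling to 10,000 counts followed by log2(x + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, NormalizedMatrix

log = logging.getLogger("preadapt.preprocess")

DEFAULT_HK_GENES = ("GAPDH", "RPL26", "RPL36")


@dataclass
class QcConfig:
    min_genes_per_cell: int = 1500
    min_umis_per_cell: int = 5000
    top_n_by_umi: int | None = None
    hk_genes: tuple[str, ...] = DEFAULT_HK_GENES
    hk_bottom_quantile: float = 0.01
    min_cells_per_gene: int = 20
    scale_factor: float = 10_000.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hk_bottom_quantile < 1.0:
            raise ValueError("hk_bottom_quantile must lie in [0, 1)")
        if self.scale_factor <= 0 or self.pseudocount <= 0:
            raise ValueError("scale_factor and pseudocount must be positive")


def filter_cells(counts: CountMatrix, cfg: QcConfig) -> CountMatrix:
    """Keep cells with enough detected genes and UMIs (thresholds inclusive).

    With ``top_n_by_umi`` set, only the top-N cells by UMI total enter the
    thresholding step (emulating sorted captures); the order of retained
    cells is preserved either way.
    """
    mat = counts.matrix
    detected = np.asarray((mat > 0).sum(axis=0)).ravel()
    umis = np.asarray(mat.sum(axis=0)).ravel()
    eligible = np.ones(counts.n_cells, dtype=bool)
    if cfg.top_n_by_umi is not None and cfg.top_n_by_umi < counts.n_cells:
        # stable selection: ties broken by original cell order
        order = np.argsort(-umis, kind="stable")[: cfg.top_n_by_umi]
        eligible = np.zeros(counts.n_cells, dtype=bool)
        eligible[order] = True
    keep = eligible & (detected >= cfg.min_genes_per_cell) & (umis >= cfg.min_umis_per_cell)
    if not keep.any():
        log.warning("filter_cells removed every cell")
    log.info("filter_cells: kept %d / %d cells", int(keep.sum()), counts.n_cells)
    return counts.subset_cells(keep)


def remove_mito(
    counts: CountMatrix,
    annotation: pd.DataFrame,
    mito_chromosomes: tuple[str, ...] = ("MT", "chrM", "chrMT", "M"),
    mito_prefix: str = "MT-",
) -> CountMatrix:
    """Drop genes on the mitochondrial chromosome or with the MT- prefix."""
    chrom = annotation.set_index("gene_id")["chromosome"]
    is_mito = np.array(
        [
            str(chrom.get(g, "")) in mito_chromosomes or g.startswith(mito_prefix)
            for g in counts.gene_ids
        ]
    )
    if is_mito.all():
        raise ValueError("all genes are mitochondrial; nothing would remain")
    log.info("remove_mito: dropped %d genes", int(is_mito.sum()))
    return counts.subset_genes(~is_mito)


def filter_by_housekeeping(counts: CountMatrix, cfg: QcConfig) -> CountMatrix:
    """Remove cells in the bottom quantile of the housekeeping score.

    The score is the per-cell sum of log-normalised, gene-standardised values
    of the housekeeping genes. Exactly ``floor(n * q)`` cells are removed:
    the lowest-scoring ones, ties broken by cell order.
    """
    present = [g for g in cfg.hk_genes if g in counts.gene_ids]
    if not present:
        raise ValueError(f"none of the housekeeping genes {list(cfg.hk_genes)} are present")
    norm = lognormalize(counts, cfg.scale_factor, cfg.pseudocount)
    idx = [norm.gene_ids.index(g) for g in present]
    vals = norm.values[idx, :]
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    score = ((vals - mu) / sd).sum(axis=0)
    n_remove = int(np.floor(counts.n_cells * cfg.hk_bottom_quantile))
    if n_remove == 0:
        return counts
    drop = np.argsort(score, kind="stable")[:n_remove]
    keep = np.ones(counts.n_cells, dtype=bool)
    keep[drop] = False
    log.info("filter_by_housekeeping: removed %d cells (genes used: %s)", n_remove, present)
    return counts.subset_cells(keep)


def filter_genes(counts: CountMatrix, min_cells: int) -> CountMatrix:
    """Keep genes detected (nonzero) in at least ``min_cells`` cells."""
    detected_in = np.asarray((counts.matrix > 0).sum(axis=1)).ravel()
    keep = detected_in >= min_cells
    log.info("filter_genes: kept %d / %d genes", int(keep.sum()), counts.n_genes)
    return counts.subset_genes(keep)


def lognormalize(
    counts: CountMatrix, scale_factor: float = 10_000.0, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """value(g, c) = log2(count / cell_total * scale_factor + pseudocount)."""
    totals = np.asarray(counts.matrix.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        raise ValueError("cells with zero total counts cannot be normalised")
    dense = counts.dense().astype(float)
    values = np.log2(dense / totals[None, :] * scale_factor + pseudocount)
    if pseudocount == 1.0:
        values[dense == 0] = 0.0  # exact zeros, no rounding residue
    return NormalizedMatrix(values, counts.gene_ids, counts.cell_ids)


def find_variable_genes(
    norm: NormalizedMatrix,
    x_low: float = 0.01,
    x_high: float = 6.0,
    y_cutoff: float = 0.01,
    num_bins: int = 100,
) -> list[str]:
    """Mean/dispersion variable-gene selection.

    The mean statistic is the exponentiated-mean convention
    ``log2(mean(2^x - 1) + 1)`` and the dispersion is ``log2(var/mean)`` of
    the de-logged values, z-scored within ``num_bins`` equal-width bins of
    the mean. Bins holding a single gene (or zero spread) get z = 0.
    """
    linear = np.exp2(norm.values) - 1.0
    m = linear.mean(axis=1)
    v = linear.var(axis=1, ddof=0)
    mean_metric = np.log2(m + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where((m > 0) & (v > 0), np.log2(np.where(m > 0, v / np.maximum(m, 1e-300), 1.0)), 0.0)

    lo, hi = mean_metric.min(), mean_metric.max()
    if hi == lo:
        bins = np.zeros(norm.n_genes, dtype=int)
    else:
        edges = np.linspace(lo, hi, num_bins + 1)
        bins = np.clip(np.digitize(mean_metric, edges[1:-1]), 0, num_bins - 1)

    z = np.zeros(norm.n_genes)
    for b in np.unique(bins):
        in_bin = bins == b
        if in_bin.sum() <= 1:
            continue
        sd = disp[in_bin].std(ddof=0)
        if sd == 0:
            continue
        z[in_bin] = (disp[in_bin] - disp[in_bin].mean()) / sd

    selected = (mean_metric >= x_low) & (mean_metric <= x_high) & (z >= y_cutoff)
    return [g for g, s in zip(norm.gene_ids, selected) if s]


# ---------------------------------------------------------------------------
# differential expression: two-part hurdle likelihood-ratio test


def differential_expression(
    norm: NormalizedMatrix,
    group_labels,
    focal_group=None,
    q_cutoff: float = 0.05,
    auc_cutoff: float = 0.6,
) -> pd.DataFrame:
    """Hurdle LRT + rank AUC marker test between exactly two groups.

    Per gene, a detection component (binomial LRT on the nonzero fraction)
    and a level component (Gaussian LRT on log-expression among detected
    cells) are combined into a chi-square statistic with 2 df. The AUC is the
    Wilcoxon U statistic of the focal group scaled to [0, 1] (ties counted
    one half). ``marker`` requires BH q <= ``q_cutoff`` and
    AUC >= ``auc_cutoff``.
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != norm.n_cells:
        raise ValueError("one label per cell required")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    if focal_group is None:
        focal_group = groups[0]
    in_a = labels == focal_group
    in_b = ~in_a
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")

    x = norm.values
    nz = x != 0
    k_a = nz[:, in_a].sum(axis=1).astype(float)
    k_b = nz[:, in_b].sum(axis=1).astype(float)

    stat = _binomial_lrt(k_a, n_a, k_b, n_b) + _level_lrt(x, nz, in_a, in_b)
    all_zero = (k_a + k_b) == 0
    p = stats.chi2.sf(stat, df=2)
    p[all_zero] = 1.0

    auc = _rank_auc(x, in_a, in_b)
    auc[all_zero] = 0.5

    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene_id": norm.gene_ids,
            "statistic": stat,
            "p_value": p,
            "q_value": q,
            "auc": auc,
            "direction": np.where(auc >= 0.5, "up", "down"),
        }
    )
    out["marker"] = (out["q_value"] <= q_cutoff) & (out["auc"] >= auc_cutoff)
    return out


def _binomial_lrt(k_a, n_a, k_b, n_b):
    def ll(k, n):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = k / n
            t1 = np.where(k > 0, k * np.log(np.where(p > 0, p, 1.0)), 0.0)
            t2 = np.where(n - k > 0, (n - k) * np.log(np.where(p < 1, 1 - p, 1.0)), 0.0)
        return t1 + t2

    pooled = ll(k_a + k_b, n_a + n_b)
    return 2.0 * (ll(k_a, n_a) + ll(k_b, n_b) - pooled)


def _level_lrt(x, nz, in_a, in_b):
    """Gaussian equal-means LRT on detected cells: n * ln(RSS0 / RSS1)."""
    xa, nza = x[:, in_a], nz[:, in_a]
    xb, nzb = x[:, in_b], nz[:, in_b]
    k_a = nza.sum(axis=1)
    k_b = nzb.sum(axis=1)
    s_a = (xa * nza).sum(axis=1)
    s_b = (xb * nzb).sum(axis=1)
    ss_a = (xa**2 * nza).sum(axis=1)
    ss_b = (xb**2 * nzb).sum(axis=1)
    k = k_a + k_b
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = (ss_a - np.where(k_a > 0, s_a**2 / np.maximum(k_a, 1), 0.0)) + (
            ss_b - np.where(k_b > 0, s_b**2 / np.maximum(k_b, 1), 0.0)
        )
        rss0 = (ss_a + ss_b) - np.where(k > 0, (s_a + s_b) ** 2 / np.maximum(k, 1), 0.0)
    rss1 = np.maximum(rss1, 0.0)
    rss0 = np.maximum(rss0, 0.0)
    stat = np.zeros_like(rss0)
    both = (k_a > 0) & (k_b > 0) & (rss0 > 0)
    # perfectly fitted alternative: cap the ratio rather than divide by zero
    ratio = np.where(rss1 > 0, rss0 / np.maximum(rss1, 1e-300), np.inf)
    with np.errstate(over="ignore"):
        stat[both] = k[both] * np.log(np.minimum(ratio[both], 1e12))
    return stat


def _rank_auc(x, in_a, in_b):
    """AUC = U / (n_a * n_b) from mid-ranks, focal group as positives."""
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    ranks = stats.rankdata(x, axis=1, method="average")
    r_a = ranks[:, in_a].sum(axis=1)
    u = r_a - n_a * (n_a + 1) / 2.0
    return u / (n_a * n_b)
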