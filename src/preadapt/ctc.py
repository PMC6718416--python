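"""Circulating-tumour-cell re-analysis statistics.

Two permutation-tested readouts: (i) for paired capture/control profiles,
the fraction of fold-change DEGs that overlap a signature, compared between
case and healthy pairs; (ii) for cluster versus single-CTC pools, a
max-normalised signature sum-score. Both use a Wilcoxon rank-sum test whose
significance is re-assessed by label permutation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSet

log = logging.getLogger("preadapt.ctc")


@dataclass
class CtcConfig:
    linear_fc_cutoff: float = 1.5
    n_permutations: int = 1000
    pseudocount: float = 1.0
    scale_factor: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.linear_fc_cutoff <= 1:
            raise ValueError("linear_fc_cutoff must exceed 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def _depth_normalise(profile: np.ndarray, scale_factor: float) -> np.ndarray:
    total = profile.sum()
    if total <= 0:
        raise ValueError("profile with non-positive total")
    return profile / total * scale_factor


def capture_deg_fraction(
    tumour_profile: np.ndarray | pd.Series,
    control_profile: np.ndarray | pd.Series,
    gene_ids,
    gs: GeneSet,
    cfg: CtcConfig | None = None,
) -> float | None:
    """Fraction of capture-vs-control DEGs overlapping the gene set.

    DEGs are genes whose depth-normalised linear ratio
    (tumour + pc) / (control + pc) is >= the fold-change cutoff (inclusive).
    Returns ``None`` when no gene passes the cutoff.
    """
    cfg = cfg or CtcConfig()
    t = _depth_normalise(np.asarray(tumour_profile, dtype=float), cfg.scale_factor)
    c = _depth_normalise(np.asarray(control_profile, dtype=float), cfg.scale_factor)
    ratio = (t + cfg.pseudocount) / (c + cfg.pseudocount)
    deg = np.asarray(gene_ids)[ratio >= cfg.linear_fc_cutoff]
    if deg.size == 0:
        log.warning("no DEGs at fold-change >= %s; fraction undefined", cfg.linear_fc_cutoff)
        return None
    members = set(gs.genes)
    return float(np.mean([g in members for g in deg]))


def capture_fractions(
    profiles: pd.DataFrame, labels: pd.DataFrame, gs: GeneSet, cfg: CtcConfig | None = None
) -> pd.DataFrame:
    """Per-pair DEG-overlap fractions from paired capture/control columns."""
    cfg = cfg or CtcConfig()
    rows = []
    for pair_id, grp in labels.groupby("pair_id", sort=False):
        cap = grp.loc[grp["arm"] == "capture", "column"].iloc[0]
        ctl = grp.loc[grp["arm"] == "control", "column"].iloc[0]
        frac = capture_deg_fraction(profiles[cap], profiles[ctl], profiles.index, gs, cfg)
        rows.append((pair_id, grp["group"].iloc[0], frac))
    return pd.DataFrame(rows, columns=["pair_id", "group", "fraction"])


# ---------------------------------------------------------------------------
# rank-sum test with permutation FDR


def _ranksum_u(values: np.ndarray, case_mask: np.ndarray) -> float:
    ranks = stats.rankdata(values)
    n_case = int(case_mask.sum())
    return ranks[case_mask].sum() - n_case * (n_case + 1) / 2.0


def group_fraction_test(
    case_values,
    control_values,
    cfg: CtcConfig | None = None,
) -> dict:
    """Wilcoxon rank-sum p plus a permutation FDR.

    The FDR is the permutation-based probability, under label exchange, of a
    test p-value at most as small as the observed one (the (r+1)/(n+1)
    convention). Because the two-sided rank-sum p is a monotone function of
    |U - n1 n2 / 2| on the pooled data, permuted p-values are compared via
    the U statistic directly.
    """
    cfg = cfg or CtcConfig()
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups need at least one observation")
    if case.size == 1 or control.size == 1:
        warnings.warn("single-observation group: rank-sum test is degenerate", stacklevel=2)
    pooled = np.concatenate([case, control])
    if np.unique(pooled).size == 1:  # every observation tied: no evidence
        return {
            "statistic": float(case.size * control.size / 2.0),
            "p_value": 1.0,
            "fdr": 1.0,
            "n_case": int(case.size),
            "n_control": int(control.size),
        }
    has_ties = np.unique(pooled).size < pooled.size
    method = "asymptotic" if has_ties else "exact"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(case, control, alternative="two-sided", method=method)
    p_obs = float(res.pvalue)

    n_case = case.size
    mid = n_case * control.size / 2.0
    obs_dev = abs(_ranksum_u(pooled, np.arange(pooled.size) < n_case) - mid)

    rng = np.random.default_rng(cfg.seed)
    ranks = stats.rankdata(pooled)
    deviations = np.empty(cfg.n_permutations)
    for i in range(cfg.n_permutations):
        pick = rng.choice(pooled.size, size=n_case, replace=False)
        u = ranks[pick].sum() - n_case * (n_case + 1) / 2.0
        deviations[i] = abs(u - mid)
    fdr = (np.sum(deviations >= obs_dev - 1e-12) + 1) / (cfg.n_permutations + 1)
    return {
        "statistic": float(res.statistic),
        "p_value": p_obs,
        "fdr": float(fdr),
        "n_case": int(n_case),
        "n_control": int(control.size),
    }


def cluster_vs_single_score(
    profiles: pd.DataFrame,
    group_labels,
    gs: GeneSet,
    cfg: CtcConfig | None = None,
) -> dict:
    """Max-normalised signature sum-scores of CTC clusters versus singles.

    Each profile is depth-normalised, the signature genes are summed, and
    the scores are divided by their maximum (so the top profile scores 1).
    Cluster and single-pool scores are compared by a Wilcoxon rank-sum test
    with permutation FDR.
    """
    cfg = cfg or CtcConfig()
    labels = np.asarray(group_labels)
    if set(labels) - {"cluster", "single_pool"}:
        raise ValueError("group labels must be 'cluster' or 'single_pool'")
    idx = [i for i, g in enumerate(profiles.index) if g in set(gs.genes)]
    if not idx:
        raise ValueError("signature shares no genes with the profiles")
    x = profiles.to_numpy(dtype=float)
    x = x / x.sum(axis=0, keepdims=True) * cfg.scale_factor
    scores = x[idx, :].sum(axis=0)
    scores = scores / scores.max()
    cluster = scores[labels == "cluster"]
    single = scores[labels == "single_pool"]
    test = group_fraction_test(cluster, single, cfg)
    return {
        "scores": pd.Series(scores, index=profiles.columns, name=gs.name),
        **test,
    }
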