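"""Rare pre-adapted (PA) cell detection.

Two complementary strategies: (i) a threshold on the leading component of a
non-negative matrix factorisation embedding of the expression matrix, and
(ii) a random-forest misclassification procedure — a classifier trained to
separate two conditions flags those treatment-naive cells it confidently
assigns to the treated condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import NMF
from sklearn.ensemble import RandomForestClassifier

from .containers import NormalizedMatrix
from .preprocess import differential_expression

log = logging.getLogger("preadapt.pa")


@dataclass
class EmbeddingConfig:
    k: int | str = "auto"
    mask_fraction: float = 0.20
    k_grid: tuple[int, ...] = tuple(range(2, 51, 2))
    init: str = "deterministic_svd"  # deterministic_svd | seeded_random
    max_cells_for_selection: int = 1000
    n_mask_repeats: int = 3
    k_rel_tolerance: float = 0.05
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mask_fraction < 1.0:
            raise ValueError("mask_fraction must lie in (0, 1)")
        if self.k != "auto" and int(self.k) < 2:
            raise ValueError("k must be >= 2")
        if self.init not in {"deterministic_svd", "seeded_random"}:
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class PaCall:
    """Per-cell PA call: detection method, score and boolean flag."""

    method: str
    cells: pd.DataFrame  # cell_id, score, is_pa
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# NMF embedding


def embed_nmf(norm: NormalizedMatrix, cfg: EmbeddingConfig | None = None) -> tuple[np.ndarray, dict]:
    """Cells x k NMF factor matrix, each factor min-max scaled to [0, 1].

    Factorisation uses multiplicative updates minimising squared error. With
    ``k='auto'``, k is chosen on a cell subsample by masked-entry imputation:
    ``mask_fraction`` of entries are held out, the factorisation is fit on
    the rest, and the k minimising held-out MSE over ``k_grid`` wins.
    Factors are ordered by the explained variance of their reconstruction
    contribution, descending.
    """
    cfg = cfg or EmbeddingConfig()
    x = norm.values.T  # cells x genes
    if (x < 0).any():
        raise ValueError("NMF requires non-negative input")

    info: dict = {"seed": cfg.seed}
    if cfg.k == "auto":
        k = select_k_masked(x, cfg)
        info["k_selected"] = k
    else:
        k = int(cfg.k)
    info["k"] = k

    init = "nndsvda" if cfg.init == "deterministic_svd" else "random"
    model = NMF(
        n_components=k,
        init=init,
        solver="mu",
        beta_loss="frobenius",
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        random_state=cfg.seed,
    )
    w = model.fit_transform(x)  # cells x k
    h = model.components_
    info["reconstruction_mse"] = float(np.mean((x - w @ h) ** 2))

    # order factors by explained variance of their reconstruction term
    contrib_var = np.array([np.var(np.outer(w[:, f], h[f, :])) for f in range(k)])
    order = np.argsort(-contrib_var, kind="stable")
    w = w[:, order]
    info["factor_variance"] = contrib_var[order]

    lo = w.min(axis=0, keepdims=True)
    span = w.max(axis=0, keepdims=True) - lo
    span[span == 0] = 1.0
    return (w - lo) / span, info


def select_k_masked(x: np.ndarray, cfg: EmbeddingConfig) -> int:
    """Pick k by masked-entry imputation MSE on a cell subsample.

    The held-out MSE is averaged over ``n_mask_repeats`` independent masks,
    which stabilises the selection where the error curve is flat beyond the
    true rank."""
    rng = np.random.default_rng(cfg.seed)
    if x.shape[0] > cfg.max_cells_for_selection:
        rows = rng.choice(x.shape[0], size=cfg.max_cells_for_selection, replace=False)
        x = x[rows, :]
    masks = [rng.random(x.shape) >= cfg.mask_fraction for _ in range(cfg.n_mask_repeats)]
    mse_by_k: dict[int, float] = {}
    for k in cfg.k_grid:
        if k >= min(x.shape):
            break
        mses = []
        for mask in masks:
            w, h = _masked_nmf(x, mask, k, rng)
            held = ~mask
            mses.append(float(np.mean((x[held] - (w @ h)[held]) ** 2)))
        mse_by_k[int(k)] = float(np.mean(mses))
    if not mse_by_k:
        raise ValueError("k grid empty or larger than the matrix")
    # parsimony: the imputation-error curve is flat beyond the true rank, so
    # take the smallest k within a relative tolerance of the minimum
    best = min(mse_by_k.values())
    return min(k for k, m in mse_by_k.items() if m <= (1.0 + cfg.k_rel_tolerance) * best)


def _masked_nmf(
    x: np.ndarray, mask: np.ndarray, k: int, rng: np.random.Generator, n_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted multiplicative-update NMF treating masked entries as missing."""
    m = mask.astype(float)
    xm = x * m
    scale = np.sqrt(max(x[mask].mean(), 1e-12) / k)
    w = rng.random((x.shape[0], k)) * scale + 1e-6
    h = rng.random((k, x.shape[1])) * scale + 1e-6
    eps = 1e-12
    for _ in range(n_iter):
        wh = w @ h
        w *= (xm @ h.T) / ((m * wh) @ h.T + eps)
        wh = w @ h
        h *= (w.T @ xm) / (w.T @ (m * wh) + eps)
    return w, h


def pa_by_threshold(
    embedding: np.ndarray,
    cell_ids: list[str],
    component_index: int = 0,
    threshold: float = 0.75,
    eligible: np.ndarray | None = None,
) -> PaCall:
    """Flag cells whose scaled leading-component loading is >= ``threshold``.

    ``eligible`` optionally restricts calls (e.g. to the treatment-naive
    condition when the embedding spans several conditions).
    """
    score = np.asarray(embedding)[:, component_index]
    flag = score >= threshold
    if eligible is not None:
        flag = flag & np.asarray(eligible, dtype=bool)
    cells = pd.DataFrame({"cell_id": cell_ids, "score": score, "is_pa": flag})
    return PaCall(method="threshold", cells=cells, details={"threshold": threshold, "component": component_index})


# ---------------------------------------------------------------------------
# random-forest misclassification


def pa_by_classifier(
    norm_a: NormalizedMatrix,
    norm_b: NormalizedMatrix,
    train_fraction: float = 0.10,
    prob_cutoff: float = 0.5,
    seed: int = 0,
    n_trees: int = 500,
) -> tuple[PaCall, dict]:
    """Random-forest outlier detection of condition-A cells resembling B.

    Cells of each condition are split into a training set (``train_fraction``)
    and a testing set. Differentially expressed genes are called on training
    cells only (marker rule: BH q <= 0.05 and AUC >= 0.6, either direction)
    and used as features of a seeded random forest (``n_trees`` trees,
    sqrt(n_features) candidate features per split). Condition-A test cells
    with P(condition B) > ``prob_cutoff`` are flagged PA. The out-of-bag
    error of the forest is recorded as the expected misclassification rate.
    """
    if norm_a.n_cells == 0 or norm_b.n_cells == 0:
        raise ValueError("both conditions must contain cells")
    if norm_a.gene_ids != norm_b.gene_ids:
        raise ValueError("conditions must share one gene universe")
    rng = np.random.default_rng(seed)
    train_a = _split_mask(norm_a.n_cells, train_fraction, rng)
    train_b = _split_mask(norm_b.n_cells, train_fraction, rng)

    joint_train = NormalizedMatrix(
        np.concatenate([norm_a.values[:, train_a], norm_b.values[:, train_b]], axis=1),
        norm_a.gene_ids,
        [f"a:{c}" for c in np.array(norm_a.cell_ids)[train_a]]
        + [f"b:{c}" for c in np.array(norm_b.cell_ids)[train_b]],
    )
    labels = np.array(["A"] * int(train_a.sum()) + ["B"] * int(train_b.sum()))
    de = differential_expression(joint_train, labels, focal_group="B")
    degs = de.loc[(de["q_value"] <= 0.05) & ((de["auc"] >= 0.6) | (de["auc"] <= 0.4)), "gene_id"]
    if degs.empty:
        raise ValueError(
            "no differentially expressed genes on the training split; "
            "increase the training fraction or relax the marker thresholds"
        )
    feat_idx = [norm_a.gene_ids.index(g) for g in degs]

    x_train = np.concatenate(
        [norm_a.values[np.ix_(feat_idx, np.flatnonzero(train_a))].T,
         norm_b.values[np.ix_(feat_idx, np.flatnonzero(train_b))].T]
    )
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(x_train, labels)
    oob_error = 1.0 - forest.oob_score_
    n_oob = len(labels)
    oob_errors = int(round(oob_error * n_oob))

    test_a = ~train_a
    x_test = norm_a.values[np.ix_(feat_idx, np.flatnonzero(test_a))].T
    proba_b = forest.predict_proba(x_test)[:, list(forest.classes_).index("B")]
    flag = proba_b > prob_cutoff
    cells = pd.DataFrame(
        {
            "cell_id": np.array(norm_a.cell_ids)[test_a],
            "score": proba_b,
            "is_pa": flag,
        }
    )
    model_summary = {
        "features": list(degs),
        "oob_error": float(oob_error),
        "oob_errors": oob_errors,
        "n_oob": n_oob,
        "seed": seed,
        "n_train_a": int(train_a.sum()),
        "n_train_b": int(train_b.sum()),
        "forest": forest,
        "feature_index": feat_idx,
    }
    return PaCall(method="classifier", cells=cells, details={"prob_cutoff": prob_cutoff, "oob_error": float(oob_error)}), model_summary


def _split_mask(n: int, train_fraction: float, rng: np.random.Generator) -> np.ndarray:
    n_train = max(1, int(round(n * train_fraction)))
    idx = rng.choice(n, size=n_train, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    return mask


def misclassification_test(
    model_summary: dict,
    held_out: NormalizedMatrix,
    true_label: str = "A",
) -> dict:
    """Fraction of held-out cells assigned to the opposite condition,
    compared with the forest's out-of-bag error.

    Two comparisons are reported: a binomial test of the observed count
    against the OOB rate taken as fixed, and Fisher's exact test of the two
    error counts. The binomial test is hypersensitive when the OOB rate is
    near zero (its own sampling noise then dominates); the Fisher comparison
    accounts for both rates being estimates and is the one to use for
    calibration claims.
    """
    if held_out.n_cells == 0:
        raise ValueError("held-out set is empty")
    forest: RandomForestClassifier = model_summary["forest"]
    x = held_out.values[model_summary["feature_index"], :].T
    predicted = forest.predict(x)
    mis = predicted != true_label
    observed = float(mis.mean())
    expected = float(model_summary["oob_error"])
    binom = stats.binomtest(
        int(mis.sum()), held_out.n_cells, p=min(max(expected, 1e-12), 1 - 1e-12)
    )
    k_obs, n_obs = int(mis.sum()), held_out.n_cells
    k_oob, n_oob = model_summary["oob_errors"], model_summary["n_oob"]
    _, fisher_p = stats.fisher_exact(
        [[k_obs, n_obs - k_obs], [k_oob, n_oob - k_oob]], alternative="two-sided"
    )
    return {
        "observed_misclassified_fraction": observed,
        "expected_rate": expected,
        "n_cells": held_out.n_cells,
        "binomial_p": float(binom.pvalue),
        "fisher_p": float(fisher_p),
    }
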