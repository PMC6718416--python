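"""Gene regulatory network inference by partial information decomposition.

Expression is discretised per gene into equal-width bins; every unordered
gene pair is scored by its proportional unique contribution (summed over all
third-gene contexts, normalised by the pairwise mutual information) and
calibrated through each gene's empirical CDF of pair scores — the PIDC
scheme. Redundancy uses the Williams–Beer minimum specific information,
which keeps every decomposition term non-negative.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix

log = logging.getLogger("preadapt.grn")


@dataclass
class GrnConfig:
    min_cell_fraction: float = 0.20
    n_bins: int = 6
    top_k_edges: int = 2000
    estimator: str = "pid_puc"  # pid_puc | mutual_information

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.top_k_edges < 1:
            raise ValueError("top_k_edges must be >= 1")
        if self.estimator not in {"pid_puc", "mutual_information"}:
            raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass
class PidComponents:
    """Williams–Beer decomposition of I(target; source1, source2), in bits."""

    redundancy: float
    unique_source1: float
    unique_source2: float
    synergy: float
    total: float


@dataclass
class GeneNetwork:
    """Top-K undirected weighted edge list with a provenance tag."""

    nodes: list[str]
    edges: pd.DataFrame  # gene_a, gene_b, confidence, rank
    condition: str = ""

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b))) for a, b in zip(self.edges["gene_a"], self.edges["gene_b"])}


# ---------------------------------------------------------------------------
# discretisation and information measures


def discretize(values: np.ndarray, n_bins: int = 6) -> np.ndarray:
    """Per-gene equal-width binning of a genes x cells matrix.

    Bin k covers [min + k*w, min + (k+1)*w) (lower-edge inclusive); the
    maximum lands in the last bin; constant genes map to all zeros.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.floor((values - lo) / span * n_bins)
    idx = np.where(span == 0, 0, idx)
    return np.clip(idx, 0, n_bins - 1).astype(np.int64)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two discrete vectors."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    kx, ky = x.max() + 1, y.max() + 1
    joint = np.bincount(x * ky + y, minlength=kx * ky).reshape(kx, ky) / x.size
    return _mi_from_joint(joint)


def _mi_from_joint(joint: np.ndarray) -> float:
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def _joint3(t: np.ndarray, s1: np.ndarray, s2: np.ndarray, k: int) -> np.ndarray:
    code = (t * k + s1) * k + s2
    return np.bincount(code, minlength=k**3).reshape(k, k, k) / t.size


def pid_decompose(
    target: np.ndarray, source1: np.ndarray, source2: np.ndarray, n_symbols: int | None = None
) -> PidComponents:
    """Williams–Beer PID of two sources' information about a target.

    Redundancy is the expected minimum specific information
    ``sum_t p(t) min_S I_spec(t; S)`` with
    ``I_spec(t; S) = sum_s p(s|t) log2(p(t|s)/p(t))``; unique and synergy
    terms follow by the usual lattice relations.
    """
    target = np.asarray(target, dtype=np.int64)
    source1 = np.asarray(source1, dtype=np.int64)
    source2 = np.asarray(source2, dtype=np.int64)
    if not (target.shape == source1.shape == source2.shape):
        raise ValueError("length mismatch")
    if n_symbols is None:
        n_symbols = int(max(target.max(), source1.max(), source2.max())) + 1
    joint = _joint3(target, source1, source2, n_symbols)
    return pid_from_joint(joint)


def pid_from_joint(joint: np.ndarray) -> PidComponents:
    """PID from a (target, source1, source2) joint probability array."""
    joint = np.asarray(joint, dtype=float)
    joint = joint / joint.sum()
    p_t = joint.sum(axis=(1, 2))
    p_ts1 = joint.sum(axis=2)
    p_ts2 = joint.sum(axis=1)

    i_t_s1 = _mi_from_joint(p_ts1)
    i_t_s2 = _mi_from_joint(p_ts2)
    i_t_s12 = _mi_from_joint(joint.reshape(joint.shape[0], -1))

    redundancy = _imin(p_t, [p_ts1, p_ts2])
    unique1 = i_t_s1 - redundancy
    unique2 = i_t_s2 - redundancy
    synergy = i_t_s12 - i_t_s1 - i_t_s2 + redundancy
    return PidComponents(
        redundancy=redundancy,
        unique_source1=max(unique1, 0.0),
        unique_source2=max(unique2, 0.0),
        synergy=max(synergy, 0.0),
        total=i_t_s12,
    )


def _imin(p_t: np.ndarray, marginals: list[np.ndarray]) -> float:
    """Expected minimum specific information over the given sources."""
    spec = []
    for p_ts in marginals:
        p_s = p_ts.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_s_given_t = np.where(p_t[:, None] > 0, p_ts / np.maximum(p_t[:, None], 1e-300), 0.0)
            ratio = np.where((p_ts > 0), p_ts / (p_s * np.maximum(p_t[:, None], 1e-300)), 1.0)
        spec.append(np.sum(p_s_given_t * np.log2(ratio), axis=1))
    spec = np.vstack(spec)
    return float(np.sum(p_t * spec.min(axis=0)))


# ---------------------------------------------------------------------------
# PIDC edge scoring


def filter_expressed(norm: NormalizedMatrix, min_cell_fraction: float) -> NormalizedMatrix:
    """Drop genes expressed (nonzero) in fewer than the given cell fraction."""
    frac = (norm.values != 0).mean(axis=1)
    return norm.subset_genes(frac >= min_cell_fraction)


def pidc_scores(disc: np.ndarray, gene_names: list[str], cfg: GrnConfig | None = None) -> pd.DataFrame:
    """All-pairs PIDC confidence scores from a discretised genes x cells matrix.

    For each unordered pair (X, Y) the proportional unique contribution
    ``u(X, Y) = sum_Z [unique_Y(X|{Y,Z}) + unique_X(Y|{X,Z})] / I(X;Y)`` is
    accumulated over all third genes Z; the confidence is
    ``F_X(u) + F_Y(u)`` with F the per-gene empirical CDF of its u values.
    Zero-MI pairs score u = 0.
    """
    cfg = cfg or GrnConfig()
    disc = np.asarray(disc, dtype=np.int64)
    n = disc.shape[0]
    if n < 3:
        raise ValueError("PIDC needs at least 3 genes (no third-party contexts)")
    k = int(disc.max()) + 1

    mi = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mi[i, j] = mi[j, i] = mutual_information(disc[i], disc[j])

    if cfg.estimator == "mutual_information":
        u = mi.copy()
    else:
        # u_contrib[t, s]: sum over contexts of unique information source s
        # carries about target t
        u_contrib = np.zeros((n, n))
        codes_hi = disc * k  # cached per-gene code component
        for t in range(n):
            others = [g for g in range(n) if g != t]
            t_code = disc[t] * k * k
            for a, b in itertools.combinations(others, 2):
                joint = np.bincount(t_code + codes_hi[a] + disc[b], minlength=k**3).reshape(k, k, k)
                comp = pid_from_joint(joint / joint.sum())
                u_contrib[t, a] += comp.unique_source1
                u_contrib[t, b] += comp.unique_source2
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(mi > 0, (u_contrib + u_contrib.T) / np.maximum(mi, 1e-300), 0.0)

    confidence = np.zeros((n, n))
    # per-gene empirical CDF over that gene's pair scores
    for g in range(n):
        partners = np.array([h for h in range(n) if h != g])
        vals = u[g, partners]
        order = np.argsort(vals, kind="stable")
        cdf = np.empty(len(vals))
        cdf[order] = np.searchsorted(np.sort(vals), vals[order], side="right") / len(vals)
        confidence[g, partners] += cdf

    # confidence(i, j) = F_i(u_ij) + F_j(u_ij)
    rows = [
        (gene_names[i], gene_names[j], u[i, j], confidence[i, j] + confidence[j, i])
        for i, j in itertools.combinations(range(n), 2)
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "u", "confidence"])


def build_network(scores: pd.DataFrame, cfg: GrnConfig | None = None, condition: str = "") -> GeneNetwork:
    """Keep the top-K edges by confidence, ties broken lexicographically."""
    cfg = cfg or GrnConfig()
    df = scores.copy()
    pairs = np.sort(df[["gene_a", "gene_b"]].to_numpy(), axis=1)
    df["gene_a"], df["gene_b"] = pairs[:, 0], pairs[:, 1]
    df = df.sort_values(
        ["confidence", "gene_a", "gene_b"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    df = df.head(cfg.top_k_edges).copy()
    df["rank"] = np.arange(1, len(df) + 1)
    nodes = sorted(set(df["gene_a"]) | set(df["gene_b"]))
    return GeneNetwork(nodes=nodes, edges=df[["gene_a", "gene_b", "confidence", "rank"]], condition=condition)


def infer_network(
    norm: NormalizedMatrix, cfg: GrnConfig | None = None, condition: str = ""
) -> GeneNetwork:
    """Full pipeline: expression filter, discretise, PIDC scores, top-K edges."""
    cfg = cfg or GrnConfig()
    kept = filter_expressed(norm, cfg.min_cell_fraction)
    if kept.n_genes < 3:
        raise ValueError("fewer than 3 genes pass the expression filter")
    disc = discretize(kept.values, cfg.n_bins)
    scores = pidc_scores(disc, kept.gene_ids, cfg)
    return build_network(scores, cfg, condition=condition)
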