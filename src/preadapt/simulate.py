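"""Synthetic single-cell data generators with planted ground truth.

The generators emulate the statistical structure the downstream analyses
assume: two cell populations carrying distinct copy-number blocks that act
multiplicatively on expression means, a rare subpopulation whose signature
genes are shifted towards the second population (the "pre-adapted" mimic), a
bimodal surface-marker gene, negative-binomial UMI counts with optional
logistic dropout, small expression sets driven by known dependency networks,
and CTC-like capture/control profile pairs.

All draws flow from the ``seed`` of the corresponding config, so identical
configurations are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from .containers import CountMatrix, GeneSet

# ---------------------------------------------------------------------------
# configuration


@dataclass
class CnaBlock:
    """A contiguous copy-number block over genome-ordered gene indices.

    ``start``/``end`` are half-open global gene indices (genome order);
    ``fold`` multiplies the expected expression of every gene in the block.
    """

    start: int
    end: int
    fold: float
    chromosome: str | None = None

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("CNA fold-change must be positive")
        if self.start < 0 or self.end <= self.start:
            raise ValueError("CNA block indices must satisfy 0 <= start < end")


@dataclass
class PopulationSpec:
    """One simulated cell population.

    ``signature_shift`` is a log2 shift applied to the signature genes of
    every cell in the population (scale-free effect size); CNA blocks act
    multiplicatively on the mean of the covered genes.
    """

    name: str
    cna_blocks: list[CnaBlock] = field(default_factory=list)
    signature_shift: float = 0.0


@dataclass
class SimConfig:
    """Study conditions for :func:`simulate_counts`.

    Defaults model a sorted 10x experiment: ~2000 genes, two populations
    (treatment-naive vs starved), a 2-fold signature shift in the starved
    population, 1% pre-adapted (rare) cells inside the naive population that
    mimic the starved signature, a bimodal surface marker splitting the naive
    population, and moderately overdispersed counts with logistic dropout.
    """

    n_genes: int = 2000
    n_cells_per_population: int = 1000
    populations: list[PopulationSpec] | None = None
    rare_fraction: float = 0.01
    rare_population: str | None = None
    rare_shift: float | None = None
    signature_genes: list[str] | None = None
    n_signature_genes: int = 100
    marker_gene: str | None = None
    marker_high_log2: float = 4.0
    marker_low_log2: float = 0.5
    marker_high_fraction: float = 0.5
    base_log2_mean: float = 1.8
    base_log2_sd: float = 1.0
    nb_dispersion: float = 2.0
    dropout_midpoint: float | None = -2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rare_fraction <= 1.0:
            raise ValueError("rare_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_cells_per_population <= 0:
            raise ValueError("populations must be non-empty")
        if self.populations is None:
            # acute-deprivation pair: the starved population differs from the
            # treatment-naive one transcriptionally (signature shift), not
            # genetically — the two share one copy-number background
            self.populations = [
                PopulationSpec("naive"),
                PopulationSpec("starved", signature_shift=1.0),
            ]
        if not self.populations:
            raise ValueError("at least one population required")
        for popn in self.populations:
            for block in popn.cna_blocks:
                if block.end > self.n_genes:
                    raise ValueError("CNA block indices must lie within [0, n_genes)")
        if self.rare_population is None:
            self.rare_population = self.populations[0].name
        if self.rare_shift is None:
            # pre-adapted cells mimic the strongest signature shift present
            self.rare_shift = max(p.signature_shift for p in self.populations)


def cna_study_config(
    n_genes: int = 2000,
    n_cells_per_population: int = 300,
    seed: int = 0,
    **kwargs,
) -> SimConfig:
    """Study conditions for the copy-number analyses: a treatment-naive and a
    fully resistant population carrying distinct planted CNA blocks (a 2-fold
    amplification in the naive line; a 2-fold loss plus a separate 2-fold
    amplification in the resistant one)."""
    populations = [
        PopulationSpec("naive", cna_blocks=[CnaBlock(200, 400, 2.0)]),
        PopulationSpec(
            "resistant",
            cna_blocks=[CnaBlock(1200, 1400, 0.5), CnaBlock(1600, 1800, 2.0)],
            signature_shift=1.0,
        ),
    ]
    return SimConfig(
        n_genes=n_genes,
        n_cells_per_population=n_cells_per_population,
        populations=populations,
        rare_fraction=0.0,
        seed=seed,
        **kwargs,
    )


@dataclass
class SimTruth:
    """Ground truth aligned with the simulated cells (one row per cell)."""

    cells: pd.DataFrame  # cell_id, population, is_rare, marker_high
    copy_ratio: pd.DataFrame  # genes x populations expected copy ratio
    signature_genes: list[str]
    edges: pd.DataFrame | None = None  # for network datasets


def gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def generate_gene_annotation(n_genes: int, n_chromosomes: int, seed: int = 0) -> pd.DataFrame:
    """Gene coordinates on a toy genome: genes split near-evenly across
    chromosomes, strictly increasing starts within each chromosome."""
    if n_genes <= 0 or n_chromosomes <= 0:
        raise ValueError("counts must be positive")
    if n_chromosomes > n_genes:
        raise ValueError("need at least one gene per chromosome")
    rng = np.random.default_rng(seed)
    ids = gene_ids(n_genes)
    per_chrom = np.full(n_chromosomes, n_genes // n_chromosomes)
    per_chrom[: n_genes % n_chromosomes] += 1
    rows = []
    i = 0
    for c, n_on_chrom in enumerate(per_chrom, start=1):
        # random positive gaps keep starts strictly increasing
        gaps = rng.integers(10_000, 200_000, size=n_on_chrom)
        starts = np.cumsum(gaps)
        lengths = rng.integers(1_000, 9_000, size=n_on_chrom)
        for s, length in zip(starts, lengths):
            rows.append((ids[i], f"chr{c}", int(s), int(s + length)))
            i += 1
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw a UMI count matrix plus aligned ground truth from ``config``.

    Counts are negative binomial with mean ``mu`` and dispersion ``theta``
    (variance ``mu + mu^2/theta``; ``theta = inf`` gives Poisson). Dropout,
    when enabled, zeroes entries with probability
    ``1 - sigmoid(ln mu - midpoint)``, so lowly expressed genes drop out more.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = gene_ids(cfg.n_genes)

    base_log2 = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=cfg.n_genes)

    if cfg.signature_genes is None:
        sig_idx = rng.choice(cfg.n_genes, size=min(cfg.n_signature_genes, cfg.n_genes), replace=False)
        sig_idx.sort()
        signature = [genes[i] for i in sig_idx]
    else:
        signature = list(cfg.signature_genes)
        sig_idx = np.array([genes.index(g) for g in signature])

    if cfg.marker_gene is None:
        non_sig = np.setdiff1d(np.arange(cfg.n_genes), sig_idx)
        marker_idx = int(non_sig[0]) if len(non_sig) else 0
        marker = genes[marker_idx]
    else:
        marker = cfg.marker_gene
        marker_idx = genes.index(marker)

    # expected copy ratio per gene per population
    copy = pd.DataFrame(1.0, index=genes, columns=[p.name for p in cfg.populations])
    for popn in cfg.populations:
        for block in popn.cna_blocks:
            copy.iloc[block.start : block.end, copy.columns.get_loc(popn.name)] *= block.fold

    blocks_of_cells = []
    cell_rows = []
    cell_counter = 0
    for popn in cfg.populations:
        n = cfg.n_cells_per_population
        log2_mu = np.tile(base_log2[:, None], (1, n))
        log2_mu += np.log2(copy[popn.name].to_numpy())[:, None]
        if popn.signature_shift:
            log2_mu[sig_idx, :] += popn.signature_shift

        is_rare = np.zeros(n, dtype=bool)
        if popn.name == cfg.rare_population and cfg.rare_fraction > 0:
            is_rare = rng.random(n) < cfg.rare_fraction
            log2_mu[np.ix_(sig_idx, np.flatnonzero(is_rare))] += cfg.rare_shift - popn.signature_shift

        marker_high = rng.random(n) < cfg.marker_high_fraction
        log2_mu[marker_idx, :] = np.where(marker_high, cfg.marker_high_log2, cfg.marker_low_log2)

        mu = np.exp2(log2_mu)
        if np.isinf(cfg.nb_dispersion):
            counts = rng.poisson(mu)
        else:
            theta = cfg.nb_dispersion
            counts = rng.negative_binomial(theta, theta / (theta + mu))
        if cfg.dropout_midpoint is not None:
            keep = rng.random(mu.shape) < expit(np.log(mu) - cfg.dropout_midpoint)
            counts = counts * keep
        blocks_of_cells.append(counts)
        for j in range(n):
            cell_rows.append(
                (
                    f"{popn.name}-{cell_counter + j:05d}",
                    popn.name,
                    bool(is_rare[j]),
                    bool(marker_high[j]),
                )
            )
        cell_counter += n

    all_counts = np.concatenate(blocks_of_cells, axis=1)
    cells = pd.DataFrame(cell_rows, columns=["cell_id", "population", "is_rare", "marker_high"])
    counts = CountMatrix(sp.csr_matrix(all_counts), genes, cells["cell_id"].tolist())
    truth = SimTruth(cells=cells, copy_ratio=copy, signature_genes=signature)
    return counts, truth


# ---------------------------------------------------------------------------
# dependency-network expression


@dataclass
class EdgeRule:
    """Maps parent values to a child mean: linear sum, AND-like (min) or
    XOR-like (on median-binarised parents), plus Gaussian noise."""

    child: str
    parents: list[str]
    kind: str = "linear"  # linear | and | xor
    weight: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in {"linear", "and", "xor"}:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if not self.parents:
            raise ValueError("rule needs at least one parent")


def simulate_network_expression(
    edge_rules: list[EdgeRule],
    n_cells: int,
    seed: int = 0,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate expression from a DAG of :class:`EdgeRule`.

    Genes without a rule are i.i.d. standard normal. Returns a genes x cells
    frame plus truth carrying the (parent, child) edge list.
    """
    rng = np.random.default_rng(seed)
    rule_by_child = {}
    for rule in edge_rules:
        if rule.child in rule_by_child:
            raise ValueError(f"multiple rules for child {rule.child!r}")
        rule_by_child[rule.child] = rule
    all_genes = list(genes) if genes is not None else []
    for rule in edge_rules:
        for g in [rule.child, *rule.parents]:
            if g not in all_genes:
                all_genes.append(g)

    order = _topological_order(all_genes, rule_by_child)
    values: dict[str, np.ndarray] = {}
    for g in order:
        rule = rule_by_child.get(g)
        if rule is None:
            values[g] = rng.normal(size=n_cells)
            continue
        parents = np.vstack([values[p] for p in rule.parents])
        noise = rng.normal(0.0, rule.noise_sd, size=n_cells)
        if rule.kind == "linear":
            values[g] = rule.weight * parents.sum(axis=0) + noise
        elif rule.kind == "and":
            values[g] = rule.weight * parents.min(axis=0) + noise
        else:  # xor on median-binarised parents
            if len(rule.parents) != 2:
                raise ValueError("xor rule needs exactly two parents")
            bits = parents > np.median(parents, axis=1, keepdims=True)
            values[g] = rule.weight * np.logical_xor(bits[0], bits[1]).astype(float) + noise

    expr = pd.DataFrame(
        np.vstack([values[g] for g in all_genes]),
        index=all_genes,
        columns=[f"cell{i:05d}" for i in range(n_cells)],
    )
    edges = pd.DataFrame(
        [(p, r.child) for r in edge_rules for p in r.parents],
        columns=["parent", "child"],
    )
    cells = pd.DataFrame(
        {"cell_id": expr.columns, "population": "net", "is_rare": False, "marker_high": False}
    )
    truth = SimTruth(cells=cells, copy_ratio=pd.DataFrame(), signature_genes=[], edges=edges)
    return expr, truth


def _topological_order(genes: list[str], rule_by_child: dict[str, EdgeRule]) -> list[str]:
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(g: str, stack: tuple = ()) -> None:
        if state.get(g) == 2:
            return
        if state.get(g) == 1:
            raise ValueError(f"edge rules contain a cycle through {g!r}")
        state[g] = 1
        rule = rule_by_child.get(g)
        if rule is not None:
            for p in rule.parents:
                visit(p)
        state[g] = 2
        order.append(g)

    for g in genes:
        visit(g)
    return order


# ---------------------------------------------------------------------------
# CTC-like capture/control profile pairs


def simulate_ctc_profiles(
    n_captures: int,
    n_controls: int,
    signature: GeneSet,
    enrichment: float,
    seed: int = 0,
    n_genes: int = 2000,
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired capture/control profiles emulating CTC re-analyses.

    ``n_captures`` tumour pairs up-shift the signature genes by ``enrichment``
    (multiplicative; 0 or 1 means no shift), ``n_controls`` healthy pairs have
    no shift. Returns (profiles genes x columns, labels per column with
    ``pair_id``, ``arm`` in {capture, control} and ``group`` in
    {case, healthy}).
    """
    if enrichment < 0:
        raise ValueError("enrichment must be >= 0")
    if n_captures < 1 or n_controls < 0:
        raise ValueError("need at least one capture pair")
    rng = np.random.default_rng(seed)
    genes = gene_ids(n_genes)
    sig = [g for g in signature.genes if g in genes]
    missing = len(signature.genes) - len(sig)
    if missing:
        raise ValueError(f"{missing} signature genes outside the simulated universe")
    sig_mask = np.isin(genes, sig)

    base = np.exp2(rng.normal(3.0, 1.0, size=n_genes))
    cols, labels = [], []
    fold = enrichment if enrichment > 0 else 1.0
    for i in range(n_captures + n_controls):
        group = "case" if i < n_captures else "healthy"
        pair = f"{group}{i:03d}"
        control = base * np.exp2(rng.normal(0.0, noise_sd, size=n_genes))
        capture = base * np.exp2(rng.normal(0.0, noise_sd, size=n_genes))
        if group == "case":
            capture = np.where(sig_mask, capture * fold, capture)
        cols += [capture, control]
        labels += [(pair, "capture", group), (pair, "control", group)]
    label_df = pd.DataFrame(labels, columns=["pair_id", "arm", "group"])
    label_df["column"] = [f"{p}_{a}" for p, a in zip(label_df["pair_id"], label_df["arm"])]
    profiles = pd.DataFrame(np.column_stack(cols), index=genes, columns=label_df["column"].tolist())
    return profiles, label_df
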