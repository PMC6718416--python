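"""Readers and writers for the on-disk formats used by the pipeline.

Formats: 10x-style MatrixMarket triples (``matrix.mtx`` + ``barcodes.tsv`` +
``features.tsv``), gene-annotation TSV (1-based inclusive coordinates), GMT
gene sets, and generic TSV outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, GeneSet

log = logging.getLogger("preadapt.io")

MTX_NAME = "matrix.mtx"
BARCODES_NAME = "barcodes.tsv"
FEATURES_NAME = "features.tsv"


def dedupe_symbols(symbols: list[str]) -> list[str]:
    """Disambiguate duplicate gene symbols by suffixing ``.1``, ``.2``, ...

    The first occurrence keeps the bare symbol, matching the common R
    ``make.unique`` convention.
    """
    counts: dict[str, int] = {}
    out = []
    for s in symbols:
        k = counts.get(s, 0)
        out.append(s if k == 0 else f"{s}.{k}")
        counts[s] = k + 1
    return out


def write_10x_mtx(counts: CountMatrix, directory: str | Path) -> None:
    """Write a 10x-style MatrixMarket triple into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(counts.matrix)
    scipy.io.mmwrite(str(directory / MTX_NAME), coo, field="integer")
    (directory / BARCODES_NAME).write_text("\n".join(counts.cell_ids) + "\n")
    (directory / FEATURES_NAME).write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in counts.gene_ids)
    )


def read_10x_mtx(directory: str | Path) -> CountMatrix:
    """Read a 10x-style MatrixMarket triple from ``directory``.

    Raises ``ValueError`` when the sidecar line counts disagree with the
    matrix header dimensions. Duplicate gene symbols are disambiguated.
    """
    directory = Path(directory)
    mat = sp.csr_matrix(scipy.io.mmread(str(directory / MTX_NAME)))
    barcodes = _read_lines(directory / BARCODES_NAME)
    feature_lines = _read_lines(directory / FEATURES_NAME)
    genes = [line.split("\t")[0] for line in feature_lines]
    n_genes, n_cells = mat.shape
    if len(genes) != n_genes:
        raise ValueError(
            f"matrix header declares {n_genes} genes but features file has {len(genes)} rows"
        )
    if len(barcodes) != n_cells:
        raise ValueError(
            f"matrix header declares {n_cells} cells but barcodes file has {len(barcodes)} rows"
        )
    unique = dedupe_symbols(genes)
    if unique != genes:
        log.warning("duplicate gene symbols disambiguated: %d affected", sum(a != b for a, b in zip(unique, genes)))
    return CountMatrix(mat.astype(np.int64), unique, barcodes)


def _read_lines(path: Path) -> list[str]:
    return [line for line in path.read_text().splitlines() if line.strip()]


# ---------------------------------------------------------------------------
# gene annotation


def write_gene_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene-annotation TSV with columns gene_id, chromosome, start, end.

    Coordinates are treated as 1-based inclusive. Genes with missing
    coordinates are dropped with a warning. The returned frame preserves input
    row order; use :func:`sort_annotation` for the genome-ordered view.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    required = {"gene_id", "chromosome", "start", "end"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"annotation file misses columns: {sorted(missing_cols)}")
    bad = df[["chromosome", "start", "end"]].isna().any(axis=1)
    if bad.any():
        log.warning("dropping %d genes with missing coordinates", int(bad.sum()))
        df = df.loc[~bad].reset_index(drop=True)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def sort_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Genome-ordered view: chromosomes in first-appearance order, starts ascending."""
    chrom_order = {c: i for i, c in enumerate(pd.unique(annotation["chromosome"]))}
    key = annotation["chromosome"].map(chrom_order)
    return (
        annotation.assign(_k=key)
        .sort_values(["_k", "start"], kind="stable")
        .drop(columns="_k")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (name, description, genes; tab-separated)."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
            raise ValueError(f"{path}:{lineno}: gene set {fields[0]!r} has no genes")
        genes = [g for g in fields[2:] if g.strip()]
        if len(set(genes)) != len(genes):
            log.warning("%s:%d: duplicate genes in %r deduplicated", path, lineno, fields[0])
        sets.append(GeneSet(name=fields[0], genes=genes))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.direction or ""] + gs.genes) + "\n")
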