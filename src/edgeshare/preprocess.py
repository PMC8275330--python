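"""Expression preprocessing: transform, gene filtering and the directed edge universe.

The pipeline operates on per-cell-type expression matrices (cells x genes,
CPM-like values).  Genes are filtered by a minimum expression fraction, the
working gene set is the union of known regulators and the most dispersed
genes, and the directed edge universe is the cross product
``regulators x genes`` minus self-edges, in a deterministic order shared by
every downstream stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneUniverse",
    "EdgeUniverse",
    "log_transform",
    "inverse_log_transform",
    "filter_genes",
    "dispersion",
    "select_gene_universe",
    "build_edge_universe",
    "read_expression_csv",
    "read_expression_mtx",
    "read_tf_list",
    "write_universe_manifest",
]


@dataclass
class ExpressionMatrix:
    """Dense cells x genes expression matrix with aligned identifier lists."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_type_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (cells x genes)")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_ids.index(gene)]


@dataclass
class GeneUniverse:
    """Ordered working gene set with its regulator (TF) subset."""

    genes: list[str]
    regulators: list[str]

    def __post_init__(self) -> None:
        self.genes = sorted(dict.fromkeys(self.genes))
        self.regulators = sorted(dict.fromkeys(self.regulators))
        missing = set(self.regulators) - set(self.genes)
        if missing:
            raise ValueError(f"regulators not in gene set: {sorted(missing)}")


@dataclass
class EdgeUniverse:
    """Deterministically ordered list of directed (regulator, target) pairs."""

    edges: list[tuple[str, str]]
    index: dict[tuple[str, str], int] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        for r, t in self.edges:
            if r == t:
                raise ValueError(f"self-edge {r}->{t}")
        self.index = {e: i for i, e in enumerate(self.edges)}

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def regulators(self) -> list[str]:
        return sorted({r for r, _ in self.edges})

    @property
    def targets(self) -> list[str]:
        return sorted({t for _, t in self.edges})


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the elementwise ``ln(1 + x/100)`` transform to CPM-like values.

    Raises ``ValueError`` naming the first offending coordinate if any entry
    is negative.
    """
    neg = np.argwhere(m.values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative expression value at cell {m.cell_ids[i]!r}, "
            f"gene {m.gene_ids[j]!r}: {m.values[i, j]}"
        )
    return ExpressionMatrix(
        values=np.log1p(m.values / 100.0),
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        cell_type_label=m.cell_type_label,
    )


def inverse_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Exact inverse of :func:`log_transform`: ``100*(exp(x) - 1)``."""
    return ExpressionMatrix(
        values=100.0 * np.expm1(m.values),
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        cell_type_label=m.cell_type_label,
    )


def filter_genes(
    mats: Sequence[ExpressionMatrix], min_fraction: float = 0.10
) -> list[str]:
    """Keep genes expressed (value > 0) in at least ``min_fraction`` of cells
    of at least one cell type.

    A gene absent from a matrix counts as all-zero in that cell type.
    Returns the kept genes in lexicographic order.
    """
    if not mats:
        raise ValueError("empty matrix list")
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    all_genes = sorted({g for m in mats for g in m.gene_ids})
    kept: list[str] = []
    for g in all_genes:
        for m in mats:
            if g not in m.gene_ids:
                logger.debug(
                    "gene %s absent from cell type %s; treated as all-zero",
                    g, m.cell_type_label,
                )
                continue
            frac = float(np.count_nonzero(m.column(g) > 0)) / m.n_cells
            if frac >= min_fraction:
                kept.append(g)
                break
    return kept


def dispersion(
    mats: Sequence[ExpressionMatrix],
    genes: Sequence[str],
    per_type_max: bool = False,
) -> np.ndarray:
    """Variance/mean (Fano factor) dispersion of transformed values.

    Pooled across all cells by default; with ``per_type_max`` the statistic
    is computed per cell type and the maximum over types is taken.  Genes
    with zero mean get dispersion 0 (ranked last).
    """
    genes = list(genes)

    def _fano(stacked: np.ndarray) -> np.ndarray:
        mean = stacked.mean(axis=0)
        var = stacked.var(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
        return f

    def _stack(m: ExpressionMatrix) -> np.ndarray:
        cols = np.zeros((m.n_cells, len(genes)))
        lookup = {g: i for i, g in enumerate(m.gene_ids)}
        for j, g in enumerate(genes):
            if g in lookup:
                cols[:, j] = m.values[:, lookup[g]]
        return cols

    if per_type_max:
        return np.max([_fano(_stack(m)) for m in mats], axis=0)
    return _fano(np.vstack([_stack(m) for m in mats]))


def select_gene_universe(
    mats: Sequence[ExpressionMatrix],
    tf_list: Sequence[str],
    top_n_dispersion: int = 1000,
    filtered_genes: Sequence[str] | None = None,
    per_type_max: bool = False,
) -> GeneUniverse:
    """Working gene set: (TFs present after filtering) union (top-n genes by
    dispersion).  Ties in the dispersion ranking break lexicographically.
    """
    if not list(tf_list):
        raise ValueError("empty TF list: no regulators, empty edge universe")
    genes = sorted(filtered_genes) if filtered_genes is not None else sorted(
        {g for m in mats for g in m.gene_ids}
    )
    tf_present = sorted(set(tf_list) & set(genes))
    disp = dispersion(mats, genes, per_type_max=per_type_max)
    # sort by (-dispersion, symbol): deterministic tie-break
    order = sorted(range(len(genes)), key=lambda i: (-disp[i], genes[i]))
    top = [genes[i] for i in order[:top_n_dispersion]]
    selected = sorted(set(tf_present) | set(top))
    if not tf_present:
        raise ValueError("no TF from the list survives filtering")
    return GeneUniverse(genes=selected, regulators=tf_present)


def build_edge_universe(u: GeneUniverse) -> EdgeUniverse:
    """All directed (regulator, target) pairs, excluding self-edges, ordered
    first by regulator then by target (both lexicographic)."""
    if not u.genes:
        raise ValueError("empty gene universe")
    edges = [
        (r, t) for r in u.regulators for t in u.genes if r != t
    ]
    return EdgeUniverse(edges=edges)


# ---------------------------------------------------------------------------
# readers / writers

def read_expression_csv(
    path: str | Path, cell_type_label: str = "", sep: str | None = None
) -> ExpressionMatrix:
    """Dense matrix with cells as rows; first column = cell id, header = genes."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.columns],
        cell_ids=[str(c) for c in df.index],
        cell_type_label=cell_type_label or path.stem,
    )


def read_expression_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    cell_type_label: str = "",
) -> ExpressionMatrix:
    """MatrixMarket triplet (cells x genes) with sidecar gene/barcode lists."""
    mat = mmread(str(mtx_path))
    genes = Path(genes_path).read_text().split()
    cells = Path(barcodes_path).read_text().split()
    return ExpressionMatrix(
        values=np.asarray(mat.todense(), dtype=float)
        if hasattr(mat, "todense") else np.asarray(mat, dtype=float),
        gene_ids=genes,
        cell_ids=cells,
        cell_type_label=cell_type_label,
    )


def read_tf_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines ignored; case-sensitive."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_universe_manifest(
    u: GeneUniverse, path: str | Path, provenance: dict | None = None
) -> None:
    payload = {
        "genes": u.genes,
        "regulators": u.regulators,
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
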