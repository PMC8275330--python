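"""Edge scoring and bootstrap estimation of per-edge score noise.

Observed edge scores for each cell type come either from the built-in
Pearson scorer or from a TSV exported by an external inference method.
Per-edge score standard deviations are estimated by resampling cells with
replacement and re-scoring (the sample standard deviation across trials,
with a small floor so downstream Gaussian likelihoods stay proper).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .preprocess import EdgeUniverse, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeScoreStack",
    "NoiseStack",
    "BootstrapConfig",
    "pearson_scores",
    "import_external_scores",
    "bootstrap_edge_std",
    "constant_std_fallback",
    "write_score_tsv",
    "read_score_tsv",
    "write_manifest",
    "read_manifest",
]

STD_FLOOR_ABS = 1e-6


@dataclass
class EdgeScoreStack:
    """N edges x C cell types of observed edge scores with a missing mask."""

    scores: np.ndarray
    cell_types: list[str]
    edge_universe: EdgeUniverse
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        n, c = self.scores.shape
        if n != len(self.edge_universe):
            raise ValueError(
                f"{n} score rows for {len(self.edge_universe)} edges"
            )
        if c != len(self.cell_types):
            raise ValueError(f"{c} columns for {len(self.cell_types)} cell types")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.scores)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.scores.shape:
            raise ValueError("missing mask shape mismatch")
        if not np.all(np.isfinite(self.scores[~self.missing_mask])):
            raise ValueError("non-finite score outside the missing mask")

    @property
    def n_edges(self) -> int:
        return self.scores.shape[0]

    @property
    def n_cell_types(self) -> int:
        return self.scores.shape[1]


@dataclass
class NoiseStack:
    """Per-edge score standard deviations aligned with an EdgeScoreStack."""

    std: np.ndarray
    cell_types: list[str]
    edge_universe: EdgeUniverse
    floor_value: float = STD_FLOOR_ABS

    def __post_init__(self) -> None:
        self.std = np.atleast_2d(np.asarray(self.std, dtype=float))
        if self.std.shape[0] != len(self.edge_universe):
            raise ValueError("std rows do not match edge universe")
        if self.std.shape[1] != len(self.cell_types):
            raise ValueError("std columns do not match cell types")
        finite = np.isfinite(self.std)
        if np.any(self.std[finite] <= 0):
            raise ValueError("non-positive std after flooring")


@dataclass
class BootstrapConfig:
    n_trials: int = 5
    seed: int = 0
    scorer: Callable[..., tuple[np.ndarray, np.ndarray]] = None  # type: ignore

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError(f"need at least 2 bootstrap trials, got {self.n_trials}")


def _pearson_matrix(
    values: np.ndarray, reg_idx: np.ndarray, tgt_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """|corr| between regulator and target columns plus a constant-gene mask."""
    centered = values - values.mean(axis=0)
    sd = centered.std(axis=0)
    constant = sd == 0
    denom = np.where(constant, 1.0, sd)
    z = centered / denom
    n = values.shape[0]
    corr = (z[:, reg_idx] * z[:, tgt_idx]).sum(axis=0) / n
    missing = constant[reg_idx] | constant[tgt_idx]
    corr = np.where(missing, 0.0, np.clip(corr, -1.0, 1.0))
    return corr, missing


def pearson_scores(
    m: ExpressionMatrix,
    u: EdgeUniverse,
    signed: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson-correlation edge scores for one cell type.

    Returns ``(scores, missing)`` aligned to the edge universe.  Scores are
    |r| by default (edge strength semantics, comparable with non-negative
    scores from tree- or information-based methods).  Edges touching a gene
    that is constant or absent in this cell type are 0 and flagged missing.
    """
    if m.n_cells < 3:
        raise ValueError(f"need at least 3 cells, got {m.n_cells}")
    lookup = {g: i for i, g in enumerate(m.gene_ids)}
    n_edges = len(u)
    scores = np.zeros(n_edges)
    missing = np.zeros(n_edges, dtype=bool)
    present = np.array(
        [r in lookup and t in lookup for r, t in u.edges], dtype=bool
    )
    missing[~present] = True
    if present.any():
        reg_idx = np.array([lookup[r] for (r, t), p in zip(u.edges, present) if p])
        tgt_idx = np.array([lookup[t] for (r, t), p in zip(u.edges, present) if p])
        corr, const_missing = _pearson_matrix(m.values, reg_idx, tgt_idx)
        sub = corr if signed else np.abs(corr)
        scores[present] = sub
        missing_idx = np.flatnonzero(present)
        missing[missing_idx[const_missing]] = True
        scores[missing] = 0.0
    return scores, missing


def import_external_scores(
    path: str | Path, u: EdgeUniverse
) -> tuple[np.ndarray, np.ndarray]:
    """Align an external ``regulator<TAB>target<TAB>score`` TSV to the universe.

    Edges absent from the file are flagged missing; rows with unknown gene
    symbols are skipped (logged with a count); duplicated edges are an error.
    """
    path = Path(path)
    scores = np.zeros(len(u))
    missing = np.ones(len(u), dtype=bool)
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    except pd.errors.EmptyDataError:
        return scores, missing
    required = {"regulator", "target", "score"}
    if not required <= set(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = df["score"].isna() | ~np.isfinite(
        pd.to_numeric(df["score"], errors="coerce")
    )
    if bad.any():
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"{path}: malformed score at line {lineno}")
    unknown = 0
    seen: set[tuple[str, str]] = set()
    for r, t, s in df[["regulator", "target", "score"]].itertuples(index=False):
        key = (r, t)
        idx = u.index.get(key)
        if idx is None:
            unknown += 1
            continue
        if key in seen:
            raise ValueError(f"{path}: duplicate edge {r}->{t}")
        seen.add(key)
        scores[idx] = float(s)
        missing[idx] = False
    if unknown:
        logger.warning("%s: skipped %d rows with unknown gene symbols", path, unknown)
    return scores, missing


def bootstrap_edge_std(
    m: ExpressionMatrix,
    u: EdgeUniverse,
    cfg: BootstrapConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Bootstrap standard deviation of edge scores for one cell type.

    Each of the ``cfg.n_trials`` trials resamples the cells with replacement
    at the original size and re-runs the scorer; the per-edge sample standard
    deviation (ddof=1) across trials is returned, floored at
    ``max(1e-6, 1st percentile of the positive stds)`` so zero-variance edges
    do not produce degenerate likelihoods.

    Returns ``(std, floor_value)``.
    """
    scorer = cfg.scorer or pearson_scores
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = m.n_cells
    trials = np.empty((cfg.n_trials, len(u)))
    for trial in range(cfg.n_trials):
        idx = rng.integers(0, n, size=n)
        resampled = ExpressionMatrix(
            values=m.values[idx],
            gene_ids=list(m.gene_ids),
            cell_ids=[f"bs{trial}_{i}" for i in range(n)],
            cell_type_label=m.cell_type_label,
        )
        scores, _ = scorer(resampled, u)
        trials[trial] = scores
    std = trials.std(axis=0, ddof=1)
    positive = std[std > 0]
    floor = STD_FLOOR_ABS
    if positive.size:
        floor = max(STD_FLOOR_ABS, float(np.percentile(positive, 1)))
    return np.maximum(std, floor), floor


def constant_std_fallback(scores: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Constant per-cell-type std for external scores with no bootstrap:
    the sample std of that cell type's observed scores."""
    observed = scores[~missing]
    value = float(observed.std(ddof=1)) if observed.size > 1 else 1.0
    value = max(value, STD_FLOOR_ABS)
    logger.info("constant-std fallback: %g", value)
    out = np.full(scores.shape, value)
    return out


# ---------------------------------------------------------------------------
# file dialects

def write_score_tsv(
    path: str | Path,
    u: EdgeUniverse,
    values: np.ndarray,
    missing: np.ndarray | None = None,
    column: str = "score",
) -> None:
    """Edge list TSV (regulator, target, <column>); missing edges are omitted."""
    if missing is None:
        missing = np.zeros(len(u), dtype=bool)
    rows = [
        (r, t, repr(float(values[i])))
        for i, (r, t) in enumerate(u.edges)
        if not missing[i]
    ]
    df = pd.DataFrame(rows, columns=["regulator", "target", column])
    df.to_csv(path, sep="\t", index=False)


def read_score_tsv(
    path: str | Path, u: EdgeUniverse, column: str = "score"
) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(
        path, sep="\t", dtype={0: str, 1: str}, float_precision="round_trip"
    )
    values = np.zeros(len(u))
    missing = np.ones(len(u), dtype=bool)
    for r, t, s in df[["regulator", "target", column]].itertuples(index=False):
        idx = u.index.get((r, t))
        if idx is None:
            continue
        values[idx] = float(s)
        missing[idx] = False
    return values, missing


def write_manifest(path: str | Path, mapping: dict[str, dict[str, str]]) -> None:
    """JSON manifest: cell-type label -> {"scores": ..., "std": ...} paths."""
    Path(path).write_text(json.dumps(mapping, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict[str, dict[str, str]]:
    return json.loads(Path(path).read_text())
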