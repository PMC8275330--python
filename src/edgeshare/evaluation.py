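"""Agreement of predicted networks with reference edge sets.

AUPRC uses the average-precision (step) convention — precision summed at
each recall increment, with equal scores grouped at a single threshold —
never trapezoidal interpolation.  The random-predictor baseline equals the
positive prevalence, so ``ratio = auprc / prevalence`` maps results from
different references onto a common scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .preprocess import EdgeUniverse

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceNetwork",
    "PRResult",
    "build_chip_reference",
    "auprc",
    "average_precision",
    "paired_signed_rank",
    "read_reference_tsv",
    "write_results_tsv",
]


@dataclass
class ReferenceNetwork:
    edges: set[tuple[str, str]]
    covered_regulators: set[str] = field(default_factory=set)
    name: str = "reference"

    def __post_init__(self) -> None:
        regs = {r for r, _ in self.edges}
        if not self.covered_regulators:
            self.covered_regulators = regs
        elif not regs <= self.covered_regulators:
            raise ValueError(
                "reference edges use regulators outside covered_regulators"
            )


@dataclass
class PRResult:
    auprc: float
    prevalence: float
    n_eval_edges: int

    @property
    def ratio(self) -> float:
        return self.auprc / self.prevalence


def build_chip_reference(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    q_max: float = 1e-5,
    window: int = 5000,
    name: str = "chip",
) -> ReferenceNetwork:
    """Edge (TF, gene) iff some peak of the TF with q < ``q_max`` lies within
    ``window`` bp of the gene's TSS on the same chromosome.

    ``peaks`` columns: tf, chrom, summit, qvalue (1-based point summit);
    ``tss`` columns: gene, chrom, tss.  Covered regulators = all TFs in the
    peak table (any q).  The q cutoff is a strict inequality; the distance
    bound is inclusive.
    """
    for col in ("tf", "chrom", "summit", "qvalue"):
        if col not in peaks.columns:
            raise ValueError(f"peak table missing column {col!r}")
    for col in ("gene", "chrom", "tss"):
        if col not in tss.columns:
            raise ValueError(f"TSS table missing column {col!r}")
    peak_chroms = set(peaks["chrom"])
    tss_chroms = set(tss["chrom"])
    only_peaks = peak_chroms - tss_chroms
    if only_peaks:
        logger.warning(
            "%d peak chromosome(s) absent from the TSS table: %s",
            len(only_peaks), sorted(only_peaks)[:5],
        )
    good = peaks[peaks["qvalue"] < q_max]
    edges: set[tuple[str, str]] = set()
    by_chrom = {c: t for c, t in tss.groupby("chrom")}
    for tf, chrom, summit in good[["tf", "chrom", "summit"]].itertuples(index=False):
        genes = by_chrom.get(chrom)
        if genes is None:
            continue
        near = genes[(genes["tss"] - summit).abs() <= window]
        for g in near["gene"]:
            if g != tf:
                edges.add((tf, g))
    return ReferenceNetwork(
        edges=edges, covered_regulators=set(peaks["tf"]), name=name
    )


def average_precision(labels: np.ndarray, scores: np.ndarray) -> float:
    """Step-convention PR area with tie groups at single thresholds."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("need at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # threshold group boundaries: last index of each distinct score
    boundary = np.flatnonzero(np.diff(s_sorted) != 0)
    ends = np.append(boundary, len(scores) - 1)
    tp = np.cumsum(l_sorted)[ends]
    predicted = ends + 1
    precision = tp / predicted
    recall = tp / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * precision))


def auprc(
    scores: np.ndarray,
    missing: np.ndarray | None,
    universe: EdgeUniverse,
    ref: ReferenceNetwork,
    restrict_to_covered: bool = True,
) -> PRResult:
    """PR area of one score column against a reference edge set.

    With ``restrict_to_covered`` only edges whose regulator the reference
    covers are evaluated.  Missing-score edges are excluded.
    """
    keep = np.ones(len(universe), dtype=bool)
    if missing is not None:
        keep &= ~np.asarray(missing, dtype=bool)
    if restrict_to_covered:
        covered = ref.covered_regulators
        keep &= np.array([r in covered for r, _ in universe.edges])
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError(f"no evaluable edges against reference {ref.name!r}")
    labels = np.array([universe.edges[i] in ref.edges for i in idx])
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError(f"no positives against reference {ref.name!r}")
    if n_pos == idx.size:
        raise ValueError(f"no negatives against reference {ref.name!r}")
    ap = average_precision(labels, np.asarray(scores)[idx])
    return PRResult(
        auprc=ap, prevalence=n_pos / idx.size, n_eval_edges=int(idx.size)
    )


def paired_signed_rank(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided Wilcoxon signed-rank p-value for the alternative a > b.

    Zero differences are dropped.  Exact null distribution (rank-sum
    convolution, valid under rank ties) for n <= 25; normal approximation
    with continuity correction above.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    n = d.size
    ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        # exact: distribution of sum of ranks with independent +/- signs;
        # doubling makes half-ranks integral
        r2 = np.rint(ranks * 2).astype(int)
        total = int(r2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = 0.5 * (dist + shifted)
        w2 = int(np.rint(w_plus * 2))
        return float(dist[w2:].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(norm.sf(z))


# ---------------------------------------------------------------------------
# file dialects

def read_reference_tsv(
    path: str | Path,
    covered_path: str | Path | None = None,
    name: str | None = None,
) -> ReferenceNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if "regulator" in cols and "target" in cols:
        pairs = df[["regulator", "target"]]
    else:  # headerless two-column file
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        pairs = df.iloc[:, :2].set_axis(["regulator", "target"], axis=1)
    edges = {(r, t) for r, t in pairs.itertuples(index=False)}
    covered: set[str] = set()
    if covered_path is not None:
        covered = set(Path(covered_path).read_text().split())
    return ReferenceNetwork(
        edges=edges,
        covered_regulators=covered or {r for r, _ in edges},
        name=name or Path(path).stem,
    )


def write_results_tsv(path: str | Path, rows: list[dict]) -> None:
    df = pd.DataFrame(
        rows,
        columns=["cell_type", "reference", "method", "auprc", "prevalence",
                 "ratio", "n_eval_edges"],
    )
    df.to_csv(path, sep="\t", index=False)
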