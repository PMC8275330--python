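"""Edge-activity dynamics along an ordered chain of cell-type networks.

Networks are binarized by keeping the top fraction of edges per cell type;
an edge's boolean activity vector along the chain is then classified as
stably added (one inactive->active flip), stably removed (the mirror),
unstable (more than ``max_flips_stable`` status changes) or other.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import EdgeScoreStack

__all__ = [
    "BinaryNetworkChain",
    "EdgeDynamicsCall",
    "binarize_top_fraction",
    "classify_dynamics",
    "dynamics_counts",
    "minmax_trajectories",
    "write_dynamics_tsv",
]

LABELS = ("stably_added", "stably_removed", "unstable", "other")


@dataclass
class BinaryNetworkChain:
    activity: np.ndarray          # (N, T) boolean
    order: list[str]
    top_fraction: float

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=bool)
        if self.activity.ndim != 2:
            raise ValueError("activity must be N x T")
        if self.activity.shape[1] != len(self.order):
            raise ValueError("chain order does not match activity columns")
        if len(self.order) < 2:
            raise ValueError("need at least two cell types in the chain")


@dataclass
class EdgeDynamicsCall:
    labels: np.ndarray            # (N,) strings from LABELS
    n_flips: np.ndarray           # (N,) ints


def binarize_top_fraction(
    scores: EdgeScoreStack, fraction: float, order: list[str] | None = None
) -> BinaryNetworkChain:
    """Per cell type, mark the ``ceil(fraction * N)`` highest-scoring edges
    active.  Ties at the cut resolve by edge-universe order (earlier edges
    win), so the selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = scores.n_edges
    n_keep = int(np.ceil(fraction * n))
    if n_keep < 1:
        raise ValueError(f"fraction {fraction} selects no edges out of {n}")
    if order is None:
        order = list(scores.cell_types)
    col_of = {ct: j for j, ct in enumerate(scores.cell_types)}
    missing = [ct for ct in order if ct not in col_of]
    if missing:
        raise ValueError(f"cell types not in the score stack: {missing}")
    activity = np.zeros((n, len(order)), dtype=bool)
    for out_j, ct in enumerate(order):
        col = scores.scores[:, col_of[ct]].copy()
        col[scores.missing_mask[:, col_of[ct]]] = -np.inf
        # stable sort on -score keeps universe order within tie blocks
        top = np.argsort(-col, kind="stable")[:n_keep]
        activity[top, out_j] = True
    return BinaryNetworkChain(activity=activity, order=order, top_fraction=fraction)


def classify_dynamics(
    chain: BinaryNetworkChain, max_flips_stable: int = 4
) -> EdgeDynamicsCall:
    """Label each edge's activity pattern.

    stably_added: 0...0 1...1 with at least one leading zero and one
    trailing one (exactly one flip, starting inactive); stably_removed is
    the mirror; unstable: more than ``max_flips_stable`` flips; everything
    else (constant patterns, multi-flip patterns under the threshold): other.
    One-flip patterns can never exceed a threshold >= 1, so the label sets
    cannot conflict.
    """
    act = chain.activity
    n, t = act.shape
    flips = (act[:, 1:] != act[:, :-1]).sum(axis=1)
    labels = np.full(n, "other", dtype=object)
    one_flip = flips == 1
    added = one_flip & ~act[:, 0] & act[:, -1]
    removed = one_flip & act[:, 0] & ~act[:, -1]
    if t >= 3:
        labels[added] = "stably_added"
        labels[removed] = "stably_removed"
    labels[flips > max_flips_stable] = "unstable"
    return EdgeDynamicsCall(labels=labels.astype(str), n_flips=flips.astype(int))


def dynamics_counts(calls: EdgeDynamicsCall) -> dict[str, int]:
    """Edge counts per dynamics label."""
    return {lab: int(np.sum(calls.labels == lab)) for lab in LABELS}


def minmax_trajectories(
    scores: EdgeScoreStack,
    chain: BinaryNetworkChain,
    calls: EdgeDynamicsCall,
    label: str,
) -> np.ndarray:
    """Min-max normalized score trajectories of the edges carrying ``label``,
    along the chain order.  A constant trajectory normalizes to all-0.5
    (degenerate but well-defined)."""
    col_of = {ct: j for j, ct in enumerate(scores.cell_types)}
    cols = [col_of[ct] for ct in chain.order]
    sel = calls.labels == label
    traj = scores.scores[np.ix_(sel, cols)].astype(float)
    lo = traj.min(axis=1, keepdims=True)
    hi = traj.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    out = np.empty_like(traj)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (traj - lo) / np.where(span == 0, 1.0, span)
    out[flat] = 0.5
    return out


def write_dynamics_tsv(
    path: str | Path,
    scores: EdgeScoreStack,
    calls: EdgeDynamicsCall,
) -> None:
    rows = [
        (r, t, calls.labels[i], int(calls.n_flips[i]))
        for i, (r, t) in enumerate(scores.edge_universe.edges)
    ]
    pd.DataFrame(
        rows, columns=["regulator", "target", "label", "n_flips"]
    ).to_csv(path, sep="\t", index=False)
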