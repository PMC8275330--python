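"""Simulators that emit data with the exact structure the models assume.

Everything here is seeded and bit-reproducible, and writes the same file
dialects the pipeline reads, so fixtures double as format tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EdgeUniverse, ExpressionMatrix, GeneUniverse
from .scoring import EdgeScoreStack, NoiseStack

__all__ = [
    "SharingSimTruth",
    "RegressionSimTruth",
    "simulate_sharing",
    "simulate_regression_truth",
    "simulate_expression",
    "simulate_chain",
    "index_edge_universe",
]


@dataclass
class SharingSimTruth:
    z_true: np.ndarray          # (N, C)
    assignments: np.ndarray     # (N,) 0-based component labels
    mu_true: np.ndarray         # (K, C)
    sigma_true: np.ndarray      # (K, C, C)
    noise_std: np.ndarray       # (N, C)


@dataclass
class RegressionSimTruth:
    beta_true: np.ndarray       # (C, p, T) coefficient per cell type
    gamma_true: np.ndarray      # (C, p, T) boolean support
    noise_var: float

    def __post_init__(self) -> None:
        if np.any((self.beta_true != 0) & ~self.gamma_true.astype(bool)):
            raise ValueError("beta_true nonzero outside gamma support")


def index_edge_universe(n_edges: int) -> EdgeUniverse:
    """Synthetic universe of ``n_edges`` directed pairs R0->Tn.

    Width-padded symbols keep the universe's lexicographic order equal to
    the numeric order, so score rows align trivially with truth arrays.
    """
    width = len(str(max(n_edges - 1, 1)))
    return EdgeUniverse(
        edges=[("R0", f"T{i:0{width}d}") for i in range(n_edges)]
    )


def _component_covariances(
    k: int, c: int, within_correlation: float, rng: np.random.Generator,
    sigma: np.ndarray | None,
) -> np.ndarray:
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != (k, c, c):
            raise ValueError(f"sigma must have shape {(k, c, c)}")
        for mat in sigma:
            try:
                np.linalg.cholesky(mat)
            except np.linalg.LinAlgError as exc:
                raise ValueError("requested covariance is not SPD") from exc
        return sigma
    lo = -1.0 / (c - 1) if c > 1 else 0.0
    if not lo < within_correlation < 1.0:
        raise ValueError(
            f"within_correlation must lie in ({lo:.3f}, 1) for C={c}"
        )
    eye = np.eye(c)
    ones = np.ones((c, c))
    base = (1.0 - within_correlation) * eye + within_correlation * ones
    scales = rng.uniform(0.8, 1.2, size=k)
    return np.stack([s * base for s in scales])


def simulate_sharing(
    n_edges: int,
    n_cell_types: int,
    n_components: int,
    separation: float = 3.0,
    noise_levels: float | np.ndarray = 0.5,
    missing_rate: float = 0.0,
    seed: int = 0,
    within_correlation: float = 0.5,
    sigma: np.ndarray | None = None,
) -> tuple[EdgeScoreStack, NoiseStack, SharingSimTruth]:
    """Draw (e, sigma_hat, truth) from the sharing model's own generative law.

    Component means are placed so their minimum pairwise distance equals
    ``separation`` times the average within-component standard deviation
    (one knob controls recovery difficulty).  Observation noise is
    heteroscedastic: per-entry std uniform in [0.5, 1.5] x ``noise_levels``
    (or exactly the per-entry values if an (N, C) array is passed).
    Entries are masked missing completely at random at ``missing_rate``.
    The reported noise std is exact (oracle mode).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    k, c, n = n_components, n_cell_types, n_edges

    sigma_true = _component_covariances(k, c, within_correlation, rng, sigma)
    # spread unit: worst-direction within-component std (largest eigenvalue),
    # averaged over components — using the mean diagonal std would understate
    # the overlap of correlated components along their dominant axis
    avg_std = float(np.mean(
        [np.sqrt(np.linalg.eigvalsh(s)[-1]) for s in sigma_true]
    ))

    mu = rng.normal(size=(k, c))
    mu -= mu.mean(axis=0, keepdims=True)
    if k > 1:
        dists = [
            np.linalg.norm(mu[a] - mu[b])
            for a in range(k) for b in range(a + 1, k)
        ]
        min_dist = min(dists)
        if min_dist > 0:
            mu *= separation * avg_std / min_dist
    mu_true = mu

    assignments = rng.integers(0, k, size=n)
    z = np.empty((n, c))
    for comp in range(k):
        idx = np.flatnonzero(assignments == comp)
        if idx.size:
            z[idx] = rng.multivariate_normal(
                mu_true[comp], sigma_true[comp], size=idx.size
            )

    noise_levels = np.asarray(noise_levels, dtype=float)
    if noise_levels.ndim == 0:
        noise_std = rng.uniform(0.5, 1.5, size=(n, c)) * float(noise_levels)
    else:
        if noise_levels.shape != (n, c):
            raise ValueError("noise_levels array must be (N, C)")
        noise_std = noise_levels.copy()
    e = z + rng.standard_normal((n, c)) * noise_std

    missing = rng.random((n, c)) < missing_rate

    universe = index_edge_universe(n)
    stack = EdgeScoreStack(
        scores=np.where(missing, 0.0, e),
        cell_types=[f"ct{j}" for j in range(c)],
        edge_universe=universe,
        missing_mask=missing,
    )
    floor = 1e-6
    noise = NoiseStack(
        std=np.maximum(noise_std, floor),
        cell_types=list(stack.cell_types),
        edge_universe=universe,
        floor_value=floor,
    )
    truth = SharingSimTruth(
        z_true=z, assignments=assignments, mu_true=mu_true,
        sigma_true=sigma_true, noise_std=noise_std,
    )
    return stack, noise, truth


def simulate_regression_truth(
    n_regulators: int,
    n_targets: int,
    n_cell_types: int,
    n_active: int,
    shared_fraction: float = 1.0,
    beta_scale: float = 1.0,
    noise_var: float = 1.0,
    seed: int = 0,
) -> RegressionSimTruth:
    """Sparse coefficient tensors with a controllable degree of support
    sharing across cell types.

    A master support of ``n_active`` (regulator, target) pairs is drawn per
    target; each cell type keeps a master pair with probability
    ``shared_fraction`` and otherwise replaces it with a random private pair.
    """
    rng = np.random.default_rng(seed)
    p, t, c = n_regulators, n_targets, n_cell_types
    if n_active > p:
        raise ValueError("n_active exceeds number of regulators")
    gamma = np.zeros((c, p, t), dtype=bool)
    beta = np.zeros((c, p, t))
    for j in range(t):
        master = rng.choice(p, size=n_active, replace=False)
        master_beta = rng.choice([-1.0, 1.0], size=n_active) * (
            beta_scale * rng.uniform(0.8, 1.2, size=n_active)
        )
        for ct in range(c):
            for slot, (i, b) in enumerate(zip(master, master_beta)):
                if rng.random() < shared_fraction:
                    gamma[ct, i, j] = True
                    beta[ct, i, j] = b
                else:
                    alt = int(rng.integers(0, p))
                    gamma[ct, alt, j] = True
                    beta[ct, alt, j] = float(
                        rng.choice([-1.0, 1.0]) * beta_scale
                    )
    return RegressionSimTruth(beta_true=beta, gamma_true=gamma, noise_var=noise_var)


def simulate_expression(
    n_cells: int,
    universe: GeneUniverse,
    truth: RegressionSimTruth,
    cell_type: int = 0,
    seed: int = 0,
    as_counts: bool = False,
    cell_type_label: str | None = None,
) -> ExpressionMatrix:
    """Expression for one cell type from the linear model.

    Regulator expression is standard Gaussian on the transformed scale;
    each target is X (beta * gamma) plus Gaussian noise.  With
    ``as_counts`` the matrix is pushed through the inverse of
    ``log(1 + x/100)`` (clipped at zero) to emulate CPM-like counts.
    """
    rng = np.random.default_rng(seed)
    regs = universe.regulators
    targets = [g for g in universe.genes if g not in set(regs)]
    c, p, t = truth.beta_true.shape
    if len(regs) != p or len(targets) != t:
        raise ValueError(
            f"universe has {len(regs)} regulators / {len(targets)} targets, "
            f"truth is {p} x {t}"
        )
    x = rng.standard_normal((n_cells, p))
    coef = truth.beta_true[cell_type] * truth.gamma_true[cell_type]
    y = x @ coef + rng.standard_normal((n_cells, t)) * np.sqrt(truth.noise_var)
    genes = list(regs) + list(targets)
    values = np.hstack([x, y])
    order = np.argsort(genes)
    genes = [genes[i] for i in order]
    values = values[:, order]
    if as_counts:
        values = np.clip(100.0 * np.expm1(values), 0.0, None)
    return ExpressionMatrix(
        values=values,
        gene_ids=genes,
        cell_ids=[f"cell{i}" for i in range(n_cells)],
        cell_type_label=cell_type_label or f"ct{cell_type}",
    )


def _pattern_for_label(
    label: str, t: int, max_flips_stable: int, rng: np.random.Generator
) -> np.ndarray:
    if label == "stably_added":
        cut = int(rng.integers(1, t))          # >=1 leading zero, >=1 trailing one
        return np.array([0] * cut + [1] * (t - cut), dtype=bool)
    if label == "stably_removed":
        cut = int(rng.integers(1, t))
        return np.array([1] * cut + [0] * (t - cut), dtype=bool)
    if label == "unstable":
        if t - 1 <= max_flips_stable:
            raise ValueError(
                f"cannot plant an unstable pattern with T={t} and "
                f"flip threshold {max_flips_stable}"
            )
        for _ in range(1000):
            pat = rng.random(t) < 0.5
            if np.count_nonzero(pat[1:] != pat[:-1]) > max_flips_stable:
                return pat
        # alternate deterministically as a fallback
        return np.arange(t) % 2 == 0
    if label == "constant":
        return np.full(t, bool(rng.integers(0, 2)))
    raise ValueError(f"unknown dynamics label {label!r}")


def simulate_chain(
    n_edges: int,
    t_steps: int,
    planted: dict[str, int],
    seed: int = 0,
    max_flips_stable: int = 4,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Binary activity matrix (N x T) with planted dynamics labels.

    ``planted`` maps label -> count for labels in {stably_added,
    stably_removed, unstable}; remaining edges are constant.  Returns
    ``(activity, order_labels, true_labels)``.
    """
    total = sum(planted.values())
    if total > n_edges:
        raise ValueError("planted counts exceed number of edges")
    if t_steps < 2:
        raise ValueError("need at least two steps in the chain")
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    for name in ("stably_added", "stably_removed", "unstable"):
        labels += [name] * planted.get(name, 0)
    labels += ["constant"] * (n_edges - total)
    activity = np.zeros((n_edges, t_steps), dtype=bool)
    for row, lab in enumerate(labels):
        activity[row] = _pattern_for_label(lab, t_steps, max_flips_stable, rng)
    order = [f"stage{j}" for j in range(t_steps)]
    return activity, order, labels
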