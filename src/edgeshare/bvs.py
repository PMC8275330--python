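"""Spike-and-slab Bayesian variable selection over regulator -> target effects.

Each target gene in each cell type is regressed on the regulator expression
matrix with a point-mass-at-zero / Gaussian-slab prior on every coefficient.
The inclusion prior is either a fixed Bernoulli(pi) or, in sharing mode, a
sigmoid-linked latent logit governed by the cross-cell-type mixture model
(the logit layer is refit jointly via a Jaakkola-Jordan quadratic bound,
which turns the Bernoulli factor into Gaussian pseudo-observations for the
sharing updates).

Coefficients are updated coordinate-wise in fixed index order (standard
variational scheme for spike-and-slab linear regression, cf. Carbonetto &
Stephens 2012).  Designs are column-centered and responses centered: the
linear model carries no intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import sharing_model as sm
from .scoring import EdgeScoreStack, NoiseStack
from .synthetic_data import index_edge_universe

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionData",
    "BVSConfig",
    "BVSVariationalState",
    "SharedBVSResult",
    "fit_bvs",
    "fit_bvs_shared",
    "posterior_inclusion",
    "holdout_log_likelihood",
    "bvs_objective",
    "train_test_split_cells",
]

_LOGIT_CAP = 30.0


@dataclass
class RegressionData:
    """Design (cells x regulators) and one response vector per target."""

    x: np.ndarray
    y: np.ndarray
    cell_type_label: str = ""

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim == 1:
            self.y = self.y[:, None]
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite entries in regression data")

    @property
    def n_cells(self) -> int:
        return self.x.shape[0]

    @property
    def n_regulators(self) -> int:
        return self.x.shape[1]

    @property
    def n_targets(self) -> int:
        return self.y.shape[1]


@dataclass
class BVSConfig:
    sigma_eps2: float | None = None   # None -> method-of-moments per target
    sigma_beta2: float = 1.0
    pi: float = 0.1
    max_iter: int = 200
    rel_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_eps2 is not None and self.sigma_eps2 <= 0:
            raise ValueError("sigma_eps2 must be positive")
        if self.sigma_beta2 <= 0:
            raise ValueError("sigma_beta2 must be positive")
        if not 0 < self.pi <= 1:
            raise ValueError("pi must be in (0, 1]")


@dataclass
class BVSVariationalState:
    """Per-coefficient variational parameters for one cell type.

    All arrays are (regulators x targets).  ``x_mean``/``y_mean`` record the
    centering applied at fit time so the predictive can replay it.
    """

    alpha: np.ndarray
    v: np.ndarray
    s2: np.ndarray
    sigma_eps2: np.ndarray        # (targets,)
    sigma_beta2: float
    x_mean: np.ndarray
    y_mean: np.ndarray
    objective_trace: list[list[float]] = field(default_factory=list)
    cell_type_label: str = ""


def _moment_sigma_eps2(xc: np.ndarray, yc: np.ndarray) -> float:
    """Residual variance of y after the best single-regulator marginal fit."""
    var_y = float(yc.var())
    if var_y == 0:
        return 1e-6
    xtx = np.square(xc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(xtx > 0, (xc.T @ yc) / np.where(xtx > 0, xtx, 1.0), 0.0)
    explained = np.square(slope) * xtx / len(yc)
    return max(var_y - float(explained.max(initial=0.0)), 0.05 * var_y)


def _prior_logit(pi: float) -> float:
    if pi >= 1.0:
        return _LOGIT_CAP
    return float(np.log(pi / (1.0 - pi)))


def bvs_objective(
    xc: np.ndarray,
    yc: np.ndarray,
    alpha: np.ndarray,
    v: np.ndarray,
    s2: np.ndarray,
    sigma_eps2: float,
    sigma_beta2: float,
    prior_logit: np.ndarray,
) -> float:
    """Variational lower bound for one (cell type, target) regression."""
    n = len(yc)
    xtx = np.square(xc).sum(axis=0)
    mean_coef = alpha * v
    resid = yc - xc @ mean_coef
    var_term = float(np.sum(xtx * (alpha * (s2 + v**2) - mean_coef**2)))
    ll = -0.5 * n * np.log(2 * np.pi * sigma_eps2) - (
        float(resid @ resid) + var_term
    ) / (2 * sigma_eps2)
    a = np.clip(alpha, 1e-12, 1 - 1e-12)
    lp = np.clip(prior_logit, -_LOGIT_CAP, _LOGIT_CAP)
    log_pi = -np.log1p(np.exp(-lp))        # log sigmoid(lp)
    log_1mpi = -np.log1p(np.exp(lp))
    kl_gamma = float(np.sum(
        a * (np.log(a) - log_pi) + (1 - a) * (np.log(1 - a) - log_1mpi)
    ))
    kl_beta = float(np.sum(
        a * (0.5 * np.log(sigma_beta2 / s2) - 0.5
             + (s2 + v**2) / (2 * sigma_beta2))
    ))
    return ll - kl_gamma - kl_beta


def _coordinate_sweeps(
    xc: np.ndarray,
    yc: np.ndarray,
    alpha: np.ndarray,
    v: np.ndarray,
    prior_logit: np.ndarray,
    sigma_eps2: float,
    sigma_beta2: float,
    max_iter: int,
    rel_tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """In-place coordinate ascent for one target; returns the trace."""
    p = xc.shape[1]
    xtx = np.square(xc).sum(axis=0)
    s2 = sigma_eps2 / (xtx + sigma_eps2 / sigma_beta2)
    resid = yc - xc @ (alpha * v)
    lp = np.clip(prior_logit, -_LOGIT_CAP, _LOGIT_CAP)
    trace: list[float] = []
    for _ in range(max_iter):
        for i in range(p):
            old = alpha[i] * v[i]
            r_i = resid + xc[:, i] * old
            v[i] = (s2[i] / sigma_eps2) * float(xc[:, i] @ r_i)
            logit = lp[i] + 0.5 * np.log(s2[i] / sigma_beta2) + v[i] ** 2 / (2 * s2[i])
            alpha[i] = 1.0 / (1.0 + np.exp(-np.clip(logit, -_LOGIT_CAP, _LOGIT_CAP)))
            resid = r_i - xc[:, i] * (alpha[i] * v[i])
        obj = bvs_objective(
            xc, yc, alpha, v, s2, sigma_eps2, sigma_beta2, lp
        )
        trace.append(obj)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= rel_tol * abs(trace[-2]):
            break
    return alpha, v, s2, trace


def fit_bvs(
    data: RegressionData,
    cfg: BVSConfig | None = None,
    prior_logit: np.ndarray | None = None,
) -> BVSVariationalState:
    """Fit the spike-and-slab model for every target of one cell type.

    ``prior_logit`` (regulators x targets) overrides the fixed Bernoulli
    prior; by default every coefficient uses logit(cfg.pi).
    """
    if cfg is None:
        cfg = BVSConfig()
    if data.n_cells < 2:
        raise ValueError("need at least 2 cells")
    p, t = data.n_regulators, data.n_targets
    x_mean = data.x.mean(axis=0)
    y_mean = data.y.mean(axis=0)
    xc = data.x - x_mean
    yc = data.y - y_mean
    if prior_logit is None:
        prior_logit = np.full((p, t), _prior_logit(cfg.pi))
    prior_logit = np.asarray(prior_logit, dtype=float)
    if prior_logit.shape != (p, t):
        raise ValueError(f"prior_logit must be {(p, t)}")

    alpha = np.full((p, t), 0.5)
    v = np.zeros((p, t))
    s2 = np.empty((p, t))
    sigma_eps2 = np.empty(t)
    traces: list[list[float]] = []
    for j in range(t):
        se2 = cfg.sigma_eps2 or _moment_sigma_eps2(xc, yc[:, j])
        sigma_eps2[j] = se2
        a, vv, ss2, trace = _coordinate_sweeps(
            xc, yc[:, j], alpha[:, j], v[:, j], prior_logit[:, j],
            se2, cfg.sigma_beta2, cfg.max_iter, cfg.rel_tol,
        )
        alpha[:, j], v[:, j], s2[:, j] = a, vv, ss2
        traces.append(trace)
    return BVSVariationalState(
        alpha=alpha, v=v, s2=s2, sigma_eps2=sigma_eps2,
        sigma_beta2=cfg.sigma_beta2, x_mean=x_mean, y_mean=y_mean,
        objective_trace=traces, cell_type_label=data.cell_type_label,
    )


def posterior_inclusion(state: BVSVariationalState) -> np.ndarray:
    """Inclusion probabilities as an edge-score matrix (regulators x targets)."""
    return state.alpha.copy()


def holdout_log_likelihood(
    state: BVSVariationalState, test: RegressionData
) -> np.ndarray:
    """Mean per-cell log density of held-out targets under the
    moment-matched Gaussian posterior predictive.

    Predictive mean: X (alpha * v); predictive variance per cell:
    sigma_eps2 + sum_i x_i^2 (alpha_i (s2_i + v_i^2) - (alpha_i v_i)^2).
    Returns one value per target.
    """
    if test.n_cells == 0:
        raise ValueError("empty test set")
    xc = test.x - state.x_mean
    yc = test.y - state.y_mean
    mean_coef = state.alpha * state.v
    pred = xc @ mean_coef
    coef_var = state.alpha * (state.s2 + state.v**2) - mean_coef**2
    var = state.sigma_eps2[None, :] + np.square(xc) @ coef_var
    ll = -0.5 * (np.log(2 * np.pi * var) + np.square(yc - pred) / var)
    return ll.mean(axis=0)


# ---------------------------------------------------------------------------
# joint fit with the cross-cell-type sharing prior

def _jj_lambda(xi: np.ndarray) -> np.ndarray:
    """Jaakkola-Jordan lambda(xi) = tanh(xi/2)/(4 xi), with the xi->0 limit."""
    xi = np.abs(xi)
    out = np.full_like(xi, 0.125)
    nz = xi > 1e-8
    out[nz] = np.tanh(xi[nz] / 2.0) / (4.0 * xi[nz])
    return out


@dataclass
class SharedBVSResult:
    states: list[BVSVariationalState]          # one per cell type
    z_mean: np.ndarray                         # (p*T, C) latent logits
    share_state: sm.ShareState
    prior: sm.NWPrior
    cell_types: list[str]


def fit_bvs_shared(
    datasets: list[RegressionData],
    cfg: BVSConfig | None = None,
    n_components: int = 3,
    outer_iters: int = 8,
    inner_share_sweeps: int = 3,
    seed: int = 0,
) -> SharedBVSResult:
    """Joint fit across cell types with the sharing prior on inclusion logits.

    Alternates between (a) per-cell-type coefficient updates whose inclusion
    prior logit is the current posterior mean of the latent z for that edge
    and cell type, and (b) refitting the z layer under the mixture sharing
    model, where each Bernoulli factor is replaced by its Jaakkola-Jordan
    quadratic bound — i.e. a Gaussian pseudo-observation with precision
    2 lambda(xi) and mean (alpha - 1/2) / (2 lambda(xi)).
    """
    if cfg is None:
        cfg = BVSConfig()
    if not datasets:
        raise ValueError("no cell types")
    p = datasets[0].n_regulators
    t = datasets[0].n_targets
    for d in datasets:
        if d.n_regulators != p or d.n_targets != t:
            raise ValueError("cell types disagree on design dimensions")
    c = len(datasets)
    n_edges = p * t
    universe = index_edge_universe(n_edges)
    cell_types = [
        d.cell_type_label or f"ct{idx}" for idx, d in enumerate(datasets)
    ]

    base_logit = _prior_logit(cfg.pi)
    z_mean = np.full((n_edges, c), base_logit)
    s_diag = np.ones((n_edges, c))
    share_prior = sm.NWPrior(
        mu0=np.full(c, base_logit), beta0=1e-3,
        psi=float(c + 2) * np.eye(c) * 4.0, nu=float(c + 2),
    )
    share_cfg = sm.ModelConfig(
        n_components=min(n_components, n_edges), seed=seed, init="kmeans",
    )
    share_state: sm.ShareState | None = None
    states: list[BVSVariationalState] = []
    for _ in range(outer_iters):
        # (a) coefficient layer, prior logit = E_q[z]
        states = []
        alpha_flat = np.empty((n_edges, c))
        for ci, d in enumerate(datasets):
            prior_logit = z_mean[:, ci].reshape(t, p).T  # edge n = j*p + i
            st = fit_bvs(d, cfg, prior_logit=prior_logit)
            states.append(st)
            alpha_flat[:, ci] = st.alpha.T.reshape(-1)
        # (b) z layer: JJ pseudo-observations
        xi = np.sqrt(np.square(z_mean) + s_diag)
        lam = _jj_lambda(xi)
        pseudo_prec = 2.0 * lam
        pseudo_e = (alpha_flat - 0.5) / pseudo_prec
        pseudo_std = 1.0 / np.sqrt(pseudo_prec)
        stack = EdgeScoreStack(
            scores=pseudo_e, cell_types=cell_types, edge_universe=universe,
        )
        noise = NoiseStack(
            std=pseudo_std, cell_types=cell_types, edge_universe=universe,
        )
        if share_state is None:
            share_state, _ = sm.init_state(stack, noise, share_cfg, share_prior)
        for _ in range(inner_share_sweeps):
            share_state = sm.update_edges(share_state, stack, noise)
            share_state = sm.update_responsibilities(share_state, stack)
            share_state = sm.update_components(share_state, stack, share_prior)
        z_mean = share_state.m_tilde.copy()
        s_diag = np.diagonal(share_state.s_tilde, axis1=1, axis2=2).copy()
    assert share_state is not None
    return SharedBVSResult(
        states=states, z_mean=z_mean, share_state=share_state,
        prior=share_prior, cell_types=cell_types,
    )


def train_test_split_cells(
    data: RegressionData, test_fraction: float = 0.2, seed: int = 0
) -> tuple[RegressionData, RegressionData, dict]:
    """Seeded 80/20 (by default) split of cells within one cell type.

    Returns (train, test, manifest) where the manifest records the cell row
    indices per fold and the seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = data.n_cells
    n_test = max(1, int(round(n * test_fraction)))
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    if train_idx.size == 0:
        raise ValueError("split leaves no training cells")
    manifest = {
        "seed": seed,
        "test_fraction": test_fraction,
        "train_rows": train_idx.tolist(),
        "test_rows": test_idx.tolist(),
    }
    mk = lambda idx: RegressionData(
        x=data.x[idx], y=data.y[idx], cell_type_label=data.cell_type_label
    )
    return mk(train_idx), mk(test_idx), manifest
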