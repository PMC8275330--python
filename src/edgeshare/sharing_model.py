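"""Hierarchical mixture model that shares edge-score information across cell types.

Generative model, per edge n (out of N) with C cell types and K components:

    u_n        ~ Categorical(1/K, ..., 1/K)
    z_n | u_n  ~ Normal(mu_{u_n}, Sigma_{u_n})            (C-dimensional)
    (mu_k, Sigma_k^{-1}) ~ NormalWishart(mu0, beta0, Psi, nu)
    e_n^{(c)} | z_n ~ Normal(z_n^{(c)}, sigma_n^{(c)2})   (observed score)

The Wishart factor is parameterized with scale matrix ``Psi`` on the
*covariance* side, i.e. ``Sigma^{-1} ~ Wishart(nu, Psi^{-1})`` so that
``E[Sigma^{-1}] = nu * Psi^{-1}``.

Posterior inference is mean-field coordinate ascent over

    q(z_n) = N(m_n, S_n),  q(u_n) = Categorical(phi_n),
    q(mu_k, Sigma_k^{-1}) = NormalWishart(a_k, beta_k, B_k, nu_k)

with closed-form conjugate updates.  Missing observations contribute zero
likelihood precision (equivalent to infinite noise).  The posterior means
``m_n`` are the revised edge scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.special import digamma, gammaln, logsumexp
from sklearn.cluster import KMeans

from .scoring import EdgeScoreStack, NoiseStack

logger = logging.getLogger(__name__)

__all__ = [
    "NWPrior",
    "ModelConfig",
    "ShareState",
    "FittedModel",
    "default_nw_prior",
    "init_state",
    "update_edges",
    "update_responsibilities",
    "update_components",
    "compute_elbo",
    "fit",
    "revised_scores",
    "component_correlation",
    "save_fit",
    "load_fit",
]


@dataclass
class NWPrior:
    """Normal-Wishart prior (mu0, beta0, Psi, nu) over (mu_k, Sigma_k^{-1})."""

    mu0: np.ndarray
    beta0: float
    psi: np.ndarray
    nu: float

    def __post_init__(self) -> None:
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        c = self.mu0.shape[0]
        if self.psi.shape != (c, c):
            raise ValueError("Psi shape does not match mu0")
        if not np.allclose(self.psi, self.psi.T):
            raise ValueError("Psi must be symmetric")
        try:
            np.linalg.cholesky(self.psi)
        except np.linalg.LinAlgError as exc:
            raise ValueError("Psi must be positive definite") from exc
        if self.nu <= c - 1:
            raise ValueError(f"nu must exceed C-1={c - 1}, got {self.nu}")
        if self.beta0 <= 0:
            raise ValueError("beta0 must be positive")


@dataclass
class ModelConfig:
    n_components: int = 10
    link: str = "identity"
    max_iter: int = 500
    rel_tol: float = 1e-6
    seed: int = 0
    init: str = "kmeans"
    block_size: int = 20000
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.link not in {"identity", "sigmoid"}:
            raise ValueError(f"unknown link {self.link!r}")
        if self.init not in {"kmeans", "random"}:
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class ShareState:
    """Variational state: component NW posteriors plus per-edge factors.

    ``s_tilde`` caches the per-edge posterior covariances from the last
    q(z) update; component updates and the ELBO read it, so it always
    reflects the responsibilities in force when q(z) was last refreshed.
    """

    a_tilde: np.ndarray      # (K, C) NW location
    beta_tilde: np.ndarray   # (K,)
    b_tilde: np.ndarray      # (K, C, C) inverse Wishart-scale (covariance side)
    nu_tilde: np.ndarray     # (K,)
    m_tilde: np.ndarray      # (N, C) edge posterior means
    s_tilde: np.ndarray      # (N, C, C) edge posterior covariances
    phi: np.ndarray          # (N, K) responsibilities

    @property
    def n_components(self) -> int:
        return self.a_tilde.shape[0]

    @property
    def weight_mass(self) -> np.ndarray:
        return self.phi.sum(axis=0)

    def copy(self) -> "ShareState":
        return ShareState(
            self.a_tilde.copy(), self.beta_tilde.copy(), self.b_tilde.copy(),
            self.nu_tilde.copy(), self.m_tilde.copy(), self.s_tilde.copy(),
            self.phi.copy(),
        )


@dataclass
class FittedModel:
    state: ShareState
    elbo_trace: list[float]
    config: ModelConfig
    prior: NWPrior
    cell_types: list[str]
    converged: bool = False


def default_nw_prior(stack: EdgeScoreStack) -> NWPrior:
    """Data-scaled default prior.

    mu0 = per-cell-type mean of observed scores; beta0 = 1e-3; nu = C + 2;
    Psi = nu * diag(per-cell-type score variances) so the expected precision
    matches the empirical diagonal: (E[Sigma^{-1}])^{-1} = Psi/nu.
    """
    c = stack.n_cell_types
    observed = ~stack.missing_mask
    n_obs_edges = int(np.any(observed, axis=1).sum())
    if n_obs_edges < c + 2:
        raise ValueError(
            f"need at least C+2={c + 2} non-missing edges, got {n_obs_edges}"
        )
    counts = observed.sum(axis=0)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(
            f"cell type {stack.cell_types[empty[0]]!r} has no observed scores"
        )
    mu0 = np.empty(c)
    var = np.empty(c)
    for j in range(c):
        col = stack.scores[observed[:, j], j]
        mu0[j] = col.mean()
        var[j] = max(col.var(), 1e-12)
    nu = float(c + 2)
    return NWPrior(mu0=mu0, beta0=1e-3, psi=nu * np.diag(var), nu=nu)


# ---------------------------------------------------------------------------
# update helpers

def _expected_precision(state: ShareState) -> np.ndarray:
    """E_q[Sigma_k^{-1}] = nu_k * B_k^{-1}, shape (K, C, C)."""
    return state.nu_tilde[:, None, None] * np.linalg.inv(state.b_tilde)


def _expected_logdet_precision(state: ShareState) -> np.ndarray:
    """E_q[log det Sigma_k^{-1}] per component, shape (K,)."""
    k, c = state.a_tilde.shape
    i = np.arange(1, c + 1)
    digam = digamma((state.nu_tilde[:, None] + 1 - i) / 2.0).sum(axis=1)
    sign, logdet_b = np.linalg.slogdet(state.b_tilde)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("B_tilde not positive definite")
    return digam + c * np.log(2.0) - logdet_b


def _noise_precision(stack: EdgeScoreStack, noise: NoiseStack) -> np.ndarray:
    """Per-entry observation precision; zero where missing."""
    with np.errstate(divide="ignore"):
        d_inv = 1.0 / np.square(noise.std)
    d_inv = np.where(stack.missing_mask, 0.0, d_inv)
    if not np.all(np.isfinite(d_inv)):
        raise ValueError("non-finite noise precision for an observed entry")
    return d_inv


def update_edges(
    state: ShareState, stack: EdgeScoreStack, noise: NoiseStack,
    block_size: int = 20000,
) -> ShareState:
    """Refresh q(z_n) = N(m_n, S_n) for every edge.

    Lambda_n = sum_k phi_nk E[Sigma_k^{-1}] + D_n^{-1};  S_n = Lambda_n^{-1};
    m_n = S_n (sum_k phi_nk E[Sigma_k^{-1} mu_k] + D_n^{-1} e_n)
    """
    new = state.copy()
    c = stack.n_cell_types
    e_prec = _expected_precision(state)                     # (K,C,C)
    e_prec_mu = np.einsum("kcd,kd->kc", e_prec, state.a_tilde)
    d_inv = _noise_precision(stack, noise)
    e_filled = np.where(stack.missing_mask, 0.0, stack.scores)
    n = stack.n_edges
    diag = np.arange(c)
    for start in range(0, n, block_size):
        sl = slice(start, min(start + block_size, n))
        lam = np.einsum("nk,kcd->ncd", state.phi[sl], e_prec)
        lam[:, diag, diag] += d_inv[sl]
        try:
            s_block = np.linalg.inv(lam)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "non-SPD edge precision; component nu_tilde="
                f"{state.nu_tilde}, beta_tilde={state.beta_tilde}"
            ) from exc
        h = state.phi[sl] @ e_prec_mu + d_inv[sl] * e_filled[sl]
        new.m_tilde[sl] = np.einsum("ncd,nd->nc", s_block, h)
        new.s_tilde[sl] = 0.5 * (s_block + s_block.transpose(0, 2, 1))
    return new


def _expected_log_gaussian(state: ShareState) -> np.ndarray:
    """E_q[log N(z_n | mu_k, Sigma_k)] for all n, k — shape (N, K).

    Uses q(z_n) = N(m_n, S_n) and the NW component posteriors:
    1/2 E[logdet Sigma^{-1}] - C/2 log 2pi
    - 1/2 (C/beta_k + nu_k [(m_n - a_k)' B_k^{-1} (m_n - a_k) + tr(B_k^{-1} S_n)])
    """
    c = state.m_tilde.shape[1]
    b_inv = np.linalg.inv(state.b_tilde)                      # (K,C,C)
    logdet = _expected_logdet_precision(state)                # (K,)
    diff = state.m_tilde[:, None, :] - state.a_tilde[None, :, :]   # (N,K,C)
    maha = np.einsum("nkc,kcd,nkd->nk", diff, b_inv, diff)
    tr = np.einsum("kcd,ndc->nk", b_inv, state.s_tilde)
    quad = c / state.beta_tilde[None, :] + state.nu_tilde[None, :] * (maha + tr)
    return 0.5 * (logdet[None, :] - c * np.log(2 * np.pi) - quad)


def update_responsibilities(state: ShareState, stack: EdgeScoreStack) -> ShareState:
    """Refresh q(u_n): phi_nk proportional to exp E_q[log N(z_n|mu_k, Sigma_k)].

    The uniform Categorical(1/K) prior adds no tilt.  Normalization uses
    log-sum-exp; an all-zero row signals an implementation bug upstream.
    """
    new = state.copy()
    log_rho = _expected_log_gaussian(state)
    norm = logsumexp(log_rho, axis=1, keepdims=True)
    if not np.all(np.isfinite(norm)):
        raise FloatingPointError("responsibility normalizer is not finite")
    new.phi = np.exp(log_rho - norm)
    return new


def update_components(
    state: ShareState, stack: EdgeScoreStack, prior: NWPrior
) -> ShareState:
    """Conjugate Normal-Wishart refresh of every component posterior.

    Standard weighted updates with responsibilities phi and the second
    moments of q(z); an empty component (N_k = 0) is reset to the prior.
    """
    new = state.copy()
    k_comp, c = state.a_tilde.shape
    nk = state.phi.sum(axis=0)                                 # (K,)
    weighted_m = state.phi.T @ state.m_tilde                   # (K,C)
    for k in range(k_comp):
        if nk[k] <= 0:
            logger.info("component %d empty; reset to prior", k)
            new.a_tilde[k] = prior.mu0
            new.beta_tilde[k] = prior.beta0
            new.b_tilde[k] = prior.psi
            new.nu_tilde[k] = prior.nu
            continue
        zbar = weighted_m[k] / nk[k]
        diff = state.m_tilde - zbar                            # (N,C)
        scatter = np.einsum("n,ncd->cd", state.phi[:, k], state.s_tilde)
        scatter += (state.phi[:, k, None] * diff).T @ diff
        new.beta_tilde[k] = prior.beta0 + nk[k]
        new.nu_tilde[k] = prior.nu + nk[k]
        new.a_tilde[k] = (prior.beta0 * prior.mu0 + nk[k] * zbar) / new.beta_tilde[k]
        dm = zbar - prior.mu0
        b = prior.psi + scatter + (
            prior.beta0 * nk[k] / new.beta_tilde[k]
        ) * np.outer(dm, dm)
        new.b_tilde[k] = 0.5 * (b + b.T)
    return new


def compute_elbo(
    state: ShareState, stack: EdgeScoreStack, noise: NoiseStack, prior: NWPrior
) -> float:
    """Evidence lower bound, all expectations in closed form.

    Raises ``FloatingPointError`` naming the term that went non-finite.
    """
    n, c = stack.scores.shape
    k_comp = state.n_components
    observed = ~stack.missing_mask
    d_inv = _noise_precision(stack, noise)

    # E[log p(e | z)] over observed entries
    resid = np.where(observed, stack.scores - state.m_tilde, 0.0)
    s_diag = np.diagonal(state.s_tilde, axis1=1, axis2=2)
    log_sigma2 = np.where(observed, np.log(np.square(noise.std)), 0.0)
    term_lik = -0.5 * (
        np.sum(observed * (np.log(2 * np.pi) + log_sigma2))
        + np.sum(d_inv * (np.square(resid) + np.where(observed, s_diag, 0.0)))
    )

    # E[log p(z | u, mu, Sigma)] and entropies of q(u)
    e_log_gauss = _expected_log_gaussian(state)
    term_z_prior = float(np.sum(state.phi * e_log_gauss))
    term_u_prior = -n * np.log(k_comp)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(state.phi > 0, state.phi * np.log(state.phi), 0.0)
    term_u_entropy = -float(np.sum(plogp))

    # entropy of q(z)
    sign, logdet_s = np.linalg.slogdet(state.s_tilde)
    if np.any(sign <= 0):
        raise FloatingPointError("q(z) covariance not positive definite")
    term_z_entropy = 0.5 * float(np.sum(logdet_s) + n * c * np.log(2 * np.pi * np.e))

    # E[log p(mu, Sigma)] - E[log q(mu, Sigma)] = -KL(q_k || prior) per
    # component, written as an explicit KL so identical parameters cancel
    # exactly (no gammaln catastrophic cancellation at large nu)
    b_inv = np.linalg.inv(state.b_tilde)
    i = np.arange(1, c + 1)
    term_nw = 0.0
    for k in range(k_comp):
        beta_t, nu_t = state.beta_tilde[k], state.nu_tilde[k]
        da = state.a_tilde[k] - prior.mu0
        maha = float(da @ b_inv[k] @ da)
        kl_gauss = 0.5 * (
            prior.beta0 * nu_t * maha
            + c * prior.beta0 / beta_t - c + c * np.log(beta_t / prior.beta0)
        )
        # KL(Wishart(nu_t, B_t^{-1}) || Wishart(nu, Psi^{-1}))
        sign_q, logdet_bq = np.linalg.slogdet(state.b_tilde[k])
        sign_p, logdet_psi = np.linalg.slogdet(prior.psi)
        if sign_q <= 0 or sign_p <= 0:
            raise FloatingPointError("Wishart scale not positive definite")
        tr_term = float(np.trace(prior.psi @ b_inv[k]))
        psi_c_q = digamma((nu_t + 1 - i) / 2.0).sum()
        kl_wishart = (
            -0.5 * prior.nu * (logdet_psi - logdet_bq)
            + 0.5 * nu_t * (tr_term - c)
            + gammaln((prior.nu + 1 - i) / 2.0).sum()
            - gammaln((nu_t + 1 - i) / 2.0).sum()
            + 0.5 * (nu_t - prior.nu) * psi_c_q
        )
        term_nw -= kl_gauss + kl_wishart

    terms = {
        "likelihood": term_lik,
        "z_prior": term_z_prior,
        "u_prior": term_u_prior,
        "u_entropy": term_u_entropy,
        "z_entropy": term_z_entropy,
        "normal_wishart": term_nw,
    }
    for name, value in terms.items():
        if not np.isfinite(value):
            raise FloatingPointError(f"ELBO term {name!r} is not finite")
    return float(sum(terms.values()))


# ---------------------------------------------------------------------------
# initialization and the fit loop

def init_state(
    stack: EdgeScoreStack,
    noise: NoiseStack,
    cfg: ModelConfig,
    prior: NWPrior | None = None,
) -> tuple[ShareState, NWPrior]:
    """Deterministic (seeded) initial state.

    Responsibilities come from k-means on the score rows (missing entries
    mean-imputed); component posteriors from one conjugate update pass;
    m is initialized at the observed scores (imputed where missing).
    """
    if prior is None:
        prior = default_nw_prior(stack)
    n, c = stack.scores.shape
    k_comp = cfg.n_components
    if k_comp > n:
        raise ValueError(f"K={k_comp} exceeds number of edges N={n}")
    observed = ~stack.missing_mask
    col_mean = np.array([
        stack.scores[observed[:, j], j].mean() if observed[:, j].any() else 0.0
        for j in range(c)
    ])
    imputed = np.where(observed, stack.scores, col_mean)

    rng = np.random.default_rng(cfg.seed)
    if k_comp == 1:
        phi = np.ones((n, 1))
    elif cfg.init == "kmeans":
        km = KMeans(
            n_clusters=k_comp, n_init=5,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        # fit on lexicographically sorted rows so the centroids depend only
        # on the multiset of score vectors, making the initialization (and
        # thus the whole fit) equivariant under edge permutations
        order = np.lexsort(imputed.T[::-1])
        km.fit(imputed[order])
        labels = km.predict(imputed)
        phi = np.zeros((n, k_comp))
        phi[np.arange(n), labels] = 1.0
    else:
        phi = rng.dirichlet(np.ones(k_comp), size=n)

    state = ShareState(
        a_tilde=np.tile(prior.mu0, (k_comp, 1)),
        beta_tilde=np.full(k_comp, prior.beta0),
        b_tilde=np.tile(prior.psi, (k_comp, 1, 1)),
        nu_tilde=np.full(k_comp, prior.nu),
        m_tilde=imputed.copy(),
        s_tilde=np.tile(np.eye(c) * 1e-6, (n, 1, 1)),
        phi=phi,
    )
    state = update_components(state, stack, prior)
    return state, prior


def fit(
    stack: EdgeScoreStack,
    noise: NoiseStack,
    cfg: ModelConfig | None = None,
    prior: NWPrior | None = None,
) -> FittedModel:
    """Coordinate-ascent fit: sweeps of q(z) -> q(u) -> q(mu, Sigma) until the
    relative ELBO change drops below ``cfg.rel_tol`` or ``cfg.max_iter``."""
    if cfg is None:
        cfg = ModelConfig()
    if stack.scores.shape != noise.std.shape:
        raise ValueError("score and noise stacks are misaligned")
    work = stack
    if cfg.standardize:
        work = _standardized(stack)
    state, prior = init_state(work, noise, cfg, prior)
    trace: list[float] = []
    converged = False
    for it in range(cfg.max_iter):
        state = update_edges(state, work, noise, block_size=cfg.block_size)
        state = update_responsibilities(state, work)
        state = update_components(state, work, prior)
        elbo = compute_elbo(state, work, noise, prior)
        trace.append(elbo)
        if it > 0:
            prev = trace[-2]
            if abs(elbo - prev) <= cfg.rel_tol * abs(prev):
                converged = True
                break
    logger.info("fit finished after %d sweeps (converged=%s)", len(trace), converged)
    return FittedModel(
        state=state, elbo_trace=trace, config=cfg, prior=prior,
        cell_types=list(stack.cell_types), converged=converged,
    )


def _standardized(stack: EdgeScoreStack) -> EdgeScoreStack:
    observed = ~stack.missing_mask
    scores = stack.scores.copy()
    for j in range(stack.n_cell_types):
        col = scores[observed[:, j], j]
        scale = col.std() or 1.0
        scores[:, j] = (scores[:, j] - col.mean()) / scale
    return EdgeScoreStack(
        scores=scores, cell_types=list(stack.cell_types),
        edge_universe=stack.edge_universe,
        missing_mask=stack.missing_mask.copy(),
    )


def revised_scores(model: FittedModel, stack: EdgeScoreStack) -> EdgeScoreStack:
    """Posterior means m_n as the revised edge-score stack (same universe
    and cell-type order as the input).  Never NaN: missing entries revise to
    the model's conditional mean given the observed cell types."""
    m = model.state.m_tilde
    if not np.all(np.isfinite(m)):
        raise FloatingPointError("revised scores contain non-finite values")
    return EdgeScoreStack(
        scores=m.copy(),
        cell_types=list(stack.cell_types),
        edge_universe=stack.edge_universe,
        missing_mask=np.zeros_like(stack.missing_mask),
    )


def component_correlation(
    model: FittedModel, k: int | None = None
) -> tuple[np.ndarray, list[int]]:
    """Correlation matrix of E_q[Sigma_k] = B_k/(nu_k - C - 1) with an
    average-linkage ordering of the cell types.

    ``k`` is a 0-based component index; by default the component with the
    largest responsibility mass.  Returns ``(correlation, leaf_order)``.
    """
    state = model.state
    if k is None:
        k = int(np.argmax(state.weight_mass))
    if not 0 <= k < state.n_components:
        raise ValueError(f"component index {k} out of range")
    c = state.a_tilde.shape[1]
    dof = state.nu_tilde[k] - c - 1
    if dof <= 0:
        raise ValueError(
            f"E[Sigma] undefined: nu_tilde={state.nu_tilde[k]} <= C+1={c + 1}"
        )
    cov = state.b_tilde[k] / dof
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    corr = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    if c > 2:
        dist = squareform(1.0 - corr, checks=False)
        order = leaves_list(average(dist)).tolist()
    else:
        order = list(range(c))
    return corr, order


# ---------------------------------------------------------------------------
# serialization (JSON; text-only, documented layout)

def save_fit(model: FittedModel, path: str | Path) -> None:
    state = model.state
    payload = {
        "format": "edgeshare-fit-v1",
        "cell_types": model.cell_types,
        "converged": model.converged,
        "elbo_trace": model.elbo_trace,
        "config": {
            "n_components": model.config.n_components,
            "link": model.config.link,
            "max_iter": model.config.max_iter,
            "rel_tol": model.config.rel_tol,
            "seed": model.config.seed,
            "init": model.config.init,
            "block_size": model.config.block_size,
            "standardize": model.config.standardize,
        },
        "prior": {
            "mu0": model.prior.mu0.tolist(),
            "beta0": model.prior.beta0,
            "psi": model.prior.psi.tolist(),
            "nu": model.prior.nu,
        },
        "components": {
            "a_tilde": state.a_tilde.tolist(),
            "beta_tilde": state.beta_tilde.tolist(),
            "b_tilde": state.b_tilde.tolist(),
            "nu_tilde": state.nu_tilde.tolist(),
            "weight_mass": state.weight_mass.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_fit(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "edgeshare-fit-v1":
        raise ValueError(f"{path}: not an edgeshare fit file")
    return payload
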