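import numpy as np
import pytest
from scipy.stats import multivariate_normal
from sklearn.metrics import adjusted_rand_score

from edgeshare import sharing_model as sm
from edgeshare import synthetic_data as sd
from edgeshare.scoring import EdgeScoreStack, NoiseStack
from edgeshare.synthetic_data import index_edge_universe


def _stacks(e, sig, missing=None):
    n, c = e.shape
    u = index_edge_universe(n)
    cts = [f"ct{j}" for j in range(c)]
    stack = EdgeScoreStack(
        scores=e, cell_types=cts, edge_universe=u, missing_mask=missing
    )
    noise = NoiseStack(std=sig, cell_types=cts, edge_universe=u)
    return stack, noise


def _frozen_state(mu, sigma, e, n_edges, big=1e12):
    """K=1 state with the NW posterior frozen (point mass) at (mu, sigma)."""
    c = len(mu)
    return sm.ShareState(
        a_tilde=mu[None, :],
        beta_tilde=np.array([big]),
        b_tilde=(big * sigma)[None, :, :],
        nu_tilde=np.array([big]),
        m_tilde=e.copy(),
        s_tilde=np.tile(np.eye(c), (n_edges, 1, 1)),
        phi=np.ones((n_edges, 1)),
    )


class TestPrior:
    def test_standardized_scores_give_zero_mean_identity_psi(self, rng):
        e = rng.standard_normal((200, 3))
        e = (e - e.mean(0)) / e.std(0)
        stack, _ = _stacks(e, np.ones_like(e))
        prior = sm.default_nw_prior(stack)
        assert np.allclose(prior.mu0, 0.0, atol=1e-12)
        assert np.allclose(prior.psi, prior.nu * np.eye(3), atol=1e-10)

    def test_nu_rule(self, rng):
        e = rng.standard_normal((50, 2))
        stack, _ = _stacks(e, np.ones_like(e))
        assert sm.default_nw_prior(stack).nu == 4.0

    def test_expected_precision_matches_empirical_diagonal(self, rng):
        # Wishart identity: E[Sigma^{-1}] = nu Psi^{-1}, so the prior's
        # expected precision inverts to the empirical diagonal
        e = rng.standard_normal((300, 4)) * np.array([1.0, 2.0, 0.5, 3.0])
        stack, _ = _stacks(e, np.ones_like(e))
        prior = sm.default_nw_prior(stack)
        implied_cov = np.linalg.inv(prior.nu * np.linalg.inv(prior.psi))
        empirical = np.diag(e.var(axis=0))
        assert np.allclose(implied_cov, empirical, atol=1e-10)

    def test_all_missing_cell_type_errors(self, rng):
        e = rng.standard_normal((20, 2))
        missing = np.zeros_like(e, dtype=bool)
        missing[:, 1] = True
        stack, _ = _stacks(e, np.ones_like(e), missing)
        with pytest.raises(ValueError, match="ct1"):
            sm.default_nw_prior(stack)


class TestInit:
    def test_k1_uniform_phi(self, rng):
        e = rng.standard_normal((30, 3))
        stack, noise = _stacks(e, np.ones_like(e))
        state, _ = sm.init_state(stack, noise, sm.ModelConfig(n_components=1, seed=0))
        assert np.array_equal(state.phi, np.ones((30, 1)))

    def test_planted_clusters_recovered_at_init(self):
        stack, noise, truth = sd.simulate_sharing(
            300, 4, 2, separation=8.0, noise_levels=0.1, seed=5
        )
        state, _ = sm.init_state(stack, noise, sm.ModelConfig(n_components=2, seed=5))
        ari = adjusted_rand_score(truth.assignments, state.phi.argmax(axis=1))
        assert ari == 1.0

    def test_same_seed_identical_state(self, rng):
        e = rng.standard_normal((40, 3))
        stack, noise = _stacks(e, np.ones_like(e))
        cfg = sm.ModelConfig(n_components=2, seed=9)
        s1, _ = sm.init_state(stack, noise, cfg)
        s2, _ = sm.init_state(stack, noise, cfg)
        assert np.array_equal(s1.phi, s2.phi)
        assert np.array_equal(s1.b_tilde, s2.b_tilde)

    def test_k_exceeding_n_errors(self, rng):
        e = rng.standard_normal((5, 2))
        stack, noise = _stacks(e, np.ones_like(e))
        with pytest.raises(ValueError, match="K"):
            sm.init_state(stack, noise, sm.ModelConfig(n_components=8, seed=0))


class TestEdgeUpdate:
    def test_conjugate_gaussian_oracle(self, rng):
        c, n = 4, 100
        mu = rng.normal(size=c)
        a = rng.normal(size=(c, c))
        sigma = a @ a.T + c * np.eye(c)
        e = rng.normal(size=(n, c))
        sig = rng.uniform(0.3, 2.0, size=(n, c))
        stack, noise = _stacks(e, sig)
        state = sm.update_edges(_frozen_state(mu, sigma, e, n), stack, noise)
        sigma_inv = np.linalg.inv(sigma)
        for i in range(n):
            d_inv = np.diag(1.0 / sig[i] ** 2)
            expected = np.linalg.solve(
                sigma_inv + d_inv, sigma_inv @ mu + d_inv @ e[i]
            )
            assert np.allclose(state.m_tilde[i], expected, atol=1e-8)

    def test_zero_noise_limit_returns_observations(self, rng):
        e = rng.normal(size=(20, 3))
        stack, noise = _stacks(e, np.full((20, 3), 1e-8))
        mu = rng.normal(size=3)
        state = sm.update_edges(
            _frozen_state(mu, np.eye(3), e, 20), stack, noise
        )
        assert np.abs(state.m_tilde - e).max() < 1e-6

    def test_infinite_noise_limit_returns_prior_mean(self, rng):
        e = rng.normal(size=(20, 3))
        stack, noise = _stacks(e, np.full((20, 3), 1e9))
        mu = rng.normal(size=3)
        state = sm.update_edges(
            _frozen_state(mu, np.eye(3), e, 20), stack, noise
        )
        assert np.abs(state.m_tilde - mu).max() < 1e-6

    def test_blocked_equals_unblocked(self, rng):
        stack, noise, _ = sd.simulate_sharing(97, 3, 2, seed=2)
        state, _ = sm.init_state(stack, noise, sm.ModelConfig(n_components=2, seed=2))
        full = sm.update_edges(state, stack, noise, block_size=10**6)
        blocked = sm.update_edges(state, stack, noise, block_size=13)
        assert np.allclose(full.m_tilde, blocked.m_tilde, atol=1e-12)
        assert np.allclose(full.s_tilde, blocked.s_tilde, atol=1e-12)


class TestResponsibilities:
    def _fitted_state(self, n=20, c=3, k=2, seed=0):
        stack, noise, _ = sd.simulate_sharing(n, c, k, seed=seed)
        state, prior = sm.init_state(
            stack, noise, sm.ModelConfig(n_components=k, seed=seed)
        )
        state = sm.update_edges(state, stack, noise)
        return state, stack, noise, prior

    def test_identical_components_give_uniform(self, rng):
        state, stack, noise, prior = self._fitted_state()
        for f in ("a_tilde", "beta_tilde", "b_tilde", "nu_tilde"):
            arr = getattr(state, f)
            arr[1] = arr[0]
        out = sm.update_responsibilities(state, stack)
        assert np.allclose(out.phi, 0.5, atol=1e-12)

    def test_dominant_component_takes_all(self, rng):
        state, stack, noise, prior = self._fitted_state()
        big = 1e10
        # component 0 centered exactly on every edge is impossible; pick one
        # edge and freeze component 0 on it with tiny covariance
        state.a_tilde[0] = state.m_tilde[0]
        state.beta_tilde[:] = big
        state.nu_tilde[:] = big
        state.b_tilde[0] = big * np.eye(3) * 1e-4
        state.a_tilde[1] = state.m_tilde[0] + 100.0
        state.b_tilde[1] = big * np.eye(3) * 1e-4
        state.s_tilde[0] = np.eye(3) * 1e-8
        out = sm.update_responsibilities(state, stack)
        assert out.phi[0, 0] > 1 - 1e-12

    def test_rows_normalize(self):
        state, stack, noise, prior = self._fitted_state(n=50, seed=3)
        out = sm.update_responsibilities(state, stack)
        assert np.allclose(out.phi.sum(axis=1), 1.0, atol=1e-10)

    def test_monte_carlo_oracle(self):
        # E_q[log N(z_n | mu_k, Sigma_k)] by joint sampling of
        # (z, mu, Lambda) from the variational posterior
        state, stack, noise, prior = self._fitted_state(n=20, c=3, k=2, seed=1)
        log_rho = sm._expected_log_gaussian(state)
        rng = np.random.default_rng(99)
        n_draws = 200_000
        for n_idx in (0, 7):
            for k in (0, 1):
                nu, beta = state.nu_tilde[k], state.beta_tilde[k]
                w_scale = np.linalg.inv(state.b_tilde[k])
                from scipy.stats import wishart

                lam = wishart.rvs(df=nu, scale=w_scale, size=n_draws, random_state=rng)
                chol = np.linalg.cholesky(lam)
                # mu | Lambda ~ N(a, (beta Lambda)^{-1}): solve L^T x = eps
                eps = rng.standard_normal((n_draws, 3))
                delta = np.linalg.solve(
                    np.transpose(chol, (0, 2, 1)), eps[..., None]
                )[..., 0] / np.sqrt(beta)
                mu = state.a_tilde[k] + delta
                zchol = np.linalg.cholesky(state.s_tilde[n_idx])
                z = state.m_tilde[n_idx] + rng.standard_normal((n_draws, 3)) @ zchol.T
                diff = z - mu
                sign, logdet = np.linalg.slogdet(lam)
                quad = np.einsum("nc,ncd,nd->n", diff, lam, diff)
                samples = 0.5 * (logdet - 3 * np.log(2 * np.pi) - quad)
                mc = samples.mean()
                se = samples.std(ddof=1) / np.sqrt(n_draws)
                assert abs(mc - log_rho[n_idx, k]) < 3.5 * se


class TestComponentUpdate:
    def test_empty_component_reset_to_prior(self, rng):
        e = rng.standard_normal((30, 3))
        stack, noise = _stacks(e, np.ones_like(e))
        state, prior = sm.init_state(
            stack, noise, sm.ModelConfig(n_components=2, seed=0)
        )
        state.phi[:, 1] = 0.0
        state.phi[:, 0] = 1.0
        out = sm.update_components(state, stack, prior)
        assert np.allclose(out.a_tilde[1], prior.mu0)
        assert np.allclose(out.b_tilde[1], prior.psi)
        assert out.nu_tilde[1] == prior.nu

    def test_degenerate_conjugacy_gives_sample_mean(self, rng):
        e = rng.standard_normal((40, 2))
        stack, noise = _stacks(e, np.ones_like(e))
        prior = sm.NWPrior(mu0=np.zeros(2), beta0=1e-12, psi=np.eye(2), nu=4.0)
        state, _ = sm.init_state(
            stack, noise, sm.ModelConfig(n_components=1, seed=0), prior
        )
        state.m_tilde = e.copy()
        state.s_tilde = np.zeros((40, 2, 2))
        out = sm.update_components(state, stack, prior)
        assert np.allclose(out.a_tilde[0], e.mean(axis=0), atol=1e-9)

    def test_b_tilde_spd_and_elbo_nondecreasing(self):
        stack, noise, _ = sd.simulate_sharing(60, 3, 2, seed=4)
        cfg = sm.ModelConfig(n_components=2, seed=4)
        state, prior = sm.init_state(stack, noise, cfg)
        state = sm.update_edges(state, stack, noise)
        state = sm.update_responsibilities(state, stack)
        before = sm.compute_elbo(state, stack, noise, prior)
        out = sm.update_components(state, stack, prior)
        for k in range(2):
            np.linalg.cholesky(out.b_tilde[k])  # raises if not SPD
        after = sm.compute_elbo(out, stack, noise, prior)
        assert after >= before - 1e-8 * abs(before)


class TestElbo:
    def test_single_coordinate_updates_never_decrease(self):
        stack, noise, _ = sd.simulate_sharing(80, 4, 3, seed=6, missing_rate=0.1)
        cfg = sm.ModelConfig(n_components=3, seed=6)
        state, prior = sm.init_state(stack, noise, cfg)
        state = sm.update_edges(state, stack, noise)
        elbo = sm.compute_elbo(state, stack, noise, prior)
        for _ in range(3):
            for step in (
                lambda s: sm.update_edges(s, stack, noise),
                lambda s: sm.update_responsibilities(s, stack),
                lambda s: sm.update_components(s, stack, prior),
            ):
                state = step(state)
                new = sm.compute_elbo(state, stack, noise, prior)
                assert new >= elbo - 1e-8 * abs(elbo)
                elbo = new

    def test_matches_exact_evidence_k1(self, rng):
        c = 3
        mu = rng.normal(size=c)
        a = rng.normal(size=(c, c))
        sigma = a @ a.T + c * np.eye(c)
        e = rng.normal(size=(1, c))
        sig = rng.uniform(0.3, 1.5, size=(1, c))
        stack, noise = _stacks(e, sig)
        big = 1e12
        prior = sm.NWPrior(mu0=mu, beta0=big, psi=big * sigma, nu=big)
        state = _frozen_state(mu, sigma, e, 1, big=big)
        state = sm.update_edges(state, stack, noise)
        elbo = sm.compute_elbo(state, stack, noise, prior)
        exact = multivariate_normal.logpdf(e[0], mu, sigma + np.diag(sig[0] ** 2))
        assert elbo == pytest.approx(exact, abs=1e-6)

    def test_local_optimality_finite_difference(self, rng):
        stack, noise, _ = sd.simulate_sharing(5, 2, 2, seed=8)
        cfg = sm.ModelConfig(n_components=2, seed=8, max_iter=50)
        model = sm.fit(stack, noise, cfg)
        state, prior = model.state, model.prior
        base = sm.compute_elbo(state, stack, noise, prior)
        # m_tilde is at a coordinate optimum given everything else
        state2 = sm.update_edges(state, stack, noise)
        base2 = sm.compute_elbo(state2, stack, noise, prior)
        for delta in (1e-3, -1e-3):
            pert = state2.copy()
            pert.m_tilde[2, 0] += delta
            assert sm.compute_elbo(pert, stack, noise, prior) <= base2 + 1e-12
        # responsibilities likewise (perturb within the simplex)
        state3 = sm.update_responsibilities(state2, stack)
        base3 = sm.compute_elbo(state3, stack, noise, prior)
        pert = state3.copy()
        row = pert.phi[1].copy()
        row = np.clip(row + np.array([1e-3, -1e-3]), 1e-9, None)
        pert.phi[1] = row / row.sum()
        assert sm.compute_elbo(pert, stack, noise, prior) <= base3 + 1e-12
        # component location
        state4 = sm.update_components(state3, stack, prior)
        base4 = sm.compute_elbo(state4, stack, noise, prior)
        for delta in (1e-4, -1e-4):
            pert = state4.copy()
            pert.a_tilde[0, 1] += delta
            assert sm.compute_elbo(pert, stack, noise, prior) <= base4 + 1e-12


class TestFit:
    def test_huge_tol_single_sweep(self):
        stack, noise, _ = sd.simulate_sharing(50, 3, 2, seed=0)
        model = sm.fit(
            stack, noise, sm.ModelConfig(n_components=2, seed=0, rel_tol=1e6)
        )
        assert len(model.elbo_trace) == 2  # needs two points to compare
        assert model.converged

    def test_same_seed_identical_trace(self):
        stack, noise, _ = sd.simulate_sharing(60, 3, 2, seed=1)
        cfg = sm.ModelConfig(n_components=2, seed=1)
        t1 = sm.fit(stack, noise, cfg).elbo_trace
        t2 = sm.fit(stack, noise, cfg).elbo_trace
        assert t1 == t2

    def test_trace_monotone_over_20_seeds(self):
        for seed in range(20):
            stack, noise, _ = sd.simulate_sharing(
                40, 3, 2, seed=seed, noise_levels=0.7, missing_rate=0.05
            )
            model = sm.fit(
                stack, noise, sm.ModelConfig(n_components=2, seed=seed, max_iter=40)
            )
            tr = np.array(model.elbo_trace)
            assert np.all(np.diff(tr) >= -1e-8 * np.abs(tr[:-1]))

    def test_edge_permutation_equivariance(self):
        stack, noise, _ = sd.simulate_sharing(50, 3, 2, seed=11)
        cfg = sm.ModelConfig(n_components=2, seed=11, max_iter=30)
        model = sm.fit(stack, noise, cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(50)
        u = index_edge_universe(50)
        stack_p = EdgeScoreStack(
            scores=stack.scores[perm],
            cell_types=list(stack.cell_types),
            edge_universe=u,
            missing_mask=stack.missing_mask[perm],
        )
        noise_p = NoiseStack(
            std=noise.std[perm], cell_types=list(stack.cell_types), edge_universe=u
        )
        model_p = sm.fit(stack_p, noise_p, cfg)
        assert np.allclose(model_p.state.m_tilde, model.state.m_tilde[perm], atol=1e-8)

    def test_parameter_recovery_and_denoising(self):
        ok = 0
        for seed in range(5):
            stack, noise, truth = sd.simulate_sharing(
                1000, 6, 3, separation=3.0, noise_levels=0.5, seed=seed
            )
            model = sm.fit(
                stack, noise, sm.ModelConfig(n_components=3, seed=seed, max_iter=200)
            )
            ari = adjusted_rand_score(
                truth.assignments, model.state.phi.argmax(axis=1)
            )
            mse_m = np.mean((model.state.m_tilde - truth.z_true) ** 2)
            mse_e = np.mean((stack.scores - truth.z_true) ** 2)
            ok += (ari >= 0.9) and (mse_m < mse_e)
        assert ok == 5


class TestOutputs:
    def test_revised_scores_no_nan_with_missing(self):
        stack, noise, _ = sd.simulate_sharing(80, 4, 2, seed=3, missing_rate=0.3)
        model = sm.fit(stack, noise, sm.ModelConfig(n_components=2, seed=3))
        rev = sm.revised_scores(model, stack)
        assert np.all(np.isfinite(rev.scores))
        assert rev.cell_types == stack.cell_types
        assert not rev.missing_mask.any()

    def test_shrinkage_only_revision_close_to_observed(self, rng):
        e = rng.standard_normal((50, 1))
        stack, noise = _stacks(e, np.full((50, 1), 0.5))
        prior = sm.NWPrior(
            mu0=np.zeros(1), beta0=1e-10, psi=np.eye(1) * 1e4, nu=2.0
        )
        model = sm.fit(
            stack, noise, sm.ModelConfig(n_components=1, seed=0), prior
        )
        # with a near-flat prior and one cell type there is nothing to share
        assert np.abs(model.state.m_tilde - e).max() < 0.05

    def test_denoising_correlated_cell_types(self, rng):
        n = 400
        z = rng.standard_normal(n)
        truth = np.column_stack([z, z])
        noisy = truth + np.column_stack(
            [rng.normal(0, 0.05, n), rng.normal(0, 1.0, n)]
        )
        stack, noise = _stacks(
            noisy, np.tile(np.array([0.05, 1.0]), (n, 1))
        )
        model = sm.fit(stack, noise, sm.ModelConfig(n_components=1, seed=0))
        err_revised = np.linalg.norm(model.state.m_tilde[:, 1] - truth[:, 1])
        err_observed = np.linalg.norm(noisy[:, 1] - truth[:, 1])
        assert err_revised < err_observed

    def test_component_correlation_properties(self):
        stack, noise, _ = sd.simulate_sharing(200, 4, 2, seed=7)
        model = sm.fit(stack, noise, sm.ModelConfig(n_components=2, seed=7))
        corr, order = sm.component_correlation(model)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)
        assert np.all(corr >= -1) and np.all(corr <= 1)
        assert sorted(order) == [0, 1, 2, 3]

    def test_component_correlation_diagonal_b(self):
        stack, noise, _ = sd.simulate_sharing(50, 3, 1, seed=0)
        model = sm.fit(stack, noise, sm.ModelConfig(n_components=1, seed=0))
        model.state.b_tilde[0] = np.diag([1.0, 2.0, 3.0])
        model.state.nu_tilde[0] = 10.0
        corr, _ = sm.component_correlation(model, 0)
        assert np.allclose(corr, np.eye(3), atol=1e-12)

    def test_block_covariance_recovered(self):
        # planted two-block sharing pattern: types {0,1,2} vs {3,4,5}
        c = 6
        block = np.zeros((c, c))
        block[:3, :3] = 0.9
        block[3:, 3:] = 0.9
        np.fill_diagonal(block, 1.0)
        sigma = np.stack([block])
        stack, noise, _ = sd.simulate_sharing(
            2000, c, 1, noise_levels=0.2, seed=2, sigma=sigma
        )
        model = sm.fit(stack, noise, sm.ModelConfig(n_components=1, seed=2))
        corr, _ = sm.component_correlation(model, 0)
        within = np.concatenate([corr[:3, :3][np.triu_indices(3, 1)],
                                 corr[3:, 3:][np.triu_indices(3, 1)]])
        between = corr[:3, 3:].ravel()
        assert within.mean() > between.mean() + 0.3

    def test_undefined_expectation_errors(self):
        stack, noise, _ = sd.simulate_sharing(50, 3, 1, seed=0)
        model = sm.fit(stack, noise, sm.ModelConfig(n_components=1, seed=0))
        model.state.nu_tilde[0] = 3.5  # <= C+1 = 4
        with pytest.raises(ValueError, match="undefined"):
            sm.component_correlation(model, 0)

    def test_save_load_roundtrip(self, tmp_path):
        stack, noise, _ = sd.simulate_sharing(50, 3, 2, seed=5)
        model = sm.fit(stack, noise, sm.ModelConfig(n_components=2, seed=5))
        sm.save_fit(model, tmp_path / "fit.json")
        payload = sm.load_fit(tmp_path / "fit.json")
        assert payload["cell_types"] == ["ct0", "ct1", "ct2"]
        assert np.allclose(
            np.array(payload["components"]["a_tilde"]), model.state.a_tilde
        )
        assert payload["elbo_trace"] == model.elbo_trace
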