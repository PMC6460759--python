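"""Full multi-trait sampler: canonical transform, conditionals, priors, Geweke."""

import numpy as np
import pytest
from scipy.stats import invwishart, ks_2samp

from mtme import (ChainConfig, Hyperparams, MTMEDataset, MTMEState,
                  build_design, compound_symmetry_grm, compute_Q,
                  default_hyperparams, dataset1_config, run_bmtme,
                  simulate_dataset)
from mtme.gibbs import conditional_b1_direct, conditional_b1_thompson

from conftest import toy_dataset


class TestComputeQ:
    def test_identity_inputs_give_orthogonal_q(self):
        qt = compute_Q(np.eye(3), np.eye(3))
        np.testing.assert_allclose(qt.D_t, np.ones(3))
        np.testing.assert_allclose(qt.Q @ qt.Q.T, np.eye(3), atol=1e-12)

    def test_already_diagonal_sorted_descending(self):
        qt = compute_Q(np.diag([4.0, 1.0]), np.eye(2))
        np.testing.assert_allclose(qt.D_t, [4.0, 1.0])
        # Q is a signed permutation (here: identity up to sign convention)
        np.testing.assert_allclose(np.abs(qt.Q), np.eye(2), atol=1e-12)

    def test_defining_identities_random_spd(self):
        St = np.array([[1.0, 0.5], [0.5, 1.0]])
        Re = np.array([[2.0, 0.3], [0.3, 1.0]])
        qt = compute_Q(St, Re)
        np.testing.assert_allclose(qt.Q @ Re @ qt.Q.T, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(qt.Q @ St @ qt.Q.T, np.diag(qt.D_t), atol=1e-10)

    def test_singular_residual_rejected(self):
        with pytest.raises(np.linalg.LinAlgError, match="jitter"):
            compute_Q(np.eye(2), np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3))
        St = A @ A.T + 3 * np.eye(3)
        qt1 = compute_Q(St, np.eye(3))
        qt2 = compute_Q(St, np.eye(3))
        np.testing.assert_array_equal(qt1.Q, qt2.Q)


class TestDefaultHyperparams:
    def test_beta0_is_group_means(self):
        ds, truth = simulate_dataset(dataset1_config(seed=2))
        hyper = default_hyperparams(ds)
        env = np.array([ds.env_ids.index(e) for e, _ in ds.row_index])
        for i in range(3):
            np.testing.assert_allclose(hyper.beta0[i], ds.Y[env == i].mean(axis=0))
        # group means sit near the generating beta (env1 trait1 near 13)
        assert abs(hyper.beta0[0, 0] - 13) < 2.0

    def test_identical_columns_give_isotropic_scale(self):
        ds = toy_dataset(2, 6, 1, seed=1)
        Y = np.tile(ds.Y, (1, 3))
        ds3 = MTMEDataset(ds.env_ids, ds.line_ids, Y, ["a", "b", "c"], ds.row_index)
        hyper = default_hyperparams(ds3)
        assert np.allclose(np.diag(hyper.S_t), np.diag(hyper.S_t)[0])

    def test_seven_traits_need_explicit_df(self):
        rng = np.random.default_rng(0)
        ds = toy_dataset(3, 10, 7, seed=0)
        with pytest.raises(ValueError, match="nu_t"):
            default_hyperparams(ds)
        hyper = default_hyperparams(ds, nu_t=10, nu_e=10)
        assert hyper.nu_t == 10


class TestConditionals:
    def _random_state(self, I, J, L, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(L, L))
        B = rng.normal(size=(L, L))
        C = rng.normal(size=(I, I))
        return MTMEState(beta=rng.normal(size=(I, L)), b1=np.zeros((J, L)),
                         b2=rng.normal(size=(I * J, L)),
                         Sigma_t=A @ A.T + L * np.eye(L),
                         Sigma_E=C @ C.T + I * np.eye(I),
                         R_e=B @ B.T + L * np.eye(L))

    def test_thompson_equals_direct_b1_conditional_mean(self):
        """The canonical transform is an exact reparametrization: the
        back-transformed per-trait conditional mean of b1 equals the joint
        vec-form conditional mean."""
        I, J, L = 2, 4, 3
        ds = toy_dataset(I, J, L, seed=4)
        d = build_design(ds)
        G = compound_symmetry_grm(J, 0.5, 0.5).G
        state = self._random_state(I, J, L, seed=7)
        _, mean_direct = conditional_b1_direct(d, G, state, ds.Y)
        mean_th = conditional_b1_thompson(d, G, state, ds.Y)
        np.testing.assert_allclose(mean_th, mean_direct, atol=1e-8)

    def test_sampled_b1_mean_matches_closed_form(self):
        """Holding all other blocks fixed, the empirical mean of repeated b1
        draws matches the stated normal's own mean."""
        I, J, L = 2, 4, 2
        ds = toy_dataset(I, J, L, seed=3)
        d = build_design(ds)
        G = compound_symmetry_grm(J, 0.4, 0.6).G
        state = self._random_state(I, J, L, seed=5)
        prec, mean = conditional_b1_direct(d, G, state, ds.Y)
        rng = np.random.default_rng(8)
        cov = np.linalg.inv(prec)
        Lc = np.linalg.cholesky(cov)
        draws = mean.reshape(-1, order="F") + (
            rng.standard_normal((20000, J * L)) @ Lc.T)
        assert np.abs(draws.mean(axis=0) - mean.reshape(-1, order="F")).max() < 1e-2

    def test_collapsed_b1_conditional_matches_dense_oracle(self):
        """The eigenbasis form of the b1 update with b2 marginalized out
        (marginal residual I + d * Sigma_E kron G) equals the dense
        linear-algebra computation."""
        rng = np.random.default_rng(0)
        I, J = 3, 5
        G = compound_symmetry_grm(J, 0.5, 0.5).G
        A = rng.normal(size=(I, I))
        SE = A @ A.T + I * np.eye(I)
        d_l = 0.7
        sg, Ug = np.linalg.eigh(G)
        se, Ve = np.linalg.eigh(SE)
        Z1 = np.vstack([np.eye(J)] * I)      # cell-space line incidence
        r0 = rng.normal(size=I * J)
        V = np.eye(I * J) + d_l * np.kron(SE, G)
        prec_dense = np.linalg.inv(G) / d_l + Z1.T @ np.linalg.solve(V, Z1)
        mean_dense = np.linalg.solve(prec_dense,
                                     Z1.T @ np.linalg.solve(V, r0))
        cvec = Ve.T @ np.ones(I)
        T = Ug.T @ r0.reshape(I, J).T @ Ve
        denom = 1.0 + d_l * np.outer(sg, se)
        prec_eig = 1.0 / (d_l * sg) + ((cvec ** 2)[None, :] / denom).sum(axis=1)
        mean_eig = Ug @ (((T / denom) @ cvec) / prec_eig)
        np.testing.assert_allclose(mean_eig, mean_dense, atol=1e-10)
        np.testing.assert_allclose((Ug * prec_eig) @ Ug.T, prec_dense, atol=1e-10)

    def test_inverse_wishart_moment(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        nu = 7
        draws = invwishart.rvs(df=nu, scale=S, size=100_000,
                               random_state=np.random.default_rng(1))
        target = S / (nu - 2 - 1)
        se = np.sqrt(np.var(draws, axis=0) / draws.shape[0])
        assert (np.abs(draws.mean(axis=0) - target) < 3 * se).all()


class TestSamplers:
    def test_beta_posterior_matches_group_means_when_randoms_vanish(self):
        """With the trait and environment covariances pinned near zero, the
        random effects collapse and the diffuse-prior beta posterior is the
        per-environment trait mean."""
        I, J, L = 2, 8, 2
        ds = toy_dataset(I, J, L, seed=6)
        ds.Y += 5.0
        d = build_design(ds)
        G = np.eye(J)
        nu_big = 1e6
        hyper = Hyperparams(
            nu_t=nu_big, nu_E=nu_big, nu_e=5.0,
            S_t=1e-8 * np.eye(L) * (nu_big - L - 1),
            S_E=1e-8 * np.eye(I) * (nu_big - I - 1),
            S_e=0.5 * np.eye(L) * (5.0 - L - 1),
            beta0=np.zeros((I, L)), S_beta_t=1e6 * np.eye(L))
        post = run_bmtme(ds, d, G, hyper, ChainConfig(6000, 1000, 1, seed=2),
                         sampler="direct")
        env = d.X.argmax(axis=1)
        means = np.vstack([ds.Y[env == i].mean(axis=0) for i in range(I)])
        assert np.abs(post.mean_state.beta - means).max() < 0.01

    def test_direct_and_thompson_agree_on_posterior(self):
        """Both samplers target the same posterior: Sigma_t posterior means
        agree within 3x their combined Monte Carlo errors."""
        I, J, L = 2, 12, 2
        rng = np.random.default_rng(10)
        cfg_ds = toy_dataset(I, J, L, seed=10)
        cfg_ds.Y = cfg_ds.Y + rng.normal(size=(1, L))
        d = build_design(cfg_ds)
        G = compound_symmetry_grm(J, 0.5, 0.5).G
        hyper = default_hyperparams(cfg_ds)
        chain = ChainConfig(n_iter=8000, burn_in=2000, thin=2, seed=1)
        p1 = run_bmtme(cfg_ds, d, G, hyper, chain, sampler="direct")
        p2 = run_bmtme(cfg_ds, d, G, hyper,
                       ChainConfig(8000, 2000, 2, seed=2), sampler="thompson")
        for draws1, draws2 in ((p1.Sigma_t_draws, p2.Sigma_t_draws),):
            m1, m2 = draws1.mean(axis=0), draws2.mean(axis=0)
            # crude ESS-deflated MC errors
            se1 = draws1.std(axis=0) / np.sqrt(draws1.shape[0] / 10)
            se2 = draws2.std(axis=0) / np.sqrt(draws2.shape[0] / 10)
            assert (np.abs(m1 - m2) < 3 * np.sqrt(se1 ** 2 + se2 ** 2)).all()

    def test_single_trait_transform_is_scalar_whitening(self):
        """L = 1: Q collapses to 1/sqrt(R_e) and both samplers agree on the
        posterior (scalar canonical transform = null reparametrization)."""
        qt = compute_Q(np.array([[2.5]]), np.array([[4.0]]))
        np.testing.assert_allclose(qt.Q, [[0.5]])
        np.testing.assert_allclose(qt.D_t, [2.5 / 4.0])
        ds = toy_dataset(2, 6, 1, seed=3)
        d = build_design(ds)
        G = compound_symmetry_grm(6, 0.5, 0.5).G
        hyper = default_hyperparams(ds)
        p1 = run_bmtme(ds, d, G, hyper, ChainConfig(6000, 1000, 2, seed=9),
                       sampler="direct")
        p2 = run_bmtme(ds, d, G, hyper, ChainConfig(6000, 1000, 2, seed=10),
                       sampler="thompson")
        for a, b in ((p1.Sigma_t_draws, p2.Sigma_t_draws),
                     (p1.R_e_draws, p2.R_e_draws)):
            se = np.sqrt(a.var() / (a.shape[0] / 10) + b.var() / (b.shape[0] / 10))
            assert abs(a.mean() - b.mean()) < 3 * se

    def test_partial_missing_rows_rejected(self):
        ds = toy_dataset(2, 5, 2, seed=0)
        ds.Y[3, 0] = np.nan
        d = build_design(ds)
        hyper = default_hyperparams(ds)
        with pytest.raises(ValueError, match="some but not all"):
            run_bmtme(ds, d, np.eye(5), hyper, ChainConfig(10, 1, 1, seed=0))

    def test_stored_covariance_draws_are_spd(self):
        ds = toy_dataset(2, 6, 2, seed=2)
        d = build_design(ds)
        G = compound_symmetry_grm(6, 0.5, 0.5).G
        post = run_bmtme(ds, d, G, default_hyperparams(ds),
                         ChainConfig(600, 100, 5, seed=4))
        for draws in (post.Sigma_t_draws, post.Sigma_E_draws, post.R_e_draws):
            for S in draws:
                np.linalg.cholesky(S)


def test_geweke_joint_distribution():
    """Successive-conditional simulation (one warm-started Gibbs sweep, then a
    fresh data draw given the state) must leave the parameter marginals at the
    prior; compared against iid prior draws with a KS test."""
    I, J, L = 2, 6, 2
    ds = toy_dataset(I, J, L, seed=0)
    d = build_design(ds)
    G = compound_symmetry_grm(J, 0.5, 0.5).G
    hyper = Hyperparams(nu_t=6.0, nu_E=5.0, nu_e=6.0,
                        S_t=np.eye(L) * 2.0, S_E=np.eye(I) * 1.5,
                        S_e=np.eye(L) * 2.0, beta0=np.zeros((I, L)),
                        S_beta_t=np.eye(L))
    rng = np.random.default_rng(2024)
    A = np.linalg.cholesky(G)

    def prior_state():
        St = invwishart.rvs(df=hyper.nu_t, scale=hyper.S_t, random_state=rng)
        SE = invwishart.rvs(df=hyper.nu_E, scale=hyper.S_E, random_state=rng)
        Re = invwishart.rvs(df=hyper.nu_e, scale=hyper.S_e, random_state=rng)
        beta = rng.standard_normal((I, L)) @ np.linalg.cholesky(hyper.S_beta_t).T
        b1 = A @ rng.standard_normal((J, L)) @ np.linalg.cholesky(St).T
        AE = np.linalg.cholesky(np.kron(SE, G))
        b2 = AE @ rng.standard_normal((I * J, L)) @ np.linalg.cholesky(St).T
        return MTMEState(beta, b1, b2, np.atleast_2d(St), np.atleast_2d(SE),
                         np.atleast_2d(Re))

    def draw_data(state):
        E = rng.standard_normal((I * J, L)) @ np.linalg.cholesky(state.R_e).T
        return d.X @ state.beta + d.Z1 @ state.b1 + d.Z2 @ state.b2 + E

    n_rounds = 4000
    mc = np.array([[s.Sigma_t[0, 0], s.R_e[0, 1]]
                   for s in (prior_state() for _ in range(6000))])
    sc = np.empty((n_rounds, 2))
    state = prior_state()
    for t in range(n_rounds):
        ds.Y = draw_data(state)
        post = run_bmtme(ds, d, G, hyper,
                         ChainConfig(n_iter=1, burn_in=0, thin=1,
                                     seed=int(rng.integers(2 ** 31))),
                         sampler="thompson", initial=state)
        state = post.final_state
        sc[t] = state.Sigma_t[0, 0], state.R_e[0, 1]
    # thin the successive chain so the KS test sees near-independent samples
    sc = sc[::8]
    assert ks_2samp(np.log(mc[:, 0]), np.log(sc[:, 0])).pvalue > 0.01
    assert ks_2samp(mc[:, 1], sc[:, 1]).pvalue > 0.01
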