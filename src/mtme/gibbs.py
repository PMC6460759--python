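"""Gibbs samplers for the Bayesian multi-trait multi-environment (BMTME) model.

Model (n rows = (environment, line) cells, L traits):

    Y = X beta + Z1 b1 + Z2 b2 + e
    b1 ~ MN(0, G, Sigma_t)                 genotype x trait
    b2 ~ MN(0, Sigma_E kron G, Sigma_t)    environment x genotype x trait
    rows of e iid N(0, R_e)

Priors: beta ~ MN(beta0, I_I, S_beta_t); Sigma_t ~ IW(nu_t, S_t);
Sigma_E ~ IW(nu_E, S_E); R_e ~ IW(nu_e, S_e).

Two samplers target the same posterior:

* ``sampler="direct"`` draws vec(b1) (J*L-dimensional) and vec(b2)
  (I*J*L-dimensional) from their joint full conditionals.  Exact but cubic in
  those dimensions; intended for small instances and validation.
* ``sampler="thompson"`` (default) recomputes, each sweep, the canonical
  transform Q with Q R_e Q' = I and Q Sigma_t Q' = D_t (diagonal), maps the
  working quantities onto the transformed scale, and samples the random
  effects ONE TRAIT AT A TIME with precisions ``d_l^{-1} G^{-1} + Z1'Z1`` and
  ``d_l^{-1} (Sigma_E kron G)^{-1} + Z2'Z2`` before mapping them back.  An
  exact reparametrization: the remaining blocks (beta, Sigma_t, Sigma_E, R_e)
  are updated exactly as in the direct sampler.

Rows whose traits are ALL missing are handled by data augmentation (a
predictive draw per sweep), which leaves the marginal posterior untouched and
keeps the design balanced so the one-off eigendecomposition of G (and the
cheap per-sweep one of Sigma_E) diagonalizes every trait-wise update.
Partially missing rows are not supported and raise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import invwishart

from .datamodel import (ChainConfig, DesignSet, Hyperparams, MTMEDataset,
                        MTMEState)
from .kernels import Kinship, condition_spd

logger = logging.getLogger(__name__)

__all__ = ["QTransform", "MTMEPosterior", "default_hyperparams", "compute_Q",
           "run_bmtme"]


@dataclass
class QTransform:
    """Trait-decorrelating transform: Q R_e Q' = I, Q Sigma_t Q' = D_t."""

    Q: np.ndarray       # L x L
    D_t: np.ndarray     # length L, positive, descending
    P: np.ndarray       # symmetric whitener of R_e
    L_mat: np.ndarray   # eigenvectors of P Sigma_t P'

    @property
    def Q_inv_T(self) -> np.ndarray:
        return np.linalg.inv(self.Q).T


def compute_Q(Sigma_t: np.ndarray, R_e: np.ndarray) -> QTransform:
    """Canonical transform diagonalizing Sigma_t while whitening R_e.

    ``P = U_e B_e^{-1/2} U_e'`` from the eigendecomposition
    ``R_e = U_e B_e U_e'``; then ``P Sigma_t P' = L D_t L'`` and ``Q = L' P``.
    Eigenvalues are sorted descending and each eigenvector's
    largest-magnitude entry is forced positive, so Q is deterministic.
    """
    R_e = np.asarray(R_e, dtype=float)
    Sigma_t = np.asarray(Sigma_t, dtype=float)
    be, Ue = np.linalg.eigh(R_e)
    if be.min() <= 0 or be.max() / be.min() > 1e12:
        raise np.linalg.LinAlgError(
            "R_e is numerically singular (condition number > 1e12); add jitter")
    P = (Ue / np.sqrt(be)) @ Ue.T
    M = P @ Sigma_t @ P.T
    d, Lm = np.linalg.eigh((M + M.T) / 2.0)
    order = np.argsort(d)[::-1]
    d, Lm = d[order], Lm[:, order]
    for k in range(Lm.shape[1]):
        if Lm[np.abs(Lm[:, k]).argmax(), k] < 0:
            Lm[:, k] = -Lm[:, k]
    if d.min() <= 0:
        raise np.linalg.LinAlgError("Sigma_t is not positive definite under P")
    return QTransform(Q=Lm.T @ P, D_t=d, P=P, L_mat=Lm)


def default_hyperparams(dataset: MTMEDataset, nu_t: float | None = None,
                        nu_E: float | None = None,
                        nu_e: float | None = None) -> Hyperparams:
    """Weakly informative defaults in the style of whole-genome regression software.

    beta0 is the per-environment trait mean (the least-squares solution for a
    cell-means X); the IW scales put half the observed variance on each
    covariance block a priori: ``S = 0.5 * diag(var) * (nu - dim - 1)`` so the
    prior mean is ``0.5 * diag(var)``.  The default nu of 5 is only proper for
    small dimensions; for larger L or I pass nu explicitly (e.g. dim + 3).
    """
    Y = dataset.Y
    I, L = dataset.n_env, dataset.n_traits
    nu_t = 5.0 if nu_t is None else float(nu_t)
    nu_E = 5.0 if nu_E is None else float(nu_E)
    nu_e = 5.0 if nu_e is None else float(nu_e)

    env_of_row = np.array([dataset.env_ids.index(e) for e, _ in dataset.row_index])
    beta0 = np.vstack([np.nanmean(Y[env_of_row == i], axis=0) for i in range(I)])

    col_var = np.nanvar(Y, axis=0, ddof=1)
    S_t = 0.5 * np.diag(col_var) * (nu_t - L - 1)
    S_e = 0.5 * np.diag(col_var) * (nu_e - L - 1)
    env_var = np.array([np.nanmean(np.nanvar(Y[env_of_row == i], axis=0, ddof=1))
                        for i in range(I)])
    S_E = 0.5 * np.diag(env_var) * (nu_E - I - 1)
    S_t, _ = condition_spd(S_t)
    S_e, _ = condition_spd(S_e)
    S_E, _ = condition_spd(S_E)

    hyper = Hyperparams(nu_t=nu_t, nu_E=nu_E, nu_e=nu_e, S_t=S_t, S_E=S_E,
                        S_e=S_e, beta0=beta0, S_beta_t=1e6 * np.eye(L))
    hyper.validate(I, L)
    return hyper


@dataclass
class MTMEPosterior:
    """Thinned draws of the small blocks plus posterior means of everything."""

    beta_draws: np.ndarray       # S x I x L
    Sigma_t_draws: np.ndarray    # S x L x L
    Sigma_E_draws: np.ndarray    # S x I x I
    R_e_draws: np.ndarray        # S x L x L
    mean_state: MTMEState        # posterior means of all blocks
    fitted: np.ndarray           # n x L posterior mean of X beta + Z1 b1 + Z2 b2
    final_state: MTMEState | None = None   # last sweep's state (warm restarts)

    @property
    def n_stored(self) -> int:
        return self.beta_draws.shape[0]

    @property
    def beta_sd(self) -> np.ndarray:
        return self.beta_draws.std(axis=0, ddof=1)


def _env_major_views(b2_col: np.ndarray, I: int, J: int) -> np.ndarray:
    """Reshape an env-major length-IJ vector to a J x I matrix (line, env)."""
    return b2_col.reshape(I, J).T


def _check_complete_rows(dataset: MTMEDataset) -> np.ndarray:
    """Return boolean mask of fully-missing rows; raise on partial missingness."""
    miss = dataset.missing_mask
    full_miss = miss.all(axis=1)
    partial = miss.any(axis=1) & ~full_miss
    if partial.any():
        r = int(np.flatnonzero(partial)[0])
        raise ValueError(
            f"row {r} {dataset.row_index[r]} has some but not all traits missing; "
            "the multi-trait sampler needs complete rows (or fully held-out cells)")
    return full_miss


def conditional_b1_direct(design: DesignSet, G: np.ndarray, state: MTMEState,
                          Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Precision and mean (as a J x L matrix) of vec(b1) | rest, direct form.

    Precision = Sigma_t^{-1} kron G^{-1} + R_e^{-1} kron Z1'Z1;
    rhs = vec(Z1' W R_e^{-1}) with W = Y - X beta - Z2 b2.
    """
    J, L = state.b1.shape
    W = Y - design.X @ state.beta - design.Z2 @ state.b2
    Ginv = np.linalg.inv(G)
    Reinv = np.linalg.inv(state.R_e)
    St_inv = np.linalg.inv(state.Sigma_t)
    prec = np.kron(St_inv, Ginv) + np.kron(Reinv, design.Z1.T @ design.Z1)
    rhs = (design.Z1.T @ W @ Reinv).reshape(-1, order="F")
    mean = np.linalg.solve(prec, rhs).reshape((J, L), order="F")
    return prec, mean


def conditional_b1_thompson(design: DesignSet, G: np.ndarray, state: MTMEState,
                            Y: np.ndarray) -> np.ndarray:
    """Back-transformed conditional mean of b1 via the canonical transform.

    At fixed (beta, Sigma_t, Sigma_E, R_e, b2) this must equal the direct
    conditional mean exactly: the transform is a reparametrization.
    """
    qt = compute_Q(state.Sigma_t, state.R_e)
    Q = qt.Q
    Yq = Y @ Q.T
    Bq = state.beta @ Q.T
    B2q = state.b2 @ Q.T
    Ginv = np.linalg.inv(G)
    Z1tZ1 = design.Z1.T @ design.Z1
    W = Yq - design.X @ Bq - design.Z2 @ B2q
    R1 = design.Z1.T @ W
    J, L = state.b1.shape
    mean_q = np.empty((J, L))
    for l in range(L):
        prec = Ginv / qt.D_t[l] + Z1tZ1
        mean_q[:, l] = np.linalg.solve(prec, R1[:, l])
    return mean_q @ qt.Q_inv_T


def run_bmtme(dataset: MTMEDataset, design: DesignSet, G: Kinship | np.ndarray,
              hyper: Hyperparams, chain: ChainConfig,
              sampler: str = "thompson",
              initial: MTMEState | None = None,
              recenter: bool = True) -> MTMEPosterior:
    """Run the BMTME Gibbs sampler and return thinned draws + posterior means.

    ``sampler`` is ``"thompson"`` (default, per-trait updates via the canonical
    transform) or ``"direct"`` (joint vec updates; limited to I*J*L <= 3000).
    ``initial`` warm-starts the chain from a given state (default: prior means
    for the covariances, beta0 for beta, zeros for the random effects).
    """
    if sampler not in ("thompson", "direct"):
        raise ValueError("sampler must be 'thompson' or 'direct'")
    Gm = G.G if isinstance(G, Kinship) else np.asarray(G, dtype=float)
    Gm, _ = condition_spd(Gm)
    I, J, L = dataset.n_env, dataset.n_lines, dataset.n_traits
    n = dataset.n_rows
    hyper.validate(I, L)
    if sampler == "direct" and I * J * L > 3000:
        raise ValueError("direct sampler limited to I*J*L <= 3000; use 'thompson'")

    full_miss = _check_complete_rows(dataset)
    Y = dataset.Y.copy()
    X, Z1, Z2 = design.X, design.Z1, design.Z2
    z1_rows = Z1.argmax(axis=1)
    z2_rows = Z2.argmax(axis=1)
    cell_order = np.argsort(z2_rows)   # rows rearranged to env-major cell order
    env_of_row = X.argmax(axis=1)

    sg, Ug = np.linalg.eigh(Gm)
    sg = np.maximum(sg, 1e-12)
    Ginv = (Ug / sg) @ Ug.T
    Ginv_one = Ginv @ np.ones(J)
    a1 = float(np.ones(J) @ Ginv_one)   # 1' G^-1 1, for the recentering moves
    d1 = Z1.sum(axis=0)
    d2 = Z2.sum(axis=0)
    balanced = np.allclose(d1, d1[0]) and np.allclose(d2, 1.0)
    if sampler == "thompson" and not balanced:
        raise ValueError("thompson sampler requires one observation per "
                         "(environment, line) cell; hold cells out as fully "
                         "missing rows instead of dropping them")
    c1 = float(d1[0])

    XtX = X.T @ X
    Sbt_inv = np.linalg.inv(hyper.S_beta_t)
    rng = np.random.default_rng(chain.seed)

    # initialization at prior means (or a supplied warm-start state)
    if initial is not None:
        beta = initial.beta.copy()
        b1 = initial.b1.copy()
        b2 = initial.b2.copy()
        Sigma_t = initial.Sigma_t.copy()
        Sigma_E = initial.Sigma_E.copy()
        R_e = initial.R_e.copy()
    else:
        beta = hyper.beta0.copy()
        b1 = np.zeros((J, L))
        b2 = np.zeros((I * J, L))
        Sigma_E = hyper.S_E / (hyper.nu_E - I - 1)
        # split the empirical trait covariance between the genetic and
        # residual blocks: with strongly correlated traits this starts the
        # chain far closer to the posterior than the diagonal prior means
        obs_rows = ~full_miss
        if obs_rows.sum() > L + 1:
            emp = np.cov((dataset.Y[obs_rows]
                          - (X @ beta)[obs_rows]).T, ddof=1)
            emp = np.atleast_2d(emp)
            emp, _ = condition_spd(0.5 * emp)
            Sigma_t = emp.copy()
            R_e = emp.copy()
        else:
            Sigma_t = hyper.S_t / (hyper.nu_t - L - 1)
            R_e = hyper.S_e / (hyper.nu_e - L - 1)
    Y[full_miss] = (X @ beta)[full_miss]

    n_store = chain.n_stored
    beta_draws = np.empty((n_store, I, L))
    St_draws = np.empty((n_store, L, L))
    SE_draws = np.empty((n_store, I, I))
    Re_draws = np.empty((n_store, L, L))
    sum_b1 = np.zeros((J, L))
    sum_b2 = np.zeros((I * J, L))
    sum_fit = np.zeros((n, L))
    kept = 0
    n_miss = int(full_miss.sum())

    for it in range(chain.n_iter):
        # impute fully-missing rows from the current predictive distribution
        if n_miss:
            fit_rows = (X @ beta + b1[z1_rows] + b2[z2_rows])[full_miss]
            Lr = np.linalg.cholesky(R_e)
            Y[full_miss] = fit_rows + rng.standard_normal((n_miss, L)) @ Lr.T

        Reinv = np.linalg.inv(R_e)

        # --- beta | rest ------------------------------------------------
        W = Y - b1[z1_rows] - b2[z2_rows]
        prec_b = np.kron(Sbt_inv, np.eye(I)) + np.kron(Reinv, XtX)
        rhs_b = (hyper.beta0 @ Sbt_inv + X.T @ W @ Reinv).reshape(-1, order="F")
        vb = _sample_prec_vec(prec_b, rhs_b, rng)
        beta = vb.reshape((I, L), order="F")
        xb = X @ beta

        if sampler == "thompson":
            qt = compute_Q(Sigma_t, R_e)
            Q = qt.Q
            d = qt.D_t
            Yq = Y @ Q.T
            xbq = xb @ Q.T

            se, Ve = np.linalg.eigh(Sigma_E)
            se = np.maximum(se, 1e-12)
            kron_eig = se[None, :] * sg[:, None]               # J x I
            cvec = Ve.T @ np.ones(I)

            # --- b1 per transformed trait, b2 marginalized --------------
            # blocked draw of (b1, b2): first b1 from its conditional with
            # b2 integrated out (marginal residual I + d_l * Sigma_E kron G,
            # diagonal in the same eigenbasis), then b2 | b1.  Avoids the
            # slow b1 <-> b2 alternation of the naive scheme.
            r0 = Yq - xbq
            b1q = np.empty((J, L))
            for l in range(L):
                Bl = _env_major_views(r0[cell_order, l], I, J)  # J x I
                T = Ug.T @ Bl @ Ve
                denom = 1.0 + d[l] * kron_eig                  # J x I
                rhs = (T / denom) @ cvec
                prec = 1.0 / (d[l] * sg) + ((cvec ** 2)[None, :] / denom).sum(axis=1)
                b1q[:, l] = Ug @ (rhs / prec
                                  + rng.standard_normal(J) / np.sqrt(prec))

            # --- b2 per transformed trait | b1 --------------------------
            R2 = Z2.T @ (Yq - xbq - b1q[z1_rows])
            b2q = np.empty_like(b2)
            for l in range(L):
                Bl = _env_major_views(R2[:, l], I, J)          # J x I
                T = Ug.T @ Bl @ Ve
                lam = 1.0 / (d[l] * kron_eig) + 1.0
                Tdraw = T / lam + rng.standard_normal((J, I)) / np.sqrt(lam)
                b2q[:, l] = (Ug @ Tdraw @ Ve.T).T.reshape(-1)
            Qit = qt.Q_inv_T
            b1 = b1q @ Qit
            b2 = b2q @ Qit
        else:
            # --- joint vec updates (small instances) --------------------
            St_inv = np.linalg.inv(Sigma_t)
            W1 = Y - xb - b2[z2_rows]
            prec1 = np.kron(St_inv, Ginv) + np.kron(Reinv, Z1.T @ Z1)
            rhs1 = (Z1.T @ W1 @ Reinv).reshape(-1, order="F")
            b1 = _sample_prec_vec(prec1, rhs1, rng).reshape((J, L), order="F")

            SEG_inv = np.kron(np.linalg.inv(Sigma_E), Ginv)
            W2 = Y - xb - b1[z1_rows]
            prec2 = np.kron(St_inv, SEG_inv) + np.kron(Reinv, Z2.T @ Z2)
            rhs2 = (Z2.T @ W2 @ Reinv).reshape(-1, order="F")
            b2 = _sample_prec_vec(prec2, rhs2, rng).reshape((I * J, L), order="F")

        # --- recentering (translation-group) moves ----------------------
        # The likelihood is invariant along beta[:,l] + c and b1[:,l] - c
        # (and the per-environment analogue with b2): when G has a large
        # common component these ridges mix very slowly under plain Gibbs,
        # so the shift is sampled exactly from its conditional.  Leaves the
        # posterior invariant.
        if recenter:
            St_inv = np.linalg.inv(Sigma_t)
            # (a) shared shift between beta and b1
            P_s = a1 * St_inv + I * Sbt_inv
            m_s = St_inv @ (b1.T @ Ginv_one) \
                - Sbt_inv @ ((beta - hyper.beta0).T @ np.ones(I))
            s = _sample_prec_vec(P_s, m_s, rng)
            beta = beta + s[None, :]
            b1 = b1 - s[None, :]
            # (b) per-environment shift between beta and the b2 blocks
            SE_inv = np.linalg.inv(Sigma_E)
            W_env = np.stack([b2[i * J:(i + 1) * J].T @ Ginv_one
                              for i in range(I)])
            P_T = a1 * np.kron(St_inv, SE_inv) + np.kron(Sbt_inv, np.eye(I))
            m_T = (SE_inv @ W_env @ St_inv - (beta - hyper.beta0) @ Sbt_inv
                   ).reshape(-1, order="F")
            T = _sample_prec_vec(P_T, m_T, rng).reshape((I, L), order="F")
            beta = beta + T
            for i in range(I):
                b2[i * J:(i + 1) * J] -= T[i][None, :]
            xb = X @ beta

        # --- Sigma_t | rest ---------------------------------------------
        A1 = Ug.T @ b1
        ss1 = A1.T @ (A1 / sg[:, None])
        T3 = b2.reshape(I, J, L)
        GT = np.einsum("jk,ikl->ijl", Ginv, T3)
        SE_inv = np.linalg.inv(Sigma_E)
        ss2 = np.einsum("ijl,ik,kjm->lm", T3, SE_inv, GT)
        scale_t = hyper.S_t + ss1 + (ss2 + ss2.T) / 2.0
        Sigma_t = invwishart.rvs(df=hyper.nu_t + J + I * J,
                                 scale=(scale_t + scale_t.T) / 2.0, random_state=rng)
        Sigma_t = np.atleast_2d(Sigma_t)

        # --- Sigma_E | rest ---------------------------------------------
        St_inv = np.linalg.inv(Sigma_t)
        M = np.einsum("kjl,lm,ijm->ik", GT, St_inv, T3)
        scale_E = hyper.S_E + (M + M.T) / 2.0
        Sigma_E = invwishart.rvs(df=hyper.nu_E + J * L,
                                 scale=(scale_E + scale_E.T) / 2.0, random_state=rng)
        Sigma_E = np.atleast_2d(Sigma_E)

        # --- R_e | rest -------------------------------------------------
        E = Y - xb - b1[z1_rows] - b2[z2_rows]
        scale_e = hyper.S_e + E.T @ E
        R_e = invwishart.rvs(df=hyper.nu_e + n,
                             scale=(scale_e + scale_e.T) / 2.0, random_state=rng)
        R_e = np.atleast_2d(R_e)

        if not (np.isfinite(Sigma_t).all() and np.isfinite(R_e).all()
                and np.isfinite(b1).all()):
            raise FloatingPointError(f"non-finite draw at iteration {it}")

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            beta_draws[kept] = beta
            St_draws[kept] = Sigma_t
            SE_draws[kept] = Sigma_E
            Re_draws[kept] = R_e
            sum_b1 += b1
            sum_b2 += b2
            sum_fit += xb + b1[z1_rows] + b2[z2_rows]
            kept += 1

    mean_state = MTMEState(
        beta=beta_draws[:kept].mean(axis=0), b1=sum_b1 / kept, b2=sum_b2 / kept,
        Sigma_t=St_draws[:kept].mean(axis=0), Sigma_E=SE_draws[:kept].mean(axis=0),
        R_e=Re_draws[:kept].mean(axis=0))
    final = MTMEState(beta=beta.copy(), b1=b1.copy(), b2=b2.copy(),
                      Sigma_t=Sigma_t.copy(), Sigma_E=Sigma_E.copy(), R_e=R_e.copy())
    return MTMEPosterior(beta_draws=beta_draws[:kept], Sigma_t_draws=St_draws[:kept],
                         Sigma_E_draws=SE_draws[:kept], R_e_draws=Re_draws[:kept],
                         mean_state=mean_state, fitted=sum_fit / kept,
                         final_state=final)


def _sample_prec_vec(prec: np.ndarray, rhs: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    prec = (prec + prec.T) / 2.0
    Lc = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    z = rng.standard_normal(rhs.size)
    return mean + np.linalg.solve(Lc.T, z)
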