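"""Single-trait Bayesian two-kernel mixed model (GBLUP with genotype-by-environment).

The model for one trait is

    y_ij = E_i + g_j + gE_ij + e_ij,
    g ~ N(0, sigma1^2 G),  gE ~ N(0, sigma2^2 I_I kron G),  e ~ N(0, sigma^2 I),

with a flat prior on the environment effects and scaled-inverse-chi-square
priors on the three variances.  The Gibbs sampler cycles
environments -> g -> gE -> variances -> missing-value imputation, in that
fixed order.  Missing responses are handled by data augmentation (a
predictive draw each iteration), so balanced designs stay balanced and the
spectral shortcuts below remain exact.

When every (environment, line) cell holds one observation, Z1'Z1 = I * I_J
and Z2'Z2 = I_{IJ}; a single eigendecomposition of G then turns each g / gE
update into diagonal work in the eigenbasis instead of a fresh Cholesky per
iteration.  The engine falls back to direct solves when that precondition
fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ChainConfig, DesignSet
from .kernels import Kinship, condition_spd

__all__ = ["UnivariatePrior", "UnivariatePosterior", "SpectralCache",
           "eigen_precompute", "fit_univariate"]

DEFAULT_DF = 5.0
DEFAULT_R2 = 0.5


@dataclass
class UnivariatePrior:
    """Scaled-inverse-chi-square settings: sigma^2 ~ S*nu / chi2_nu (mode S*nu/(nu+2))."""

    df: float
    S_g: float
    S_gE: float
    S_e: float

    @classmethod
    def from_response(cls, y: np.ndarray, df: float = DEFAULT_DF,
                      r2: float = DEFAULT_R2) -> "UnivariatePrior":
        """BGLR-style rule: prior modes are (1-r2)*var(y) for the residual and
        r2*var(y)/2 for each of the two genetic terms."""
        vy = float(np.nanvar(y))
        if vy == 0:
            vy = 1e-8
        mode_e = (1.0 - r2) * vy
        mode_g = r2 * vy / 2.0
        to_scale = (df + 2.0) / df
        return cls(df=df, S_g=mode_g * to_scale, S_gE=mode_g * to_scale,
                   S_e=mode_e * to_scale)


@dataclass
class SpectralCache:
    """Eigendecomposition of G plus the (constant) replication counts."""

    U: np.ndarray        # J x J eigenvectors of G
    s: np.ndarray        # eigenvalues of G (ascending, floored positive)
    c1: float | None     # Z1'Z1 = c1 * I_J if constant, else None
    c2: float | None     # Z2'Z2 = c2 * I_IJ if constant, else None
    G: np.ndarray

    @property
    def spectral_ok(self) -> bool:
        return self.c1 is not None and self.c2 is not None


def eigen_precompute(G: Kinship | np.ndarray, design: DesignSet) -> SpectralCache:
    """Factor G once and record whether the design permits the spectral path."""
    Gm = G.G if isinstance(G, Kinship) else np.asarray(G, dtype=float)
    Gm, _ = condition_spd(Gm)
    s, U = np.linalg.eigh(Gm)
    s = np.maximum(s, 1e-12)
    d1 = design.Z1.sum(axis=0)
    d2 = design.Z2.sum(axis=0)
    c1 = float(d1[0]) if np.allclose(d1, d1[0]) else None
    c2 = float(d2[0]) if np.allclose(d2, d2[0]) and d2[0] > 0 else None
    return SpectralCache(U=U, s=s, c1=c1, c2=c2, G=Gm)


@dataclass
class UnivariatePosterior:
    """Thinned draws and posterior means of one single-trait fit."""

    env_draws: np.ndarray      # S x I
    var_g_draws: np.ndarray    # S
    var_gE_draws: np.ndarray   # S
    var_e_draws: np.ndarray    # S
    mean_env: np.ndarray       # I
    mean_g: np.ndarray         # J
    mean_gE: np.ndarray        # I*J
    fitted: np.ndarray         # n  (posterior mean of X eta + Z1 g + Z2 gE)

    @property
    def var_g(self) -> float:
        return float(self.var_g_draws.mean())

    @property
    def var_gE(self) -> float:
        return float(self.var_gE_draws.mean())

    @property
    def var_e(self) -> float:
        return float(self.var_e_draws.mean())

    @property
    def n_stored(self) -> int:
        return self.var_g_draws.size

    def var_summary(self, which: str = "mean") -> tuple[float, float, float]:
        if which == "mean":
            return self.var_g, self.var_gE, self.var_e
        if which == "median":
            return (float(np.median(self.var_g_draws)),
                    float(np.median(self.var_gE_draws)),
                    float(np.median(self.var_e_draws)))
        raise ValueError("which must be 'mean' or 'median'")


def _sample_prec(prec: np.ndarray, rhs: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw from N(prec^{-1} rhs, prec^{-1}) via Cholesky of the precision."""
    Lc = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    z = rng.standard_normal(rhs.size)
    return mean + np.linalg.solve(Lc.T, z)


def fit_univariate(y: np.ndarray, design: DesignSet, G: Kinship | np.ndarray,
                   chain: ChainConfig, prior: UnivariatePrior | None = None,
                   fixed_variances: tuple[float, float, float] | None = None,
                   cache: SpectralCache | None = None) -> UnivariatePosterior:
    """Gibbs sampler for the single-trait two-kernel model.

    Parameters
    ----------
    y : length-n response; np.nan marks missing entries (imputed each sweep)
    fixed_variances : optional (sigma1^2, sigma2^2, sigma^2); when given the
        variance updates are skipped (useful for closed-form validation)
    cache : reuse an :func:`eigen_precompute` result across traits
    """
    y = np.asarray(y, dtype=float).copy()
    n = y.size
    X, Z1, Z2 = design.X, design.Z1, design.Z2
    I, J = X.shape[1], Z1.shape[1]
    miss = np.isnan(y)
    obs = ~miss
    env_of_row = X.argmax(axis=1)
    for i in range(I):
        if (obs & (env_of_row == i)).sum() < 2:
            raise ValueError(f"environment index {i} has fewer than 2 observed responses")
    if prior is None and fixed_variances is None:
        prior = UnivariatePrior.from_response(y[obs])
    if cache is None:
        cache = eigen_precompute(G, design)
    U, s = cache.U, cache.s
    Ginv = (U / s) @ U.T

    Ginv_one = Ginv @ np.ones(J)
    a1 = float(np.ones(J) @ Ginv_one)   # 1' G^-1 1
    rng = np.random.default_rng(chain.seed)
    # initialization
    y_cur = y.copy()
    y_cur[miss] = np.nanmean(y) if obs.any() else 0.0
    eta = np.zeros(I)
    g = np.zeros(J)
    gE = np.zeros(I * J)
    if fixed_variances is not None:
        v_g, v_gE, v_e = (float(v) for v in fixed_variances)
    else:
        vy = float(np.var(y[obs]))
        v_g = v_gE = max(vy / 4.0, 1e-8)
        v_e = max(vy / 2.0, 1e-8)

    env_counts = X.sum(axis=0)
    n_store = chain.n_stored
    env_draws = np.empty((n_store, I))
    vg_draws = np.empty(n_store)
    vgE_draws = np.empty(n_store)
    ve_draws = np.empty(n_store)
    sum_g = np.zeros(J)
    sum_gE = np.zeros(I * J)
    sum_fit = np.zeros(n)
    kept = 0

    z1_rows = Z1.argmax(axis=1)
    z2_rows = Z2.argmax(axis=1)
    spectral = cache.spectral_ok

    for it in range(chain.n_iter):
        # environment (fixed) effects: flat prior
        resid = y_cur - g[z1_rows] - gE[z2_rows]
        for i in range(I):
            sel = env_of_row == i
            m = resid[sel].mean()
            eta[i] = m + np.sqrt(v_e / env_counts[i]) * rng.standard_normal()
        xb = eta[env_of_row]

        # line effects g
        r1 = np.bincount(z1_rows, weights=y_cur - xb - gE[z2_rows], minlength=J) / v_e
        if spectral:
            lam = 1.0 / (v_g * s) + cache.c1 / v_e
            t = U.T @ r1
            g = U @ (t / lam + rng.standard_normal(J) / np.sqrt(lam))
        else:
            prec = Ginv / v_g + np.diag(design.Z1.sum(axis=0)) / v_e
            g = _sample_prec(prec, r1, rng)

        # interaction effects gE (independent G-blocks per environment)
        r2 = np.bincount(z2_rows, weights=y_cur - xb - g[z1_rows], minlength=I * J) / v_e
        if spectral:
            lam = 1.0 / (v_gE * s) + cache.c2 / v_e       # shared across blocks
            R2 = r2.reshape(I, J).T                        # J x I
            T = U.T @ R2
            draw = U @ (T / lam[:, None] + rng.standard_normal((J, I)) / np.sqrt(lam)[:, None])
            gE = draw.T.reshape(-1)
        else:
            for i in range(I):
                idx = slice(i * J, (i + 1) * J)
                cnt = design.Z2.sum(axis=0)[idx]
                prec = Ginv / v_gE + np.diag(cnt) / v_e
                gE[idx] = _sample_prec(prec, r2[idx], rng)

        # recentering moves: the likelihood is flat along eta + c / g - c (and
        # the per-environment analogue with gE); with a strong common kinship
        # component these ridges mix slowly, so draw the shift exactly from
        # its conditional (the flat eta prior leaves only the g / gE terms)
        shift = rng.normal(Ginv_one @ g / a1, np.sqrt(v_g / a1))
        eta += shift
        g -= shift
        for i in range(I):
            blk = slice(i * J, (i + 1) * J)
            shift_i = rng.normal(Ginv_one @ gE[blk] / a1, np.sqrt(v_gE / a1))
            eta[i] += shift_i
            gE[blk] -= shift_i
        xb = eta[env_of_row]

        # variances: scaled-inv-chi-square conjugate updates
        if fixed_variances is None:
            tg = U.T @ g
            ss_g = float(np.sum(tg * tg / s))
            GEm = gE.reshape(I, J).T
            TT = U.T @ GEm
            ss_gE = float(np.sum(TT * TT / s[:, None]))
            e_vec = y_cur - xb - g[z1_rows] - gE[z2_rows]
            ss_e = float(e_vec @ e_vec)
            v_g = (prior.df * prior.S_g + ss_g) / rng.chisquare(prior.df + J)
            v_gE = (prior.df * prior.S_gE + ss_gE) / rng.chisquare(prior.df + I * J)
            v_e = (prior.df * prior.S_e + ss_e) / rng.chisquare(prior.df + n)

        # impute missing responses from the predictive distribution
        fit = xb + g[z1_rows] + gE[z2_rows]
        if miss.any():
            y_cur[miss] = fit[miss] + np.sqrt(v_e) * rng.standard_normal(int(miss.sum()))

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            env_draws[kept] = eta
            vg_draws[kept] = v_g
            vgE_draws[kept] = v_gE
            ve_draws[kept] = v_e
            sum_g += g
            sum_gE += gE
            sum_fit += fit
            kept += 1

    return UnivariatePosterior(
        env_draws=env_draws[:kept], var_g_draws=vg_draws[:kept],
        var_gE_draws=vgE_draws[:kept], var_e_draws=ve_draws[:kept],
        mean_env=env_draws[:kept].mean(axis=0), mean_g=sum_g / kept,
        mean_gE=sum_gE / kept, fitted=sum_fit / kept)
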