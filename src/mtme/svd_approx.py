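"""Four-step SVD approximation to the multi-trait multi-environment model.

Instead of sampling the trait dimension jointly, the method

1. decorrelates the trait responses with a thin SVD, ``Y = U D V'``, taking
   ``Y* = Y V`` as new responses (columns of ``Y*`` are orthogonal);
2. fits the single-trait two-kernel model (:mod:`mtme.univariate`) to each
   column of ``Y*`` independently — L cheap univariate analyses;
3. collects the posterior means ``beta*``, ``b1*``, ``b2*`` and the three
   variance components per transformed trait into diagonal matrices
   ``D_t1``, ``D_t2``, ``D_te``;
4. maps everything back with ``V'``:  ``beta_hat = beta* V'``,
   ``Y_hat = (X beta* + Z1 b1* + Z2 b2*) V'``,
   ``Sigma_hat = V diag(D_*) V'``.

The method implicitly assumes an identity covariance between environments
and restricts the trait covariances to share V as their eigenvectors — an
approximation, not a reparametrization.  For cross-validation the SVD is
computed on the TRAINING rows only; held-out rows enter the univariate fits
as missing values and are imputed by augmentation, then scored on the
original trait scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import ChainConfig, DesignSet, MTMEDataset
from .kernels import Kinship
from .univariate import (UnivariatePosterior, eigen_precompute,
                         fit_univariate)

logger = logging.getLogger(__name__)

__all__ = ["SVDTransform", "ApproxEstimates", "svd_decorrelate",
           "fit_bmtme_approx", "fit_bmtme_approx_cv"]


@dataclass
class SVDTransform:
    """Thin SVD of the response matrix with a fixed sign convention."""

    U: np.ndarray  # n x L
    D: np.ndarray  # length L, descending, nonnegative
    V: np.ndarray  # L x L orthogonal


@dataclass
class ApproxEstimates:
    """Transformed-scale estimates and their back-transformed counterparts."""

    beta_star: np.ndarray     # I x L
    b1_star: np.ndarray       # J x L
    b2_star: np.ndarray       # IJ x L
    D_t1: np.ndarray          # length L: per-trait genomic variances
    D_t2: np.ndarray          # length L: per-trait G x E variances
    D_te: np.ndarray          # length L: per-trait residual variances
    V: np.ndarray             # L x L
    beta_hat: np.ndarray      # I x L
    b1_hat: np.ndarray        # J x L
    b2_hat: np.ndarray        # IJ x L
    Y_hat: np.ndarray         # n x L on the original trait scale
    Sigma_t1_hat: np.ndarray  # V diag(D_t1) V'
    Sigma_t2_hat: np.ndarray  # V diag(D_t2) V'
    Sigma_te_hat: np.ndarray  # V diag(D_te) V'


def svd_decorrelate(Y: np.ndarray) -> tuple[SVDTransform, np.ndarray]:
    """Thin SVD of a complete n x L response matrix; returns (transform, Y V).

    Sign convention: the largest-magnitude entry of each right singular
    vector is forced positive.  Columns of the returned ``Y*`` are mutually
    orthogonal with squared norms ``D**2``.
    """
    Y = np.asarray(Y, dtype=float)
    n, L = Y.shape
    if n < L:
        raise ValueError("need at least as many rows as traits for the thin SVD")
    if np.isnan(Y).any():
        raise ValueError("missing entries: use the cross-validation variant")
    U, D, Vt = np.linalg.svd(Y, full_matrices=False)
    V = Vt.T
    for k in range(L):
        if V[np.abs(V[:, k]).argmax(), k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    return SVDTransform(U=U, D=D, V=V), Y @ V


def _collect(dataset: MTMEDataset, design: DesignSet, V: np.ndarray,
             fits: list[UnivariatePosterior],
             variance_summary: str) -> ApproxEstimates:
    I, J, L = dataset.n_env, dataset.n_lines, dataset.n_traits
    beta_star = np.column_stack([f.mean_env for f in fits])
    b1_star = np.column_stack([f.mean_g for f in fits])
    b2_star = np.column_stack([f.mean_gE for f in fits])
    vg, vgE, ve = zip(*[f.var_summary(variance_summary) for f in fits])
    D_t1, D_t2, D_te = np.array(vg), np.array(vgE), np.array(ve)
    Ystar_hat = np.column_stack([f.fitted for f in fits])
    Vt = V.T
    return ApproxEstimates(
        beta_star=beta_star, b1_star=b1_star, b2_star=b2_star,
        D_t1=D_t1, D_t2=D_t2, D_te=D_te, V=V,
        beta_hat=beta_star @ Vt, b1_hat=b1_star @ Vt, b2_hat=b2_star @ Vt,
        Y_hat=Ystar_hat @ Vt,
        Sigma_t1_hat=V @ np.diag(D_t1) @ Vt,
        Sigma_t2_hat=V @ np.diag(D_t2) @ Vt,
        Sigma_te_hat=V @ np.diag(D_te) @ Vt)


def _trait_seeds(seed: int, L: int) -> list[int]:
    """Deterministic per-trait sub-seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(L)]


def fit_bmtme_approx(dataset: MTMEDataset, design: DesignSet,
                     G: Kinship | np.ndarray, chain: ChainConfig,
                     variance_summary: str = "mean",
                     transform: SVDTransform | None = None) -> tuple[ApproxEstimates, list[UnivariatePosterior]]:
    """Whole-data fit: SVD-decorrelate, L univariate fits, collect, back-transform.

    ``transform`` may inject a precomputed transform (e.g. identity V for
    validation); by default the SVD of ``dataset.Y`` is used.  Per-trait
    chains get deterministic sub-seeds of ``chain.seed``, so serial and
    parallel execution agree.
    """
    if transform is None:
        transform, Ystar = svd_decorrelate(dataset.Y)
    else:
        Ystar = dataset.Y @ transform.V
    cache = eigen_precompute(G, design)
    seeds = _trait_seeds(chain.seed, dataset.n_traits)
    fits = []
    for l in range(dataset.n_traits):
        sub = ChainConfig(n_iter=chain.n_iter, burn_in=chain.burn_in,
                          thin=chain.thin, seed=seeds[l])
        try:
            fits.append(fit_univariate(Ystar[:, l], design, G, sub, cache=cache))
        except Exception as err:
            raise RuntimeError(f"univariate fit failed for transformed trait {l}") from err
    return _collect(dataset, design, transform.V, fits, variance_summary), fits


def fit_bmtme_approx_cv(dataset: MTMEDataset, design: DesignSet,
                        G: Kinship | np.ndarray, chain: ChainConfig,
                        test_rows: np.ndarray,
                        variance_summary: str = "mean") -> ApproxEstimates:
    """Cross-validation variant: training-rows-only SVD, missing-value fits.

    ``test_rows`` is a boolean mask over dataset rows; the SVD (hence V) is
    computed from the training rows alone, the held-out rows are entered as
    missing responses for every transformed trait, imputed by augmentation
    during each univariate fit, and predictions are returned on the original
    trait scale in ``Y_hat``.
    """
    test_rows = np.asarray(test_rows, dtype=bool)
    if test_rows.shape != (dataset.n_rows,):
        raise ValueError("test_rows must be a boolean mask over dataset rows")
    train = ~test_rows
    line_of_row = np.array([dataset.line_ids.index(l) for _, l in dataset.row_index])
    uncovered = set(range(dataset.n_lines)) - set(line_of_row[train])
    if uncovered:
        logger.warning("lines with no training environment are excluded from "
                       "prediction: %s", sorted(uncovered)[:10])
    if not test_rows.any():
        est, _ = fit_bmtme_approx(dataset, design, G, chain,
                                  variance_summary=variance_summary)
        return est
    transform, Ystar_train = svd_decorrelate(dataset.Y[train])
    Ystar = np.full_like(dataset.Y, np.nan)
    Ystar[train] = Ystar_train

    cache = eigen_precompute(G, design)
    seeds = _trait_seeds(chain.seed, dataset.n_traits)
    fits = []
    for l in range(dataset.n_traits):
        sub = ChainConfig(n_iter=chain.n_iter, burn_in=chain.burn_in,
                          thin=chain.thin, seed=seeds[l])
        fits.append(fit_univariate(Ystar[:, l], design, G, sub, cache=cache))
    return _collect(dataset, design, transform.V, fits, variance_summary)
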