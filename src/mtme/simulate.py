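"""Synthetic multi-trait multi-environment data from the BMTME generative model.

Data are drawn from

    Y = X beta + Z1 b1 + Z2 b2 + e,
    b1 ~ MN(0, G, Sigma_t),  b2 ~ MN(0, Sigma_E kron G, Sigma_t),
    rows of e iid N(0, R_e),

with every covariance assembled from a correlation matrix and a variance
vector as ``Sigma[a,b] = sqrt(v[a]) * R[a,b] * sqrt(v[b])``.

Two reference designs are built in:

* ``dataset1_config()`` — 3 environments x 200 lines x 3 traits (600 rows),
  compound-symmetry kinship ``0.3 I + 0.7 J``, exchangeable 0.25 correlation
  among traits and among environments.
* ``dataset2_config()`` — 3 environments x 200 lines x 7 traits (600 rows),
  independent environments and very high (0.73--0.97) trait correlations.

Both are exactly reproducible from a seed: the generator draws b1, then b2,
then e, in that fixed order, from a single seeded stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import MTMEDataset, MTMEState, build_design
from .kernels import Kinship, compound_symmetry_grm

__all__ = [
    "SimConfig",
    "build_covariance",
    "matrix_normal_draw",
    "simulate_dataset",
    "dataset1_config",
    "dataset2_config",
]


def _check_correlation(R: np.ndarray, name: str) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError(f"{name} must have unit diagonal")
    if np.linalg.eigvalsh(R).min() <= 0:
        raise ValueError(f"{name} must be positive definite")
    return R


@dataclass
class SimConfig:
    """Generating parameters for one synthetic MTME data set.

    ``v_t``, ``v_E``, ``v_e`` are VARIANCE vectors (the diagonals of the
    corresponding covariance matrices); correlations and variances are
    combined by :func:`build_covariance`.
    """

    I: int
    J: int
    L: int
    beta_true: np.ndarray            # I x L
    R_t: np.ndarray                  # L x L correlation
    R_E: np.ndarray                  # I x I correlation
    R_e_corr: np.ndarray             # L x L correlation
    v_t: np.ndarray                  # length L variances
    v_E: np.ndarray                  # length I variances
    v_e: np.ndarray                  # length L variances
    grm: Kinship | None = None       # defaults to compound symmetry 0.3 I + 0.7 J
    reps: int = 1
    seed: int = 0

    def __post_init__(self):
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.beta_true.shape != (self.I, self.L):
            raise ValueError("beta_true must be I x L")
        self.R_t = _check_correlation(self.R_t, "R_t")
        self.R_E = _check_correlation(self.R_E, "R_E")
        self.R_e_corr = _check_correlation(self.R_e_corr, "R_e_corr")
        for v, dim, name in ((self.v_t, self.L, "v_t"), (self.v_E, self.I, "v_E"),
                             (self.v_e, self.L, "v_e")):
            v = np.asarray(v, dtype=float)
            if v.shape != (dim,) or (v <= 0).any():
                raise ValueError(f"{name} must be {dim} positive variances")
        self.v_t = np.asarray(self.v_t, dtype=float)
        self.v_E = np.asarray(self.v_E, dtype=float)
        self.v_e = np.asarray(self.v_e, dtype=float)
        if self.reps != 1:
            raise ValueError("only one replicate per (environment, line) cell is supported")

    @property
    def Sigma_t(self) -> np.ndarray:
        return build_covariance(self.R_t, self.v_t)

    @property
    def Sigma_E(self) -> np.ndarray:
        return build_covariance(self.R_E, self.v_E)

    @property
    def R_e(self) -> np.ndarray:
        return build_covariance(self.R_e_corr, self.v_e)

    def kinship(self) -> Kinship:
        if self.grm is not None:
            return self.grm
        return compound_symmetry_grm(self.J, 0.3, 0.7,
                                     line_ids=[f"L{j + 1:03d}" for j in range(self.J)])


def build_covariance(R: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Covariance from a correlation matrix and a variance vector.

    ``Sigma = D^{1/2} R D^{1/2}`` with ``D = diag(v)``, i.e.
    ``Sigma[a,b] = sqrt(v[a]) * R[a,b] * sqrt(v[b])``; exactly symmetric.
    """
    R = np.asarray(R, dtype=float)
    v = np.asarray(v, dtype=float)
    if R.shape != (v.size, v.size):
        raise ValueError("dimension mismatch between R and v")
    if (v <= 0).any():
        raise ValueError("variances must be positive")
    s = np.sqrt(v)
    Sigma = s[:, None] * R * s[None, :]
    Sigma = (Sigma + Sigma.T) / 2.0
    if np.linalg.eigvalsh(Sigma).min() <= 0:
        raise ValueError("resulting covariance is not positive definite")
    return Sigma


def matrix_normal_draw(M: np.ndarray, Omega: np.ndarray, Sigma: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """One draw from MN(M, Omega, Sigma): ``M + A E B^T`` with ``A A^T = Omega``,
    ``B B^T = Sigma`` and E iid standard normal."""
    M = np.asarray(M, dtype=float)
    p, q = M.shape
    if Omega.shape != (p, p) or Sigma.shape != (q, q):
        raise ValueError("shape mismatch between mean and covariance factors")
    A = np.linalg.cholesky(Omega)
    B = np.linalg.cholesky(Sigma)
    E = rng.standard_normal((p, q))
    return M + A @ E @ B.T


def simulate_dataset(cfg: SimConfig) -> tuple[MTMEDataset, MTMEState]:
    """Draw one data set from the generative model; returns (data, ground truth).

    Draw order is fixed (b1, b2, e) so a given (config, seed) always produces
    bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    I, J, L = cfg.I, cfg.J, cfg.L
    kin = cfg.kinship()
    G = kin.G
    Sigma_t, Sigma_E, R_e = cfg.Sigma_t, cfg.Sigma_E, cfg.R_e

    b1 = matrix_normal_draw(np.zeros((J, L)), G, Sigma_t, rng)
    b2 = matrix_normal_draw(np.zeros((I * J, L)), np.kron(Sigma_E, G), Sigma_t, rng)
    e = matrix_normal_draw(np.zeros((I * J, L)), np.eye(I * J), R_e, rng)

    env_ids = [f"Env{i + 1}" for i in range(I)]
    line_ids = list(kin.line_ids)
    # rows environment-major: row (i-1)*J + j is (env i, line j), one rep per cell
    row_index = [(env_ids[i], line_ids[j]) for i in range(I) for j in range(J)]
    dataset = MTMEDataset(env_ids, line_ids, np.zeros((I * J, L)),
                          [f"Trait{l + 1}" for l in range(L)], row_index)
    design = build_design(dataset)
    Y = design.X @ cfg.beta_true + design.Z1 @ b1 + design.Z2 @ b2 + e
    dataset.Y = Y
    truth = MTMEState(beta=cfg.beta_true.copy(), b1=b1, b2=b2,
                      Sigma_t=Sigma_t, Sigma_E=Sigma_E, R_e=R_e)
    return dataset, truth


def _exchangeable(dim: int, off: float) -> np.ndarray:
    R = np.full((dim, dim), off)
    np.fill_diagonal(R, 1.0)
    return R


def dataset1_config(seed: int = 0) -> SimConfig:
    """Reference design 1: I=3 environments, J=200 lines, L=3 traits.

    beta arranged environments x traits as [[13,12,11],[10,8,9],[5,7,6]];
    all three correlation matrices exchangeable 0.75 I + 0.25 J; trait genetic
    variances (0.9, 0.8, 0.9), environment variances (0.5, 0.65, 0.75),
    residual variances (0.6, 0.42, 0.33); kinship 0.3 I_200 + 0.7 J_200.
    600 rows x 3 traits = 1800 scalar observations.
    """
    R3 = _exchangeable(3, 0.25)
    return SimConfig(
        I=3, J=200, L=3,
        beta_true=np.array([[13.0, 12.0, 11.0],
                            [10.0, 8.0, 9.0],
                            [5.0, 7.0, 6.0]]),
        R_t=R3, R_E=R3, R_e_corr=R3,
        v_t=np.array([0.9, 0.8, 0.9]),
        v_E=np.array([0.5, 0.65, 0.75]),
        v_e=np.array([0.6, 0.42, 0.33]),
        seed=seed,
    )


# 7x7 trait correlation of reference design 2 (upper triangle, symmetrized)
_D2_CORR = np.array([
    [1.000, 0.970, 0.944, 0.917, 0.890, 0.862, 0.833],
    [0.970, 1.000, 0.925, 0.899, 0.872, 0.844, 0.816],
    [0.944, 0.925, 1.000, 0.875, 0.849, 0.822, 0.794],
    [0.917, 0.899, 0.875, 1.000, 0.825, 0.798, 0.772],
    [0.890, 0.872, 0.849, 0.825, 1.000, 0.775, 0.748],
    [0.862, 0.844, 0.822, 0.798, 0.775, 1.000, 0.725],
    [0.833, 0.816, 0.794, 0.772, 0.748, 0.725, 1.000],
])


def dataset2_config(seed: int = 0) -> SimConfig:
    """Reference design 2: I=3 environments, J=200 lines, L=7 highly correlated traits.

    beta assigned row-wise (the first seven values are traits 1-7 in
    environment 1); environments independent (R_E = I, unit variances); the
    7x7 trait correlation has first row (1, .970, .944, .917, .890, .862,
    .833) and is shared by the genetic and residual covariances.
    600 rows x 7 traits = 4200 scalar observations.
    """
    beta = np.array([
        [13.0, 12.5, 12.0, 11.5, 11.0, 10.5, 10.0],
        [12.0, 11.5, 11.0, 10.5, 10.5, 10.0, 10.0],
        [11.0, 11.5, 12.0, 12.0, 11.0, 10.0, 10.5],
    ])
    v_f = np.array([1.0, 1.0003, 1.0003, 1.0, 0.9996, 1.0, 1.0003])
    return SimConfig(
        I=3, J=200, L=7,
        beta_true=beta,
        R_t=_D2_CORR.copy(), R_E=np.eye(3), R_e_corr=_D2_CORR.copy(),
        v_t=v_f.copy(), v_E=np.ones(3), v_e=v_f.copy(),
        seed=seed,
    )
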