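"""Core containers and linear-algebra conventions for multi-trait multi-environment data.

The central object is an :class:`MTMEDataset`: an ``n x L`` phenotype matrix ``Y``
whose rows are (environment, line) cells of a trial network, together with the
incidence (design) matrices of the mixed model

    Y = X beta + Z1 b1 + Z2 b2 + e

where ``X`` (n x I) maps rows to environments, ``Z1`` (n x J) maps rows to lines
and ``Z2`` (n x I*J) maps rows to environment-line combinations.  Every module in
the package relies on two conventions fixed here:

* ``vec`` is COLUMN stacking, so a matrix-variate normal MN(H, Omega, Sigma)
  (row covariance Omega, column covariance Sigma) has
  ``cov(vec(M)) = Sigma (kron) Omega``.
* ``Z2`` columns are ENVIRONMENT-MAJOR: column ``(i-1)*J + j`` is environment
  ``i``, line ``j``.  Under this ordering the stacked interaction effect ``b2``
  has ``cov(vec(b2)) = Sigma_t (kron) (Sigma_E (kron) G)`` literally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MTMEDataset",
    "DesignSet",
    "MTMEState",
    "Hyperparams",
    "ChainConfig",
    "build_design",
    "vec_colstack",
    "unvec_colstack",
]


@dataclass
class MTMEDataset:
    """Aligned phenotype matrix with its environment/line row index.

    Parameters
    ----------
    env_ids : ordered environment labels (length I)
    line_ids : ordered line labels (length J)
    Y : (n, L) float array; np.nan marks a missing trait value
    trait_names : trait labels (length L)
    row_index : length-n sequence of (env_label, line_label) pairs, one per row
    """

    env_ids: list
    line_ids: list
    Y: np.ndarray
    trait_names: list
    row_index: list

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be 2-dimensional (rows x traits)")
        n, L = self.Y.shape
        if L < 1:
            raise ValueError("at least one trait is required")
        if len(self.trait_names) != L:
            raise ValueError("trait_names length does not match Y columns")
        if len(self.row_index) != n:
            raise ValueError("row_index length does not match Y rows")
        env_set, line_set = set(self.env_ids), set(self.line_ids)
        seen = set()
        for env, line in self.row_index:
            if env not in env_set:
                raise ValueError(f"row references unknown environment {env!r}")
            if line not in line_set:
                raise ValueError(f"row references unknown line {line!r}")
            if (env, line) in seen:
                raise ValueError(f"duplicate (environment, line) pair ({env!r}, {line!r})")
            seen.add((env, line))

    @property
    def n_env(self) -> int:
        return len(self.env_ids)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_traits(self) -> int:
        return self.Y.shape[1]

    @property
    def n_rows(self) -> int:
        return self.Y.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean mask of missing trait values."""
        return np.isnan(self.Y)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, env_order: Sequence | None = None,
                   line_order: Sequence | None = None) -> "MTMEDataset":
        """Build from a long table with columns ``line``, ``env`` then one column per trait.

        Environments and lines are ordered lexicographically by label unless an
        explicit order is supplied, so runs are reproducible.
        """
        if "line" not in df.columns or "env" not in df.columns:
            raise ValueError("phenotype table must have 'line' and 'env' columns")
        traits = [c for c in df.columns if c not in ("line", "env")]
        if not traits:
            raise ValueError("phenotype table has no trait columns")
        env_ids = list(env_order) if env_order is not None else sorted(df["env"].unique())
        line_ids = list(line_order) if line_order is not None else sorted(df["line"].unique())
        Y = df[traits].to_numpy(dtype=float)
        row_index = list(zip(df["env"].tolist(), df["line"].tolist()))
        return cls(env_ids, line_ids, Y, traits, row_index)

    def to_frame(self) -> pd.DataFrame:
        envs = [e for e, _ in self.row_index]
        lines = [l for _, l in self.row_index]
        out = pd.DataFrame({"line": lines, "env": envs})
        for k, t in enumerate(self.trait_names):
            out[t] = self.Y[:, k]
        return out


@dataclass
class DesignSet:
    """Incidence matrices of the MTME mixed model (one 1 per row)."""

    X: np.ndarray   # n x I
    Z1: np.ndarray  # n x J
    Z2: np.ndarray  # n x I*J, environment-major columns

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class MTMEState:
    """One draw (or the truth) of all BMTME parameters."""

    beta: np.ndarray      # I x L
    b1: np.ndarray        # J x L
    b2: np.ndarray        # (I*J) x L
    Sigma_t: np.ndarray   # L x L
    Sigma_E: np.ndarray   # I x I
    R_e: np.ndarray       # L x L


@dataclass
class Hyperparams:
    """Inverse-Wishart / matrix-normal prior settings for the BMTME sampler.

    ``nu_*`` are IW degrees of freedom (proper only when nu > dim + 1);
    ``S_*`` the IW scale matrices; ``beta0``/``S_beta_t`` the matrix-normal
    prior mean and column covariance of the environment fixed effects.
    """

    nu_t: float
    nu_E: float
    nu_e: float
    S_t: np.ndarray
    S_E: np.ndarray
    S_e: np.ndarray
    beta0: np.ndarray
    S_beta_t: np.ndarray

    def validate(self, I: int, L: int) -> None:
        if not self.nu_t > L + 1:
            raise ValueError(
                f"nu_t={self.nu_t} is improper for L={L} traits (need nu_t > L+1); "
                f"pass nu_t explicitly, e.g. nu_t={L + 3}")
        if not self.nu_e > L + 1:
            raise ValueError(
                f"nu_e={self.nu_e} is improper for L={L} traits (need nu_e > L+1); "
                f"pass nu_e explicitly, e.g. nu_e={L + 3}")
        if not self.nu_E > I + 1:
            raise ValueError(
                f"nu_E={self.nu_E} is improper for I={I} environments (need nu_E > I+1); "
                f"pass nu_E explicitly, e.g. nu_E={I + 3}")


@dataclass
class ChainConfig:
    """MCMC run length settings."""

    n_iter: int = 60000
    burn_in: int = 20000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def build_design(dataset: MTMEDataset) -> DesignSet:
    """Construct X, Z1, Z2 incidence matrices for a dataset.

    Z2 column ``(i-1)*J + j`` corresponds to environment ``i`` and line ``j``
    (environment-major), matching the ``Sigma_E (kron) G`` row-block structure
    of the interaction covariance.
    """
    I, J, n = dataset.n_env, dataset.n_lines, dataset.n_rows
    env_pos = {e: i for i, e in enumerate(dataset.env_ids)}
    line_pos = {l: j for j, l in enumerate(dataset.line_ids)}
    X = np.zeros((n, I))
    Z1 = np.zeros((n, J))
    Z2 = np.zeros((n, I * J))
    for r, (env, line) in enumerate(dataset.row_index):
        i, j = env_pos[env], line_pos[line]
        X[r, i] = 1.0
        Z1[r, j] = 1.0
        Z2[r, i * J + j] = 1.0
    return DesignSet(X=X, Z1=Z1, Z2=Z2)


def vec_colstack(M: np.ndarray) -> np.ndarray:
    """Column-stacking vec operator: stacks columns of M left to right."""
    M = np.asarray(M)
    return M.reshape(-1, order="F").copy()


def unvec_colstack(v: np.ndarray, p: int, q: int) -> np.ndarray:
    """Inverse of :func:`vec_colstack` for a p x q matrix."""
    v = np.asarray(v)
    if v.size != p * q:
        raise ValueError(f"cannot unvec length-{v.size} vector into {p}x{q}")
    return v.reshape((p, q), order="F").copy()
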