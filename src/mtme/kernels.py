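"""Genomic relationship matrices (GRM) and positive-definite conditioning.

Two kernels are provided: the VanRaden marker-based GRM ``G = Z Z^T / p``
(with optional column centering of the marker matrix) and the
compound-symmetry kernel ``a*I + b*J`` used to emulate a panel of highly
related lines in simulation studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["Kinship", "vanraden_grm", "compound_symmetry_grm", "condition_spd"]


@dataclass
class Kinship:
    """A J x J symmetric line-relationship matrix with its labels."""

    G: np.ndarray
    line_ids: list
    jitter_used: float = 0.0

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        J = self.G.shape[0]
        if self.G.shape != (J, J):
            raise ValueError("kinship matrix must be square")
        if len(self.line_ids) != J:
            raise ValueError("line_ids length does not match kinship order")
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n_lines(self) -> int:
        return self.G.shape[0]

    def reorder(self, line_ids: list) -> "Kinship":
        """Return a copy aligned to the given label order (label-based join)."""
        pos = {l: i for i, l in enumerate(self.line_ids)}
        missing = [l for l in line_ids if l not in pos]
        if missing:
            raise ValueError(f"kinship is missing lines: {missing[:10]}")
        idx = np.array([pos[l] for l in line_ids])
        return Kinship(self.G[np.ix_(idx, idx)], list(line_ids), self.jitter_used)


def vanraden_grm(markers: np.ndarray, line_ids=None, center: bool = True) -> Kinship:
    """VanRaden-style GRM from a J x p numeric marker matrix: ``G = Z Z^T / p``.

    Markers are column-centered by default (standard practice); pass
    ``center=False`` for the literal uncentered product.  Constant marker
    columns carry no relationship information and are dropped with a logged
    count (before centering they would only shift the matrix).
    """
    Z = np.asarray(markers, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 1:
        raise ValueError("marker matrix must be J x p with p >= 1")
    if np.isnan(Z).any():
        raise ValueError("marker matrix contains missing values; impute upstream")
    J = Z.shape[0]
    keep = Z.std(axis=0) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("vanraden_grm: dropped %d constant marker column(s)", n_dropped)
        Z = Z[:, keep]
    if Z.shape[1] == 0:
        raise ValueError("no polymorphic markers left after dropping constant columns")
    if center:
        Z = Z - Z.mean(axis=0)
    p = Z.shape[1]
    G = Z @ Z.T / p
    G = (G + G.T) / 2.0
    if line_ids is None:
        line_ids = list(range(J))
    return Kinship(G, list(line_ids))


def compound_symmetry_grm(J: int, diag_extra: float, common: float,
                          line_ids=None) -> Kinship:
    """Compound-symmetry kernel ``diag_extra * I_J + common * J_J``.

    Eigenvalues are ``diag_extra`` (multiplicity J-1) and
    ``diag_extra + J*common``; both must be positive.
    """
    if common < 0 or diag_extra + common <= 0:
        raise ValueError("need common >= 0 and diag_extra + common > 0")
    if diag_extra <= 0 or diag_extra + J * common <= 0:
        raise ValueError("parameter combination is not positive definite")
    G = np.full((J, J), float(common))
    np.fill_diagonal(G, diag_extra + common)
    if line_ids is None:
        line_ids = list(range(J))
    return Kinship(G, list(line_ids))


def condition_spd(M: np.ndarray, tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Smallest power-of-ten ridge making a symmetric matrix Cholesky-factorizable.

    Starts at ``1e-10 * mean(diag)`` (floored at ``tol``) and multiplies by 10
    until the Cholesky succeeds; deterministic.  Returns ``(conditioned, eps)``
    with ``eps == 0`` when no ridge was needed.
    """
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("condition_spd expects a symmetric matrix")
    M = (M + M.T) / 2.0
    try:
        np.linalg.cholesky(M)
        return M, 0.0
    except np.linalg.LinAlgError:
        pass
    base = abs(np.mean(np.diag(M)))
    if base == 0:
        base = 1.0
    eps = max(1e-10 * base, tol)
    # round eps down to a power of ten for a reproducible, loggable ridge
    eps = 10.0 ** np.floor(np.log10(eps))
    I = np.eye(M.shape[0])
    for _ in range(40):
        try:
            np.linalg.cholesky(M + eps * I)
            logger.info("condition_spd: applied ridge eps=%.1e", eps)
            return M + eps * I, eps
        except np.linalg.LinAlgError:
            eps *= 10.0
    raise np.linalg.LinAlgError("could not condition matrix to SPD")  # pragma: no cover
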