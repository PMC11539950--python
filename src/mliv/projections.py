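"""Least-squares core: orthogonal projectors, OLS, and the ellipsoidal
quadratic form of the validity constraint.

Everything downstream (both estimators and every feasibility theorem)
reduces to projections onto design-matrix column spaces.  Normal
equations are never solved by explicit inversion: a thin QR/SVD of the
design is used, with rank decided at 1e-10 of the largest singular
value, because the polynomial designs used in the simulation studies
(z, z^2, z^3 columns) are noticeably correlated.

The projector is represented by its orthonormal basis Q (n x k); the
dense n x n matrix is materialized lazily and only for n <= 5000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import MulticollinearityError

__all__ = ["HatMatrix", "hat_matrix", "ols_fit", "constraint_quadratic", "OLSFit"]

_RANK_RTOL = 1e-10
_DENSE_MAX_N = 5000


@dataclass(frozen=True)
class HatMatrix:
    """Orthogonal projector onto the column space of a design matrix."""

    Q: np.ndarray  # n x k orthonormal basis
    source_rank: int

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    def apply(self, v: np.ndarray) -> np.ndarray:
        """H v without forming H."""
        v = np.asarray(v, dtype=float)
        return self.Q @ (self.Q.T @ v)

    def quad(self, v: np.ndarray) -> float:
        """v^T H v = ||Q^T v||^2."""
        w = self.Q.T @ np.asarray(v, dtype=float).ravel()
        return float(w @ w)

    @property
    def H(self) -> np.ndarray:
        """Dense projector; refuses above n=5000 (use .apply instead)."""
        if self.n > _DENSE_MAX_N:
            raise ValueError(
                f"refusing to materialize a {self.n}x{self.n} hat matrix; "
                "use .apply/.quad"
            )
        return self.Q @ self.Q.T

    @property
    def trace(self) -> float:
        return float(self.source_rank)


def _orth_basis(Xd: np.ndarray) -> np.ndarray:
    """Orthonormal basis of col(Xd); raises if Xd is rank deficient."""
    Xd = np.atleast_2d(np.asarray(Xd, dtype=float))
    if Xd.shape[0] == 1 and Xd.shape[1] > 1:
        Xd = Xd.T
    if Xd.shape[1] == 0:
        return np.empty((Xd.shape[0], 0))
    U, s, _ = np.linalg.svd(Xd, full_matrices=False)
    tol = _RANK_RTOL * s[0] if s.size else 0.0
    rank = int(np.sum(s > tol))
    if rank < Xd.shape[1]:
        raise MulticollinearityError(
            f"design matrix is rank deficient (rank {rank} < {Xd.shape[1]})"
        )
    return U[:, :rank]


def hat_matrix(Xd: np.ndarray) -> HatMatrix:
    """Projector H = Xd (Xd^T Xd)^-1 Xd^T, built from an orthonormal basis."""
    Q = _orth_basis(Xd)
    return HatMatrix(Q=Q, source_rank=Q.shape[1])


@dataclass(frozen=True)
class OLSFit:
    coefficients: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    sse: float


def ols_fit(Xd: np.ndarray, target: np.ndarray) -> OLSFit:
    """Ordinary least squares of ``target`` on ``Xd`` (full column rank)."""
    Xd = np.atleast_2d(np.asarray(Xd, dtype=float))
    if Xd.shape[0] == 1 and Xd.shape[1] > 1:
        Xd = Xd.T
    target = np.asarray(target, dtype=float).ravel()
    n, k = Xd.shape
    if n <= k:
        raise ValueError(f"need more rows than columns (n={n}, k={k})")
    _orth_basis(Xd)  # rank check with shared tolerance
    coef, *_ = np.linalg.lstsq(Xd, target, rcond=None)
    fitted = Xd @ coef
    resid = target - fitted
    return OLSFit(coefficients=coef, fitted=fitted, residuals=resid,
                  sse=float(resid @ resid))


def constraint_quadratic(
    beta: np.ndarray, X_y: np.ndarray, H: HatMatrix, y: np.ndarray
) -> float:
    """The ellipsoidal validity form b^T Xy^T H Xy b - 2 b^T Xy^T H y + y^T H y.

    Equals r^T H r with r = y - X_y beta, hence always >= 0: it is the
    squared norm of the remainder's projection onto the remainder-model
    feature space — exactly how much of the remainder the instrument
    (and covariates) can explain.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    X_y = np.atleast_2d(np.asarray(X_y, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X_y.shape[0] != y.shape[0] or X_y.shape[1] != beta.shape[0]:
        raise ValueError(
            f"shape mismatch: X_y {X_y.shape}, beta {beta.shape}, y {y.shape}"
        )
    r = y - X_y @ beta
    return H.quad(r)
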