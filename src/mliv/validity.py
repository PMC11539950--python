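"""The empirical validity check and its calibration.

An instrument is only credible if the second-stage remainder
r = y - y_hat cannot be predicted from the covariates and the proposed
instrument any better than the model that is identically zero, up to an
absolute tolerance eps':

    loss(r, r_hat) >= loss(r, 0) - eps'

with r_hat the least-squares fit of r on the remainder design X_r.
Because r_hat is a projection, loss(r, r_hat) <= loss(r, 0) always: the
check can only fail by predicting the remainder *too well*.

eps' is calibrated from a relative tolerance gamma in [0, 1):
eps' = gamma * loss(r_tilde, 0), where r_tilde is the remainder of the
traditional (unconstrained) two-stage fit.  gamma ~ 1 - ratio, where
ratio = loss(r, r_hat) / loss(r, 0) is the "true percentage" reported
by the misspecification studies.

A companion relevance check asks the symmetric question of stage one:
do the instruments actually help predict the treatment?
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .data import IVDataset
from .features import FeatureSpec, build_design_matrix, ValidityViolationError
from .projections import hat_matrix, ols_fit

__all__ = [
    "ValidityReport",
    "RelevanceResult",
    "fit_remainder",
    "epsilon_prime_from_gamma",
    "empirical_validity_check",
    "relevance_check",
]


@dataclass(frozen=True)
class ValidityReport:
    """Outcome of the empirical validity check on one remainder vector."""

    loss_r_zero: float
    loss_r_hat: float
    ratio: float          # loss(r, r_hat) / loss(r, 0), the "true percentage"
    gamma_true: float     # 1 - ratio
    epsilon_prime: float
    gamma: float
    passed: bool

    def to_json(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RelevanceResult:
    passed: bool
    loss_with: float
    loss_without: float
    epsilon: float


def fit_remainder(r: np.ndarray, X_r: np.ndarray):
    """Least-squares fit of the remainder on the remainder design.

    Returns (alpha, r_hat).  The remainder model class is exactly the
    span of the declared X_r columns — deliberately with no intercept,
    so the comparison against the zero model is between models built
    from the stated features only (a free constant would let the class
    dominate the zero model whenever the remainder has nonzero mean,
    blinding the check).
    """
    fit = ols_fit(X_r, r)
    return fit.coefficients, fit.fitted


def epsilon_prime_from_gamma(gamma: float, r_tilde: np.ndarray) -> float:
    """Absolute tolerance eps' = gamma * ||r_tilde||^2.

    ``r_tilde`` is the remainder of the traditional unconstrained
    two-stage fit; gamma is the relative tolerance.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be nonnegative, got {gamma}")
    r_tilde = np.asarray(r_tilde, dtype=float).ravel()
    return float(gamma * (r_tilde @ r_tilde))


def empirical_validity_check(
    r: np.ndarray,
    X_r: np.ndarray,
    epsilon_prime: float,
    gamma: float = float("nan"),
) -> ValidityReport:
    """Run the check: can X_r predict r better than the zero model, by
    more than epsilon_prime?

    The degenerate r = 0 (zero remainder, nothing left to predict)
    passes with ratio defined as 1.
    """
    r = np.asarray(r, dtype=float).ravel()
    loss_zero = float(r @ r)
    if loss_zero == 0.0:
        return ValidityReport(0.0, 0.0, 1.0, 0.0, float(epsilon_prime),
                              float(gamma), True)
    _, r_hat = fit_remainder(r, X_r)
    diff = r - r_hat
    loss_hat = float(diff @ diff)
    ratio = loss_hat / loss_zero
    return ValidityReport(
        loss_r_zero=loss_zero,
        loss_r_hat=loss_hat,
        ratio=ratio,
        gamma_true=1.0 - ratio,
        epsilon_prime=float(epsilon_prime),
        gamma=float(gamma),
        passed=bool(loss_hat >= loss_zero - epsilon_prime),
    )


def relevance_check(
    data: IVDataset,
    spec_with_z: FeatureSpec,
    spec_without_z: FeatureSpec,
    epsilon: float | None = None,
    epsilon_frac: float = 0.05,
) -> RelevanceResult:
    """Does the instrument actually help predict the treatment?

    Compares the stage-one loss using (X, Z) against the loss using X
    alone; passes when loss_with <= loss_without - epsilon.  By default
    epsilon is ``epsilon_frac`` (5%) of the covariates-only loss.
    """
    if spec_without_z.references_instrument():
        raise ValidityViolationError(
            "the baseline spec of the relevance check must not reference z"
        )
    Xw = build_design_matrix(data, spec_with_z, stage="one")
    Xo = build_design_matrix(data, spec_without_z, stage="one")
    loss_with = ols_fit(Xw, data.t).sse
    loss_without = ols_fit(Xo, data.t).sse if Xo.shape[1] else float(data.t @ data.t)
    if epsilon is None:
        epsilon = epsilon_frac * loss_without
    return RelevanceResult(
        passed=bool(loss_with <= loss_without - epsilon),
        loss_with=loss_with,
        loss_without=loss_without,
        epsilon=float(epsilon),
    )
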