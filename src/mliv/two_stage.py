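"""The constrained two-stage estimator.

Stage one is an ordinary least-squares fit of the treatment on
covariates and instruments.  Stage two minimizes the outcome loss
subject to the validity constraint

    min_beta ||y - X_y beta||^2   s.t.   r^T H r <= eps',   r = y - X_y beta

where H projects onto the remainder-model feature space.  The
constraint is ellipsoidal, so the problem is a convex QCQP with an
exact solution structure:

* if the unconstrained OLS solution already satisfies the constraint,
  it is optimal (status ``inactive``);
* otherwise, if even the constraint's own minimizer exceeds eps', no
  beta is feasible (status ``infeasible``) — the proposed instrument is
  flagged invalid;
* otherwise the optimum lies on the ellipsoid boundary (status
  ``active``) and is found by safeguarded root-finding on the secular
  equation of the Lagrange multiplier.

The taxonomy of which statuses are reachable under which model classes
(linear vs general additive, 1-D vs multi-D instrument) is exercised in
the experiments module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .data import IVDataset
from .features import FeatureSpec, build_design_matrix, _term_variables
from .projections import HatMatrix, hat_matrix, ols_fit
from .validity import (
    RelevanceResult,
    ValidityReport,
    empirical_validity_check,
    epsilon_prime_from_gamma,
    relevance_check,
)

__all__ = [
    "StageOneFit",
    "StageTwoResult",
    "TwoStageFit",
    "SolverFailureError",
    "fit_stage_one",
    "min_constraint_value",
    "constrained_stage_two",
    "traditional_two_stage",
    "fit_two_stage",
]

# feasibility slack and activity band; the theorems distinguish
# active/inactive exactly, floating point needs a tolerance band
_FEAS_RTOL = 1e-8
_FEAS_ATOL = 1e-12


class SolverFailureError(RuntimeError):
    """Multiplier search failed; never silently mis-reports a status."""


@dataclass(frozen=True)
class StageOneFit:
    omega: np.ndarray
    t_hat: np.ndarray
    relevance: RelevanceResult | None
    sse: float


@dataclass(frozen=True)
class StageTwoResult:
    beta: np.ndarray | None
    y_hat: np.ndarray | None
    r: np.ndarray | None
    status: str                    # inactive | active | infeasible
    objective_value: float | None  # ||y - X_y beta||^2
    constraint_value: float        # r^T H r at the solution (or its minimum)
    epsilon_prime: float


@dataclass(frozen=True)
class TwoStageFit:
    stage_one: StageOneFit
    stage_two: StageTwoResult
    validity: ValidityReport
    r_tilde: np.ndarray
    beta_traditional: np.ndarray


def _x_only_spec(spec: FeatureSpec) -> FeatureSpec:
    """Drop every term that touches an instrument column."""
    keep = [t for t in spec.terms
            if not any(v.startswith("z") for v in _term_variables(t))]
    return FeatureSpec(keep, include_intercept=spec.include_intercept)


def fit_stage_one(
    data: IVDataset,
    spec: FeatureSpec,
    epsilon: float | None = None,
    epsilon_frac: float = 0.05,
    check_relevance: bool = True,
) -> StageOneFit:
    """OLS fit of t on X_t with the relevance check attached.

    A failed relevance check is reported, never raised — a weak
    instrument is a finding, not an error.
    """
    X_t = build_design_matrix(data, spec, stage="one")
    fit = ols_fit(X_t, data.t)
    relevance = None
    if check_relevance:
        baseline = _x_only_spec(spec)
        if baseline.terms or baseline.include_intercept:
            relevance = relevance_check(data, spec, baseline,
                                        epsilon=epsilon, epsilon_frac=epsilon_frac)
        else:
            tss = float(data.t @ data.t)
            eps = epsilon if epsilon is not None else epsilon_frac * tss
            relevance = RelevanceResult(
                passed=bool(fit.sse <= tss - eps),
                loss_with=fit.sse, loss_without=tss, epsilon=float(eps),
            )
    return StageOneFit(omega=fit.coefficients, t_hat=fit.fitted,
                       relevance=relevance, sse=fit.sse)


def min_constraint_value(X_y: np.ndarray, H: HatMatrix, y: np.ndarray):
    """Minimize the constraint quadratic r^T H r over beta.

    Returns (beta_cmin, value).  In the reduced basis this is a plain
    least-squares problem ||Q^T y - Q^T X_y beta||^2; the pseudoinverse
    solution is taken when Q^T X_y is singular.
    """
    X_y = np.atleast_2d(np.asarray(X_y, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    C = H.Q.T @ X_y
    q = H.Q.T @ y
    beta, *_ = np.linalg.lstsq(C, q, rcond=None)
    resid = q - C @ beta
    return beta, float(resid @ resid)


def _solve_on_constraint_argmin(X_y, C, q, y, beta_star):
    """Minimize the objective over { beta : C beta = C beta_star }."""
    _, s, Vt = np.linalg.svd(C, full_matrices=True)
    tol = (s[0] * 1e-12) if s.size else 0.0
    rank = int(np.sum(s > tol))
    N = Vt[rank:].T  # nullspace basis of C
    if N.shape[1] == 0:
        return beta_star
    resid = y - X_y @ beta_star
    w, *_ = np.linalg.lstsq(X_y @ N, resid, rcond=None)
    return beta_star + N @ w


def constrained_stage_two(
    y: np.ndarray,
    X_y: np.ndarray,
    H_r: HatMatrix,
    epsilon_prime: float,
) -> StageTwoResult:
    """Solve the validity-constrained outcome regression (convex QCQP)."""
    if epsilon_prime < 0:
        raise ValueError(f"epsilon_prime must be >= 0, got {epsilon_prime}")
    y = np.asarray(y, dtype=float).ravel()
    X_y = np.atleast_2d(np.asarray(X_y, dtype=float))
    C = H_r.Q.T @ X_y
    q = H_r.Q.T @ y
    feas_band = epsilon_prime * (1 + _FEAS_RTOL) + _FEAS_ATOL

    def finish(beta, status, cv):
        fitted = X_y @ beta
        r = y - fitted
        return StageTwoResult(
            beta=beta, y_hat=fitted, r=r, status=status,
            objective_value=float(r @ r), constraint_value=float(cv),
            epsilon_prime=float(epsilon_prime),
        )

    # (1) unconstrained optimum
    fit = ols_fit(X_y, y)
    beta_hat = fit.coefficients
    w = q - C @ beta_hat
    cv_hat = float(w @ w)
    if not math.isfinite(epsilon_prime) or cv_hat <= feas_band:
        return finish(beta_hat, "inactive", cv_hat)

    # (2) constraint minimizer -> feasibility
    beta_cmin, v_min = min_constraint_value(X_y, H_r, y)
    if v_min > feas_band:
        return StageTwoResult(
            beta=None, y_hat=None, r=None, status="infeasible",
            objective_value=None, constraint_value=float(v_min),
            epsilon_prime=float(epsilon_prime),
        )

    # (3) active constraint: secular equation on the multiplier.
    A = X_y.T @ X_y
    a = X_y.T @ y
    B = C.T @ C
    c = C.T @ q

    def beta_of(lam: float) -> np.ndarray:
        return np.linalg.solve(A + lam * B, a + lam * c)

    def phi(lam: float) -> float:
        d = q - C @ beta_of(lam)
        return float(d @ d) - epsilon_prime

    lo, hi = 0.0, 1.0
    grew = 0
    while phi(hi) > 0 and grew < 60:
        lo, hi = hi, hi * 10.0
        grew += 1
    if phi(hi) > 0:
        # constraint value cannot be driven below eps' along the path:
        # eps' ~ v_min; minimize the objective on the constraint argmin set
        if v_min >= epsilon_prime * (1 - 1e-6) - _FEAS_ATOL:
            beta = _solve_on_constraint_argmin(X_y, C, q, y, beta_cmin)
            d = q - C @ beta
            return finish(beta, "active", float(d @ d))
        raise SolverFailureError(
            f"multiplier bracketing failed (phi({hi:g})={phi(hi):g}, "
            f"v_min={v_min:g}, eps'={epsilon_prime:g})"
        )
    lam = brentq(phi, lo, hi, xtol=1e-14, rtol=1e-13, maxiter=200)
    beta = beta_of(lam)
    d = q - C @ beta
    return finish(beta, "active", float(d @ d))


def traditional_two_stage(
    data: IVDataset,
    spec_one: FeatureSpec,
    spec_two: FeatureSpec,
):
    """Plain (unconstrained) two-stage least squares with GAM features.

    Returns (omega, beta, r_tilde, t_hat); r_tilde = y - y_hat is the
    remainder used to calibrate eps'.
    """
    s1 = fit_stage_one(data, spec_one, check_relevance=False)
    X_y = build_design_matrix(data, spec_two, stage="two", t_hat=s1.t_hat)
    fit = ols_fit(X_y, data.y)
    return s1.omega, fit.coefficients, fit.residuals, s1.t_hat


def fit_two_stage(
    data: IVDataset,
    spec_one: FeatureSpec,
    spec_two: FeatureSpec,
    spec_remainder: FeatureSpec,
    gamma: float = 0.01,
    epsilon: float | None = None,
    epsilon_frac: float = 0.05,
) -> TwoStageFit:
    """Full pipeline: stage one -> eps' calibration -> constrained stage
    two -> validity report.

    When the constrained problem is infeasible the validity report is
    computed post hoc on the traditional remainder r_tilde, which is
    also what the misspecification studies tabulate.
    """
    s1 = fit_stage_one(data, spec_one, epsilon=epsilon, epsilon_frac=epsilon_frac)
    X_y = build_design_matrix(data, spec_two, stage="two", t_hat=s1.t_hat)
    trad = ols_fit(X_y, data.y)
    r_tilde = trad.residuals
    eps_prime = epsilon_prime_from_gamma(gamma, r_tilde)
    X_r = build_design_matrix(data, spec_remainder, stage="remainder")
    H = hat_matrix(X_r)
    s2 = constrained_stage_two(data.y, X_y, H, eps_prime)
    r_for_report = s2.r if s2.r is not None else r_tilde
    report = empirical_validity_check(r_for_report, X_r, eps_prime, gamma)
    return TwoStageFit(stage_one=s1, stage_two=s2, validity=report,
                       r_tilde=r_tilde, beta_traditional=trad.coefficients)
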