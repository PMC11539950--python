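"""The one-stage joint estimator.

Instead of fixing the stage-one model first, the outcome loss is
minimized over (omega, beta) simultaneously, subject to

* a Rashomon-set constraint on stage one — the treatment model must
  beat the covariates-only baseline by at least epsilon:
  ||t - X_t omega||^2 <= baseline - epsilon; and
* the validity constraint on stage two, exactly as in the two-stage
  estimator.

This extra freedom matters when the two-stage problem is infeasible
only because of the particular stage-one fit: many stage-one models
predict the treatment almost equally well, and a different member of
that Rashomon set can yield a feasible outcome model.

The solver is block-coordinate descent: for fixed omega the
beta-subproblem is the convex QCQP of ``constrained_stage_two`` (solved
globally); for fixed beta the omega-subproblem is projected gradient
descent on the Rashomon ellipsoid (the projection itself is a
norm-constrained least-squares problem solved by the same secular
machinery).  Multi-start over seeded initializations always includes
the two-stage and traditional solutions; the best feasible point found
is returned, re-verified through the projections/validity modules
rather than trusted from solver internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .data import IVDataset
from .features import FeatureSpec, build_design_matrix
from .projections import hat_matrix, ols_fit
from .two_stage import (
    SolverFailureError,
    _x_only_spec,
    constrained_stage_two,
    fit_stage_one,
    traditional_two_stage,
)
from .validity import epsilon_prime_from_gamma

__all__ = ["OneStageResult", "rashomon_baseline", "fit_one_stage"]

_MAX_OUTER = 200
_REL_TOL = 1e-9


@dataclass(frozen=True)
class OneStageResult:
    omega: np.ndarray | None
    beta: np.ndarray | None
    t_hat: np.ndarray | None
    objective_value: float | None
    rashomon_slack: float | None   # baseline - eps - loss(t, t_hat); >= 0 if feasible
    validity_constraint_value: float | None
    epsilon_prime: float
    status: str                    # feasible | infeasible | solver_failed
    restarts_used: int


def rashomon_baseline(data: IVDataset, spec_x_only: FeatureSpec) -> float:
    """Best achievable stage-one loss using covariates alone.

    An empty spec with intercept gives the total sum of squares about
    the mean; a fully empty spec gives ||t||^2 (zero model).
    """
    if spec_x_only.references_instrument():
        raise ValueError("rashomon baseline spec must use covariates only")
    if not spec_x_only.terms and not spec_x_only.include_intercept:
        return float(data.t @ data.t)
    X = build_design_matrix(data, spec_x_only, stage="one")
    return ols_fit(X, data.t).sse


def _project_to_rashomon(omega, X_t, t, tau):
    """Project omega onto { w : ||t - X_t w||^2 <= tau } (closest point)."""
    resid = t - X_t @ omega
    if float(resid @ resid) <= tau:
        return omega
    # min ||w - omega||^2 s.t. ||t - X_t w||^2 = tau; Lagrangian
    # (I + mu X_t^T X_t) w = omega + mu X_t^T t, monotone in mu
    A = X_t.T @ X_t
    b = X_t.T @ t
    I = np.eye(len(omega))

    def w_of(mu):
        return np.linalg.solve(I + mu * A, omega + mu * b)

    def phi(mu):
        d = t - X_t @ w_of(mu)
        return float(d @ d) - tau

    lo, hi = 0.0, 1.0
    for _ in range(80):
        if phi(hi) <= 0:
            break
        lo, hi = hi, hi * 10.0
    else:
        raise SolverFailureError("Rashomon projection bracketing failed")
    mu = brentq(phi, lo, hi, xtol=1e-14, rtol=1e-13, maxiter=200)
    return w_of(mu)


def _omega_step(omega, beta, data, spec_two, X_t, tau, n_steps=25):
    """Projected gradient descent on the outcome loss over omega."""
    t, y = data.t, data.y

    def loss(w):
        Xy = build_design_matrix(data, spec_two, stage="two", t_hat=X_t @ w)
        d = y - Xy @ beta
        return float(d @ d)

    cur = loss(omega)
    step = 1.0 / (np.linalg.norm(X_t, ord=2) ** 2 + 1e-12)
    w = omega.copy()
    for _ in range(n_steps):
        # numerical gradient via linearization of t_hat; exact when the
        # stage-two spec uses t_hat linearly, finite differences otherwise
        g = _outcome_grad(w, beta, data, spec_two, X_t)
        cand = _project_to_rashomon(w - step * g, X_t, t, tau)
        new = loss(cand)
        if new < cur - 1e-15:
            w, cur = cand, new
        else:
            step /= 2.0
            if step < 1e-12:
                break
    return w


def _outcome_grad(w, beta, data, spec_two, X_t, h=1e-6):
    Xy = build_design_matrix(data, spec_two, stage="two", t_hat=X_t @ w)
    base = data.y - Xy @ beta
    linear_in_that = all(term == "t_hat" for term in spec_two.terms
                         if "t_hat" in term)
    if linear_in_that and "t_hat" in spec_two.terms:
        # exact gradient: d loss / d w = -2 beta_th X_t^T r
        b_th = beta[spec_two.column_names.index("t_hat")]
        return -2.0 * b_th * (X_t.T @ base)
    g = np.empty_like(w)
    f0 = float(base @ base)
    for j in range(len(w)):
        wp = w.copy()
        wp[j] += h
        Xyp = build_design_matrix(data, spec_two, stage="two", t_hat=X_t @ wp)
        dp = data.y - Xyp @ beta
        g[j] = (float(dp @ dp) - f0) / h
    return g


def fit_one_stage(
    data: IVDataset,
    spec_one: FeatureSpec,
    spec_two: FeatureSpec,
    spec_remainder: FeatureSpec,
    gamma: float = 0.01,
    epsilon: float | None = None,
    epsilon_frac: float = 0.05,
    restarts: int = 10,
    seed: int = 0,
) -> OneStageResult:
    """Joint (omega, beta) fit under the Rashomon and validity constraints."""
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    X_t = build_design_matrix(data, spec_one, stage="one")
    X_r = build_design_matrix(data, spec_remainder, stage="remainder")
    H = hat_matrix(X_r)
    t, y = data.t, data.y

    baseline = rashomon_baseline(data, _x_only_spec(spec_one))
    s1 = fit_stage_one(data, spec_one, check_relevance=False)
    eps = epsilon if epsilon is not None else epsilon_frac * baseline
    tau = baseline - eps  # Rashomon radius on the stage-one loss
    if s1.sse > tau:
        return OneStageResult(
            omega=None, beta=None, t_hat=None, objective_value=None,
            rashomon_slack=float(tau - s1.sse), validity_constraint_value=None,
            epsilon_prime=float("nan"), status="infeasible", restarts_used=0,
        )

    # eps' calibrated once, from the traditional two-stage remainder
    _, _, r_tilde, _ = traditional_two_stage(data, spec_one, spec_two)
    eps_prime = epsilon_prime_from_gamma(gamma, r_tilde)

    def beta_step(omega):
        t_hat = X_t @ omega
        Xy = build_design_matrix(data, spec_two, stage="two", t_hat=t_hat)
        return constrained_stage_two(y, Xy, H, eps_prime), Xy

    starts = [s1.omega]
    scale = np.abs(s1.omega).max() + 1.0
    for _ in range(restarts - 1):
        starts.append(_project_to_rashomon(
            s1.omega + 0.5 * scale * rng.standard_normal(len(s1.omega)),
            X_t, t, tau))

    best = None
    used = 0
    failed = False
    for omega0 in starts:
        used += 1
        omega = omega0.copy()
        prev_obj = math.inf
        for _ in range(_MAX_OUTER):
            try:
                s2, Xy = beta_step(omega)
            except SolverFailureError:
                failed = True
                break
            if s2.beta is None:
                # infeasible at this omega: move omega to shrink the
                # remainder's projection, staying in the Rashomon set
                beta_probe, _ = np.linalg.lstsq(H.Q.T @ Xy, H.Q.T @ y,
                                                rcond=None)[:2]
                omega_new = _omega_constraint_descent(
                    omega, beta_probe, data, spec_two, X_t, H, t, tau)
                if np.allclose(omega_new, omega, rtol=0, atol=1e-12):
                    break
                omega = omega_new
                continue
            obj = s2.objective_value
            cand = (obj, omega.copy(), s2)
            if best is None or obj < best[0]:
                best = cand
            if prev_obj - obj <= _REL_TOL * max(1.0, abs(prev_obj)):
                break
            prev_obj = obj
            omega = _omega_step(omega, s2.beta, data, spec_two, X_t, tau)

    if best is None:
        status = "solver_failed" if failed else "infeasible"
        return OneStageResult(
            omega=None, beta=None, t_hat=None, objective_value=None,
            rashomon_slack=None, validity_constraint_value=None,
            epsilon_prime=float(eps_prime), status=status, restarts_used=used,
        )

    obj, omega, s2 = best
    t_hat = X_t @ omega
    stage_one_loss = float((t - t_hat) @ (t - t_hat))
    # independent re-check of both constraints
    cv = s2.constraint_value
    feasible = (stage_one_loss <= tau * (1 + 1e-8) + 1e-12
                and cv <= eps_prime * (1 + 1e-8) + 1e-12)
    return OneStageResult(
        omega=omega, beta=s2.beta, t_hat=t_hat, objective_value=obj,
        rashomon_slack=float(tau - stage_one_loss),
        validity_constraint_value=float(cv),
        epsilon_prime=float(eps_prime),
        status="feasible" if feasible else "solver_failed",
        restarts_used=used,
    )


def _omega_constraint_descent(omega, beta, data, spec_two, X_t, H, t, tau,
                              n_steps=50):
    """Reduce the validity-constraint value over omega (feasibility search)."""
    y = data.y

    def cval(w):
        Xy = build_design_matrix(data, spec_two, stage="two", t_hat=X_t @ w)
        b, *_ = np.linalg.lstsq(H.Q.T @ Xy, H.Q.T @ y, rcond=None)
        d = H.Q.T @ y - (H.Q.T @ Xy) @ b
        return float(d @ d)

    w = omega.copy()
    cur = cval(w)
    step = 1.0 / (np.linalg.norm(X_t, ord=2) ** 2 + 1e-12)
    for _ in range(n_steps):
        g = np.empty_like(w)
        for j in range(len(w)):
            wp = w.copy()
            wp[j] += 1e-6
            g[j] = (cval(wp) - cur) / 1e-6
        cand = _project_to_rashomon(w - step * g, X_t, t, tau)
        new = cval(cand)
        if new < cur - 1e-15:
            w, cur = cand, new
        else:
            step /= 2.0
            if step < 1e-12:
                break
    return w
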