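"""scikit-learn style estimator classes.

These wrap the functional cores in :mod:`mliv.two_stage` and
:mod:`mliv.one_stage` behind the familiar ``fit`` / ``predict`` /
``get_params`` surface so they compose with sklearn tooling.  ``fit``
takes an :class:`~mliv.data.IVDataset` (or a DataFrame with
``x*``/``z*``/``t``/``y`` columns) because an IV problem carries four
blocks, not the usual (X, y) pair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .data import IVDataset
from .features import FeatureSpec, build_design_matrix
from .one_stage import fit_one_stage
from .two_stage import fit_two_stage, traditional_two_stage

__all__ = ["TwoStageIVRegressor", "OneStageIVRegressor"]


def _as_dataset(data) -> IVDataset:
    if isinstance(data, IVDataset):
        return data
    if isinstance(data, pd.DataFrame):
        return IVDataset.from_frame(data)
    raise TypeError(f"expected IVDataset or DataFrame, got {type(data).__name__}")


def _as_spec(spec, intercept_default=False) -> FeatureSpec:
    if isinstance(spec, FeatureSpec):
        return spec
    return FeatureSpec(spec, include_intercept=intercept_default)


class TwoStageIVRegressor(BaseEstimator, RegressorMixin):
    """Validity-constrained two-stage IV regression.

    Parameters
    ----------
    stage_one : feature terms for the treatment model (may use x, z);
        fitted with an intercept by default.
    stage_two : feature terms for the outcome model (x and ``t_hat``
        only; a raw instrument term is rejected).
    remainder : feature terms for the remainder (validity-check) model.
    gamma : relative validity tolerance; eps' = gamma * ||r_tilde||^2
        with r_tilde the traditional two-stage remainder.
    epsilon_frac : relevance-check threshold as a fraction of the
        covariates-only stage-one loss.
    constrained : if False, fit plain (unconstrained) two-stage least
        squares and only report the validity check post hoc.

    Attributes (after fit)
    ----------------------
    omega_, beta_ : stage coefficients (beta_ is None when infeasible)
    t_hat_ : first-stage fitted treatment
    status_ : "inactive" | "active" | "infeasible"
    constraint_value_, epsilon_prime_, objective_value_
    validity_report_ : :class:`~mliv.validity.ValidityReport`
    relevance_ : stage-one relevance check result
    """

    def __init__(self, stage_one=("x1", "z1"), stage_two=("x1", "t_hat"),
                 remainder=("x1", "z1"), gamma=0.01, epsilon_frac=0.05,
                 stage_one_intercept=True, constrained=True):
        self.stage_one = stage_one
        self.stage_two = stage_two
        self.remainder = remainder
        self.gamma = gamma
        self.epsilon_frac = epsilon_frac
        self.stage_one_intercept = stage_one_intercept
        self.constrained = constrained

    def _specs(self):
        return (
            _as_spec(self.stage_one, intercept_default=self.stage_one_intercept),
            _as_spec(self.stage_two),
            _as_spec(self.remainder),
        )

    def fit(self, data, y=None):
        ds = _as_dataset(data)
        s_one, s_two, s_rem = self._specs()
        gamma = self.gamma if self.constrained else float("inf")
        res = fit_two_stage(ds, s_one, s_two, s_rem, gamma=gamma,
                            epsilon_frac=self.epsilon_frac)
        self.result_ = res
        self.omega_ = res.stage_one.omega
        self.t_hat_ = res.stage_one.t_hat
        self.relevance_ = res.stage_one.relevance
        self.beta_ = res.stage_two.beta
        self.status_ = res.stage_two.status
        self.constraint_value_ = res.stage_two.constraint_value
        self.objective_value_ = res.stage_two.objective_value
        self.epsilon_prime_ = res.stage_two.epsilon_prime
        self.validity_report_ = res.validity
        self.beta_traditional_ = res.beta_traditional
        self.n_features_in_ = ds.p + ds.q
        return self

    def predict(self, data):
        if getattr(self, "beta_", None) is None:
            raise ValueError("no feasible stage-two model (status "
                             f"{getattr(self, 'status_', 'unfitted')!r})")
        ds = _as_dataset(data)
        s_one, s_two, _ = self._specs()
        X_t = build_design_matrix(ds, s_one, stage="one")
        t_hat = X_t @ self.omega_
        X_y = build_design_matrix(ds, s_two, stage="two", t_hat=t_hat)
        return X_y @ self.beta_

    @property
    def treatment_effect_(self) -> float:
        """Coefficient on t_hat in the outcome model (when linear)."""
        if self.beta_ is None:
            raise ValueError("infeasible fit has no treatment effect")
        names = _as_spec(self.stage_two).column_names
        return float(self.beta_[names.index("t_hat")])


class OneStageIVRegressor(BaseEstimator, RegressorMixin):
    """Joint one-stage IV fit under Rashomon + validity constraints."""

    def __init__(self, stage_one=("x1", "z1"), stage_two=("x1", "t_hat"),
                 remainder=("x1", "z1"), gamma=0.01, epsilon=None,
                 epsilon_frac=0.05, stage_one_intercept=True,
                 restarts=10, seed=0):
        self.stage_one = stage_one
        self.stage_two = stage_two
        self.remainder = remainder
        self.gamma = gamma
        self.epsilon = epsilon
        self.epsilon_frac = epsilon_frac
        self.stage_one_intercept = stage_one_intercept
        self.restarts = restarts
        self.seed = seed

    def fit(self, data, y=None):
        ds = _as_dataset(data)
        s_one = _as_spec(self.stage_one, intercept_default=self.stage_one_intercept)
        s_two = _as_spec(self.stage_two)
        s_rem = _as_spec(self.remainder)
        res = fit_one_stage(ds, s_one, s_two, s_rem, gamma=self.gamma,
                            epsilon=self.epsilon, epsilon_frac=self.epsilon_frac,
                            restarts=self.restarts, seed=self.seed)
        self.result_ = res
        self.omega_ = res.omega
        self.beta_ = res.beta
        self.t_hat_ = res.t_hat
        self.status_ = res.status
        self.objective_value_ = res.objective_value
        self.n_features_in_ = ds.p + ds.q
        return self

    def predict(self, data):
        if getattr(self, "beta_", None) is None:
            raise ValueError("no feasible joint model (status "
                             f"{getattr(self, 'status_', 'unfitted')!r})")
        ds = _as_dataset(data)
        s_one = _as_spec(self.stage_one, intercept_default=self.stage_one_intercept)
        s_two = _as_spec(self.stage_two)
        X_t = build_design_matrix(ds, s_one, stage="one")
        X_y = build_design_matrix(ds, s_two, stage="two", t_hat=X_t @ self.omega_)
        return X_y @ self.beta_
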