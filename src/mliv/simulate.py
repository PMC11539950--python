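"""Seeded generators for the three study designs.

All designs share the same skeleton: x ~ N(0,1), z ~ N(0,1)
independently, and correlated errors

    (e1, e2) ~ N(0, [[1, rho], [rho, 1]]),   rho = 0.8 by default,

whose correlation is the unmeasured confounding the instrument is
supposed to defeat.

* ``valid``:          t = x + z + z^2 + e1,        y = x + t + e2
* ``non_instrument``: adds an unknown mediator of the instrument to the
  outcome, y = x + phi * m(z) + t + e2 with m(z) proportional to z^3.
  phi measures the mediator's strength.  By default the mediator is
  scaled to unit variance (m = z^3 / sqrt(15), since E[z^6] = 15 for
  standard-normal z) so phi is the mediator's standard-deviation
  contribution to the outcome; ``mediator_scale="raw"`` uses m = z^3
  unscaled.  The mediator column itself is never exposed — it is
  unknown to the analyst.
* ``robustness``:     t = x + pi * f(z) + e1,      y = x + beta * t + e2
  with f one of six nonlinear forms and pi the instrument strength;
  the structural effect beta is 1 by default.

x, z and (e1, e2) are drawn from independent substreams of one seed, so
changing phi or pi alters the signal but not the underlying noise —
conditions can be compared pairwise on identical draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import IVDataset
from .features import FeatureSpec

__all__ = [
    "SimulationConfig",
    "gen_errors",
    "gen_valid",
    "gen_non_instrument",
    "gen_robustness",
    "generate",
    "ROBUSTNESS_FUNCTIONS",
    "preset_specs",
]

_MEDIATOR_SD = np.sqrt(15.0)  # sd of z^3 for z ~ N(0,1)

ROBUSTNESS_FUNCTIONS = {
    "quadratic": lambda z: z**2,
    "cubic": lambda z: z**3,
    "exp": np.exp,
    "log": lambda z: np.log(np.clip(np.abs(z), 1e-12, None)),
    "sqrt": lambda z: np.sqrt(np.abs(z)),
    "logistic": lambda z: 1.0 / (1.0 + np.exp(-z)),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study."""

    dgp: str = "valid"             # valid | non_instrument | robustness
    n: int = 1000
    phi: float = 1.0               # mediator strength (non_instrument)
    pi: float = 1.0                # instrument strength (robustness)
    f_name: str | None = None      # robustness nonlinearity
    rho: float = 0.8
    beta_true: float = 1.0
    seed: int = 0
    mediator_scale: str = "unit"   # unit | raw

    def __post_init__(self):
        if self.dgp not in ("valid", "non_instrument", "robustness"):
            raise ValueError(f"unknown dgp {self.dgp!r}")
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")
        if self.dgp == "robustness" and self.f_name not in ROBUSTNESS_FUNCTIONS:
            raise ValueError(
                f"robustness dgp needs f_name in {sorted(ROBUSTNESS_FUNCTIONS)}")
        if self.mediator_scale not in ("unit", "raw"):
            raise ValueError("mediator_scale must be 'unit' or 'raw'")


def _streams(seed: int):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(3)]


def gen_errors(n: int, rho: float, seed: int | np.random.Generator):
    """Bivariate normal errors with unit variances and correlation rho."""
    if not -1 < rho < 1:
        raise ValueError("rho must lie in (-1, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e = rng.standard_normal((n, 2))
    e2 = rho * e[:, 0] + np.sqrt(1 - rho**2) * e[:, 1]
    return e[:, 0], e2


def _base_draws(config: SimulationConfig):
    rx, rz, re = _streams(config.seed)
    x = rx.standard_normal(config.n)
    z = rz.standard_normal(config.n)
    e1, e2 = gen_errors(config.n, config.rho, re)
    return x, z, e1, e2


def gen_valid(config: SimulationConfig) -> IVDataset:
    """Valid-instrument design: t = x + z + z^2 + e1, y = x + t + e2."""
    x, z, e1, e2 = _base_draws(config)
    t = x + z + z**2 + e1
    y = x + t + e2
    return IVDataset(X=x[:, None], Z=z[:, None], t=t, y=y)


def mediator(z: np.ndarray, scale: str = "unit") -> np.ndarray:
    """The unknown mediator m(z) proportional to z^3."""
    m = z**3
    return m / _MEDIATOR_SD if scale == "unit" else m


def gen_non_instrument(config: SimulationConfig) -> IVDataset:
    """Non-instrument design: the z^3 mediator leaks into the outcome."""
    x, z, e1, e2 = _base_draws(config)
    t = x + z + z**2 + e1
    y = x + config.phi * mediator(z, config.mediator_scale) + t + e2
    return IVDataset(X=x[:, None], Z=z[:, None], t=t, y=y)


def gen_robustness(config: SimulationConfig) -> IVDataset:
    """Robustness design: t = x + pi*f(z) + e1, y = x + beta*t + e2."""
    x, z, e1, e2 = _base_draws(config)
    f = ROBUSTNESS_FUNCTIONS[config.f_name]
    t = x + config.pi * f(z) + e1
    y = x + config.beta_true * t + e2
    return IVDataset(X=x[:, None], Z=z[:, None], t=t, y=y)


def generate(config: SimulationConfig) -> IVDataset:
    """Dispatch on config.dgp."""
    return {"valid": gen_valid,
            "non_instrument": gen_non_instrument,
            "robustness": gen_robustness}[config.dgp](config)


def preset_specs(name: str) -> dict[str, FeatureSpec]:
    """Named predictor-matrix presets used by the simulation studies.

    Stage-one specs carry an intercept (the stage-one class is affine);
    the stage-two and remainder designs are exactly the printed
    matrices (see docs/methods.md for why the remainder class must not
    contain a free constant).
    """
    presets = {
        # identification studies: X_t=(x,z,z^2), X_y=(x,t_hat), X_r=(x,z,z^2)
        "identification": (["x1", "z1", "z1^2"], ["x1", "t_hat"], ["x1", "z1", "z1^2"]),
        # misspecification example 1 (valid instrument)
        "misspec_linear": (["x1", "z1"], ["x1", "t_hat"], ["x1", "z1", "z1^2"]),
        "misspec_quadratic": (["x1", "z1", "z1^2"], ["x1", "t_hat"],
                              ["x1", "z1", "z1^2", "z1^3"]),
        # misspecification example 2 (non-instrument)
        "noninstr_quadratic": (["x1", "z1", "z1^2"], ["x1", "t_hat"],
                               ["x1", "z1", "z1^2", "z1^3"]),
        "noninstr_cubic": (["x1", "z1", "z1^2", "z1^3"], ["x1", "t_hat"],
                           ["x1", "z1", "z1^2", "z1^3", "z1^4"]),
        # robustness study
        "robust_quadratic": (["x1", "z1", "z1^2"], ["x1", "t_hat"],
                             ["x1", "z1", "z1^2"]),
        "robust_cubic": (["x1", "z1", "z1^2", "z1^3"], ["x1", "t_hat"],
                         ["x1", "z1", "z1^2", "z1^3"]),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    one, two, rem = presets[name]
    return {
        "stage_one": FeatureSpec(one, include_intercept=True),
        "stage_two": FeatureSpec(two),
        "remainder": FeatureSpec(rem),
    }
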