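"""Declarative construction of the three design matrices.

A general additive model here is a linear combination of possibly
nonlinear features of the inputs.  Each feature (term) is written as a
small string expression over the dataset's named columns::

    "x1"            identity
    "z1^2"          power
    "exp(z1)"       exponential
    "log|z1|"       log of absolute value (|.| clipped at 1e-12)
    "sqrt|z1|"      square root of absolute value
    "logistic(z1)"  1 / (1 + exp(-z1))
    "x1*z1"         product of two columns
    "t_hat"         first-stage fitted treatment (stage two only)

Three stages exist: ``one`` (treatment model, may use x and z),
``two`` (outcome model, may use x and t_hat but never z — a direct
instrument term in the outcome model would contradict what a valid
instrument is), and ``remainder`` (the validity-check model, may use x
and z).  ``FeatureSpec`` is an ordered list of such terms plus an
intercept flag, and serializes to/from plain JSON lists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .data import IVDataset

__all__ = [
    "FeatureSpec",
    "DesignMatrices",
    "build_design_matrix",
    "standardize",
    "MulticollinearityError",
    "ValidityViolationError",
]

_LOG_CLIP = 1e-12

_FUNCS = {
    "exp": np.exp,
    "logistic": lambda v: 1.0 / (1.0 + np.exp(-v)),
}
_ABS_FUNCS = {
    "log": lambda v: np.log(np.clip(np.abs(v), _LOG_CLIP, None)),
    "sqrt": lambda v: np.sqrt(np.abs(v)),
}

_TERM_RE = re.compile(
    r"^(?:"
    r"(?P<func>exp|logistic)\((?P<farg>[a-z_0-9]+)\)"
    r"|(?P<absfunc>log|sqrt)\|(?P<aarg>[a-z_0-9]+)\|"
    r"|(?P<base>[a-z_0-9]+)(?:\^(?P<power>\d+))?"
    r"(?:\*(?P<base2>[a-z_0-9]+)(?:\^(?P<power2>\d+))?)?"
    r")$"
)


class MulticollinearityError(ValueError):
    """Raised when a design matrix is rank deficient."""


class ValidityViolationError(ValueError):
    """Raised when a stage references columns it must not see."""


def _term_variables(term: str) -> list[str]:
    m = _TERM_RE.match(term)
    if m is None:
        raise ValueError(f"cannot parse feature term {term!r}")
    names = [m.group(g) for g in ("farg", "aarg", "base", "base2")]
    return [v for v in names if v]


def _eval_term(term: str, lookup) -> np.ndarray:
    m = _TERM_RE.match(term)
    if m is None:
        raise ValueError(f"cannot parse feature term {term!r}")
    if m.group("func"):
        return _FUNCS[m.group("func")](lookup(m.group("farg")))
    if m.group("absfunc"):
        return _ABS_FUNCS[m.group("absfunc")](lookup(m.group("aarg")))
    col = lookup(m.group("base"))
    if m.group("power"):
        col = col ** int(m.group("power"))
    if m.group("base2"):
        other = lookup(m.group("base2"))
        if m.group("power2"):
            other = other ** int(m.group("power2"))
        col = col * other
    return col


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered feature list for one design matrix.

    Duplicate terms are rejected.  ``include_intercept`` prepends a
    column of ones; default False so the matrix is exactly the declared
    terms.
    """

    terms: tuple[str, ...]
    include_intercept: bool = False

    def __init__(self, terms, include_intercept: bool = False):
        terms = tuple(str(t).replace(" ", "") for t in terms)
        if len(set(terms)) != len(terms):
            dup = [t for t in terms if terms.count(t) > 1]
            raise ValueError(f"duplicate feature terms: {sorted(set(dup))}")
        for t in terms:
            _term_variables(t)  # validates syntax
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "include_intercept", bool(include_intercept))

    @property
    def column_names(self) -> list[str]:
        names = ["intercept"] if self.include_intercept else []
        return names + list(self.terms)

    def variables(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms:
            out.update(_term_variables(t))
        return out

    def references_instrument(self) -> bool:
        return any(v.startswith("z") for v in self.variables())

    def references_t_hat(self) -> bool:
        return "t_hat" in self.variables()

    def to_json(self) -> dict:
        return {"terms": list(self.terms), "include_intercept": self.include_intercept}

    @classmethod
    def from_json(cls, obj) -> "FeatureSpec":
        if isinstance(obj, (list, tuple)):
            return cls(obj)
        return cls(obj["terms"], obj.get("include_intercept", False))


@dataclass(frozen=True)
class DesignMatrices:
    """The three matrices the estimators run on."""

    X_t: np.ndarray
    X_y: np.ndarray
    X_r: np.ndarray


def standardize(columns: np.ndarray):
    """z-score each column; returns (standardized, centers, scales).

    Raises on a zero-variance column — such a column cannot carry
    signal and silently dividing by ~0 would poison downstream fits.
    """
    M = np.atleast_2d(np.asarray(columns, dtype=float))
    if M.shape[0] == 1:
        M = M.T
    centers = M.mean(axis=0)
    scales = M.std(axis=0, ddof=0)
    dead = np.where(scales < 1e-14)[0]
    if dead.size:
        raise ValueError(f"zero-variance column(s) at index {dead.tolist()}")
    return (M - centers) / scales, centers, scales


def unstandardize(columns: np.ndarray, centers, scales) -> np.ndarray:
    """Inverse of :func:`standardize`."""
    return np.asarray(columns, dtype=float) * scales + centers


def build_design_matrix(
    data: IVDataset,
    spec: FeatureSpec,
    stage: str,
    t_hat: np.ndarray | None = None,
    normalize: bool = False,
) -> np.ndarray:
    """Evaluate a FeatureSpec on a dataset into an n x k matrix.

    Columns appear in spec order (intercept first when requested).
    ``stage`` is one of ``"one"``, ``"two"``, ``"remainder"``; stage two
    must not name a raw instrument column, and only stage two may use
    ``t_hat``.
    """
    if stage not in ("one", "two", "remainder"):
        raise ValueError(f"unknown stage {stage!r}")
    if stage == "two" and spec.references_instrument():
        bad = sorted(v for v in spec.variables() if v.startswith("z"))
        raise ValidityViolationError(
            f"stage-two model references instrument column(s) {bad}; "
            "the outcome model may only see the instrument through t_hat"
        )
    if stage != "two" and spec.references_t_hat():
        raise ValidityViolationError(f"stage-{stage} model cannot reference t_hat")
    if spec.references_t_hat() and t_hat is None:
        raise ValueError("spec references t_hat but no t_hat vector was supplied")

    def lookup(name: str) -> np.ndarray:
        if name == "t_hat":
            return np.asarray(t_hat, dtype=float).ravel()
        return data.column(name)

    cols = [_eval_term(t, lookup) for t in spec.terms]
    M = np.column_stack(cols) if cols else np.empty((data.n, 0))
    if normalize and M.shape[1]:
        M, _, _ = standardize(M)
    if spec.include_intercept:
        M = np.column_stack([np.ones(data.n), M])
    if M.shape[1]:
        rank = np.linalg.matrix_rank(M, tol=None)
        if rank < M.shape[1]:
            raise MulticollinearityError(
                f"design matrix for stage {stage} is rank deficient "
                f"(rank {rank} < {M.shape[1]} columns: {spec.column_names})"
            )
    return M
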