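"""Tabular container for one instrumental-variable study.

An IV analysis always carries four blocks: observed covariates ``X``
(n x p), one or more candidate instruments ``Z`` (n x q), a treatment
vector ``t`` and an outcome vector ``y``.  :class:`IVDataset` holds them
as aligned numpy arrays and round-trips to a flat CSV with columns
``x1..xp, z1..zq, t, y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IVDataset", "read_dataset", "write_dataset"]


@dataclass(frozen=True)
class IVDataset:
    """One study's data: covariates, instruments, treatment, outcome.

    All blocks must share the same number of rows and contain no missing
    values; instruments are kept separate from covariates because the
    validity machinery must know which columns are proposed instruments.
    """

    X: np.ndarray
    Z: np.ndarray
    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(self.t).size == X.shape[1]:
            X = X.T
        if Z.shape[0] == 1 and Z.shape[1] > 1 and np.asarray(self.t).size == Z.shape[1]:
            Z = Z.T
        t = np.asarray(self.t, dtype=float).ravel()
        y = np.asarray(self.y, dtype=float).ravel()
        n = t.shape[0]
        if not (X.shape[0] == Z.shape[0] == y.shape[0] == n):
            raise ValueError(
                f"inconsistent row counts: X {X.shape[0]}, Z {Z.shape[0]}, "
                f"t {n}, y {y.shape[0]}"
            )
        for name, block in (("X", X), ("Z", Z), ("t", t), ("y", y)):
            if not np.all(np.isfinite(block)):
                rows = np.where(~np.isfinite(np.atleast_2d(block)).all(axis=-1))[0]
                raise ValueError(f"non-finite values in {name} (rows {rows[:5].tolist()})")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.t.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def column(self, name: str) -> np.ndarray:
        """Return a named column: ``x3`` / ``z1`` / ``t`` / ``y``."""
        if name == "t":
            return self.t
        if name == "y":
            return self.y
        kind, idx = name[0], name[1:]
        if kind in ("x", "z") and idx.isdigit():
            j = int(idx) - 1
            block = self.X if kind == "x" else self.Z
            if 0 <= j < block.shape[1]:
                return block[:, j]
        raise KeyError(f"no column named {name!r}")

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        for j in range(self.p):
            cols[f"x{j + 1}"] = self.X[:, j]
        for j in range(self.q):
            cols[f"z{j + 1}"] = self.Z[:, j]
        cols["t"] = self.t
        cols["y"] = self.y
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IVDataset":
        xcols = sorted((c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
                       key=lambda c: int(c[1:]))
        zcols = sorted((c for c in df.columns if c.startswith("z") and c[1:].isdigit()),
                       key=lambda c: int(c[1:]))
        missing = [c for c in ("t", "y") if c not in df.columns]
        if missing or not xcols or not zcols:
            need = missing + ([] if xcols else ["x*"]) + ([] if zcols else ["z*"])
            raise ValueError(f"dataset is missing required column(s): {', '.join(need)}")
        bad = df[xcols + zcols + ["t", "y"]].isna()
        if bad.to_numpy().any():
            rows = np.where(bad.any(axis=1))[0]
            raise ValueError(f"missing values in rows {rows[:5].tolist()}")
        return cls(
            X=df[xcols].to_numpy(float),
            Z=df[zcols].to_numpy(float),
            t=df["t"].to_numpy(float),
            y=df["y"].to_numpy(float),
        )


def read_dataset(path) -> IVDataset:
    """Read a CSV with header columns ``x*``, ``z*``, ``t``, ``y``."""
    try:
        df = pd.read_csv(path)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"could not parse {path}: {exc}") from exc
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cells in column {col!r} (rows {list(bad[:5])})"
            )
    return IVDataset.from_frame(df)


def write_dataset(data: IVDataset, path) -> None:
    """Write the dataset as CSV at full (round-trippable) precision."""
    data.to_frame().to_csv(path, index=False)
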