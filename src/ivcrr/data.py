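"""The individual-level data container and its CSV dialect.

Every analysis in this package runs on aligned vectors ``(g, x, y)`` for ``n``
individuals: a (possibly continuous) instrument ``g`` such as a weighted
allele score, a continuous exposure ``x``, and a binary outcome ``y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IVData",
    "DegenerateDataError",
    "read_dataset",
    "write_dataset",
    "toy_fixture",
    "TOY_FIXTURES",
]


class DegenerateDataError(ValueError):
    """Raised when an operation's contract excludes the supplied data
    (e.g. a constant instrument, or no observed events where required)."""


@dataclass(frozen=True)
class IVData:
    """Aligned instrument / exposure / binary-outcome vectors.

    Parameters
    ----------
    g, x : array-like of float, length n
        Instrument and exposure values.
    y : array-like of {0, 1}, length n
        Binary outcome indicator.
    """

    g: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        g = np.ascontiguousarray(self.g, dtype=float)
        x = np.ascontiguousarray(self.x, dtype=float)
        y = np.ascontiguousarray(self.y)
        if not (g.ndim == x.ndim == y.ndim == 1):
            raise ValueError("g, x, y must be one-dimensional")
        if not (len(g) == len(x) == len(y)):
            raise ValueError(
                f"length mismatch: g={len(g)}, x={len(x)}, y={len(y)}"
            )
        if len(g) < 2:
            raise ValueError("need at least 2 individuals")
        yv = np.unique(y)
        if not np.isin(yv, (0, 1)).all():
            raise ValueError(f"y must contain only 0 and 1, found {yv!r}")
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", np.ascontiguousarray(y, dtype=np.int8))

    @property
    def n(self) -> int:
        return len(self.g)

    @property
    def n_events(self) -> int:
        return int(self.y.sum())

    @property
    def g_is_constant(self) -> bool:
        return bool(np.all(self.g == self.g[0]))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IVData":
        missing = {"g", "x", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        return cls(df["g"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"g": self.g, "x": self.x, "y": self.y.astype(int)}
        )


def write_dataset(ds: IVData, path) -> None:
    """Write a dataset as headered CSV (``g,x,y``; y as integers)."""
    ds.to_dataframe().to_csv(path, index=False)


def read_dataset(path) -> IVData:
    """Read a ``g,x,y`` CSV, validating the header and the outcome coding.

    Malformed numeric fields and out-of-range y are reported with the
    offending line number (header = line 1).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # malformed row structure
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if list(df.columns) != ["g", "x", "y"]:
        raise ValueError(
            f"expected header 'g,x,y', found {','.join(map(str, df.columns))!r}"
        )
    for col in ("g", "x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & ~df[col].isna()
        if bad.any() or df[col].isna().any():
            line = int(np.flatnonzero(bad | df[col].isna())[0]) + 2
            raise ValueError(f"non-numeric or missing {col!r} value at line {line}")
        df[col] = vals
    off = ~df["y"].isin((0, 1))
    if off.any():
        line = int(np.flatnonzero(off)[0]) + 2
        raise ValueError(
            f"y must be 0 or 1; found {df['y'].iloc[line - 2]!r} at line {line}"
        )
    return IVData.from_dataframe(df)


# Hand-sized fixtures used throughout the test documentation; every quantity
# asserted against them is computable by hand.
TOY_FIXTURES: dict[str, dict[str, tuple]] = {
    # no events at all: every estimating function is identically zero
    "allzero": {"g": (0.0, 1.0, 2.0, 3.0), "x": (0.0, 1.0, 0.5, 2.0), "y": (0, 0, 0, 0)},
    # two individuals, both events
    "twopoint": {"g": (0.0, 1.0), "x": (0.0, 1.0), "y": (1, 1)},
    # 2x2 balanced layout
    "balanced4": {"g": (0.0, 0.0, 1.0, 1.0), "x": (0.0, 1.0, 0.0, 1.0), "y": (0, 1, 0, 1)},
    # unequal event weighting: the multiplicative estimating function has the
    # closed-form root beta1 = ln 2
    "skew3": {"g": (0.0, 0.0, 1.0), "x": (0.0, 0.0, 1.0), "y": (1, 0, 1)},
}


def toy_fixture(name: str) -> IVData:
    """Return a documented toy dataset by name (see :data:`TOY_FIXTURES`)."""
    try:
        entry = TOY_FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(TOY_FIXTURES)}"
        ) from None
    return IVData(np.array(entry["g"]), np.array(entry["x"]), np.array(entry["y"]))
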