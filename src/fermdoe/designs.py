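"""Experimental designs for medium-optimization studies.

Two designs are supported: the three-level L27 orthogonal array used for
factor screening, and the rotatable central composite design (CCD) used to
fit a full quadratic response surface.  All analysis in this package is
carried out in *coded* factor units; :class:`FactorSpec` carries the map
between coded levels and actual concentrations/settings and handles the
(possibly asymmetric) conversion in both directions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignMatrix",
    "build_l27",
    "build_ccd",
    "rotatable_alpha",
]


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its coded-level -> actual-value map.

    Parameters
    ----------
    name : str
        Human-readable factor name (e.g. ``"orange peel"``).
    symbol : str
        Short column symbol used in design tables (e.g. ``"x1"`` or ``"A"``).
    unit : str
        Unit of the actual values (e.g. ``"w/%"``, ``"degC"``, ``"min"``).
    levels : tuple of (coded, actual) pairs
        Tabulated levels, 3 for a Taguchi factor or 5 for a CCD factor.
        Coded levels must be strictly increasing and actual values strictly
        monotone.  Spacing of the actual values may be asymmetric; conversion
        between scales is piecewise linear between adjacent tabulated levels.
    """

    name: str
    symbol: str
    unit: str
    levels: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.levels) not in (3, 5):
            raise ValueError(
                f"factor {self.symbol!r}: expected 3 or 5 levels, got {len(self.levels)}"
            )
        coded = np.array([c for c, _ in self.levels], dtype=float)
        actual = np.array([a for _, a in self.levels], dtype=float)
        if not np.all(np.diff(coded) > 0):
            raise ValueError(f"factor {self.symbol!r}: coded levels must be strictly increasing")
        d = np.diff(actual)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError(f"factor {self.symbol!r}: actual values must be strictly monotone")

    @property
    def coded_levels(self) -> np.ndarray:
        return np.array([c for c, _ in self.levels], dtype=float)

    @property
    def actual_levels(self) -> np.ndarray:
        return np.array([a for _, a in self.levels], dtype=float)

    def to_actual(self, coded: float) -> float:
        """Convert a coded level to the actual scale (piecewise linear)."""
        c = self.coded_levels
        a = self.actual_levels
        if coded < c[0] or coded > c[-1]:
            raise ValueError(
                f"factor {self.symbol!r}: coded value {coded} outside [{c[0]}, {c[-1]}]"
            )
        return float(np.interp(coded, c, a))

    def to_coded(self, actual: float) -> float:
        """Inverse of :meth:`to_actual`; exact at tabulated levels."""
        c = self.coded_levels
        a = self.actual_levels
        if a[-1] < a[0]:  # decreasing actuals: flip for np.interp
            a, c = a[::-1], c[::-1]
        if actual < a[0] or actual > a[-1]:
            raise ValueError(
                f"factor {self.symbol!r}: actual value {actual} outside [{a[0]}, {a[-1]}]"
            )
        return float(np.interp(actual, a, c))


@dataclass
class DesignMatrix:
    """Runs x factors in coded units with per-run point-type tags.

    ``coded`` is indexed by 1-based ``run_id`` with one column per factor
    symbol; ``point_type`` holds one of ``{"factorial", "axial", "center",
    "oa"}`` per run.  ``factors`` is optional; when present it enables
    conversion of the whole matrix to actual units.
    """

    coded: pd.DataFrame
    point_type: pd.Series
    factors: tuple[FactorSpec, ...] | None = None

    def __post_init__(self) -> None:
        self.coded = self.coded.astype(float)
        if not self.coded.index.equals(self.point_type.index):
            raise ValueError("coded and point_type must share the same run index")
        bad = set(self.point_type) - {"factorial", "axial", "center", "oa"}
        if bad:
            raise ValueError(f"unknown point types: {sorted(bad)}")
        if self.factors is not None:
            syms = [f.symbol for f in self.factors]
            if syms != list(self.coded.columns):
                raise ValueError(
                    f"factor symbols {syms} do not match design columns {list(self.coded.columns)}"
                )
        center = self.coded.loc[self.point_type == "center"]
        if len(center) and not np.allclose(center.to_numpy(), 0.0):
            raise ValueError("center runs must have all-zero coded vectors")

    @property
    def k(self) -> int:
        return self.coded.shape[1]

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def symbols(self) -> list[str]:
        return list(self.coded.columns)

    def actual(self) -> pd.DataFrame:
        """Design matrix converted to actual units (requires factor specs)."""
        if self.factors is None:
            raise ValueError("no FactorSpec list attached to this design")
        out = {}
        for spec in self.factors:
            out[spec.symbol] = [spec.to_actual(v) for v in self.coded[spec.symbol]]
        return pd.DataFrame(out, index=self.coded.index)


def build_l27(n_factors: int = 6, factors: tuple[FactorSpec, ...] | None = None) -> DesignMatrix:
    """Construct the three-level L27 orthogonal array over GF(3).

    Columns are generated from three basis columns *a* (changes every nine
    runs), *b* (every three runs) and *c* (every run) and the derived columns
    ``a+b``, ``2a+b`` and ``a+c`` (mod 3), assigned in the order
    ``a, b, a+b, 2a+b, c, a+c`` and mapped to coded levels {-1, 0, +1}.
    Every column is balanced (each level nine times) and every pair of
    columns contains each ordered level pair exactly three times.
    """
    if not (1 <= n_factors <= 6):
        raise ValueError(f"n_factors must be in 1..6, got {n_factors}")
    runs = np.arange(27)
    a, b, c = runs // 9, (runs // 3) % 3, runs % 3
    cols = [a, b, (a + b) % 3, (2 * a + b) % 3, c, (a + c) % 3]
    coded = np.stack(cols[:n_factors], axis=1) - 1.0
    symbols = [f"x{i + 1}" for i in range(n_factors)]
    if factors is not None:
        symbols = [f.symbol for f in factors]
    df = pd.DataFrame(coded, columns=symbols, index=pd.RangeIndex(1, 28, name="run_id"))
    pt = pd.Series("oa", index=df.index, name="point_type")
    return DesignMatrix(df, pt, factors)


def rotatable_alpha(k: int) -> float:
    """Axial distance making a k-factor CCD rotatable: (2^k)^(1/4)."""
    return float((2.0**k) ** 0.25)


def build_ccd(
    k: int,
    alpha: float,
    n_center: int,
    factors: tuple[FactorSpec, ...] | None = None,
    symbols: list[str] | None = None,
) -> DesignMatrix:
    """Construct a central composite design in standard run order.

    2^k factorial points at +/-1 (first factor varying fastest), then 2k
    axial points taken one factor at a time (-alpha before +alpha), then
    ``n_center`` all-zero center replicates.  Total runs: 2^k + 2k + n_center.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if n_center < 1:
        raise ValueError(f"n_center must be >= 1, got {n_center}")
    rows: list[list[float]] = []
    types: list[str] = []
    # factorial block in standard (Yates) order: first factor cycles fastest
    for combo in itertools.product((-1.0, 1.0), repeat=k):
        rows.append(list(combo)[::-1])
        types.append("factorial")
    for i in range(k):
        for s in (-alpha, alpha):
            p = [0.0] * k
            p[i] = s
            rows.append(p)
            types.append("axial")
    for _ in range(n_center):
        rows.append([0.0] * k)
        types.append("center")
    if symbols is None:
        symbols = [f.symbol for f in factors] if factors is not None else [f"x{i+1}" for i in range(k)]
    idx = pd.RangeIndex(1, len(rows) + 1, name="run_id")
    df = pd.DataFrame(rows, columns=symbols, index=idx)
    pt = pd.Series(types, index=idx, name="point_type")
    return DesignMatrix(df, pt, factors)
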