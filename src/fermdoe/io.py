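"""Reading and writing design/response tables and flat model files.

The sole tabular interchange format is CSV (UTF-8, header row required):
``run_id``, optional ``point_type``, one column per factor symbol holding
coded levels, then response columns as ``<name>`` (replicate mean) with an
optional ``<name>_sd`` column.  Unicode minus signs are normalized on read;
ASCII is written.  Quadratic models are stored as flat ``term value`` text
files (one term per line, ``#`` comments allowed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import DesignMatrix, FactorSpec

__all__ = ["ResponseTable", "ParseError", "read_response_table", "write_response_table",
           "read_model_file", "write_model_file"]

_UNICODE_MINUS = "−"
# short symbol-like column names: x1..x9, A..D, chi1... etc.
_FACTOR_RE = re.compile(r"^(?:[A-Za-z]|[A-Za-z]{1,3}\d{1,2})$")
_META_COLS = {"run_id", "point_type"}


class ParseError(ValueError):
    """Raised when a CSV table cannot be parsed; message carries location."""


@dataclass
class ResponseTable:
    """A design matrix joined to one or more response columns.

    ``responses`` is indexed like ``design.coded`` and holds mean columns
    (response units) plus optional ``<name>_sd`` columns (sd >= 0).
    """

    design: DesignMatrix
    responses: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.design.coded.index.equals(self.responses.index):
            raise ValueError("responses must be indexed by the design's run_id")
        for col in self.sd_names:
            sd = self.responses[col]
            if (sd.dropna() < 0).any():
                raise ValueError(f"negative sd in column {col!r}")

    @property
    def response_names(self) -> list[str]:
        return [c for c in self.responses.columns if not c.endswith("_sd")]

    @property
    def sd_names(self) -> list[str]:
        return [c for c in self.responses.columns if c.endswith("_sd")]

    def response(self, name: str) -> pd.Series:
        if name not in self.response_names:
            raise KeyError(f"unknown response column {name!r}; have {self.response_names}")
        return self.responses[name]


def _infer_factor_columns(columns: list[str]) -> list[str]:
    out = []
    for c in columns:
        if c in _META_COLS or c.endswith("_sd"):
            continue
        if _FACTOR_RE.match(c):
            out.append(c)
    return out


def read_response_table(
    path: str | Path,
    factor_symbols: list[str] | None = None,
    factors: tuple[FactorSpec, ...] | None = None,
) -> ResponseTable:
    """Read a coded design + response CSV into a :class:`ResponseTable`.

    Factor columns are taken from ``factors``/``factor_symbols`` when given,
    otherwise inferred as the short symbol-like column names (``x1``, ``A``,
    ...); every remaining non-meta column is a response (or ``_sd``) column.
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8").replace(_UNICODE_MINUS, "-")
    from io import StringIO

    df = pd.read_csv(StringIO(raw))
    if "run_id" not in df.columns:
        raise ParseError(f"{path.name}: missing required column 'run_id'")
    if df["run_id"].duplicated().any():
        dup = df.loc[df["run_id"].duplicated(), "run_id"].iloc[0]
        raise ParseError(f"{path.name}: duplicate run_id {dup}")
    df = df.set_index("run_id")
    df.index.name = "run_id"

    if factors is not None:
        symbols = [f.symbol for f in factors]
    elif factor_symbols is not None:
        symbols = list(factor_symbols)
    else:
        symbols = _infer_factor_columns(list(df.columns))
    missing = [s for s in symbols if s not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing factor column(s) {missing}")

    if "point_type" in df.columns:
        pt = df["point_type"].astype(str)
    else:
        pt = pd.Series("oa", index=df.index, name="point_type")
    resp_cols = [c for c in df.columns if c not in symbols and c not in _META_COLS]
    for col in symbols + resp_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(f"{path.name}: non-numeric cell at run_id {bad[0]}, column {col!r}")
        df[col] = vals
    design = DesignMatrix(df[symbols], pt.rename("point_type"), factors)
    return ResponseTable(design, df[resp_cols].astype(float))


def write_response_table(table: ResponseTable, path: str | Path) -> None:
    """Write a :class:`ResponseTable` back to CSV (round-trips with read)."""
    df = pd.concat(
        [table.design.point_type, table.design.coded, table.responses], axis=1
    ).reset_index()
    df.to_csv(path, index=False, encoding="utf-8")


def read_model_file(path: str | Path) -> dict[str, float]:
    """Read a flat ``term value`` model file into an ordered dict."""
    out: dict[str, float] = {}
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.split("#", 1)[0].strip().replace(_UNICODE_MINUS, "-")
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{Path(path).name}:{ln}: expected 'term value', got {line!r}")
        out[parts[0]] = float(parts[1])
    return out


def write_model_file(terms: dict[str, float], path: str | Path) -> None:
    lines = [f"{k} {v!r}" for k, v in terms.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
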