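"""Bundled study datasets and fixture models.

The package ships the three response tables of a published fermentation
optimization study (transcribed verbatim): a 27-run L27 screening table for
polygalacturonase (PGase) production, a 30-run four-factor CCD for PGase,
and a 30-run CCD for banana-fiber pectin hydrolysis (pectin yield % and
reducing sugar), plus the corresponding factor-level maps and the printed
quadratic models.

Several printed cells are internally inconsistent; they are kept verbatim
and flagged here rather than corrected:

* ``TAGUCHI_ANOMALOUS_RUNS``: run 10's response does not agree with the
  table's own additive predictions or level-mean summaries.
* ``TAGUCHI_ANOMALOUS_CELLS``: in runs 20/21, 23/24 and 26/27 the printed
  x6 levels are pairwise swapped relative to the only GF(3) column (a+c)
  consistent with runs 1-18; as printed, x6 is not orthogonal to x5.
* ``CCD_ANOMALOUS_RUNS``: runs 14 and 20 of the PGase CCD disagree with the
  printed model/predictions; the printed coefficient table is consequently
  not recoverable from the printed responses by least squares.
* the reducing-sugar model file is corrupted in print (lost exponents) and
  is flagged via ``MODEL_FLAGS``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .designs import FactorSpec
from .io import ResponseTable, read_model_file, read_response_table
from .rsm import QuadraticModel

__all__ = [
    "load_taguchi_pgase",
    "load_ccd_pgase",
    "load_ccd_pectin",
    "taguchi_factors",
    "ccd_factors",
    "pectin_factors",
    "load_model",
    "TAGUCHI_ANOMALOUS_RUNS",
    "TAGUCHI_ANOMALOUS_CELLS",
    "CCD_ANOMALOUS_RUNS",
    "CCD_ANOMALOUS_PRED_RUNS",
    "MODEL_FLAGS",
]

#: run 10's response is inconsistent with the printed predictions/summaries
TAGUCHI_ANOMALOUS_RUNS = frozenset({10})
#: (run_id, symbol) cells where the printed design deviates from the
#: orthogonal GF(3) construction (x6 level pairs swapped within runs 19-27)
TAGUCHI_ANOMALOUS_CELLS = frozenset(
    {(20, "x6"), (21, "x6"), (23, "x6"), (24, "x6"), (26, "x6"), (27, "x6")}
)
#: PGase CCD runs inconsistent with the printed model
CCD_ANOMALOUS_RUNS = frozenset({14, 20})
#: runs whose printed prediction disagrees with the printed model by > 0.01
#: (run 11's prediction cell appears misprinted as well: 20.29 vs 24.27)
CCD_ANOMALOUS_PRED_RUNS = frozenset({11, 14, 20})
#: model fixture provenance flags
MODEL_FLAGS = {
    "eq6": "ok",
    "eq7_yield": "ok",
    "eq7_sugar": "corrupted: printed coefficients lost their exponents",
}
#: factor-level rows that are garbled in print (values are the natural reading)
UNCERTAIN_FACTOR_LEVELS = frozenset({("pectin", "A"), ("pectin", "C"), ("pectin", "D")})


def _data_path(name: str):
    return resources.files("fermdoe.data").joinpath(name)


def _load_factors(name: str) -> tuple[FactorSpec, ...]:
    with resources.as_file(_data_path(name)) as p:
        df = pd.read_csv(p, comment="#")
    specs = []
    for sym, grp in df.groupby("symbol", sort=False):
        grp = grp.sort_values("coded")
        specs.append(
            FactorSpec(
                name=grp["name"].iloc[0],
                symbol=str(sym),
                unit=grp["unit"].iloc[0],
                levels=tuple(zip(grp["coded"].astype(float), grp["actual"].astype(float))),
            )
        )
    return tuple(specs)


def taguchi_factors() -> tuple[FactorSpec, ...]:
    """Factor-level maps of the six screening factors (three levels each)."""
    return _load_factors("factors_taguchi.csv")


def ccd_factors() -> tuple[FactorSpec, ...]:
    """Five-level maps of the four factors carried into the PGase CCD."""
    return _load_factors("factors_ccd.csv")


def pectin_factors() -> tuple[FactorSpec, ...]:
    """Five-level maps of the pectin-hydrolysis factors A-D."""
    return _load_factors("factors_pectin.csv")


def _load_table(name: str, factors) -> ResponseTable:
    with resources.as_file(_data_path(name)) as p:
        return read_response_table(p, factors=factors)


def load_taguchi_pgase() -> ResponseTable:
    """27-run L27 screening table: PGase activity (U/mL) mean, sd and the
    study's own additive predictions (``PGase_pred``)."""
    return _load_table("taguchi_pgase.csv", taguchi_factors())


def load_ccd_pgase() -> ResponseTable:
    """30-run PGase CCD (columns x1, x2, x3, x6) with printed predictions."""
    return _load_table("ccd_pgase.csv", ccd_factors())


def load_ccd_pectin() -> ResponseTable:
    """30-run pectin-hydrolysis CCD: pectin yield (%) and reducing sugar."""
    return _load_table("ccd_pectin.csv", pectin_factors())


_MODEL_SYMBOLS = {
    "eq6": ["x1", "x2", "x3", "x6"],
    "eq7_yield": ["A", "B", "C", "D"],
    "eq7_sugar": ["A", "B", "C", "D"],
}


def load_model(name: str) -> QuadraticModel:
    """Load a printed fixture model (``eq6``, ``eq7_yield``, ``eq7_sugar``).

    ``eq7_sugar`` is flagged corrupted (see :data:`MODEL_FLAGS`); loading it
    emits a warning and analyses should refit from data instead.
    """
    if name not in _MODEL_SYMBOLS:
        raise KeyError(f"unknown model {name!r}; have {sorted(_MODEL_SYMBOLS)}")
    if MODEL_FLAGS[name] != "ok":
        import warnings

        warnings.warn(f"model {name!r} is {MODEL_FLAGS[name]}", stacklevel=2)
    with resources.as_file(_data_path(f"{name}.model")) as p:
        terms = read_model_file(p)
    return QuadraticModel.from_terms(terms, _MODEL_SYMBOLS[name], alpha=2.0)
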