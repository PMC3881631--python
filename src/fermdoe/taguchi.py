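"""Taguchi orthogonal-array factor screening.

Given a balanced three-level orthogonal-array experiment, this module
computes per-factor level means and signal-to-noise (S/N) ratios, ranks the
factors by their delta (max level summary minus min), selects the optimal
level combination with its additive-model prediction, and screens factors
for significance with a fixed-effects ANOVA against the pooled residual of
the main-effects model (default confidence 90%, i.e. P < 0.10).

S/N ratios use the standard Taguchi forms in decibels:

    larger-is-better   -10 log10( mean(1 / y^2) )
    smaller-is-better  -10 log10( mean(y^2) )
    nominal-is-best     10 log10( mean^2 / variance )
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .designs import FactorSpec
from .io import ResponseTable

__all__ = [
    "LevelSummary",
    "OptimalCombination",
    "TaguchiAnova",
    "SaturatedModelError",
    "level_means",
    "sn_ratio",
    "summarize_levels",
    "delta_rank",
    "optimal_levels",
    "taguchi_anova",
]


class SaturatedModelError(ValueError):
    """Raised when the main-effects model leaves no residual degrees of freedom."""


@dataclass
class LevelSummary:
    """Per-factor level summaries of an orthogonal-array experiment.

    ``means`` and ``sn`` are DataFrames indexed by coded level with one
    column per factor symbol; ``delta``/``rank`` are DataFrames indexed by
    factor with columns ``mean`` and ``sn``.  Rank 1 marks the largest delta;
    ties are broken by design column order.
    """

    means: pd.DataFrame
    sn: pd.DataFrame
    delta: pd.DataFrame
    rank: pd.DataFrame
    grand_mean: float


def sn_ratio(values, criterion: str = "larger") -> float:
    """Taguchi signal-to-noise ratio (dB) of a set of response values."""
    y = np.asarray(values, dtype=float)
    if criterion == "larger":
        if np.any(y <= 0):
            raise ValueError("larger-is-better S/N requires strictly positive values")
        return float(-10.0 * np.log10(np.mean(1.0 / y**2)))
    if criterion == "smaller":
        return float(-10.0 * np.log10(np.mean(y**2)))
    if criterion == "nominal":
        v = float(np.var(y, ddof=1))
        if v <= 0:
            raise ValueError("nominal-is-best S/N requires positive variance")
        return float(10.0 * np.log10(np.mean(y) ** 2 / v))
    raise ValueError(f"unknown criterion {criterion!r}")


def level_means(table: ResponseTable, response: str) -> pd.DataFrame:
    """Mean response per factor level (levels as rows, factors as columns).

    For a balanced L27 each cell averages the nine runs at that level.
    """
    y = table.response(response)
    coded = table.design.coded
    levels = sorted(set(np.unique(coded.to_numpy())))
    out = pd.DataFrame(index=pd.Index(levels, name="coded_level"),
                       columns=coded.columns, dtype=float)
    for sym in coded.columns:
        for lev in levels:
            mask = coded[sym] == lev
            if not mask.any():
                raise ValueError(f"factor {sym!r} has no runs at level {lev}")
            out.loc[lev, sym] = y[mask].mean()
    return out


def _level_sn(table: ResponseTable, response: str, criterion: str) -> pd.DataFrame:
    y = table.response(response)
    coded = table.design.coded
    levels = sorted(set(np.unique(coded.to_numpy())))
    out = pd.DataFrame(index=pd.Index(levels, name="coded_level"),
                       columns=coded.columns, dtype=float)
    for sym in coded.columns:
        for lev in levels:
            out.loc[lev, sym] = sn_ratio(y[coded[sym] == lev], criterion)
    return out


def delta_rank(summary: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Delta (max - min over levels) and rank per factor for one criterion.

    Rank 1 is the largest delta; exact ties are resolved in favour of the
    factor that comes first in the design.
    """
    if summary.shape[1] < 2:
        raise ValueError("need at least two factors to rank")
    delta = summary.max(axis=0) - summary.min(axis=0)
    order = np.lexsort((np.arange(len(delta)), -delta.to_numpy()))
    rank = pd.Series(0, index=delta.index, dtype=int)
    rank.iloc[order] = np.arange(1, len(delta) + 1)
    return delta, rank


def summarize_levels(
    table: ResponseTable, response: str, criterion: str = "larger"
) -> LevelSummary:
    """Full response table: level means + S/N, deltas and ranks."""
    means = level_means(table, response)
    sn = _level_sn(table, response, criterion)
    d_mean, r_mean = delta_rank(means)
    d_sn, r_sn = delta_rank(sn)
    delta = pd.DataFrame({"mean": d_mean, "sn": d_sn})
    rank = pd.DataFrame({"mean": r_mean, "sn": r_sn})
    return LevelSummary(means, sn, delta, rank,
                        float(table.response(response).mean()))


@dataclass
class OptimalCombination:
    """Best level per factor plus the additive-model prediction there."""

    levels: dict[str, float]  # symbol -> coded level
    predicted: float
    criterion: str
    actual: dict[str, float] | None = None


def optimal_levels(
    summary: LevelSummary,
    criterion: str = "mean",
    factors: tuple[FactorSpec, ...] | None = None,
) -> OptimalCombination:
    """Pick the level with the highest mean (or S/N) for every factor.

    The predicted response is the additive main-effects prediction
    ``grand mean + sum_f (best level mean of f - grand mean)``, evaluated on
    the level *means* regardless of the selection criterion.
    """
    source = summary.means if criterion == "mean" else summary.sn
    best = {sym: float(source[sym].idxmax()) for sym in source.columns}
    pred = summary.grand_mean + sum(
        summary.means.loc[lev, sym] - summary.grand_mean for sym, lev in best.items()
    )
    actual = None
    if factors is not None:
        actual = {f.symbol: f.to_actual(best[f.symbol]) for f in factors}
    return OptimalCombination(best, float(pred), criterion, actual)


@dataclass
class TaguchiAnova:
    """Fixed-effects level ANOVA of an orthogonal-array experiment."""

    table: pd.DataFrame  # rows: per-factor, Residual, Total
    r2: float
    adj_r2: float
    significant: list[str]
    alpha: float


def taguchi_anova(
    table: ResponseTable, response: str, alpha: float = 0.10
) -> TaguchiAnova:
    """Per-factor between-level ANOVA with a pooled residual.

    Each three-level factor contributes a between-level sum of squares on
    2 df; the residual pools everything the main effects leave unexplained.
    Factors with P below ``alpha`` (default 0.10, i.e. confidence above 90%)
    form the significant set carried forward to response-surface work.
    """
    y = table.response(response).to_numpy(dtype=float)
    coded = table.design.coded
    n = len(y)
    gm = y.mean()
    ss_total = float(((y - gm) ** 2).sum())
    rows = []
    ss_factors = 0.0
    df_factors = 0
    for sym in coded.columns:
        ss_f = 0.0
        levels = np.unique(coded[sym].to_numpy())
        for lev in levels:
            g = y[coded[sym].to_numpy() == lev]
            ss_f += len(g) * (g.mean() - gm) ** 2
        df_f = len(levels) - 1
        rows.append([sym, df_f, ss_f])
        ss_factors += ss_f
        df_factors += df_f
    df_resid = (n - 1) - df_factors
    if df_resid <= 0:
        raise SaturatedModelError(
            "main-effects model is saturated (no residual df); "
            "pool weak factors into the error term before testing"
        )
    ss_resid = ss_total - ss_factors
    ms_resid = ss_resid / df_resid
    out = []
    significant = []
    for sym, df_f, ss_f in rows:
        ms_f = ss_f / df_f
        fval = ms_f / ms_resid if ms_resid > 0 else np.inf
        pval = float(_stats.f.sf(fval, df_f, df_resid)) if np.isfinite(fval) else 0.0
        out.append((sym, df_f, ss_f, ms_f, fval, pval))
        if pval < alpha:
            significant.append(sym)
    out.append(("Residual", df_resid, ss_resid, ms_resid, np.nan, np.nan))
    out.append(("Total", n - 1, ss_total, np.nan, np.nan, np.nan))
    anova = pd.DataFrame(out, columns=["source", "df", "SS", "MS", "F", "P"]).set_index("source")
    r2 = ss_factors / ss_total if ss_total > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    return TaguchiAnova(anova, float(r2), float(adj_r2), significant, alpha)
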