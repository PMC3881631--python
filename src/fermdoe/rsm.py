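"""Second-order response-surface modelling for central composite designs.

Fits the full quadratic model

    y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j

by ordinary least squares on the coded design matrix, and provides the
coefficient table (SE, t, two-sided P), the sequential ANOVA with the
linear/square/interaction partition and the lack-of-fit vs pure-error
decomposition of the residual, the R-squared family (plain, adjusted,
prediction via PRESS), adequate precision, and constrained maximization of
the fitted surface (stationary-point analysis with a bounded multi-start
fallback).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as _opt
from scipy import stats as _stats

from .io import ResponseTable

__all__ = [
    "QuadraticModel",
    "SingularDesignError",
    "fit_quadratic",
    "predict",
    "rsm_anova",
    "stationary_point",
    "optimize_bounded",
    "SurfaceOptimum",
]


class SingularDesignError(ValueError):
    """Raised when the quadratic model matrix is rank deficient."""


@dataclass
class QuadraticModel:
    """Full quadratic polynomial in coded factor units.

    ``linear`` has length k, ``quadratic`` length k (pure x_i^2 terms) and
    ``interaction`` length k(k-1)/2 ordered as (0,1), (0,2), ..., (k-2,k-1).
    ``alpha`` optionally records the axial distance of the design the model
    was fitted on (used only to warn on extrapolation).
    """

    symbols: list[str]
    intercept: float
    linear: np.ndarray
    quadratic: np.ndarray
    interaction: np.ndarray
    alpha: float | None = None

    def __post_init__(self) -> None:
        k = len(self.symbols)
        self.linear = np.asarray(self.linear, dtype=float)
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        self.interaction = np.asarray(self.interaction, dtype=float)
        if self.linear.shape != (k,) or self.quadratic.shape != (k,):
            raise ValueError("linear and quadratic coefficient vectors must have length k")
        if self.interaction.shape != (k * (k - 1) // 2,):
            raise ValueError("interaction coefficient vector must have length k(k-1)/2")

    @property
    def k(self) -> int:
        return len(self.symbols)

    @property
    def n_coef(self) -> int:
        return 1 + 2 * self.k + self.k * (self.k - 1) // 2

    def pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i in range(self.k) for j in range(i + 1, self.k)]

    def term_names(self) -> list[str]:
        s = self.symbols
        return (
            ["const"]
            + list(s)
            + [f"{v}^2" for v in s]
            + [f"{s[i]}*{s[j]}" for i, j in self.pairs()]
        )

    def coefficients(self) -> pd.Series:
        vals = np.concatenate(
            [[self.intercept], self.linear, self.quadratic, self.interaction]
        )
        return pd.Series(vals, index=self.term_names(), name="coefficient")

    @classmethod
    def from_terms(cls, terms: dict[str, float], symbols: list[str],
                   alpha: float | None = None) -> "QuadraticModel":
        """Build a model from a flat ``term -> coefficient`` mapping.

        Missing terms default to zero; unknown terms raise.
        """
        k = len(symbols)
        idx = {s: i for i, s in enumerate(symbols)}
        lin = np.zeros(k)
        quad = np.zeros(k)
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
        inter = np.zeros(len(pairs))
        intercept = 0.0
        for name, val in terms.items():
            if name in ("const", "intercept"):
                intercept = val
            elif name in idx:
                lin[idx[name]] = val
            elif name.endswith("^2") and name[:-2] in idx:
                quad[idx[name[:-2]]] = val
            elif "*" in name:
                a, b = name.split("*")
                if a not in idx or b not in idx:
                    raise ValueError(f"unknown symbols in term {name!r}")
                i, j = sorted((idx[a], idx[b]))
                inter[pairs.index((i, j))] = val
            else:
                raise ValueError(f"unknown model term {name!r}")
        return cls(list(symbols), intercept, lin, quad, inter, alpha)

    def b_matrix(self) -> np.ndarray:
        """Symmetric matrix B with B_ii = b_ii and B_ij = b_ij / 2."""
        B = np.diag(self.quadratic).astype(float)
        for (i, j), c in zip(self.pairs(), self.interaction):
            B[i, j] = B[j, i] = c / 2.0
        return B

    def __call__(self, x) -> np.ndarray | float:
        return predict(self, x)


def model_matrix(X: np.ndarray) -> np.ndarray:
    """Expand an (n, k) coded matrix to the quadratic model matrix.

    Column order: 1, linear, pure quadratic, interactions (i<j).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    cols = [np.ones(n)] + [X[:, i] for i in range(k)]
    cols += [X[:, i] ** 2 for i in range(k)]
    cols += [X[:, i] * X[:, j] for i in range(k) for j in range(i + 1, k)]
    return np.stack(cols, axis=1)


def predict(model: QuadraticModel, x) -> np.ndarray | float:
    """Evaluate the quadratic at one coded point or an (n, k) array of them.

    Warns (does not fail) if a coordinate lies outside the design's axial
    range, where the fitted surface is an extrapolation.
    """
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    X = np.atleast_2d(arr)
    if X.shape[1] != model.k:
        raise ValueError(f"expected {model.k} coordinates, got {X.shape[1]}")
    if model.alpha is not None and np.any(np.abs(X) > model.alpha + 1e-12):
        warnings.warn(
            f"evaluating model outside its design region (|x| > {model.alpha})",
            stacklevel=2,
        )
    beta = model.coefficients().to_numpy()
    out = model_matrix(X) @ beta
    return float(out[0]) if single else out


def _aliased_columns(M: np.ndarray, names: list[str]) -> list[str]:
    # pivoted QR: columns pivoted beyond the numerical rank are aliased
    from scipy.linalg import qr

    _, R, piv = qr(M, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(M.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[i] for i in piv[rank:]]


def fit_quadratic(
    table: ResponseTable, response: str
) -> tuple[QuadraticModel, pd.DataFrame]:
    """Fit the full quadratic by OLS; return the model and coefficient stats.

    Standard errors are ``sqrt(sigma2 * (X'X)^-1_jj)`` with ``sigma2`` the
    residual mean square; t is estimate/SE with two-sided P on the residual
    degrees of freedom.
    """
    y = table.response(response).to_numpy(dtype=float)
    X = table.design.coded.to_numpy(dtype=float)
    n, k = X.shape
    M = model_matrix(X)
    p = M.shape[1]
    if n <= p:
        raise ValueError(f"need more runs ({n}) than coefficients ({p})")
    symbols = table.design.symbols
    names = (
        ["const"] + symbols + [f"{s}^2" for s in symbols]
        + [f"{symbols[i]}*{symbols[j]}" for i in range(k) for j in range(i + 1, k)]
    )
    if np.linalg.matrix_rank(M) < p:
        raise SingularDesignError(
            "model matrix is rank deficient; aliased columns: "
            + ", ".join(_aliased_columns(M, names))
        )
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(M.T @ M)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2.0 * _stats.t.sf(np.abs(tvals), dof)
    axial = table.design.coded.loc[table.design.point_type == "axial"]
    alpha = float(np.abs(axial.to_numpy()).max()) if len(axial) else None
    model = QuadraticModel(
        symbols,
        float(beta[0]),
        beta[1 : 1 + k],
        beta[1 + k : 1 + 2 * k],
        beta[1 + 2 * k :],
        alpha,
    )
    stats_df = pd.DataFrame(
        {"estimate": beta, "se": se, "t": tvals, "p": pvals, "df": dof}, index=names
    )
    return model, stats_df


def _sequential_ss(X: np.ndarray, y: np.ndarray, k: int) -> tuple[float, float, float, float]:
    """Sequential (type I) SS for the linear, square and interaction blocks."""
    M = model_matrix(X)
    blocks = [1, 1 + k, 1 + 2 * k, M.shape[1]]
    rss = []
    for stop in blocks:
        beta, *_ = np.linalg.lstsq(M[:, :stop], y, rcond=None)
        r = y - M[:, :stop] @ beta
        rss.append(float(r @ r))
    ss_lin = rss[0] - rss[1]
    ss_sq = rss[1] - rss[2]
    ss_int = rss[2] - rss[3]
    return ss_lin, ss_sq, ss_int, rss[3]


def rsm_anova(model: QuadraticModel, table: ResponseTable, response: str) -> dict:
    """ANOVA of a quadratic fit with lack-of-fit vs pure-error partition.

    Returns a dict with an ANOVA ``table`` (DataFrame indexed by source) and
    the fit summaries ``r2``, ``adj_r2``, ``pred_r2`` (PRESS-based, NaN when
    the fit is saturated) and ``adequate_precision``.  Pure error is pooled
    over groups of replicated design points; when the design has no
    replicates the lack-of-fit rows are omitted and ``has_replicates`` is
    False.
    """
    y = table.response(response).to_numpy(dtype=float)
    X = table.design.coded.to_numpy(dtype=float)
    n, k = X.shape
    p = model.n_coef
    M = model_matrix(X)
    beta = model.coefficients().to_numpy()
    yhat = M @ beta
    resid = y - yhat
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_resid = float(resid @ resid)
    ss_lin, ss_sq, ss_int, _ = _sequential_ss(X, y, k)
    ss_reg = ss_lin + ss_sq + ss_int

    # pure error from replicate groups
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(np.round(X, 10)):
        groups.setdefault(tuple(row), []).append(i)
    ss_pe, df_pe = 0.0, 0
    for idxs in groups.values():
        if len(idxs) > 1:
            g = y[list(idxs)]
            ss_pe += float(((g - g.mean()) ** 2).sum())
            df_pe += len(idxs) - 1
    has_reps = df_pe > 0

    df_reg, df_lin, df_sq = p - 1, k, k
    df_int = k * (k - 1) // 2
    df_resid = n - p
    rows = {
        "Regression": (df_reg, ss_reg),
        "Linear": (df_lin, ss_lin),
        "Square": (df_sq, ss_sq),
        "Interaction": (df_int, ss_int),
        "Residual error": (df_resid, ss_resid),
    }
    if has_reps:
        df_lof = df_resid - df_pe
        ss_lof = ss_resid - ss_pe
        rows["Lack of fit"] = (df_lof, ss_lof)
        rows["Pure error"] = (df_pe, ss_pe)
    rows["Total"] = (n - 1, ss_total)

    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
    tab = []
    for src, (df, ss) in rows.items():
        ms = ss / df if df > 0 else np.nan
        f = pval = np.nan
        if src in ("Regression", "Linear", "Square", "Interaction") and df_resid > 0:
            f = ms / ms_resid
            pval = _stats.f.sf(f, df, df_resid)
        elif src == "Lack of fit" and df_pe > 0 and rows["Lack of fit"][0] > 0:
            ms_pe = ss_pe / df_pe
            if ms_pe > 0:
                f = ms / ms_pe
                pval = _stats.f.sf(f, df, df_pe)
        tab.append((src, df, ss, ms, f, pval))
    anova = pd.DataFrame(
        tab, columns=["source", "df", "SS", "MS", "F", "P"]
    ).set_index("source")

    r2 = 1.0 - ss_resid / ss_total if ss_total > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else np.nan
    # PRESS via the hat-matrix shortcut e_i / (1 - h_ii)
    if df_resid > 0:
        H = M @ np.linalg.inv(M.T @ M) @ M.T
        h = np.diag(H)
        press = float(((resid / (1.0 - h)) ** 2).sum())
        pred_r2 = 1.0 - press / ss_total if ss_total > 0 else np.nan
        adeq = float((yhat.max() - yhat.min()) / np.sqrt(p * ms_resid / n))
    else:
        press, pred_r2, adeq = np.nan, np.nan, np.nan
    return {
        "table": anova,
        "r2": r2,
        "adj_r2": adj_r2,
        "pred_r2": pred_r2,
        "press": press,
        "adequate_precision": adeq,
        "has_replicates": has_reps,
        "ms_residual": ms_resid,
    }


@dataclass
class SurfaceOptimum:
    """A located optimum of a fitted quadratic surface."""

    coded: np.ndarray
    predicted: float
    nature: str  # maximum | minimum | saddle | boundary
    actual: dict[str, float] | None = None


def stationary_point(
    model: QuadraticModel, bounds: list[tuple[float, float]] | None = None
) -> SurfaceOptimum:
    """Canonical analysis: solve grad y = 0 via the symmetric B matrix.

    The nature of the point follows from the eigenvalue signs of B.  If B is
    singular (ridge system) or the stationary point falls outside ``bounds``
    (default: the design box +/- alpha, or +/-2), falls through to
    :func:`optimize_bounded`.
    """
    if bounds is None:
        a = model.alpha if model.alpha is not None else 2.0
        bounds = [(-a, a)] * model.k
    B = model.b_matrix()
    if np.linalg.matrix_rank(B) < model.k or abs(np.linalg.det(B)) < 1e-12:
        warnings.warn("quadratic coefficient matrix is singular (ridge); "
                      "falling back to bounded optimization", stacklevel=2)
        return optimize_bounded(model, bounds)
    xs = -0.5 * np.linalg.solve(B, model.linear)
    eig = np.linalg.eigvalsh(B)
    if np.all(eig < 0):
        nature = "maximum"
    elif np.all(eig > 0):
        nature = "minimum"
    else:
        nature = "saddle"
    inside = all(lo - 1e-9 <= v <= hi + 1e-9 for v, (lo, hi) in zip(xs, bounds))
    if not inside:
        return optimize_bounded(model, bounds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val = float(predict(model, xs))
    return SurfaceOptimum(xs, val, nature)


def optimize_bounded(
    model: QuadraticModel,
    bounds: list[tuple[float, float]],
    maximize: bool = True,
) -> SurfaceOptimum:
    """Global box-constrained optimum of the quadratic by multi-start search.

    L-BFGS-B is started from every box vertex plus the center; for a
    quadratic over a box this reliably reaches the global optimum and serves
    as the deterministic oracle for the genetic algorithm.
    """
    for lo, hi in bounds:
        if not lo < hi:
            raise ValueError(f"invalid bounds ({lo}, {hi})")
    sign = -1.0 if maximize else 1.0
    beta = model.coefficients().to_numpy()

    def f(x):
        return sign * float((model_matrix(x[None, :]) @ beta)[0])

    def grad(x):
        B = model.b_matrix()
        return sign * (model.linear + 2.0 * B @ x)

    import itertools as _it

    starts = [np.array(v, dtype=float) for v in _it.product(*bounds)]
    starts.append(np.array([(lo + hi) / 2.0 for lo, hi in bounds]))
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = _opt.minimize(f, x0, jac=grad, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    x = np.clip(best_x, [b[0] for b in bounds], [b[1] for b in bounds])
    on_boundary = any(
        np.isclose(v, lo, atol=1e-7) or np.isclose(v, hi, atol=1e-7)
        for v, (lo, hi) in zip(x, bounds)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val = float(predict(model, x))
    eig = np.linalg.eigvalsh(model.b_matrix())
    if on_boundary:
        nature = "boundary"
    elif np.all(eig < 0):
        nature = "maximum"
    elif np.all(eig > 0):
        nature = "minimum"
    else:
        nature = "saddle"
    return SurfaceOptimum(x, val, nature)
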