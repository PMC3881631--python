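"""Synthetic response generators with known ground truth.

Two data-generating processes mirror the structures the analysis modules
assume: an additive main-effects model on an orthogonal array (screening
regime) and a full quadratic surface on a CCD (response-surface regime),
each with i.i.d. Gaussian noise added at the design points.  Replicate
means are simulated directly, i.e. sigma is the standard deviation of the
reported per-run mean.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import DesignMatrix
from .io import ResponseTable
from .rsm import QuadraticModel, predict

__all__ = ["AdditiveTruth", "QuadraticTruth", "simulate_taguchi", "simulate_ccd"]


@dataclass
class AdditiveTruth:
    """Additive main-effects ground truth for an orthogonal array.

    ``effects`` maps each factor symbol to its three per-level effects
    (ordered by coded level, low to high); the response at a run is
    ``grand_mean + sum_f effect_f(level_f) + N(0, sigma^2)``.
    """

    grand_mean: float
    effects: dict[str, tuple[float, float, float]]
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for sym, eff in self.effects.items():
            if len(eff) != 3:
                raise ValueError(f"factor {sym!r}: need exactly 3 level effects")


@dataclass
class QuadraticTruth:
    """Quadratic-surface ground truth for a CCD."""

    model: QuadraticModel
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def simulate_taguchi(
    truth: AdditiveTruth, design: DesignMatrix, response: str = "y"
) -> ResponseTable:
    """Simulate per-run replicate-mean responses on an orthogonal array."""
    missing = set(truth.effects) - set(design.symbols)
    if missing:
        raise ValueError(f"effects given for unknown factors: {sorted(missing)}")
    coded = design.coded
    rng = np.random.default_rng(truth.seed)
    y = np.full(design.n_runs, truth.grand_mean, dtype=float)
    for sym, eff in truth.effects.items():
        levels = np.sort(np.unique(coded[sym].to_numpy()))
        if len(levels) != 3:
            raise ValueError(f"factor {sym!r} does not have 3 levels in this design")
        lut = dict(zip(levels, eff))
        y += np.array([lut[v] for v in coded[sym]])
    y = y + rng.normal(0.0, truth.sigma, size=design.n_runs)
    resp = pd.DataFrame({response: y, f"{response}_sd": truth.sigma}, index=coded.index)
    return ResponseTable(design, resp)


def simulate_ccd(
    truth: QuadraticTruth, design: DesignMatrix, response: str = "y"
) -> ResponseTable:
    """Simulate responses from a quadratic surface at the design points."""
    if truth.model.k != design.k:
        raise ValueError(
            f"model has {truth.model.k} factors but design has {design.k}"
        )
    rng = np.random.default_rng(truth.seed)
    mu = predict(truth.model, design.coded.to_numpy(dtype=float))
    y = mu + rng.normal(0.0, truth.sigma, size=design.n_runs)
    resp = pd.DataFrame(
        {response: y, f"{response}_sd": truth.sigma}, index=design.coded.index
    )
    return ResponseTable(design, resp)
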