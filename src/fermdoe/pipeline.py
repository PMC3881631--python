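"""End-to-end screening -> response surface -> ANN-GA pipeline.

Chains the three optimization stages the study performs: Taguchi screening
of the full factor set (significance at P < alpha against the pooled
main-effects residual), a quadratic response-surface fit with bounded
optimization on the follow-up CCD, and the ANN-surrogate + GA hybrid on the
same CCD table.  The result bundle includes a method-comparison table
(screening optimum, RSM optimum, ANN-GA optimum with their predicted
responses).  Given the same config and master seed the bundle is
byte-identical when serialized.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annga, rsm, taguchi
from .io import ResponseTable, write_response_table

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline", "save_report"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated, fully serializable settings for one pipeline run."""

    response: str
    screening_alpha: float = 0.10
    ccd_bounds: tuple[float, float] = (-2.0, 2.0)
    ann_hidden: tuple[int, ...] = (10,)
    ann_epochs: int = 20000
    ann_restarts: int = 10
    ga_pop_size: int = 50
    ga_generations: int = 1000
    ga_p_crossover: float = 0.95
    ga_p_mutation: float = 0.04
    ga_bits_per_var: int = 5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.screening_alpha < 1.0:
            raise ValueError("screening_alpha must lie in (0, 1)")
        lo, hi = self.ccd_bounds
        if not lo < hi:
            raise ValueError("ccd_bounds must satisfy low < high")
        if self.ann_epochs < 1 or self.ann_restarts < 1:
            raise ValueError("ann_epochs and ann_restarts must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["ann_hidden"] = tuple(d["ann_hidden"])
        d["ccd_bounds"] = tuple(d["ccd_bounds"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def run_full_pipeline(
    screening_table: ResponseTable,
    ccd_table: ResponseTable,
    cfg: PipelineConfig,
) -> dict:
    """Run screening, RSM and ANN-GA; return the full result bundle.

    The screening stage runs on ``screening_table``; the RSM and ANN-GA
    stages run on ``ccd_table`` (the follow-up design over the factors the
    screen retained).  Any stage failure raises :class:`PipelineError`
    naming the stage.
    """
    out: dict = {"config": cfg, "config_hash": cfg.config_hash(),
                 "seeds": {"master": cfg.master_seed}}
    try:
        summary = taguchi.summarize_levels(screening_table, cfg.response)
        anova = taguchi.taguchi_anova(screening_table, cfg.response,
                                      alpha=cfg.screening_alpha)
        combo = taguchi.optimal_levels(summary, "mean",
                                       factors=screening_table.design.factors)
        out["screening"] = {
            "summary": summary,
            "anova": anova,
            "significant": anova.significant,
            "optimum": combo,
        }
    except Exception as e:  # noqa: BLE001 - stage-named rethrow
        raise PipelineError(f"screening stage failed: {e}") from e

    try:
        model, coef = rsm.fit_quadratic(ccd_table, cfg.response)
        anova_rsm = rsm.rsm_anova(model, ccd_table, cfg.response)
        bounds = [cfg.ccd_bounds] * model.k
        opt = rsm.optimize_bounded(model, bounds)
        actual = None
        if ccd_table.design.factors is not None:
            actual = {
                f.symbol: f.to_actual(float(v))
                for f, v in zip(ccd_table.design.factors, opt.coded)
            }
        opt.actual = actual
        out["rsm"] = {"model": model, "coefficients": coef,
                      "anova": anova_rsm, "optimum": opt}
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"rsm stage failed: {e}") from e

    try:
        ga_seed_pool = np.random.SeedSequence(cfg.master_seed)
        cfg_ga = annga.GAConfig(
            n_vars=ccd_table.design.k,
            bits_per_var=cfg.ga_bits_per_var,
            pop_size=cfg.ga_pop_size,
            max_generations=cfg.ga_generations,
            p_crossover=cfg.ga_p_crossover,
            p_mutation=cfg.ga_p_mutation,
            bounds=[cfg.ccd_bounds] * ccd_table.design.k,
            seed=int(ga_seed_pool.generate_state(1)[0] % (2**31)),
        )
        hybrid = annga.annga_pipeline(
            ccd_table, cfg.response,
            bounds=[cfg.ccd_bounds] * ccd_table.design.k,
            master_seed=cfg.master_seed,
            n_restarts=cfg.ann_restarts,
            hidden=cfg.ann_hidden,
            epochs=cfg.ann_epochs,
            ga_config=cfg_ga,
        )
        out["annga"] = hybrid
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"annga stage failed: {e}") from e

    rows = []
    sc = out["screening"]["optimum"]
    rows.append(("screening", json.dumps(sc.levels, sort_keys=True), sc.predicted))
    ro = out["rsm"]["optimum"]
    rows.append(("rsm", json.dumps({s: round(float(v), 4) for s, v in
                                    zip(ccd_table.design.symbols, ro.coded)},
                                   sort_keys=True), ro.predicted))
    rows.append(("ann-ga", json.dumps({s: round(float(v), 4) for s, v in
                                       zip(ccd_table.design.symbols,
                                           hybrid["best_coded"])},
                                      sort_keys=True), hybrid["best_predicted"]))
    out["comparison"] = pd.DataFrame(
        rows, columns=["method", "composition_coded", "predicted_response"]
    )
    return out


def save_report(bundle: dict, outdir: str | Path) -> None:
    """Write the pipeline bundle as deterministic CSV/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg: PipelineConfig = bundle["config"]
    (outdir / "config.json").write_text(cfg.to_json() + "\n", encoding="utf-8")
    sc = bundle["screening"]
    sc["summary"].means.to_csv(outdir / "screening_level_means.csv")
    sc["summary"].sn.to_csv(outdir / "screening_level_sn.csv")
    sc["anova"].table.to_csv(outdir / "screening_anova.csv")
    rs = bundle["rsm"]
    rs["coefficients"].to_csv(outdir / "rsm_coefficients.csv")
    rs["anova"]["table"].to_csv(outdir / "rsm_anova.csv")
    bundle["comparison"].to_csv(outdir / "comparison.csv", index=False)
    traj = bundle["annga"]["ga"].trajectory
    pd.DataFrame({"generation": range(len(traj)), "best_fitness": traj}).to_csv(
        outdir / "annga_trajectory.csv", index=False
    )
    meta = {
        "config_hash": bundle["config_hash"],
        "master_seed": cfg.master_seed,
        "significant_factors": bundle["screening"]["significant"],
    }
    (outdir / "run_log.json").write_text(
        json.dumps(meta, sort_keys=True) + "\n", encoding="utf-8"
    )
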