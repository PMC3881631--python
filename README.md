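# fermdoe

Design-of-experiments toolkit for fermentation medium optimization, built
around the three-stage workflow used to maximize microbial enzyme yields:

1. **Taguchi L27 orthogonal-array screening** — level means, signal-to-noise
   ratios (dB), delta/rank factor ordering, and a main-effects ANOVA that
   retains factors significant at 90% confidence (P < 0.10);
2. **Central composite design (CCD) / response-surface methodology (RSM)** —
   ordinary-least-squares fit of the full second-order model in coded units,

   y = β₀ + Σᵢ βᵢxᵢ + Σᵢ βᵢᵢxᵢ² + Σᵢ<ⱼ βᵢⱼxᵢxⱼ + ε,

   with coefficient t-tests, sequential ANOVA (linear/square/interaction),
   lack-of-fit vs pure-error partition, R²/adj R²/pred R² (PRESS), adequate
   precision, canonical (stationary-point) analysis and bounded optimization;
3. **ANN-GA hybrid** — a small feed-forward backpropagation network
   (default 4-10-1, sigmoid hidden units, linear output, min-max scaling)
   trained as a surrogate of the response surface and maximized by a
   binary-coded genetic algorithm (population 50, 20-bit chromosomes,
   crossover 0.95, per-bit mutation 0.04, roulette selection, elitism).

It also ships deterministic bioprocess helpers (enzyme activity in U/mL from
absorbance via a molar extinction coefficient; pectin yield %), synthetic
data generators with known ground truth for every stage, and the bundled
tables of a published polygalacturonase (PGase) optimization study —
including a banana-fiber pectin-hydrolysis CCD — transcribed verbatim with
their internal inconsistencies flagged, never corrected
(`fermdoe.datasets`).

Intended users: bioprocess engineers and statisticians who want a scripted,
reproducible alternative to point-and-click DoE software for screening and
optimizing fermentation media.

## Worked example

Fit and optimize the bundled 30-run PGase CCD:

```python
from fermdoe import datasets, rsm

table = datasets.load_ccd_pgase()          # 30 runs, factors x1 x2 x3 x6
model, coef = rsm.fit_quadratic(table, "PGase")
anova = rsm.rsm_anova(model, table, "PGase")
print(round(anova["table"].loc["Pure error", "SS"], 3),
      int(anova["table"].loc["Pure error", "df"]))
opt = rsm.optimize_bounded(model, [(-2.0, 2.0)] * 4)
print(round(opt.predicted, 2), [round(v, 2) for v in opt.coded])
```

prints

```
0.913 5
33.02 [-1.22, 2.0, -2.0, -2.0]
```

i.e. the six center replicates contribute a pure-error sum of squares of
0.913 on 5 degrees of freedom, and the fitted surface attains its maximum
predicted activity of 33.02 U/mL on the boundary of the coded design box
(high bactopeptone, low MgCl₂ and NaCl, slightly reduced orange peel).

The four numbered drivers under `analysis/` run the complete story —
screening, RSM, ANN-GA and the pectin-hydrolysis CCD — and write their
tables under `results/`:

```sh
python analysis/01_taguchi_screen.py
python analysis/02_rsm_pgase.py
python analysis/03_annga_optimize.py
python analysis/04_pectin_hydrolysis.py
```

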