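# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions. All quantitative statements
here are recomputed by the test suite or the analysis drivers; nothing is
asserted that the code does not itself produce.

## Designs and coded units

All model fitting is done in **coded units**. Each factor carries an
explicit coded-level → actual-value map (`FactorSpec`): three levels
{−1, 0, +1} for screening factors, five levels {−2, −1, 0, +1, +2} for CCD
factors. Actual spacings in the bundled tables are asymmetric (e.g. NaCl
0.60/0.70/0.80/1.00/1.10 w/%), so coded↔actual conversion is piecewise
linear between adjacent tabulated levels, exact at the tabulated levels and
round-trip consistent to 1e-12. Because of this asymmetry an "actual-units"
polynomial is not a simple affine re-expression of the coded one; the
package deliberately fits, stores and optimizes only coded-unit models and
converts the final optimum point to actual units.

The **L27 orthogonal array** is generated over GF(3) from basis columns
*a* (changes every 9 runs), *b* (every 3) and *c* (every run) with derived
columns a+b, 2a+b and a+c (mod 3), assigned in the order
(a, b, a+b, 2a+b, c, a+c). This assignment was chosen because it reproduces
the bundled screening design; the source table does not state its
column-to-factor assignment, so the mapping is inferred from the printed
matrix. Every column is balanced (each level ×9) and every column pair
contains each ordered level pair exactly 3 times. The bundled table's x6
column deviates from this (and from *any* linear GF(3) column) in six cells
— runs 20/21, 23/24 and 26/27 have pairwise-swapped levels, which breaks
orthogonality between x5 and x6 in the printed design. The generator emits
the orthogonal column; the dataset keeps the printed values with the cells
flagged (`datasets.TAGUCHI_ANOMALOUS_CELLS`).

The **CCD** is built in standard order: 2^k factorial points (first factor
fastest), 2k axial points one factor at a time (−α before +α), then the
center replicates. α = (2^k)^¼ gives rotatability (α = 2 for k = 4).
Run order is deterministic; no randomization order is modelled.

## Taguchi screening

Level summaries use the standard S/N forms (dB): larger-is-better
−10·log10(mean(1/y²)), smaller-is-better −10·log10(mean(y²)),
nominal-is-best 10·log10(mean²/variance). The bundled study's printed S/N
values (≈51–58 dB for responses of 11–16 U/mL) match none of these forms
and are treated as non-reproducible; only rank behaviour is examined.

Delta = max − min over the three level summaries; rank 1 is the largest
delta with ties broken by design-column order. The optimal combination
takes each factor's best level (by level means by default — the
reproducible column in the bundled tables; S/N optional) and predicts the
response additively: grand mean + Σ(best level mean − grand mean). On
noise-free additive data this prediction is exact.

The significance screen is a fixed-effects ANOVA: each three-level factor
contributes a between-level SS on 2 df, the residual pools the rest
(14 df for six factors on an L27), and factors pass at P < 0.10 (the
"90% confidence" convention). A saturated main-effects model (no residual
df) raises an explicit error instructing factor pooling rather than
silently testing against zero. On the bundled 27-run table the screen
retains **no** factor at P < 0.10 (main effects explain only ~34% of the
total SS); the printed screening ANOVA is arithmetically incompatible with
its own data table, so the empty screen is reported as-is.

## Response-surface modelling

`fit_quadratic` solves the OLS problem on the model matrix
[1, xᵢ, xᵢ², xᵢxⱼ] via `numpy.linalg.lstsq`; tests verify equivalence with
a normal-equations solve and with statsmodels OLS to 1e-8 on 50 seeded
data sets. SEⱼ = √(σ̂²(XᵀX)⁻¹ⱼⱼ) with σ̂² the residual mean square;
coefficient P values are two-sided t on the residual df and are reported
raw (no multiplicity adjustment), with 0.05 as the conventional reporting
threshold. Rank-deficient model matrices raise an error naming the aliased
columns (pivoted QR).

The ANOVA partitions the regression SS sequentially (Type I) into Linear
(k terms), Square (k), and Interaction (k(k−1)/2) blocks — on an
orthogonal CCD this matches the usual adjusted partition. Pure error sums
squared deviations within replicate groups (the center points); lack of
fit is residual − pure error, tested against the pure-error MS.
pred R² = 1 − PRESS/SS_total with PRESS computed by the hat-matrix
shortcut Σ(eᵢ/(1−hᵢᵢ))²; a test confirms equality with literal
leave-one-out refits. Adequate precision uses the Design-Expert-style form
(max ŷ − min ŷ)/√(p·MS_res/n) with the conventional >4 adequacy rule; the
bundled study's printed value is recorded but not asserted because its
formula provenance is uncertain.

`stationary_point` performs canonical analysis (solve ∇ŷ = 0 via the
symmetric B matrix, nature from eigenvalue signs) and falls through to
`optimize_bounded` for ridge systems or exterior stationary points.
`optimize_bounded` maximizes the quadratic over the box by multi-start
L-BFGS-B from all box vertices plus the center — exhaustive for a
quadratic — and serves as the deterministic oracle for the GA; a 41⁴
dense-grid test confirms it.

## ANN surrogate and genetic algorithm

The conceptual neuron is the classic threshold unit O = g(Σwᵢxᵢ − t) with
g the unit step; training requires gradients, so hidden layers use the
logistic sigmoid and the output neuron is linear. Default architecture is
one hidden layer of 10 neurons (4-10-1 for a four-factor table) — the
smallest faithful reading of a "ten neurons, three layers (input, hidden,
output)" description — with multi-hidden-layer variants available through
the `hidden` tuple. Inputs and targets are min-max scaled to [0, 1]; MSE
and MAE are reported in scaled space, R² in original units. Training is
full-batch gradient descent with momentum 0.9 and learning rate 0.5 for
20 000 epochs; on the bundled 30-run CCD every one of ten seeded restarts
reaches a training R² of 0.991–0.995. These defaults intentionally allow
the 61-parameter network to overfit the 30-point table — the surrogate
regime the workflow calls for — so the training R² is a goodness-of-fit
summary, not a generalization estimate.

The GA encodes each variable in a 5-bit field (20-bit chromosome for four
variables), decoding b ∈ [0, 31] linearly onto [xᵢᴸ, xᵢᵁ]; defaults are
population 50, ≤1000 generations, crossover 0.95 (single-point), per-bit
mutation 0.04, roulette-wheel selection on min-shifted fitness with a
uniform fallback when the population is fitness-flat, elitism 1 (making
the best-so-far trajectory provably non-decreasing), and a stagnation stop
after 50 generations without improvement. Default bounds are the coded
design box [−2, 2]⁴. Seeds: a master seed (`numpy.random.SeedSequence`)
derives the restart seeds and the GA seed, so the whole hybrid pipeline is
bit-reproducible.

## Assay calculations

Activity: U/mL = (A/ε)·10⁶·(V_rxn/V_enz)/t, taking the extinction
coefficient in the assay's printed units (M⁻¹ mL⁻¹) at face value with a
1 cm path length absorbed into ε; 10⁶ converts mol mL⁻¹ to μmol mL⁻¹. The
unit definition (1 U releases 1 μmol mL⁻¹ min⁻¹) makes both operations
linear in their numerator, which the tests exercise. Pectin yield is
100 × extracted mass / sample mass, unit-invariant under a common mass
scale; an extracted mass exceeding the sample warns (likely unit error)
but still returns the value.

## Synthetic data

`simulate_taguchi` draws y = grand mean + Σ effects + N(0, σ²) on the L27;
`simulate_ccd` draws y = quadratic(x) + N(0, σ²) at the CCD points. Noise
is i.i.d. homoscedastic Gaussian on the *replicate mean* (the bundled
tables report triplicate means with small, roughly constant sds, which
this mirrors); replicate-level simulation and heteroscedasticity are not
modelled. What passing tests show is therefore calibration of the
estimators under the models' own assumptions (exact recovery at σ = 0,
RMSE matching √(σ²(XᵀX)⁻¹ⱼⱼ) to within 15% at σ ∈ {0.1, 0.5, 1.0});
they do not validate the quadratic or additive model against real
fermentation behaviour, nor do they capture run-order effects, batch
drift, or measurement-scale nonlinearity.

## Numerical conventions and problem sizes

Comparisons against two-decimal printed values use ±0.01 absolute (±0.001
where three decimals are printed). ANOVA additivity identities are
enforced to 1e-9; OLS dual-route equivalence to 1e-8; coded↔actual round
trips to 1e-12. Simulation-based checks use 100–200 replicates and the
grid oracle 41 points per axis — sizes chosen so the full suite exercises
every stochastic claim while remaining quick to run routinely. GA
consistency-in-the-limit is checked at 16 bits/variable against the
bounded-quadratic optimum.

## Known limitations

* The bundled tables contain documented misprints (flagged in
  `fermdoe.datasets`); analyses on them reproduce the reproducible cells
  and report, rather than hide, the rest.
* Only the single L27 column assignment above is supported (no general
  orthogonal-array catalogue), and CCDs are unblocked and unfractionated.
* No desirability functions or multi-response optimization; optimization
  is single-response over a box.
* The GA is a plain generational scheme; no alternative metaheuristics.
* The package exposes a library + numbered-script interface; there is no
  console-script CLI, as the intended use is scripted analyses.
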