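"""ANN surrogate + genetic-algorithm hybrid optimizer.

A small feed-forward network is trained by full-batch backpropagation on a
response-surface data set (inputs and target min-max scaled to [0, 1]) and
then used as the fitness function of a binary-coded genetic algorithm that
searches the design box for the medium composition maximizing the predicted
response.

The conceptual neuron is a threshold unit, output ``g(sum_i w_i x_i - t)``
with ``g`` the unit step (1 when the argument is non-negative); training
uses the differentiable logistic sigmoid in the hidden layer(s) and a
linear output neuron so that gradients exist.  Every stochastic component
takes an explicit seed; a master seed derives per-component seeds, so a run
is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ResponseTable

__all__ = [
    "NeuralSurrogate",
    "TrainReport",
    "GAConfig",
    "GAResult",
    "step",
    "sigmoid",
    "forward",
    "train_backprop",
    "ga_optimize",
    "annga_pipeline",
]


def step(z):
    """Unit step: 1 when the argument is non-negative, else 0."""
    return (np.asarray(z, dtype=float) >= 0).astype(float)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass
class NeuralSurrogate:
    """Feed-forward net with per-neuron thresholds and min-max scaling.

    ``weights[l]`` maps layer l to l+1; ``thresholds[l]`` are subtracted
    from the weighted sums (the classic threshold-unit convention), so a
    layer computes ``g(W.T a - t)``.  Hidden activations are sigmoid, the
    output neuron is linear.  ``x_min``/``x_max``/``y_min``/``y_max`` are
    the training-data scaling parameters; the forward pass accepts inputs in
    original units and returns the response in original units.
    """

    weights: list[np.ndarray]
    thresholds: list[np.ndarray]
    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float
    seed: int | None = None

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def scale_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_min) / (self.x_max - self.x_min)

    def unscale_y(self, ys: np.ndarray) -> np.ndarray:
        return ys * (self.y_max - self.y_min) + self.y_min


def forward(net: NeuralSurrogate, x, scaled: bool = False):
    """Evaluate the network at one point or an (n, k) array of points.

    With ``scaled=True`` the input is taken to be already in [0, 1] space
    and the scaled output is returned; otherwise original units in and out.
    """
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    X = np.atleast_2d(arr)
    if X.shape[1] != net.weights[0].shape[0]:
        raise ValueError(
            f"expected {net.weights[0].shape[0]} inputs, got {X.shape[1]}"
        )
    a = X if scaled else net.scale_x(X)
    n_layers = len(net.weights)
    for l, (W, t) in enumerate(zip(net.weights, net.thresholds)):
        z = a @ W - t
        a = z if l == n_layers - 1 else sigmoid(z)  # linear output neuron
    out = a.ravel()
    if not scaled:
        out = net.unscale_y(out)
    return float(out[0]) if single else out


@dataclass
class TrainReport:
    epochs: int
    mse: float        # scaled space
    mae: float        # scaled space
    r2: float         # original units
    converged: bool


def train_backprop(
    X: np.ndarray,
    y: np.ndarray,
    hidden: tuple[int, ...] = (10,),
    lr: float = 0.5,
    momentum: float = 0.9,
    epochs: int = 20000,
    tol: float = 0.0,
    seed: int = 0,
) -> tuple[NeuralSurrogate, TrainReport]:
    """Train a sigmoid-hidden / linear-output net by gradient descent.

    Inputs and targets are min-max scaled to [0, 1]; weights and thresholds
    start uniform on [-0.5, 0.5] from ``seed``, so identical calls are
    bit-identical.  Training stops early once the scaled MSE drops below
    ``tol`` (0 disables).  Raises on divergence (non-finite loss).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(X) < 1 or len(X) != len(y):
        raise ValueError("need at least one (x, y) training pair")
    rng = np.random.default_rng(seed)
    x_min, x_max = X.min(axis=0), X.max(axis=0)
    span = np.where(x_max > x_min, x_max - x_min, 1.0)
    Xs = (X - x_min) / span
    y_min, y_max = float(y.min()), float(y.max())
    yspan = (y_max - y_min) or 1.0
    Ys = ((y - y_min) / yspan)[:, None]

    sizes = [X.shape[1], *hidden, 1]
    Ws = [rng.uniform(-0.5, 0.5, (sizes[i], sizes[i + 1])) for i in range(len(sizes) - 1)]
    Ts = [rng.uniform(-0.5, 0.5, sizes[i + 1]) for i in range(len(sizes) - 1)]
    vW = [np.zeros_like(w) for w in Ws]
    vT = [np.zeros_like(t) for t in Ts]
    n = len(Xs)
    last = len(Ws) - 1
    mse = np.inf
    converged = False
    ep = 0
    with np.errstate(over="ignore", invalid="ignore"):  # divergence caught below
        for ep in range(1, epochs + 1):
            acts = [Xs]
            a = Xs
            for l, (W, t) in enumerate(zip(Ws, Ts)):
                z = a @ W - t
                a = z if l == last else sigmoid(z)
                acts.append(a)
            err = acts[-1] - Ys
            mse = float((err**2).mean())
            if not np.isfinite(mse):
                raise FloatingPointError(
                    "training diverged (non-finite loss); try a smaller learning rate"
                )
            if tol > 0 and mse < tol:
                converged = True
                break
            delta = err  # linear output
            for l in range(last, -1, -1):
                gW = acts[l].T @ delta / n
                gT = -delta.mean(axis=0)  # thresholds enter with a minus sign
                if l > 0:  # propagate through the pre-update weights
                    delta = (delta @ Ws[l].T) * acts[l] * (1.0 - acts[l])
                vW[l] = momentum * vW[l] - lr * gW
                vT[l] = momentum * vT[l] - lr * gT
                Ws[l] = Ws[l] + vW[l]
                Ts[l] = Ts[l] + vT[l]
    net = NeuralSurrogate(Ws, Ts, x_min, x_min + span, y_min, y_min + yspan, seed)
    pred_s = forward(net, Xs, scaled=True)
    errs = pred_s - Ys.ravel()
    yp = net.unscale_y(pred_s)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - yp) ** 2).sum()) / sst if sst > 0 else np.nan
    report = TrainReport(ep, float((errs**2).mean()), float(np.abs(errs).mean()),
                         r2, converged)
    return net, report


@dataclass
class GAConfig:
    """Binary-coded GA settings (defaults follow the study configuration)."""

    n_vars: int = 4
    bits_per_var: int = 5
    pop_size: int = 50
    max_generations: int = 1000
    p_crossover: float = 0.95
    p_mutation: float = 0.04
    bounds: list[tuple[float, float]] = field(
        default_factory=lambda: [(-2.0, 2.0)] * 4
    )
    elitism: int = 1
    stagnation: int = 50
    seed: int = 0

    @property
    def string_length(self) -> int:
        return self.n_vars * self.bits_per_var

    def __post_init__(self) -> None:
        if len(self.bounds) != self.n_vars:
            raise ValueError("bounds must give one (low, high) pair per variable")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bounds ({lo}, {hi})")
        for p in (self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GAResult:
    best_point: np.ndarray
    best_fitness: float
    trajectory: np.ndarray  # best-so-far fitness per generation
    generations: int


def decode(chrom: np.ndarray, cfg: GAConfig) -> np.ndarray:
    """Decode a binary chromosome into real variables within the bounds.

    Each variable's bit field b in [0, 2^bits - 1] maps linearly to
    ``low + b * (high - low) / (2^bits - 1)``.
    """
    bits = chrom.reshape(cfg.n_vars, cfg.bits_per_var)
    weights = 2 ** np.arange(cfg.bits_per_var - 1, -1, -1)
    ints = bits @ weights
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    return lo + ints * (hi - lo) / (2**cfg.bits_per_var - 1)


def ga_optimize(fitness, cfg: GAConfig) -> GAResult:
    """Maximize ``fitness(decoded_point)`` with a binary-coded GA.

    Roulette-wheel selection on min-shifted fitness (uniform fallback when
    the population is fitness-flat), single-point crossover, per-bit
    mutation and elitism preserving the best individual.  Stops at
    ``max_generations`` or after ``stagnation`` generations without
    improvement.  With elitism >= 1 the best-so-far trajectory is
    non-decreasing.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.string_length
    pop = rng.integers(0, 2, size=(cfg.pop_size, L))

    def evaluate(p):
        return np.array([float(fitness(decode(ind, cfg))) for ind in p])

    fit = evaluate(pop)
    best_i = int(np.argmax(fit))
    best_chrom, best_fit = pop[best_i].copy(), float(fit[best_i])
    traj = [best_fit]
    stale = 0
    gen = 0
    for gen in range(1, cfg.max_generations + 1):
        shifted = fit - fit.min()
        total = shifted.sum()
        if total <= 0:
            probs = np.full(cfg.pop_size, 1.0 / cfg.pop_size)  # flat fitness
        else:
            probs = shifted / total
        parents = pop[rng.choice(cfg.pop_size, size=cfg.pop_size, p=probs)]
        children = parents.copy()
        for i in range(0, cfg.pop_size - 1, 2):
            if rng.random() < cfg.p_crossover:
                cut = int(rng.integers(1, L))
                children[i, cut:], children[i + 1, cut:] = (
                    parents[i + 1, cut:].copy(),
                    parents[i, cut:].copy(),
                )
        mask = rng.random(children.shape) < cfg.p_mutation
        children = np.where(mask, 1 - children, children)
        cfit = evaluate(children)
        if cfg.elitism > 0:
            worst = np.argsort(cfit)[: cfg.elitism]
            elite = np.argsort(fit)[::-1][: cfg.elitism]
            children[worst] = pop[elite]
            cfit[worst] = fit[elite]
        pop, fit = children, cfit
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit = float(fit[gen_best])
            best_chrom = pop[gen_best].copy()
            stale = 0
        else:
            stale += 1
        traj.append(best_fit)
        if cfg.stagnation and stale >= cfg.stagnation:
            break
    return GAResult(decode(best_chrom, cfg), best_fit, np.array(traj), gen)


def annga_pipeline(
    table: ResponseTable,
    response: str,
    bounds: list[tuple[float, float]] | None = None,
    master_seed: int = 0,
    n_restarts: int = 10,
    hidden: tuple[int, ...] = (10,),
    epochs: int = 20000,
    ga_config: GAConfig | None = None,
) -> dict:
    """Train the surrogate (best of ``n_restarts`` seeds) and run the GA.

    Per-component seeds are derived from ``master_seed``, so the whole
    pipeline is deterministic.  Returns the trained net, its training
    report, the GA result in coded units, and the optimum converted to
    actual units when the table carries factor specs.
    """
    X = table.design.coded.to_numpy(dtype=float)
    y = table.response(response).to_numpy(dtype=float)
    k = X.shape[1]
    if bounds is None:
        a = float(np.abs(X).max())
        bounds = [(-a, a)] * k
    ss = np.random.SeedSequence(master_seed)
    train_seeds, ga_seed = ss.spawn(2)
    seeds = train_seeds.generate_state(n_restarts) % (2**31)
    best_net, best_rep = None, None
    for s in seeds:
        net, rep = train_backprop(X, y, hidden=hidden, epochs=epochs, seed=int(s))
        if best_rep is None or rep.r2 > best_rep.r2:
            best_net, best_rep = net, rep
    cfg = ga_config or GAConfig(
        n_vars=k, bounds=bounds, seed=int(ga_seed.generate_state(1)[0] % (2**31))
    )
    result = ga_optimize(lambda p: forward(best_net, p), cfg)
    out = {"net": best_net, "train_report": best_rep, "ga": result,
           "best_coded": result.best_point, "best_predicted": result.best_fitness}
    if table.design.factors is not None:
        out["best_actual"] = {
            f.symbol: f.to_actual(float(v))
            for f, v in zip(table.design.factors, result.best_point)
        }
    return out
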