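"""Neural surrogate training and genetic-algorithm optimization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fermdoe import annga, rsm
from fermdoe.annga import GAConfig, NeuralSurrogate, decode, forward, ga_optimize, step
from fermdoe.designs import build_ccd
from fermdoe.synthetic import QuadraticTruth, simulate_ccd

from conftest import random_quadratic


def _identity_net(weights, thresholds, k):
    return NeuralSurrogate(weights, thresholds, np.zeros(k), np.ones(k), 0.0, 1.0)


class TestForward:
    def test_zero_net_outputs_zero(self):
        net = _identity_net([np.zeros((3, 2)), np.zeros((2, 1))],
                            [np.zeros(2), np.zeros(1)], 3)
        assert forward(net, np.array([0.2, 0.5, 0.9]), scaled=True) == 0.0

    def test_step_threshold_unit(self):
        # single neuron, w=1, t=0: output 1 when the argument is non-negative
        assert step(np.array([1.0 * 0.5 - 0.0])) == 1.0
        assert step(np.array([-0.1])) == 0.0

    def test_hand_built_2_2_1_sigmoid_net(self):
        W1 = np.array([[0.3, -0.2], [0.5, 0.1]])
        t1 = np.array([0.1, -0.4])
        W2 = np.array([[1.5], [-0.7]])
        t2 = np.array([0.2])
        net = _identity_net([W1, W2], [t1, t2], 2)
        x = np.array([0.6, 0.9])
        h = 1.0 / (1.0 + np.exp(-(x @ W1 - t1)))
        expect = (h @ W2 - t2).item()
        assert forward(net, x, scaled=True) == pytest.approx(expect, abs=1e-12)

    def test_dimension_mismatch(self):
        net = _identity_net([np.zeros((3, 2)), np.zeros((2, 1))],
                            [np.zeros(2), np.zeros(1)], 3)
        with pytest.raises(ValueError):
            forward(net, np.zeros(2))

    def test_pure_function(self):
        net, _ = annga.train_backprop(np.linspace(0, 1, 8)[:, None],
                                      np.linspace(0, 1, 8), epochs=200, seed=0)
        x = np.array([0.37])
        assert forward(net, x) == forward(net, x)


class TestTraining:
    def test_linear_toy_converges(self):
        x = np.linspace(0, 1, 20)[:, None]
        net, rep = annga.train_backprop(x, x.ravel(), hidden=(4,), epochs=5000, seed=0)
        assert rep.mse < 1e-3

    def test_bit_identical_given_seed(self):
        x = np.linspace(0, 1, 10)[:, None]
        y = np.sin(x).ravel()
        n1, r1 = annga.train_backprop(x, y, epochs=500, seed=42)
        n2, r2 = annga.train_backprop(x, y, epochs=500, seed=42)
        assert all(np.array_equal(a, b) for a, b in zip(n1.weights, n2.weights))
        assert all(np.array_equal(a, b) for a, b in zip(n1.thresholds, n2.thresholds))
        assert r1.mse == r2.mse

    def test_divergence_raises(self):
        x = np.linspace(0, 1, 10)[:, None]
        with pytest.raises(FloatingPointError, match="learning rate"):
            annga.train_backprop(x, x.ravel(), lr=500.0, epochs=5000, seed=0)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            annga.train_backprop(np.zeros((0, 2)), np.zeros(0))

    def test_report_metrics_consistent(self):
        x = np.linspace(0, 1, 15)[:, None]
        y = 2.0 + 3.0 * x.ravel()
        net, rep = annga.train_backprop(x, y, epochs=3000, seed=1)
        assert rep.mse >= 0 and rep.mae >= 0 and rep.r2 <= 1.0
        yp = forward(net, x)
        sst = ((y - y.mean()) ** 2).sum()
        assert rep.r2 == pytest.approx(1 - ((y - yp) ** 2).sum() / sst, abs=1e-10)


class TestGAConfig:
    def test_study_defaults(self):
        cfg = GAConfig()
        assert cfg.pop_size == 50 and cfg.max_generations == 1000
        assert cfg.p_crossover == 0.95 and cfg.p_mutation == 0.04
        assert cfg.string_length == 20 and cfg.n_vars == 4

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(bounds=[(2.0, -2.0)] * 4)
        with pytest.raises(ValueError):
            GAConfig(p_mutation=1.5)
        with pytest.raises(ValueError):
            GAConfig(bounds=[(-2.0, 2.0)] * 3)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**20 - 1))
    def test_decoded_points_always_within_bounds(self, bits):
        cfg = GAConfig(bounds=[(-2.0, 2.0), (0.0, 1.0), (-1.0, 3.0), (5.0, 6.0)])
        chrom = np.array([(bits >> i) & 1 for i in range(20)])
        x = decode(chrom, cfg)
        for v, (lo, hi) in zip(x, cfg.bounds):
            assert lo - 1e-12 <= v <= hi + 1e-12

    def test_decode_endpoints(self):
        cfg = GAConfig()
        assert np.allclose(decode(np.zeros(20, dtype=int), cfg), -2.0)
        assert np.allclose(decode(np.ones(20, dtype=int), cfg), 2.0)


class TestGA:
    def test_finds_known_separable_optimum(self):
        # -sum (x-0.5)^2 on [0,1]^4; decode step is 1/31 per coordinate
        cfg_base = dict(n_vars=4, bounds=[(0.0, 1.0)] * 4)
        for seed in range(10):
            res = ga_optimize(lambda p: -np.sum((p - 0.5) ** 2),
                              GAConfig(seed=seed, **cfg_base))
            assert np.all(np.abs(res.best_point - 0.5) <= 1.0 / 31 + 1e-12), seed
            assert np.all(np.diff(res.trajectory) >= 0)

    def test_constant_fitness_flat_trajectory(self):
        res = ga_optimize(lambda p: 3.5, GAConfig(seed=0, max_generations=60))
        assert np.all(res.trajectory == 3.5)
        assert res.best_fitness == 3.5

    def test_matches_bounded_quadratic_oracle(self):
        # GA vs the deterministic multi-start optimizer on a seeded fitted
        # quadratic: within 0.05 response units in at least 9 of 10 seeds
        model = random_quadratic(13)
        oracle = rsm.optimize_bounded(model, [(-2.0, 2.0)] * 4)
        ok = 0
        for seed in range(10):
            res = ga_optimize(lambda p: float(rsm.predict(model, p)),
                              GAConfig(seed=seed))
            assert np.all(np.diff(res.trajectory) >= 0)  # elitism
            if abs(res.best_fitness - oracle.predicted) <= 0.05:
                ok += 1
        assert ok >= 9

    def test_fine_decoding_converges_to_rsm_optimum(self):
        # at 16 bits/variable the decode grid is ~6e-5 wide: GA optimum of a
        # concave quadratic approaches the analytic optimum
        model = random_quadratic(17, concave=True)
        oracle = rsm.optimize_bounded(model, [(-2.0, 2.0)] * 4)
        cfg = GAConfig(bits_per_var=16, seed=5, max_generations=2000, stagnation=200)
        res = ga_optimize(lambda p: float(rsm.predict(model, p)), cfg)
        assert res.best_fitness == pytest.approx(oracle.predicted, abs=0.01)


class TestHybridPipeline:
    def test_deterministic_given_master_seed(self, ccd_table):
        kwargs = dict(master_seed=7, n_restarts=1, epochs=500)
        a = annga.annga_pipeline(ccd_table, "PGase", **kwargs)
        b = annga.annga_pipeline(ccd_table, "PGase", **kwargs)
        assert np.array_equal(a["best_coded"], b["best_coded"])
        assert a["best_predicted"] == b["best_predicted"]
        assert np.array_equal(a["ga"].trajectory, b["ga"].trajectory)

    def test_reduces_to_quadratic_optimum_with_synthetic_truth(self):
        # surrogate trained on noiseless concave-quadratic data recovers an
        # optimum close to the generating surface's bounded optimum
        model = random_quadratic(29, concave=True)
        table = simulate_ccd(QuadraticTruth(model, sigma=0.0), build_ccd(4, 2.0, 6))
        out = annga.annga_pipeline(table, "y", master_seed=3, n_restarts=3,
                                   epochs=20000)
        oracle = rsm.optimize_bounded(model, [(-2.0, 2.0)] * 4)
        assert out["train_report"].r2 > 0.98
        assert abs(out["best_predicted"] - oracle.predicted) < 0.6

    def test_best_point_in_actual_units(self, ccd_table):
        out = annga.annga_pipeline(ccd_table, "PGase", master_seed=1,
                                   n_restarts=1, epochs=300)
        assert set(out["best_actual"]) == {"x1", "x2", "x3", "x6"}
        assert 0.50 <= out["best_actual"]["x1"] <= 1.50
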