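import numpy as np
import pytest

from fluctid import (
    FluctuationObjective,
    NoiseModel,
    ObjectiveConfig,
    TimeGrid,
    TimeSeries,
    build_immigration_death,
    objective_landscape,
    pso_minimize,
    rho_immigration_death,
    scan_confidence_interval,
    simulate_ensemble,
)
from fluctid.manifold import ManifoldRho


def id_make_model(params, x0=10):
    return build_immigration_death(params["theta1"], params["theta2"], x0), None


@pytest.fixture(scope="module")
def id_data(id_net, grid100):
    return simulate_ensemble(id_net, grid100, 1, 2024)[0]


@pytest.fixture(scope="module")
def id_rho():
    return rho_immigration_death(xs=10.0)


class TestConfigValidation:
    def test_bad_measure(self):
        with pytest.raises(ValueError):
            ObjectiveConfig(measure="variance")

    def test_bad_level(self):
        with pytest.raises(ValueError):
            ObjectiveConfig(level=1.2)

    def test_bad_m(self):
        with pytest.raises(ValueError):
            ObjectiveConfig(M=0)


class TestObjective:
    def test_same_seed_identity_is_exactly_zero(self, id_rho, grid100):
        """Data replaced by a same-seeded M=1 simulation: objective is 0."""
        eval_seed = 314
        net, _ = id_make_model(id_rho(0.1))
        sim_root = FluctuationObjective.ensemble_seed(eval_seed)
        data = simulate_ensemble(net, grid100, 1, sim_root)[0]
        cfg = ObjectiveConfig(M=1)
        obj = FluctuationObjective(data, id_rho, id_make_model, cfg)
        assert obj.evaluate(0.1, eval_seed=eval_seed) == 0.0

    def test_act_identity_zero(self, id_rho, grid100):
        eval_seed = 99
        net, _ = id_make_model(id_rho(0.1))
        data = simulate_ensemble(net, grid100, 1, FluctuationObjective.ensemble_seed(eval_seed))[0]
        cfg = ObjectiveConfig(measure="act", M=1)
        obj = FluctuationObjective(data, id_rho, id_make_model, cfg)
        assert obj.evaluate(0.1, eval_seed=eval_seed) == 0.0

    def test_truth_beats_far_point_on_average(self, id_data, id_rho):
        """E F(θ_true) < E F(3×θ_true): Monte-Carlo ordering over replicate evals."""
        cfg = ObjectiveConfig(M=50)
        obj = FluctuationObjective(id_data, id_rho, id_make_model, cfg)
        at_truth = np.mean([obj.evaluate(0.1, eval_seed=s) for s in range(8)])
        at_far = np.mean([obj.evaluate(0.3, eval_seed=s) for s in range(8)])
        assert at_truth < at_far

    def test_out_of_domain_returns_penalty(self, id_data, grid100):
        rho = rho_immigration_death(xs=10.0)
        scan = ManifoldRho(
            "theta2", "interpolated", scan_grid=[0.05, 0.1, 0.2],
            dependent_names=["theta1"], fitted_points=[[0.5], [1.0], [2.0]],
        )
        cfg = ObjectiveConfig(M=2)
        obj = FluctuationObjective(id_data, scan, id_make_model, cfg)
        assert obj.evaluate(0.4, eval_seed=0) == obj.penalty

    def test_event_cap_returns_penalty(self, id_data, id_rho):
        cfg = ObjectiveConfig(M=2, max_events=3)
        obj = FluctuationObjective(id_data, id_rho, id_make_model, cfg)
        assert obj.evaluate(0.1, eval_seed=0) == obj.penalty

    def test_unknown_sigma_requires_value(self, id_data, id_rho):
        cfg = ObjectiveConfig(M=1, sigma_known=False)
        obj = FluctuationObjective(id_data, id_rho, id_make_model, cfg)
        with pytest.raises(ValueError):
            obj.evaluate(0.1, eval_seed=0)

    def test_act_requires_univariate(self, id_rho):
        grid = TimeGrid(0.0, 5, 1.0)
        data = TimeSeries(grid, np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            FluctuationObjective(data, id_rho, id_make_model, ObjectiveConfig(measure="act"))


class TestPSO:
    def test_quadratic_converges(self):
        res = pso_minimize(lambda x, seed: (x[0] - 0.3) ** 2, [(0.0, 1.0)], seed=0)
        assert res.x[0] == pytest.approx(0.3, abs=1e-3)

    def test_deterministic_given_seed(self):
        f = lambda x, seed: (x[0] - 0.7) ** 2 + (x[1] + 0.2) ** 2
        r1 = pso_minimize(f, [(0, 1), (-1, 1)], seed=5)
        r2 = pso_minimize(f, [(0, 1), (-1, 1)], seed=5)
        assert np.array_equal(r1.x, r2.x) and r1.fun == r2.fun

    def test_history_monotone_nonincreasing(self):
        res = pso_minimize(lambda x, seed: np.sin(5 * x[0]) + x[0] ** 2, [(-2, 2)], seed=1)
        assert np.all(np.diff(res.history) <= 0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            pso_minimize(lambda x, s: 0.0, [(1.0, 0.0)])
        with pytest.raises(ValueError):
            pso_minimize(lambda x, s: 0.0, [(0.0, np.inf)])

    def test_stays_in_bounds(self):
        seen = []

        def f(x, seed):
            seen.append(x.copy())
            return float(np.sum(x**2))

        pso_minimize(f, [(-0.5, 0.5)], n_particles=5, n_iter=10, seed=2)
        arr = np.array(seen)
        assert arr.min() >= -0.5 and arr.max() <= 0.5


class TestScanCI:
    def test_degenerate_single_point_grid_is_open(self, id_data, id_rho):
        cfg = ObjectiveConfig(M=5)
        res = scan_confidence_interval(id_data, id_rho, id_make_model, [0.1], cfg, seed=0)
        assert res.lo_open and res.hi_open

    def test_bracket_contains_crossings(self, id_data, id_rho):
        cfg = ObjectiveConfig(M=40)
        grid = np.linspace(0.02, 0.3, 10)
        res = scan_confidence_interval(id_data, id_rho, id_make_model, grid, cfg, seed=0)
        assert res.lo <= res.hi
        assert grid[0] <= res.lo and res.hi <= grid[-1]
        frame = res.to_frame()
        assert list(frame.columns) == ["theta", "q10", "mean", "q90"]


class TestLandscape:
    def test_zero_model_zero_data_is_flat_zero(self):
        grid = TimeGrid(0.0, 20, 1.0)
        data = TimeSeries(grid, np.zeros(20))
        rho = ManifoldRho(
            "theta2", "closed_form", fn=lambda t: {"theta1": 0.0, "theta2": 0.0},
            domain=(0.0, 1.0),
        )

        def make_model(params):
            return build_immigration_death(0.0, 0.0, 0), None

        out = objective_landscape(data, rho, make_model, [0.1, 0.5], None,
                                  ObjectiveConfig(M=3), seed=0)
        assert np.all(out == 0.0)

    def test_two_dimensional_shape(self, id_data, id_rho):
        out = objective_landscape(
            id_data, id_rho, id_make_model, [0.05, 0.1], [0.0, 0.5],
            ObjectiveConfig(M=5), seed=0,
        )
        assert out.shape == (2, 2) and np.all(np.isfinite(out))
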