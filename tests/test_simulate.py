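import numpy as np
import pytest
from scipy import stats

from fluctid import (
    NoiseModel,
    SimulationCapExceeded,
    TimeGrid,
    TimeSeries,
    add_measurement_noise,
    apply_observables,
    build_epo_receptor,
    build_immigration_death,
    integrate_ode,
    simulate_ensemble,
    simulate_ssa,
)
from fluctid.simulate import _child_seeds


class TestGrid:
    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            TimeGrid(0.0, 100, 0.0)
        with pytest.raises(ValueError):
            TimeGrid(0.0, 1, 0.5)

    def test_times(self):
        g = TimeGrid(1.0, 4, 0.5)
        assert np.allclose(g.times, [1.0, 1.5, 2.0, 2.5])


class TestSSA:
    def test_seed_determinism(self, id_net, grid100):
        a = simulate_ssa(id_net, grid100, 123).values
        b = simulate_ssa(id_net, grid100, 123).values
        assert np.array_equal(a, b)
        c = simulate_ssa(id_net, grid100, 124).values
        assert not np.array_equal(a, c)

    def test_zero_rates_constant(self):
        net = build_immigration_death(0.0, 0.0, 7)
        traj = simulate_ssa(net, TimeGrid(0.0, 20, 1.0), 1)
        assert np.all(traj.values == 7)

    def test_grid_refinement_invariance(self, id_net):
        coarse = TimeGrid(0.0, 50, 1.0)
        fine = TimeGrid(0.0, 99, 0.5)
        a = simulate_ssa(id_net, coarse, 77).values[:, 0]
        b = simulate_ssa(id_net, fine, 77).values[::2, 0]
        assert np.array_equal(a, b)

    def test_stationary_poisson_distribution(self, long_stationary_series):
        """Immigration-death at (1, 0.1) is Poisson(10) in the stationary state."""
        x = long_stationary_series
        assert x.mean() == pytest.approx(10.0, rel=0.02)
        assert x.var() / x.mean() == pytest.approx(1.0, rel=0.05)
        # total-variation distance of the empirical marginal vs Poisson(10)
        kmax = int(x.max())
        emp = np.bincount(x.astype(int), minlength=kmax + 1) / x.size
        pmf = stats.poisson.pmf(np.arange(kmax + 1), 10.0)
        tv = 0.5 * np.abs(emp - pmf).sum()
        assert tv < 0.02

    def test_event_cap_raises(self, id_net, grid100):
        with pytest.raises(SimulationCapExceeded):
            simulate_ssa(id_net, grid100, 1, max_events=5)


class TestEnsemble:
    def test_m1_matches_sub_seeded_single(self, id_net, grid100):
        sub = _child_seeds(9, 1)[0]
        a = simulate_ensemble(id_net, grid100, 1, 9)[0]
        b = simulate_ssa(id_net, grid100, sub)
        assert np.array_equal(a.values, b.values)

    def test_same_seed_identical_ensembles(self, id_net, grid100):
        e1 = simulate_ensemble(id_net, grid100, 5, 3)
        e2 = simulate_ensemble(id_net, grid100, 5, 3)
        assert all(np.array_equal(a.values, b.values) for a, b in zip(e1, e2))

    def test_ensemble_mean_tracks_ode(self):
        """Linear kinetics: the ensemble mean follows the mean-field relaxation."""
        net = build_immigration_death(1.0, 0.1, 0)
        grid = TimeGrid(0.0, 26, 2.0)
        ens = simulate_ensemble(net, grid, 300, 11)
        mean = np.mean([e.values[:, 0] for e in ens], axis=0)
        phi = integrate_ode(net, np.array([0.0]), grid).values[:, 0]
        # se of the mean is ~ sqrt(var/300) <= sqrt(10/300) ~ 0.18
        assert np.all(np.abs(mean - phi) < 4 * np.sqrt(np.maximum(phi, 1.0) / 300))


class TestObservablesAndNoise:
    def test_identity_observable(self, id_net, grid100):
        from fluctid import ObservableMap

        traj = simulate_ssa(id_net, grid100, 4)
        obs = ObservableMap(["X"], [("X", {"X": 1.0}, 1.0)])
        assert np.array_equal(apply_observables(traj, obs).values, traj.values)

    def test_species_mismatch_rejected(self, id_net, grid100):
        _, epo_obs = build_epo_receptor()
        traj = simulate_ssa(id_net, grid100, 4)
        with pytest.raises(ValueError):
            apply_observables(traj, epo_obs)

    def test_zero_sigma_identity(self, id_net, grid100):
        traj = simulate_ssa(id_net, grid100, 4)
        assert add_measurement_noise(traj, NoiseModel("additive", 0.0), 1) is traj
        assert add_measurement_noise(traj, NoiseModel(), 1) is traj

    def test_additive_noise_sd_recovered(self):
        grid = TimeGrid(0.0, 20000, 1.0)
        base = TimeSeries(grid, np.full(grid.n_samples, 10.0))
        noisy = add_measurement_noise(base, NoiseModel("additive", 1.0), 8)
        resid = noisy.values - base.values
        assert resid.std() == pytest.approx(1.0, rel=0.03)

    def test_relative_noise_sd_recovered(self):
        grid = TimeGrid(0.0, 20000, 1.0)
        base = TimeSeries(grid, np.full(grid.n_samples, 2736.0))
        noisy = add_measurement_noise(base, NoiseModel("relative", 0.01), 8)
        resid = noisy.values - base.values
        assert resid.std() == pytest.approx(27.36, rel=0.03)

    def test_invalid_noise_model(self):
        with pytest.raises(ValueError):
            NoiseModel("multiplicative", 1.0)
        with pytest.raises(ValueError):
            NoiseModel("additive", -1.0)


def test_csv_round_trip(tmp_path, id_net, grid100):
    traj = simulate_ssa(id_net, grid100, 99)
    noisy = add_measurement_noise(traj, NoiseModel("additive", 0.37), 5)
    path = tmp_path / "series.csv"
    noisy.to_csv(path)
    back = TimeSeries.from_csv(path)
    assert np.array_equal(back.values, noisy.values)
    assert back.labels == noisy.labels
    assert np.allclose(back.grid.times, noisy.grid.times)
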