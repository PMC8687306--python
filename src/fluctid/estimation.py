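"""Simulation-ensemble objectives on the non-identifiability manifold,
particle-swarm point estimation, quantile-scan confidence intervals and
objective landscapes.

The objective for a candidate free-parameter value θ is the squared
distance between the fluctuation measure of the data and the mean measure
over an ensemble of M stochastic simulations at the full parameter point
(θ, ρ(θ)):

    F(θ) = Σ_obs ( D(ν) − (1/M) Σ_j D(H^(j)(θ)) )²

with D either the differences-based measure or the level-crossing
autocorrelation time, and simulations carrying the same measurement-noise
model as the data (noise std known, or itself a search dimension).
The objective is stochastic: every evaluation draws a fresh ensemble from
a per-evaluation seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .manifold import ManifoldRho
from .meanfield import integrate_ode, subtract_meanfield
from .measures import d_act, d_diff
from .networks import ObservableMap, ReactionNetwork
from .simulate import (
    NoiseModel,
    SimulationCapExceeded,
    TimeSeries,
    _child_seeds,
    add_measurement_noise,
    apply_observables,
    simulate_ssa,
)

__all__ = [
    "ObjectiveConfig",
    "FluctuationObjective",
    "PSOResult",
    "pso_minimize",
    "ScanCIResult",
    "scan_confidence_interval",
    "objective_landscape",
]

MakeModel = Callable[[dict], tuple[ReactionNetwork, ObservableMap | None]]


@dataclass(frozen=True)
class ObjectiveConfig:
    """Configuration of the simulation-ensemble objective.

    Attributes
    ----------
    measure : {'diff', 'act'}
        Fluctuation measure used on data and simulations.
    M : int
        Ensemble size per objective evaluation.
    level : float
        Threshold l ∈ (0,1) for the autocorrelation-time measure.
    noise : NoiseModel
        Measurement-noise model of the data (applied to simulations too
        when the amplitude is known).
    sigma_known : bool
        If False, the additive-noise std becomes a search dimension.
    meanfield_mode : {'steady_state', 'transient'}
        Center by the per-observable sample mean ν̄, or by the ODE solution
        at the candidate parameter point.
    max_events : int
        Event cap per trajectory; exceeding it fails the evaluation.
    penalty_factor : float
        Failed evaluations return penalty_factor × max(ΣD(ν)², 1e-3).
    """

    measure: str = "diff"
    M: int = 100
    level: float = 0.6
    noise: NoiseModel = field(default_factory=NoiseModel)
    sigma_known: bool = True
    meanfield_mode: str = "steady_state"
    max_events: int = 10**7
    penalty_factor: float = 1e6
    absolute_diff: bool = True

    def __post_init__(self):
        if self.measure not in ("diff", "act"):
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.M < 1:
            raise ValueError("M must be at least 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.meanfield_mode not in ("steady_state", "transient"):
            raise ValueError(f"unknown meanfield_mode {self.meanfield_mode!r}")


class FluctuationObjective:
    """F_diff / F_act for one dataset, evaluated along a manifold ρ."""

    def __init__(self, data: TimeSeries, rho: ManifoldRho, make_model: MakeModel, cfg: ObjectiveConfig):
        self.data = data
        self.rho = rho
        self.make_model = make_model
        self.cfg = cfg
        if cfg.measure == "act" and data.n_observables != 1:
            raise ValueError("autocorrelation-based objective requires univariate data")
        # penalty base: data measure with sample-mean centering (always defined)
        base = self._measure_vector(data.values - data.values.mean(axis=0))
        base = base[np.isfinite(base)]
        self.penalty = cfg.penalty_factor * max(float(np.sum(base**2)), 1e-3)
        if cfg.meanfield_mode == "steady_state":
            self._d_data = self._measure_vector(data.values - data.values.mean(axis=0))

    # -- helpers -------------------------------------------------------

    def _measure_vector(self, centered_values: np.ndarray) -> np.ndarray:
        """Per-observable measure of a centered matrix."""
        if self.cfg.measure == "diff":
            return d_diff(centered_values, absolute=self.cfg.absolute_diff)
        return np.array([d_act(centered_values[:, 0], self.cfg.level, self.data.grid.dt)])

    @staticmethod
    def ensemble_seed(eval_seed: int) -> int:
        """Root seed of the simulation ensemble for a given evaluation seed."""
        return _child_seeds(eval_seed, 2)[0]

    # -- evaluation ----------------------------------------------------

    def evaluate(self, theta_free: float, sigma: float | None = None, eval_seed: int = 0) -> float:
        """One stochastic evaluation of the objective at (θ, ρ(θ))[, σ]."""
        cfg = self.cfg
        try:
            params = self.rho(theta_free)
        except ValueError:
            return self.penalty
        try:
            net, obs = self.make_model(params)
        except (ValueError, KeyError):
            return self.penalty
        if cfg.sigma_known:
            noise = cfg.noise
        else:
            if sigma is None:
                raise ValueError("sigma must be supplied when the noise amplitude is unknown")
            noise = NoiseModel("additive", float(sigma))

        # mean-field trajectory for centering
        if cfg.meanfield_mode == "transient":
            try:
                phi = integrate_ode(net, None, self.data.grid, observables=obs)
            except RuntimeError:
                return self.penalty
            d_data = self._measure_vector(self.data.values - phi.values)
        else:
            phi = None
            d_data = self._d_data

        sim_root, noise_root = _child_seeds(eval_seed, 2)
        sim_seeds = _child_seeds(sim_root, cfg.M)
        noise_seeds = _child_seeds(noise_root, cfg.M)
        sims = np.empty((cfg.M, d_data.size))
        for j in range(cfg.M):
            try:
                traj = simulate_ssa(net, self.data.grid, sim_seeds[j], cfg.max_events)
            except SimulationCapExceeded:
                return self.penalty
            if obs is not None:
                traj = apply_observables(traj, obs)
            traj = add_measurement_noise(traj, noise, noise_seeds[j])
            if phi is not None:
                centered = traj.values - phi.values
            else:
                centered = traj.values - traj.values.mean(axis=0)
            sims[j] = self._measure_vector(centered)

        if cfg.measure == "act":
            defined = np.isfinite(sims[:, 0])
            if defined.sum() <= cfg.M / 2 or not np.isfinite(d_data[0]):
                return self.penalty
            sim_mean = np.array([sims[defined, 0].mean()])
        else:
            sim_mean = sims.mean(axis=0)
        return float(np.sum((d_data - sim_mean) ** 2))

    def __call__(self, x: np.ndarray, eval_seed: int = 0) -> float:
        x = np.atleast_1d(x)
        if self.cfg.sigma_known:
            return self.evaluate(float(x[0]), eval_seed=eval_seed)
        return self.evaluate(float(x[0]), sigma=float(x[1]), eval_seed=eval_seed)


# ----------------------------------------------------------------------
# Particle swarm optimisation
# ----------------------------------------------------------------------

@dataclass
class PSOResult:
    x: np.ndarray
    fun: float
    history: np.ndarray  # best objective value per generation


def pso_minimize(
    objective: Callable[[np.ndarray, int], float],
    bounds: Sequence[tuple[float, float]],
    n_particles: int = 10,
    n_iter: int = 25,
    seed: int = 0,
    inertia: float = 0.7,
    cognitive: float = 1.5,
    social: float = 1.5,
) -> PSOResult:
    """Global-best particle swarm minimisation on a box.

    ``objective(x, seed)`` may be stochastic; every evaluation receives a
    fresh seed from a deterministic stream, so the whole run is reproducible
    given ``seed``.  Particles start uniformly in the box with zero
    velocity and reflect at the boundaries.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim == 1:
        bounds = bounds[None, :]
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)) or np.any(hi <= lo):
        raise ValueError("bounds must be finite with lower < upper")
    d = bounds.shape[0]
    rng = np.random.Generator(np.random.PCG64(seed))

    def fresh_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    pos = lo + rng.uniform(size=(n_particles, d)) * (hi - lo)
    vel = np.zeros((n_particles, d))
    fvals = np.array([objective(pos[i], fresh_seed()) for i in range(n_particles)])
    pbest, pbest_f = pos.copy(), fvals.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    history = [gbest_f]
    for _ in range(n_iter):
        r1 = rng.uniform(size=(n_particles, d))
        r2 = rng.uniform(size=(n_particles, d))
        vel = inertia * vel + cognitive * r1 * (pbest - pos) + social * r2 * (gbest - pos)
        pos = pos + vel
        # reflect at box boundaries
        for _ in range(2):
            under = pos < lo
            pos = np.where(under, 2 * lo - pos, pos)
            vel = np.where(under, -vel, vel)
            over = pos > hi
            pos = np.where(over, 2 * hi - pos, pos)
            vel = np.where(over, -vel, vel)
        pos = np.clip(pos, lo, hi)
        for i in range(n_particles):
            f = objective(pos[i], fresh_seed())
            if f < pbest_f[i]:
                pbest[i], pbest_f[i] = pos[i].copy(), f
                if f < gbest_f:
                    gbest, gbest_f = pos[i].copy(), float(f)
        history.append(gbest_f)
    return PSOResult(gbest, gbest_f, np.asarray(history))


# ----------------------------------------------------------------------
# Quantile-scan confidence interval
# ----------------------------------------------------------------------

@dataclass
class ScanCIResult:
    """Per-grid-point simulated measure quantiles and the bracketed interval."""

    theta: np.ndarray
    q10: np.ndarray
    mean: np.ndarray
    q90: np.ndarray
    d_data: float
    lo: float
    hi: float
    lo_open: bool
    hi_open: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"theta": self.theta, "q10": self.q10, "mean": self.mean, "q90": self.q90})

    @property
    def width(self) -> float:
        return self.hi - self.lo


def _cross_point(theta: np.ndarray, curve: np.ndarray, level: float, i: int, j: int) -> float:
    """Linear interpolation of curve == level between grid indices i and j."""
    a, b = curve[i] - level, curve[j] - level
    if not np.isfinite(a) or not np.isfinite(b) or a == b:
        return float(theta[j])
    return float(theta[i] + (theta[j] - theta[i]) * a / (a - b))


def _scalar_measures(objconf: FluctuationObjective, params: dict, eval_seed: int) -> np.ndarray:
    """Per-simulation scalar measures (summed over observables) at one point."""
    cfg = objconf.cfg
    net, obs = objconf.make_model(params)
    noise = cfg.noise if cfg.sigma_known else NoiseModel()
    if cfg.meanfield_mode == "transient":
        phi = integrate_ode(net, None, objconf.data.grid, observables=obs)
    else:
        phi = None
    sim_root, noise_root = _child_seeds(eval_seed, 2)
    sim_seeds = _child_seeds(sim_root, cfg.M)
    noise_seeds = _child_seeds(noise_root, cfg.M)
    vals = np.empty(cfg.M)
    for j in range(cfg.M):
        traj = simulate_ssa(net, objconf.data.grid, sim_seeds[j], cfg.max_events)
        if obs is not None:
            traj = apply_observables(traj, obs)
        traj = add_measurement_noise(traj, noise, noise_seeds[j])
        centered = traj.values - (phi.values if phi is not None else traj.values.mean(axis=0))
        vals[j] = float(np.nansum(objconf._measure_vector(centered))) if cfg.measure == "diff" else float(
            objconf._measure_vector(centered)[0]
        )
    return vals


def scan_confidence_interval(
    data: TimeSeries,
    rho: ManifoldRho,
    make_model: MakeModel,
    theta_grid: Sequence[float],
    cfg: ObjectiveConfig,
    seed: int = 0,
    quantiles: tuple[float, float] = (0.1, 0.9),
) -> ScanCIResult:
    """Bracketed confidence interval from a free-parameter scan.

    At each grid value, M simulated series give an empirical distribution of
    the fluctuation measure.  The bracketed interval is the set of grid
    values whose 10%–90% quantile band contains the measure computed on the
    data; its endpoints are refined by linear interpolation of the crossing
    of the violated quantile curve with the data value.  Endpoints at the
    grid edge are flagged open-ended.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    objconf = FluctuationObjective(data, rho, make_model, cfg)
    if cfg.meanfield_mode == "steady_state":
        d_data = float(np.nansum(objconf._d_data))
    else:
        params_mid = rho(float(theta_grid[len(theta_grid) // 2]))
        net, obs = make_model(params_mid)
        phi = integrate_ode(net, None, data.grid, observables=obs)
        d_data = float(np.nansum(objconf._measure_vector(data.values - phi.values)))
    point_seeds = _child_seeds(seed, len(theta_grid))
    q10 = np.empty(len(theta_grid))
    q90 = np.empty(len(theta_grid))
    mean = np.empty(len(theta_grid))
    for g, th in enumerate(theta_grid):
        vals = _scalar_measures(objconf, rho(float(th)), point_seeds[g])
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            q10[g] = q90[g] = mean[g] = np.nan
            continue
        q10[g], q90[g] = np.quantile(vals, quantiles)
        mean[g] = vals.mean()
    inside = (q10 <= d_data) & (d_data <= q90)
    if len(theta_grid) < 2 or not inside.any():
        return ScanCIResult(
            theta_grid, q10, mean, q90, d_data,
            float(theta_grid[0]), float(theta_grid[-1]), True, True,
        )
    i0 = int(np.argmax(inside))
    i1 = int(len(inside) - 1 - np.argmax(inside[::-1]))
    if i0 == 0:
        lo, lo_open = float(theta_grid[0]), True
    else:
        violated = q10 if q10[i0 - 1] > d_data else q90
        lo, lo_open = _cross_point(theta_grid, violated, d_data, i0 - 1, i0), False
    if i1 == len(theta_grid) - 1:
        hi, hi_open = float(theta_grid[-1]), True
    else:
        violated = q10 if q10[i1 + 1] > d_data else q90
        hi, hi_open = _cross_point(theta_grid, violated, d_data, i1 + 1, i1), False
    return ScanCIResult(theta_grid, q10, mean, q90, d_data, lo, hi, lo_open, hi_open)


def objective_landscape(
    data: TimeSeries,
    rho: ManifoldRho,
    make_model: MakeModel,
    theta_grid: Sequence[float],
    sigma_grid: Sequence[float] | None,
    cfg: ObjectiveConfig,
    seed: int = 0,
) -> np.ndarray:
    """Objective values on a (θ × σ) grid for landscape inspection.

    With ``sigma_grid`` None a 1-D array over θ is returned (noise taken
    from ``cfg.noise``); otherwise entry [i, j] is the objective at
    θ_i with additive simulation noise of std σ_j.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    if sigma_grid is None:
        obj = FluctuationObjective(data, rho, make_model, cfg)
        seeds = _child_seeds(seed, len(theta_grid))
        return np.array([obj.evaluate(float(t), eval_seed=s) for t, s in zip(theta_grid, seeds)])
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    obj = FluctuationObjective(data, rho, make_model, replace(cfg, sigma_known=False))
    out = np.empty((len(theta_grid), len(sigma_grid)))
    seeds = _child_seeds(seed, out.size)
    k = 0
    for i, t in enumerate(theta_grid):
        for j, s in enumerate(sigma_grid):
            out[i, j] = obj.evaluate(float(t), sigma=float(s), eval_seed=seeds[k])
            k += 1
    return out
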