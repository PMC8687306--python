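"""Deterministic (mean-field) semantics: ODE trajectories, steady states,
and mean-field subtraction from measurements.

Mean-field subtraction isolates the fluctuations: either the ODE solution
φ(t) from a known initial condition is subtracted ("transient mode"), or —
for stationary recordings with no trusted initial condition — the
per-observable sample mean ν̄ ("steady-state mode").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .networks import ObservableMap, ReactionNetwork
from .simulate import TimeGrid, TimeSeries

__all__ = [
    "MeanFieldTrajectory",
    "integrate_ode",
    "steady_state",
    "subtract_meanfield",
    "estimate_steady_state_from_data",
]


@dataclass
class MeanFieldTrajectory:
    """Deterministic trajectory on a grid (species or observables)."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and self.grid.n_samples > 1:
            self.values = self.values.T
        if self.values.shape[0] != self.grid.n_samples:
            raise ValueError("row count must equal grid.n_samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("mean-field trajectory contains non-finite values")


def integrate_ode(
    net: ReactionNetwork,
    x0: np.ndarray | None,
    grid: TimeGrid,
    observables: ObservableMap | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> MeanFieldTrajectory:
    """Solve the mass-action rate equations on the grid.

    ``x0`` is the state at ``grid.t_start`` (defaults to the network's
    exact, real-valued initial state).  If ``observables`` is given the
    returned values are the projected observables rather than raw species.
    """
    if x0 is None:
        x0 = net.initial_state_real
    x0 = np.asarray(x0, dtype=float)
    sol = solve_ivp(
        net.ode_rhs,
        (grid.t_start, grid.t_end),
        x0,
        t_eval=grid.times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    values = sol.y.T
    if observables is not None:
        values = observables.apply(values)
    return MeanFieldTrajectory(grid, values)


def steady_state(net: ReactionNetwork, guess: np.ndarray | None = None) -> np.ndarray:
    """Root of the rate equations near ``guess`` (residual norm ≤ 1e-10)."""
    if guess is None:
        guess = net.initial_state.astype(float)
    res = root(lambda x: net.ode_rhs(0.0, x), np.asarray(guess, dtype=float), tol=1e-13)
    resid = np.linalg.norm(net.ode_rhs(0.0, res.x))
    if not res.success or resid > 1e-10 * max(1.0, np.linalg.norm(res.x)):
        raise RuntimeError(f"steady-state search did not converge (residual {resid:.2e})")
    return res.x


def subtract_meanfield(data: TimeSeries, phi: MeanFieldTrajectory) -> TimeSeries:
    """Centered fluctuations ν_i = ν'_i − φ(t_i)."""
    if not np.allclose(data.grid.times, phi.grid.times, rtol=1e-9, atol=1e-12):
        raise ValueError("data and mean-field grids differ")
    if data.values.shape != phi.values.shape:
        raise ValueError("data and mean-field shapes differ")
    return TimeSeries(data.grid, data.values - phi.values, list(data.labels))


def estimate_steady_state_from_data(data: TimeSeries) -> np.ndarray:
    """Sample mean ν̄ per observable, as an estimate of the steady state."""
    return data.values.mean(axis=0)


def constant_meanfield(grid: TimeGrid, levels: np.ndarray) -> MeanFieldTrajectory:
    """Constant trajectory at the given per-observable levels (steady-state mode)."""
    levels = np.atleast_1d(np.asarray(levels, dtype=float))
    return MeanFieldTrajectory(grid, np.tile(levels, (grid.n_samples, 1)))
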