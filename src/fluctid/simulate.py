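"""Exact stochastic simulation with fixed-grid sampling and noise overlay.

Wraps the Gillespie Direct Method kernel with equally spaced sampling
(:class:`TimeGrid`), ensemble generation from hierarchical seed streams,
observable projection and Gaussian measurement-noise models.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._gillespie import STATUS_EVENT_CAP, direct_method
from .networks import ObservableMap, ReactionNetwork

__all__ = [
    "TimeGrid",
    "TimeSeries",
    "NoiseModel",
    "SimulationCapExceeded",
    "simulate_ssa",
    "simulate_ensemble",
    "apply_observables",
    "add_measurement_noise",
]

DEFAULT_EVENT_CAP = 10**8


class SimulationCapExceeded(RuntimeError):
    """Raised when a trajectory exceeds the configured event cap."""


@dataclass(frozen=True)
class TimeGrid:
    """Equally spaced sampling times t_i = t_start + i·dt, i = 0..n_samples−1."""

    t_start: float
    n_samples: int
    dt: float

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_samples)

    @property
    def t_end(self) -> float:
        return self.t_start + self.dt * (self.n_samples - 1)


@dataclass
class TimeSeries:
    """Equally spaced (possibly multivariate) observations on a grid."""

    grid: TimeGrid
    values: np.ndarray  # (n_samples, n_observables)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and self.grid.n_samples > 1:
            self.values = self.values.T
        if self.values.shape[0] != self.grid.n_samples:
            raise ValueError("row count must equal grid.n_samples")
        if not self.labels:
            self.labels = [f"obs{i}" for i in range(self.values.shape[1])]
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("one label per column required")

    @property
    def n_observables(self) -> int:
        return self.values.shape[1]

    def column(self, key: int | str) -> np.ndarray:
        if isinstance(key, str):
            key = self.labels.index(key)
        return self.values[:, key]

    def to_csv(self, path) -> None:
        """Write as CSV (time + one column per observable), full precision."""
        header = ",".join(["time"] + self.labels)
        data = np.column_stack([self.grid.times, self.values])
        np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.17g")

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        times = df.iloc[:, 0].to_numpy()
        if len(times) < 2:
            raise ValueError("time series must have at least two rows")
        dts = np.diff(times)
        if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time column is not equally spaced")
        grid = TimeGrid(float(times[0]), len(times), float(dts[0]))
        return cls(grid, df.iloc[:, 1:].to_numpy(), list(df.columns[1:]))


@dataclass(frozen=True)
class NoiseModel:
    """Zero-mean Gaussian measurement noise.

    ``kind='additive'``: adds N(0, sigma) per entry (measurement units);
    ``kind='relative'``: adds N(0, sigma·|value|) per entry (sigma a fraction);
    ``kind='none'``: no noise (sigma ignored).
    """

    kind: str = "none"
    sigma: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "additive", "relative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def _child_seeds(seed: int, n: int) -> list[int]:
    """Hierarchical sub-seeds (31-bit) derived from one root seed."""
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in np.random.SeedSequence(seed).spawn(n)]


def simulate_ssa(
    net: ReactionNetwork,
    grid: TimeGrid,
    seed: int,
    max_events: int = DEFAULT_EVENT_CAP,
) -> TimeSeries:
    """One exact Direct-Method trajectory sampled on ``grid``.

    The value at t_i is the state immediately after the last reaction event
    at or before t_i.  Identical seeds give identical output.
    """
    sub, prod, rates = net.stoich_arrays()
    out, status, n_events = direct_method(
        sub, prod, rates, net.initial_state, float(grid.t_start), float(grid.dt),
        grid.n_samples, int(max_events), int(seed) & 0x7FFFFFFF,
    )
    if status == STATUS_EVENT_CAP:
        raise SimulationCapExceeded(
            f"trajectory exceeded {max_events} events (rates {net.parameters}); "
            "likely a runaway parameter proposal"
        )
    return TimeSeries(grid, out.astype(float), list(net.species_names))


def simulate_ensemble(
    net: ReactionNetwork,
    grid: TimeGrid,
    M: int,
    seed: int,
    max_events: int = DEFAULT_EVENT_CAP,
) -> list[TimeSeries]:
    """M independent trajectories from a seeded stream of sub-seeds."""
    if M < 1:
        raise ValueError("M must be at least 1")
    return [simulate_ssa(net, grid, s, max_events) for s in _child_seeds(seed, M)]


def apply_observables(traj: TimeSeries, obs: ObservableMap) -> TimeSeries:
    """Project species counts to scaled linear observables."""
    if traj.labels != obs.species_names:
        raise ValueError(
            f"trajectory species {traj.labels} do not match observable map "
            f"species {obs.species_names}"
        )
    return TimeSeries(traj.grid, obs.apply(traj.values), list(obs.names))


def add_measurement_noise(series: TimeSeries, noise: NoiseModel, seed: int) -> TimeSeries:
    """Overlay i.i.d. Gaussian measurement noise on every entry."""
    if noise.kind == "none" or noise.sigma == 0.0:
        return series
    rng = np.random.Generator(np.random.PCG64(seed))
    z = rng.standard_normal(series.values.shape)
    if noise.kind == "additive":
        noisy = series.values + noise.sigma * z
    else:  # relative
        noisy = series.values + noise.sigma * np.abs(series.values) * z
    return TimeSeries(series.grid, noisy, list(series.labels))
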