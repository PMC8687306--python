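"""Scalar fluctuation measures.

Two quantifications of intrinsic fluctuations in an equally spaced,
mean-field-centered series ν:

* ``d_diff`` — the mean absolute consecutive difference
  (1/(n−1))·Σ|ν_i − ν_{i−1}|, a proxy for the system's reactivity
  (reaction events per unit time between samples);
* ``d_act`` — a level-crossing autocorrelation time: the linearly
  interpolated lag at which the estimated autocorrelation function first
  drops below a user level l ∈ (0, 1), in time units.

``d_diff`` without absolute values telescopes to (ν_n − ν_1)/(n−1) and is
useless as a fluctuation measure; it is retained (``absolute=False``) only
for comparison.
"""

from __future__ import annotations

import numpy as np

from .simulate import TimeSeries

__all__ = ["d_diff", "autocorr", "acf", "level_crossing_time", "d_act"]


def _values(x) -> np.ndarray:
    if isinstance(x, TimeSeries):
        return x.values
    return np.atleast_2d(np.asarray(x, dtype=float).T).T if np.ndim(x) == 1 else np.asarray(x, dtype=float)


def d_diff(centered, absolute: bool = True) -> np.ndarray:
    """Differences-based fluctuation measure, per observable column.

    Parameters
    ----------
    centered
        Mean-field-subtracted series (TimeSeries, 1-D or 2-D array).
    absolute
        If True (default) use |ν_i − ν_{i−1}|; if False, the literal
        telescoping sum (ν_n − ν_1)/(n−1).
    """
    v = _values(centered)
    n = v.shape[0]
    if n < 2:
        raise ValueError("d_diff requires at least two samples")
    diffs = np.diff(v, axis=0)
    if absolute:
        diffs = np.abs(diffs)
    return diffs.sum(axis=0) / (n - 1)


def acf(x, max_lag: int | None = None) -> np.ndarray:
    """Autocorrelation estimates R̂(k), k = 0..max_lag, for a univariate series.

    Uses the sample mean and the 1/n sample variance; each lag is
    normalised by 1/((n−k)·σ²), so R̂(0) = 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if max_lag is None:
        max_lag = n - 2
    if not 0 <= max_lag < n:
        raise ValueError("max_lag must be in [0, n)")
    mu = x.mean()
    var = np.mean((x - mu) ** 2)
    if var <= 0:
        raise ValueError("autocorrelation undefined for a constant series")
    d = x - mu
    r = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        r[k] = np.dot(d[: n - k], d[k:]) / ((n - k) * var)
    return r


def autocorr(x, k: int) -> float:
    """Single-lag autocorrelation estimate R̂(k)."""
    return float(acf(x, max_lag=k)[k])


def level_crossing_time(r: np.ndarray, level: float, dt: float) -> float:
    """First down-crossing of ``level`` by an autocorrelation sequence.

    With k̃ = min{k > 0 : r[k] < level}, returns
    dt · (k̃ − 1 + (level − r[k̃−1]) / (r[k̃] − r[k̃−1])); NaN when no lag
    falls below the level (autocorrelation time undefined).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    r = np.asarray(r, dtype=float)
    below = np.nonzero(r[1:] < level)[0]
    if below.size == 0:
        return float("nan")
    k = int(below[0]) + 1
    return dt * (k - 1 + (level - r[k - 1]) / (r[k] - r[k - 1]))


def d_act(x, level: float = 0.6, dt: float = 1.0, max_lag: int | None = None) -> float:
    """Level-crossing autocorrelation time of a univariate series.

    Returns NaN when the estimated autocorrelation never drops below
    ``level`` within the available lags (undefined autocorrelation time) or
    when the series is constant.
    """
    if isinstance(x, TimeSeries):
        if x.n_observables != 1:
            raise ValueError("d_act is defined for univariate series only")
        x = x.values[:, 0]
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("d_act is defined for univariate series only")
    try:
        r = acf(x, max_lag=max_lag)
    except ValueError:
        return float("nan")
    return level_crossing_time(r, level, dt)
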