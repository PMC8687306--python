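"""Numba kernel for the Gillespie Direct Method with fixed-grid sampling.

The jump process is simulated exactly; the recorded value at grid time t_i
is the state immediately after the last event at or before t_i.  Random
draws depend only on the seed and the event sequence, never on the grid,
so refining the grid and sub-sampling reproduces a coarse-grid series
bit-for-bit for the same seed.
"""

from __future__ import annotations

import numba
import numpy as np

STATUS_OK = 0
STATUS_EVENT_CAP = 1


@numba.njit(cache=True)
def direct_method(sub, prod, rates, x0, t_start, dt, n_samples, max_events, seed):
    """Simulate one trajectory, sampled on t_start + i*dt, i = 0..n_samples-1.

    Returns (out, status, n_events); out is (n_samples × n_species) int64.
    On status == STATUS_EVENT_CAP the output is only filled up to the grid
    point reached before the cap was hit.
    """
    np.random.seed(seed)
    n_r, n_sp = sub.shape
    out = np.zeros((n_samples, n_sp), dtype=np.int64)
    x = x0.astype(np.float64)
    t = t_start
    i_grid = 0
    n_events = 0
    a = np.empty(n_r)
    while i_grid < n_samples:
        a0 = 0.0
        for j in range(n_r):
            h = rates[j]
            for i in range(n_sp):
                s = sub[j, i]
                if s == 1:
                    h *= x[i]
                elif s == 2:
                    h *= x[i] * (x[i] - 1.0) * 0.5
                elif s > 2:
                    for m in range(s):
                        h *= x[i] - m
                        h /= m + 1.0
            if h < 0.0:
                h = 0.0
            a[j] = h
            a0 += h
        if a0 <= 0.0:
            # absorbing state: constant for all remaining grid points
            for g in range(i_grid, n_samples):
                for i in range(n_sp):
                    out[g, i] = np.int64(x[i])
            i_grid = n_samples
            break
        tau = -np.log(np.random.random()) / a0
        t_next = t + tau
        while i_grid < n_samples and t_start + i_grid * dt < t_next:
            for i in range(n_sp):
                out[i_grid, i] = np.int64(x[i])
            i_grid += 1
        if i_grid >= n_samples:
            break
        r = np.random.random() * a0
        acc = 0.0
        jsel = n_r - 1
        for j in range(n_r):
            acc += a[j]
            if r < acc:
                jsel = j
                break
        for i in range(n_sp):
            x[i] += prod[jsel, i] - sub[jsel, i]
        t = t_next
        n_events += 1
        if n_events >= max_events:
            return out, STATUS_EVENT_CAP, n_events
    return out, STATUS_OK, n_events
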