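"""Numba-compiled inner loop of the rate-network Euler integration.

The recurrent matrix is passed dense (typically float32) so the per-step
matrix-vector product dispatches to BLAS; everything else is fused
elementwise work. Kept free of Python objects so it can be cached.
"""
from __future__ import annotations

import numba
import numpy as np

__all__ = ["euler_integrate"]


@numba.njit(inline="always")
def _transfer(x, y0, ymax):
    # piecewise saturating rate function, continuous at 0 with slope 1
    if x <= 0.0:
        return y0 + y0 * np.tanh(x / y0)
    return y0 + (ymax - y0) * np.tanh(x / (ymax - y0))


@numba.njit(cache=True)
def euler_integrate(W, g, drive, seg, x0, noise, dt_tau, sigma, y0, ymax):
    """Integrate x' = (-x + g W y + drive + sigma*u) / tau with Euler steps.

    Parameters are all arrays of one dtype. ``noise`` is (T, N); row t is
    applied on the step producing the state at time (t+1)*dt. The input
    drive is segment-coded: step t uses row ``seg[t]`` of ``drive`` —
    boxcar schedules then need only a handful of distinct columns.
    Returns the (T, N) rate trajectory.
    """
    T, N = noise.shape
    rates = np.empty((T, N), dtype=x0.dtype)
    x = x0.copy()
    y = np.empty(N, dtype=x0.dtype)
    for i in range(N):
        y[i] = _transfer(x[i], y0, ymax)
    for t in range(T):
        rec = np.dot(W, y)
        d = drive[seg[t]]
        for i in range(N):
            x[i] += dt_tau * (-x[i] + g * rec[i] + d[i] + sigma * noise[t, i])
            y[i] = _transfer(x[i], y0, ymax)
            rates[t, i] = y[i]
    return rates
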