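"""The state encoding layer: a fixed, sparse random recurrent rate network.

The network plays the role attributed to the orbitofrontal cortex: a
reservoir whose rich dynamics nonlinearly encode the history of task
events (stimuli, intermediate outcomes, and — crucially — reward) within
a trial. Its connectivity is drawn once and never trained; only the
linear readout (see :mod:`taskspace.readout`) learns.

Dynamics per neuron, Euler-integrated with step ``dt``::

    tau * dx_i/dt = -x_i + g * sum_j w_ij y_j + (W_in I(t))_i + sigma_noise * u_i

where ``u_i`` is a fresh uniform [0, 1] draw each step (implemented
exactly as specified, with a small positive mean; a zero-mean variant is
available), and the rate ``y_i`` is a saturating function of ``x_i``
bounded in [ymin, ymax] with baseline ``y0``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._kernel import euler_integrate

__all__ = [
    "ReservoirParams",
    "ReservoirWeights",
    "ActivityTrace",
    "build_reservoir_weights",
    "rate_transfer",
    "integrate_trial",
    "integrate_with_rng",
]


@dataclass(frozen=True)
class ReservoirParams:
    """Structural and dynamical parameters of the state encoding layer.

    Defaults are the reversal-task settings; per-task presets live in
    :func:`taskspace.session.default_params`.
    """

    N: int = 500                 # number of reservoir neurons
    p: float = 0.1               # recurrent connection probability
    g: float = 2.0               # recurrent gain (chaos control parameter)
    tau: float = 100.0           # membrane time constant, ms
    dt: float = 1.0              # Euler step, ms
    sigma_noise: float = 0.01    # per-step uniform-noise amplitude
    sigma_ini: float = 0.01      # std of the initial activation x(0)
    g_IR: float = 4.0            # std of nonzero input weights
    p_IR: float = 0.2            # input connection probability
    y0: float = 0.1              # baseline firing rate
    ymin: float = 0.0
    ymax: float = 1.0
    # The printed equations both scale the recurrent weight variance by g^2
    # and multiply by g in the dynamics; the default applies g once (sampling
    # variance 1/(pN)).  Setting literal_double_gain=True reproduces the
    # printed double-g reading.
    literal_double_gain: bool = False
    # The per-step noise is a uniform [0,1] draw as printed (positive mean);
    # zero_mean_noise subtracts 0.5 instead.
    zero_mean_noise: bool = False
    dtype: str = "float32"       # integration dtype; float64 available

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if not 0 < self.p <= 1:
            raise ValueError("p must be in (0, 1]")
        if not 0 < self.p_IR <= 1:
            raise ValueError("p_IR must be in (0, 1]")
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        if self.dt > self.tau:
            raise ValueError("dt must not exceed tau")
        if not self.ymin <= self.y0 <= self.ymax:
            raise ValueError("require ymin <= y0 <= ymax")
        if self.sigma_noise < 0 or self.sigma_ini < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")

    def replace(self, **kw) -> "ReservoirParams":
        return replace(self, **kw)


@dataclass
class ReservoirWeights:
    """Fixed connectivity: recurrent matrix and input projection.

    ``W_rec`` entries are nonzero with probability ``p`` and drawn from
    N(0, 1/(pN)); ``W_in`` entries are nonzero with probability ``p_IR``
    and drawn from N(0, g_IR^2). Both are frozen after construction.
    """

    W_rec: np.ndarray           # (N, N)
    W_in: np.ndarray            # (N, M)
    seed: int
    _W_rec_f32: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def N(self) -> int:
        return self.W_rec.shape[0]

    @property
    def num_inputs(self) -> int:
        return self.W_in.shape[1]

    def recurrent_as(self, dtype: str) -> np.ndarray:
        if dtype == "float64":
            return self.W_rec
        if self._W_rec_f32 is None:
            self._W_rec_f32 = np.ascontiguousarray(self.W_rec, dtype=np.float32)
        return self._W_rec_f32


@dataclass
class ActivityTrace:
    """Rate trajectory of one trial: ``rates[t]`` is y at time (t+1)*dt."""

    rates: np.ndarray           # (T, N)
    times: np.ndarray           # (T,), ms
    decision_index: int

    @property
    def decision_rates(self) -> np.ndarray:
        return self.rates[self.decision_index]


def build_reservoir_weights(
    params: ReservoirParams, num_inputs: int, seed: int
) -> ReservoirWeights:
    """Draw the fixed recurrent and input matrices for a given seed.

    Recurrent entries are zero with probability 1-p, otherwise Gaussian
    with variance 1/(pN) (the gain g is applied in the dynamics, so the
    effective coupling variance is g^2/(pN)). Input entries are zero with
    probability 1-p_IR, otherwise Gaussian with std g_IR.
    """
    if num_inputs < 1:
        raise ValueError("num_inputs must be >= 1")
    rng = np.random.default_rng(seed)
    N = params.N
    rec_std = 1.0 / np.sqrt(params.p * N)
    if params.literal_double_gain:
        rec_std *= params.g
    W_rec = rng.normal(0.0, rec_std, size=(N, N))
    W_rec[rng.random((N, N)) >= params.p] = 0.0
    W_in = rng.normal(0.0, params.g_IR, size=(N, num_inputs))
    W_in[rng.random((N, num_inputs)) >= params.p_IR] = 0.0
    return ReservoirWeights(W_rec=W_rec, W_in=W_in, seed=seed)


def rate_transfer(
    x: np.ndarray | float, y0: float = 0.1, ymin: float = 0.0, ymax: float = 1.0
) -> np.ndarray | float:
    """Saturating rate function, elementwise.

    For x <= 0: y = y0 + y0*tanh(x/y0); for x > 0:
    y = y0 + (ymax - y0)*tanh(x/(ymax - y0)). Continuous at 0 with unit
    slope, monotone non-decreasing, with limits 0 and ymax.
    """
    x = np.asarray(x, dtype=float)
    neg = y0 + y0 * np.tanh(x / y0)
    pos = y0 + (ymax - y0) * np.tanh(x / (ymax - y0))
    out = np.where(x <= 0, neg, pos)
    return out if out.ndim else float(out)


def integrate_with_rng(weights, schedule, params, rng) -> ActivityTrace:
    """Integrate one trial drawing x(0) and the step noise from ``rng``."""
    inputs = np.asarray(schedule.inputs)
    M, T = inputs.shape
    if M != weights.num_inputs:
        raise ValueError(
            f"schedule has {M} input rows but W_in expects {weights.num_inputs}"
        )
    decision_index = int(round(schedule.decision_time / params.dt)) - 1
    if not 0 <= decision_index < T:
        raise ValueError("schedule shorter than the decision time")
    dtype = np.dtype(params.dtype)
    x0 = rng.normal(0.0, params.sigma_ini, size=weights.N).astype(dtype)
    noise = rng.random((T, weights.N), dtype=np.float32).astype(dtype, copy=False)
    if params.zero_mean_noise:
        noise = noise - dtype.type(0.5)
    # segment-code the drive: one projected column per stretch of constant input
    change = np.empty(T, dtype=bool)
    change[0] = True
    np.any(inputs[:, 1:] != inputs[:, :-1], axis=0, out=change[1:])
    starts = np.flatnonzero(change)
    seg = (np.cumsum(change) - 1).astype(np.int32)
    drive = np.ascontiguousarray((weights.W_in @ inputs[:, starts]).T, dtype=dtype)
    W = weights.recurrent_as(params.dtype)
    rates = euler_integrate(
        W,
        dtype.type(params.g),
        drive,
        seg,
        x0,
        noise,
        dtype.type(params.dt / params.tau),
        dtype.type(params.sigma_noise),
        dtype.type(params.y0),
        dtype.type(params.ymax),
    )
    times = (np.arange(1, T + 1) * params.dt).astype(float)
    return ActivityTrace(rates=rates, times=times, decision_index=decision_index)


def integrate_trial(weights, schedule, params, seed: int) -> ActivityTrace:
    """Deterministic trial integration: a pure function of (inputs, seed)."""
    return integrate_with_rng(weights, schedule, params, np.random.default_rng(seed))
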