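"""Hybrid model-free / model-based reinforcement-learning fit.

The one-choice-per-trial simplification of the Daw two-step hybrid
model: a model-free learner caches values of the intermediate states and
passes an eligibility-weighted share of their prediction error back to
the chosen first-stage option, while a model-based learner re-derives
the first-stage values through the (true, fixed) transition matrix. The
net value is the w-weighted mixture, and choices follow a softmax with
fixed inverse temperature beta = 2 and no perseveration term. The free
parameters (alpha1, alpha2, lambda, w) live in [0, 1]^4 and are
estimated by maximum likelihood with multiple restarts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["HybridModel", "HybridResults", "hybrid_loglik", "simulate_hybrid_agent"]

_PARAM_NAMES = ("alpha1", "alpha2", "lambda", "w")


@numba.njit(cache=True)
def _negloglik(theta, choices, intermediates, rewards, p_common, beta):
    a1, a2, lam, w = theta[0], theta[1], theta[2], theta[3]
    # state order: A1, A2, B1, B2
    vmf = np.zeros(4)
    vmb = np.zeros(4)
    nll = 0.0
    for t in range(choices.shape[0]):
        d = beta * ((w * vmb[0] + (1 - w) * vmf[0]) - (w * vmb[1] + (1 - w) * vmf[1]))
        # stable log p(choice)
        if choices[t] == 0:
            nll += np.log(1.0 + np.exp(-d)) if d > -30 else -d
        else:
            nll += np.log(1.0 + np.exp(d)) if d < 30 else d
        b = 2 + intermediates[t]
        c = choices[t]
        r = rewards[t]
        old_b = vmf[b]
        vmf[b] = old_b + a1 * (r - old_b)
        vmf[c] += a1 * lam * (vmf[b] - old_b)
        vmb[b] += a2 * (r - vmb[b])
        vmb[0] = p_common * vmb[2] + (1.0 - p_common) * vmb[3]
        vmb[1] = (1.0 - p_common) * vmb[2] + p_common * vmb[3]
    return nll


def hybrid_loglik(
    params,
    choices: np.ndarray,
    intermediates: np.ndarray,
    rewards: np.ndarray,
    p_common: float = 0.8,
    beta: float = 2.0,
) -> float:
    """Log-likelihood of a two-stage choice sequence under the hybrid model.

    ``params`` is (alpha1, alpha2, lambda, w). Value updates per trial:
    the observed intermediate state's cached value moves toward the
    reward (model-free, rate alpha1; model-based, rate alpha2), the
    chosen option inherits lambda times the model-free update, and both
    first-stage model-based values are recomputed through the transition
    matrix. Unobserved states are left unchanged.
    """
    theta = np.asarray(params, dtype=float)
    if theta.shape != (4,):
        raise ValueError("params must be (alpha1, alpha2, lambda, w)")
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("hybrid parameters must lie in [0, 1]")
    return -float(_negloglik(
        theta,
        np.ascontiguousarray(choices, dtype=np.int64),
        np.ascontiguousarray(intermediates, dtype=np.int64),
        np.ascontiguousarray(rewards, dtype=np.float64),
        float(p_common), float(beta),
    ))


class HybridModel:
    """Maximum-likelihood hybrid MF/MB model for one behavioral session.

    Parameters
    ----------
    choices, intermediates, rewards : per-trial integer/float arrays
        (first-stage choice 0/1, intermediate outcome 0/1, reward).
    p_common : fixed common-transition probability of the environment.
    beta : fixed softmax inverse temperature (matches the generator).
    """

    def __init__(self, choices, intermediates, rewards,
                 p_common: float = 0.8, beta: float = 2.0):
        self.choices = np.asarray(choices, dtype=np.int64)
        self.intermediates = np.asarray(intermediates, dtype=np.int64)
        self.rewards = np.asarray(rewards, dtype=np.float64)
        if not (len(self.choices) == len(self.intermediates) == len(self.rewards)):
            raise ValueError("inputs must have equal length")
        self.p_common = float(p_common)
        self.beta = float(beta)

    @classmethod
    def from_log(cls, log: pd.DataFrame, p_common: float = 0.8,
                 beta: float = 2.0) -> "HybridModel":
        mask = np.isfinite(log["intermediate"].to_numpy(dtype=float))
        return cls(
            log.loc[mask, "choice"], log.loc[mask, "intermediate"],
            log.loc[mask, "reward"], p_common=p_common, beta=beta,
        )

    @property
    def nobs(self) -> int:
        return len(self.choices)

    def loglik(self, params) -> float:
        return hybrid_loglik(params, self.choices, self.intermediates,
                             self.rewards, self.p_common, self.beta)

    #: restart solutions within this many nats of the best are treated as
    #: ties; see fit().
    degeneracy_tol: float = 0.1

    def fit(self, restarts: int = 20, seed: int = 0) -> "HybridResults":
        """Bounded quasi-Newton optimization from multiple random starts.

        When the likelihood is flat in some direction (e.g. behavior with
        no reward dependence leaves w unidentified because the learning
        rates fit to zero), the maximizer is a set rather than a point
        and restarts land arbitrarily on it. Among restart solutions
        within ``degeneracy_tol`` nats of the best, the minimum-norm
        parameter vector is returned — a deterministic minimal-complexity
        convention for set-valued maxima, akin to pseudo-inverse
        solutions of rank-deficient least squares.
        """
        if self.nobs < 100:
            raise ValueError("need at least 100 trials to fit")
        args = (
            np.ascontiguousarray(self.choices),
            np.ascontiguousarray(self.intermediates),
            np.ascontiguousarray(self.rewards),
            self.p_common, self.beta,
        )
        rng = np.random.default_rng(seed)
        starts = [np.full(4, 0.5)] + [rng.random(4) for _ in range(restarts - 1)]
        solutions = []
        for x0 in starts:
            res = optimize.minimize(
                _negloglik, x0, args=args, method="L-BFGS-B",
                bounds=[(0.0, 1.0)] * 4,
            )
            if np.isfinite(res.fun):
                solutions.append(res)
        if not solutions:
            raise RuntimeError("hybrid fit failed on all restarts")
        fun_best = min(s.fun for s in solutions)
        ties = [s for s in solutions if s.fun <= fun_best + self.degeneracy_tol]
        best = min(ties, key=lambda s: float(np.linalg.norm(s.x)))
        se = self._standard_errors(best.x, args)
        return HybridResults(
            params=pd.Series(best.x, index=_PARAM_NAMES),
            bse=pd.Series(se, index=_PARAM_NAMES),
            loglik=-float(best.fun), nobs=self.nobs, model=self,
        )

    @staticmethod
    def _standard_errors(x, args):
        """Inverse observed information; NaN at the box boundary."""
        try:
            from statsmodels.tools.numdiff import approx_hess1

            H = approx_hess1(x, _negloglik, args=args)
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except Exception:
            return np.full(4, np.nan)
        se[(x < 1e-6) | (x > 1 - 1e-6)] = np.nan
        return se

    def simulate(self, params, n_trials: int, seed: int = 0, env=None) -> pd.DataFrame:
        """Generate synthetic behavior from the hybrid agent itself.

        Runs the agent closed-loop in a two-stage environment (a default
        one is created when ``env`` is None) and returns a log usable by
        the behavioral analyses and by :meth:`fit` (parameter recovery).
        """
        from .tasks import TwoStageConfig, TwoStageEnv

        a1, a2, lam, w = np.asarray(params, dtype=float)
        if env is None:
            env = TwoStageEnv(TwoStageConfig())
            env.reset(seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        vmf = np.zeros(4)
        vmb = np.zeros(4)
        rows = []
        for t in range(n_trials):
            d = self.beta * (
                (w * vmb[0] + (1 - w) * vmf[0]) - (w * vmb[1] + (1 - w) * vmf[1])
            )
            p0 = 1.0 / (1.0 + np.exp(-d))
            c = int(rng.random() >= p0)
            out = env.step(c)
            b = 2 + out["intermediate"]
            r = float(out["reward"])
            old_b = vmf[b]
            vmf[b] = old_b + a1 * (r - old_b)
            vmf[c] += a1 * lam * (vmf[b] - old_b)
            vmb[b] += a2 * (r - vmb[b])
            vmb[0] = self.p_common * vmb[2] + (1 - self.p_common) * vmb[3]
            vmb[1] = (1 - self.p_common) * vmb[2] + self.p_common * vmb[3]
            rows.append({"trial": t, **out, "choice": c, "p0": p0})
        return pd.DataFrame(rows)


def simulate_hybrid_agent(
    params, n_trials: int, seed: int = 0, p_common: float = 0.8, beta: float = 2.0
) -> pd.DataFrame:
    """Convenience wrapper: synthetic two-stage behavior of a hybrid agent."""
    empty = np.empty(0, dtype=np.int64)
    model = HybridModel(empty, empty, empty.astype(float),
                        p_common=p_common, beta=beta)
    return model.simulate(params, n_trials, seed=seed)


@dataclass
class HybridResults:
    params: pd.Series
    bse: pd.Series
    loglik: float
    nobs: int
    model: HybridModel = field(repr=False)

    @property
    def w(self) -> float:
        return float(self.params["w"])

    def summary(self) -> str:
        lines = [
            "Hybrid MF/MB reinforcement-learning fit",
            f"  n trials: {self.nobs}   log-likelihood: {self.loglik:.2f}",
            f"  fixed: beta = {self.model.beta}, perseveration = 0, "
            f"P(common) = {self.model.p_common}",
            "  parameter   estimate      se",
        ]
        for name in _PARAM_NAMES:
            lines.append(
                f"  {name:<10}  {self.params[name]:8.4f}  {self.bse[name]:8.4f}"
            )
        return "\n".join(lines)
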