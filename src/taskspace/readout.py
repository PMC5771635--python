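"""Softmax decision readout and the reward-modulated Hebbian rule.

Two output units (the decision-making layer) receive the reservoir's
decision-time rates through a plastic weight matrix whose columns are
kept at unit Euclidean norm. Choice is stochastic via a softmax on the
summed drives; after the outcome, the chosen column moves by

    dW_ik = eta * (r - E[r]) * (y_i - y_th) * z_k

— a three-factor rule gated by the reward prediction error — and every
column is renormalized, which stops the weights from growing without
bound.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DecisionParams",
    "ReadoutWeights",
    "ChoiceOutcome",
    "init_readout_weights",
    "choice_probabilities",
    "sample_choice",
    "hebbian_update",
]


@dataclass(frozen=True)
class DecisionParams:
    beta: float = 4.0            # softmax inverse temperature
    eta: float = 0.001           # Hebbian learning rate
    y_th: float = 0.2            # presynaptic rate threshold
    # "preferred" uses exp(+beta v): rewarded strengthening of a drive
    # raises its choice probability. "literal" is the printed exp(-beta v),
    # kept available because the source equation is presumed a typo.
    sign_convention: str = "preferred"

    def __post_init__(self) -> None:
        if self.beta < 0 or self.eta < 0:
            raise ValueError("beta and eta must be non-negative")
        if not 0.0 <= self.y_th <= 1.0:
            raise ValueError("y_th must lie in [0, 1]")
        if self.sign_convention not in ("preferred", "literal"):
            raise ValueError("sign_convention must be 'preferred' or 'literal'")

    def replace(self, **kw) -> "DecisionParams":
        return replace(self, **kw)


@dataclass
class ReadoutWeights:
    """Plastic reservoir-to-output weights; columns stay unit-norm."""

    W2: np.ndarray              # (N, K)
    trial_index: int = 0        # number of updates applied

    def copy(self) -> "ReadoutWeights":
        return ReadoutWeights(W2=self.W2.copy(), trial_index=self.trial_index)

    def column_norms(self) -> np.ndarray:
        return np.linalg.norm(self.W2, axis=0)


@dataclass
class ChoiceOutcome:
    chosen: int
    probs: np.ndarray           # (K,)
    z: np.ndarray               # (K,) one-hot at chosen
    expected_reward: float      # E[r] used by the weight update


def init_readout_weights(N: int, K: int, seed: int) -> ReadoutWeights:
    """Uniform [0, 1] entries, then each column scaled to unit norm."""
    if N < 1 or K < 1:
        raise ValueError("N and K must be >= 1")
    rng = np.random.default_rng(seed)
    W2 = rng.random((N, K))
    W2 /= np.linalg.norm(W2, axis=0, keepdims=True)
    return ReadoutWeights(W2=W2, trial_index=0)


def choice_probabilities(
    y: np.ndarray, W2: ReadoutWeights | np.ndarray, beta: float,
    convention: str = "preferred",
) -> np.ndarray:
    """Softmax over the output drives v_k = sum_i w_ik y_i (overflow-safe)."""
    W = W2.W2 if isinstance(W2, ReadoutWeights) else W2
    v = np.asarray(y, dtype=float) @ W
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite readout drive")
    sign = 1.0 if convention == "preferred" else -1.0
    logits = sign * beta * v
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def sample_choice(
    probs: np.ndarray, rng: np.random.Generator,
    expected_reward: float | None = None,
) -> ChoiceOutcome:
    """Draw a choice by inverse-CDF from ``probs`` on a dedicated stream.

    For binary-reward tasks E[r] equals the probability of the chosen
    option; tasks with graded rewards supply ``expected_reward``
    externally (it is data to the weight update, never recomputed here).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValueError("probs must be a 1-D probability vector")
    u = rng.random()
    chosen = int(np.searchsorted(np.cumsum(probs), u, side="right"))
    chosen = min(chosen, len(probs) - 1)
    z = np.zeros(len(probs))
    z[chosen] = 1.0
    er = float(probs[chosen]) if expected_reward is None else float(expected_reward)
    return ChoiceOutcome(chosen=chosen, probs=probs, z=z, expected_reward=er)


def hebbian_update(
    W2: ReadoutWeights, y: np.ndarray, outcome: ChoiceOutcome, r: float,
    params: DecisionParams,
) -> ReadoutWeights:
    """Apply the reward-prediction-error-gated Hebbian step and renormalize.

    Only the chosen column receives the increment (z_k gating); all
    columns are renormalized, which is a no-op for the unchosen ones.
    """
    if not np.isfinite(r) or not np.isfinite(outcome.expected_reward):
        raise FloatingPointError("non-finite reward or expected reward")
    W = W2.W2.copy()
    rpe = r - outcome.expected_reward
    W[:, outcome.chosen] += params.eta * rpe * (np.asarray(y, dtype=float) - params.y_th)
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    return ReadoutWeights(W2=W, trial_index=W2.trial_index + 1)
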