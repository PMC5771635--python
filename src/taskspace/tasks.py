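"""Task environments and trial input schedules.

Three paradigms drive the network. In each, what the input layer shows
on trial *n* is the choice and outcome of trial *n-1* (the network must
decide from its internal encoding of the previous trial's events), and
the decision is read off the reservoir at a fixed within-trial time.

* Reversal learning: two options, one rewarded; the contingency flips
  every ``block_length`` trials. Inputs: chosen option (A/B) and reward
  (R), concurrent boxcars.
* Two-stage Markov decision task: options A1/A2 lead to intermediate
  outcomes B1/B2 (80/20 transitions, fixed); reward depends only on the
  intermediate outcome, with the good outcome flipping every block.
  Inputs are sequential boxcars: A, then B, then reward/non-reward.
* Value-based economic choice: two offers with magnitudes drawn each
  trial; option A is worth ``gamma`` times option B per unit magnitude.
  Inputs are range-adapted transient profiles mimicking sensory neurons.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TrialSchedule",
    "ReversalConfig",
    "TwoStageConfig",
    "EconChoiceConfig",
    "ReversalEnv",
    "TwoStageEnv",
    "EconChoiceEnv",
    "make_reversal_schedule",
    "make_twostage_schedule",
    "make_econ_schedule",
    "econ_input_profile",
    "econ_expected_value",
]


@dataclass
class TrialSchedule:
    """Per-input-unit drive over one trial plus the decision read-off time."""

    inputs: np.ndarray          # (M, T) at dt=1 ms, values in [0, 1]
    decision_time: float        # ms
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.inputs.min() < 0 or self.inputs.max() > 1:
            raise ValueError("schedule activities must lie in [0, 1]")
        if self.decision_time > self.inputs.shape[1]:
            raise ValueError("decision time exceeds trial duration")


# ---------------------------------------------------------------------------
# Reversal learning


@dataclass(frozen=True)
class ReversalConfig:
    block_length: int = 100
    stim_on: int = 200              # ms
    stim_off: int = 700             # ms
    decision_time: int = 900        # ms
    criterion_initial: tuple[int, int] = (28, 30)   # m-of-n, first block
    criterion_reversal: tuple[int, int] = (24, 30)  # m-of-n, later blocks
    reward_input_present: bool = True
    first_rewarded: int = 0         # option rewarded in block 0 (0 = A)
    labels: tuple[str, ...] = ("A", "B", "R")

    def replace(self, **kw) -> "ReversalConfig":
        return replace(self, **kw)

    @property
    def num_inputs(self) -> int:
        return len(self.labels)


class ReversalEnv:
    """Deterministic reward contingency that flips every block."""

    def __init__(self, cfg: ReversalConfig):
        self.cfg = cfg
        self.trial = 0

    def reset(self, seed: Optional[int] = None) -> None:
        self.trial = 0

    def rewarded_option(self, trial: Optional[int] = None) -> int:
        t = self.trial if trial is None else trial
        block = t // self.cfg.block_length
        return self.cfg.first_rewarded if block % 2 == 0 else 1 - self.cfg.first_rewarded

    @property
    def block(self) -> int:
        return self.trial // self.cfg.block_length

    def step(self, choice: int) -> dict:
        good = self.rewarded_option()
        out = {
            "trial": self.trial,
            "block": self.block,
            "block_type": "AB"[good],
            "reward": int(choice == good),
            "correct": int(choice == good),
        }
        self.trial += 1
        return out


def make_reversal_schedule(
    prev_choice: int, prev_reward: int, cfg: ReversalConfig
) -> TrialSchedule:
    """Concurrent boxcars: the previously chosen option, and reward if any.

    With ``reward_input_present=False`` the reward row is zeroed — the
    lesion model in which outcome information never reaches the
    reservoir.
    """
    T = cfg.decision_time
    inputs = np.zeros((cfg.num_inputs, T))
    sl = slice(cfg.stim_on, cfg.stim_off)
    inputs[prev_choice, sl] = 1.0
    if prev_reward and cfg.reward_input_present:
        inputs[2, sl] = 1.0
    return TrialSchedule(inputs=inputs, decision_time=cfg.decision_time,
                         labels=cfg.labels)


# ---------------------------------------------------------------------------
# Two-stage Markov decision task


@dataclass(frozen=True)
class TwoStageConfig:
    common_prob: float = 0.8
    reward_prob_hi: float = 0.8
    reward_prob_lo: float = 0.2
    block_length: int = 50
    A_window: tuple[int, int] = (200, 700)      # ms
    B_window: tuple[int, int] = (700, 1200)
    R_window: tuple[int, int] = (1200, 1700)
    decision_time: int = 1900                   # ms
    event_order: str = "A-first"                # or "B-first"
    reward_input_present: bool = True
    nonreward_input_present: bool = True
    first_good_intermediate: int = 0            # B1 rewarded at hi prob in block 0
    labels: tuple[str, ...] = ("A1", "A2", "B1", "B2", "R", "N")

    def replace(self, **kw) -> "TwoStageConfig":
        return replace(self, **kw)

    def __post_init__(self) -> None:
        for q in (self.common_prob, self.reward_prob_hi, self.reward_prob_lo):
            if not 0.0 <= q <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.event_order not in ("A-first", "B-first"):
            raise ValueError("event_order must be 'A-first' or 'B-first'")

    @property
    def num_inputs(self) -> int:
        return len(self.labels)


class TwoStageEnv:
    """Fixed 80/20 transitions; reward contingency flips every block."""

    def __init__(self, cfg: TwoStageConfig):
        self.cfg = cfg
        self.trial = 0
        self.rng = np.random.default_rng()

    def reset(self, seed: Optional[int] = None) -> None:
        self.trial = 0
        self.rng = np.random.default_rng(seed)

    @property
    def block(self) -> int:
        return self.trial // self.cfg.block_length

    def good_intermediate(self, trial: Optional[int] = None) -> int:
        t = self.trial if trial is None else trial
        block = t // self.cfg.block_length
        g = self.cfg.first_good_intermediate
        return g if block % 2 == 0 else 1 - g

    def step(self, choice: int) -> dict:
        cfg = self.cfg
        common = self.rng.random() < cfg.common_prob
        intermediate = choice if common else 1 - choice
        p_r = cfg.reward_prob_hi if intermediate == self.good_intermediate() else cfg.reward_prob_lo
        reward = int(self.rng.random() < p_r)
        # the currently better first-stage option is the one whose common
        # outcome is the good intermediate
        good = self.good_intermediate()
        out = {
            "trial": self.trial,
            "block": self.block,
            "block_type": f"B{good + 1}",
            "intermediate": intermediate,
            "common": int(common),
            "reward": reward,
            "correct": int(choice == good),
        }
        self.trial += 1
        return out


def make_twostage_schedule(
    choice: int, intermediate: int, reward: int, cfg: TwoStageConfig
) -> TrialSchedule:
    """Sequential boxcars: chosen A unit, observed B unit, then R or N.

    ``event_order="B-first"`` swaps the A and B windows (a control for
    recency of the intermediate outcome at decision time).
    """
    T = cfg.decision_time
    inputs = np.zeros((cfg.num_inputs, T))
    a_win, b_win = cfg.A_window, cfg.B_window
    if cfg.event_order == "B-first":
        a_win, b_win = b_win, a_win
    inputs[choice, slice(*a_win)] = 1.0
    inputs[2 + intermediate, slice(*b_win)] = 1.0
    if reward:
        if cfg.reward_input_present:
            inputs[4, slice(*cfg.R_window)] = 1.0
    elif cfg.nonreward_input_present:
        inputs[5, slice(*cfg.R_window)] = 1.0
    return TrialSchedule(inputs=inputs, decision_time=cfg.decision_time,
                         labels=cfg.labels)


# ---------------------------------------------------------------------------
# Value-based economic choice


@dataclass(frozen=True)
class EconChoiceConfig:
    gamma: float = 2.0                  # relative value of A vs B
    offers_A: tuple[int, ...] = (0, 1, 2, 3)
    offers_B: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 8)
    stim_on: int = 300                  # ms
    stim_off: int = 1300                # ms
    decision_time: int = 1400           # ms
    rise_center: float = 475.0          # ms, sigmoid onset of the profile
    rise_slope: float = 30.0
    decay_center: float = 700.0
    decay_slope: float = 100.0
    step_profile: bool = False          # flat boxcar variant of the profile
    # Rewards and expected values are expressed in units of the largest
    # available option value, keeping the reward-prediction error on the
    # same [0, 1] scale as the binary-reward tasks. Set False for raw
    # juice-value units.
    normalize_reward: bool = True
    labels: tuple[str, ...] = ("offerA", "offerB")

    def replace(self, **kw) -> "EconChoiceConfig":
        return replace(self, **kw)

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if min(self.offers_A) < 0 or min(self.offers_B) < 0:
            raise ValueError("offer magnitudes must be non-negative")

    @property
    def num_inputs(self) -> int:
        return len(self.labels)

    @property
    def value_unit(self) -> float:
        """Scale of the reward units fed to the learning rule."""
        if not self.normalize_reward:
            return 1.0
        return max(self.gamma * max(self.offers_A), float(max(self.offers_B)))


class EconChoiceEnv:
    """Draws offer pairs uniformly from the grid, excluding (0, 0)."""

    def __init__(self, cfg: EconChoiceConfig):
        self.cfg = cfg
        self.trial = 0
        self.rng = np.random.default_rng()

    def reset(self, seed: Optional[int] = None) -> None:
        self.trial = 0
        self.rng = np.random.default_rng(seed)

    def draw_offers(self) -> tuple[int, int]:
        while True:
            m_a = int(self.rng.choice(self.cfg.offers_A))
            m_b = int(self.rng.choice(self.cfg.offers_B))
            if (m_a, m_b) != (0, 0):
                return m_a, m_b

    def step(self, choice: int, offers: tuple[int, int]) -> dict:
        m_a, m_b = offers
        reward = self.cfg.gamma * m_a if choice == 0 else float(m_b)
        reward /= self.cfg.value_unit
        out = {
            "trial": self.trial,
            "offer_A": m_a,
            "offer_B": m_b,
            "reward": reward,
            "correct": int((self.cfg.gamma * m_a >= m_b) == (choice == 0)),
        }
        self.trial += 1
        return out


def econ_input_profile(
    t: np.ndarray | float, mag: float, mag_max: float, mag_min: float,
    cfg: EconChoiceConfig,
) -> np.ndarray | float:
    """Range-adapted transient drive for one offer.

    g(t) is a product of a rising and a decaying sigmoid; the drive is
    (mag - mag_min) * g(t) normalized so the block-maximal offer peaks at
    1, and zero outside the stimulus window.
    """
    if mag_max <= mag_min:
        raise ValueError("degenerate offer range: mag_max must exceed mag_min")
    t = np.asarray(t, dtype=float)
    grid = np.arange(cfg.stim_on, cfg.stim_off, 1.0)
    if cfg.step_profile:
        g = np.ones_like(t)
        g_max = 1.0
    else:
        def _g(u):
            return 1.0 / (
                (1.0 + np.exp(-(u - cfg.rise_center) / cfg.rise_slope))
                * (1.0 + np.exp((u - cfg.decay_center) / cfg.decay_slope))
            )
        g = _g(t)
        g_max = _g(grid).max()
    f = (mag - mag_min) * g / ((mag_max - mag_min) * g_max)
    window = (t >= cfg.stim_on) & (t < cfg.stim_off)
    out = np.where(window, f, 0.0)
    return out if out.ndim else float(out)


def make_econ_schedule(
    offers: tuple[float, float], cfg: EconChoiceConfig
) -> TrialSchedule:
    """Two offer-magnitude inputs with the range-adapted transient profile."""
    T = cfg.decision_time
    t = np.arange(1, T + 1, dtype=float)
    inputs = np.zeros((2, T))
    maxima = (max(cfg.offers_A), max(cfg.offers_B))
    minima = (min(cfg.offers_A), min(cfg.offers_B))
    for i in range(2):
        inputs[i] = econ_input_profile(t, offers[i], maxima[i], minima[i], cfg)
    return TrialSchedule(inputs=inputs, decision_time=cfg.decision_time,
                         labels=cfg.labels)


def econ_expected_value(
    probs: Sequence[float], mags: tuple[float, float], gamma: float
) -> float:
    """E[r] = p_A * (gamma * m_A) + p_B * m_B (the graded-reward case)."""
    return float(probs[0] * gamma * mags[0] + probs[1] * mags[1])
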