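"""Closed-loop training sessions and session-level manipulations.

A session alternates environment and network: the events of trial *n-1*
(choice, intermediate outcome, reward) are presented as trial *n*'s
inputs, the reservoir is integrated, the readout picks the next choice,
the environment returns the outcome, and the readout weights take one
Hebbian step. The very first trial uses a randomly selected choice input
with the environment-consistent reward and applies no weight update.

Manipulations supported here: removing the reward input (a lesion of the
outcome pathway), freezing learning after a given trial, and zeroing a
set of neurons at the readout stage only (decision-time inactivation;
the reservoir integration itself is untouched).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .readout import (
    DecisionParams,
    ReadoutWeights,
    choice_probabilities,
    hebbian_update,
    init_readout_weights,
    sample_choice,
)
from .reservoir import (
    ReservoirParams,
    ReservoirWeights,
    build_reservoir_weights,
    integrate_with_rng,
)
from . import tasks as _tasks
from .tasks import (
    EconChoiceConfig,
    EconChoiceEnv,
    ReversalConfig,
    ReversalEnv,
    TwoStageConfig,
    TwoStageEnv,
    econ_expected_value,
    make_econ_schedule,
    make_reversal_schedule,
    make_twostage_schedule,
)

__all__ = [
    "SessionConfig",
    "SessionResult",
    "default_params",
    "run_session",
    "errors_to_criterion",
    "apply_inactivation",
    "select_inactivation_group",
]

#: Per-task reservoir and decision parameters, as used throughout.
_TASK_PRESETS = {
    "reversal": dict(
        reservoir=dict(tau=100.0, g=2.0, sigma_noise=0.01, sigma_ini=0.01, g_IR=4.0),
        decision=dict(beta=4.0, eta=0.001, y_th=0.2),
        config=ReversalConfig,
    ),
    "twostage": dict(
        reservoir=dict(tau=500.0, g=2.25, sigma_noise=0.01, sigma_ini=0.01, g_IR=2.0),
        decision=dict(beta=2.0, eta=0.001, y_th=0.2),
        config=TwoStageConfig,
    ),
    "econ": dict(
        reservoir=dict(tau=100.0, g=2.5, sigma_noise=0.05, sigma_ini=0.2, g_IR=2.0),
        decision=dict(beta=4.0, eta=0.005, y_th=0.2),
        config=EconChoiceConfig,
    ),
}


def default_params(task: str, **reservoir_overrides):
    """Standard (ReservoirParams, DecisionParams) for a task."""
    if task not in _TASK_PRESETS:
        raise ValueError(f"unknown task {task!r}")
    preset = _TASK_PRESETS[task]
    res = ReservoirParams(**{**preset["reservoir"], **reservoir_overrides})
    dec = DecisionParams(**preset["decision"])
    return res, dec


@dataclass
class SessionConfig:
    """Everything needed to reproduce a session bit-for-bit."""

    task: str                               # 'reversal' | 'twostage' | 'econ'
    task_config: object = None              # per-task config dataclass
    reservoir: Optional[ReservoirParams] = None
    decision: Optional[DecisionParams] = None
    n_trials: int = 1000
    seed: int = 0
    freeze_after_trial: Optional[int] = None  # no updates from this trial on (0 = frozen)
    inactivate: Optional[np.ndarray] = None   # neuron indices zeroed at readout
    collect_traces: bool = False
    trace_from_trial: int = 0
    trace_stride: int = 5                   # ms between stored trace samples
    record_decision_rates: bool = True
    snapshot_every: Optional[int] = None    # readout snapshots; default block length
    weights: Optional[ReservoirWeights] = None   # reuse a built reservoir
    readout: Optional[ReadoutWeights] = None     # continue from trained readout

    def __post_init__(self) -> None:
        if self.task not in _TASK_PRESETS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.task_config is None:
            self.task_config = _TASK_PRESETS[self.task]["config"]()
        if self.reservoir is None or self.decision is None:
            res, dec = default_params(self.task)
            self.reservoir = self.reservoir or res
            self.decision = self.decision or dec
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if self.inactivate is not None:
            idx = np.asarray(self.inactivate, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= self.reservoir.N):
                raise ValueError("inactivation indices out of range")
            self.inactivate = idx


@dataclass
class SessionResult:
    log: pd.DataFrame
    weights: ReservoirWeights
    readout: ReadoutWeights
    decision_rates: Optional[np.ndarray]       # (n_trials, N), NaN where no decision
    window_rates: Optional[np.ndarray]         # econ: post-offer mean rates
    weight_history: list                       # [(trial, W2 copy), ...]
    condition_traces: dict                     # label -> (T', N) mean rate trace
    trace_times: Optional[np.ndarray]
    config: SessionConfig


def apply_inactivation(rates: np.ndarray, indices: Optional[np.ndarray]) -> np.ndarray:
    """Zero the given neurons' rates for the readout computation only."""
    if indices is None or len(indices) == 0:
        return rates
    out = rates.copy()
    out[indices] = 0.0
    return out


def select_inactivation_group(
    labels: np.ndarray,
    group: str,
    count: int,
    rng: Optional[np.random.Generator] = None,
    scores: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Pick ``count`` neurons to silence: a selectivity group or 'random'.

    Within a labelled group, neurons are ranked by ``scores`` (e.g. the
    selectivity F statistic) when given, else taken in index order.
    """
    labels = np.asarray(labels)
    if group == "random":
        if rng is None:
            rng = np.random.default_rng()
        if count > labels.size:
            raise ValueError("count exceeds population size")
        return np.sort(rng.choice(labels.size, size=count, replace=False))
    members = np.flatnonzero(labels == group)
    if members.size < count:
        raise ValueError(
            f"group {group!r} has {members.size} neurons, fewer than count={count}"
        )
    if scores is not None:
        members = members[np.argsort(np.asarray(scores)[members])[::-1]]
    return np.sort(members[:count])


def _seed_streams(seed: int):
    """Documented stream split: (reservoir build, readout init, trial noise,
    environment, choice sampling)."""
    children = np.random.SeedSequence(seed).spawn(5)
    build_seed = int(children[0].generate_state(1)[0] % (2 ** 31))
    readout_seed = int(children[1].generate_state(1)[0] % (2 ** 31))
    noise_rng = np.random.default_rng(children[2])
    env_seed = int(children[3].generate_state(1)[0] % (2 ** 31))
    choice_rng = np.random.default_rng(children[4])
    return build_seed, readout_seed, noise_rng, env_seed, choice_rng


def _condition_label(task: str, prev: dict) -> str:
    if task == "reversal":
        return f"{'AB'[prev['choice']]}{'NR'[prev['reward']]}"
    return (
        f"A{prev['choice'] + 1}B{prev['intermediate'] + 1}"
        f"{'NR'[int(prev['reward'] > 0)]}"
    )


def run_session(cfg: SessionConfig) -> SessionResult:
    """Run one closed-loop session; a pure function of the config."""
    task, tcfg = cfg.task, cfg.task_config
    build_seed, readout_seed, noise_rng, env_seed, choice_rng = _seed_streams(cfg.seed)
    weights = cfg.weights
    if weights is None:
        weights = build_reservoir_weights(cfg.reservoir, tcfg.num_inputs, build_seed)
    readout = cfg.readout.copy() if cfg.readout is not None else init_readout_weights(
        cfg.reservoir.N, 2, readout_seed
    )

    if task == "reversal":
        env = ReversalEnv(tcfg)
    elif task == "twostage":
        env = TwoStageEnv(tcfg)
    else:
        env = EconChoiceEnv(tcfg)
    env.reset(env_seed)

    n = cfg.n_trials
    N = cfg.reservoir.N
    dec_rates = np.full((n, N), np.nan, dtype=np.float32) if cfg.record_decision_rates else None
    win_rates = np.full((n, N), np.nan, dtype=np.float32) if task == "econ" else None
    snapshot_every = cfg.snapshot_every or getattr(tcfg, "block_length", 500) or 500
    weight_history: list = []
    trace_sums: dict = {}
    trace_counts: dict = {}
    trace_times = None
    rows = []

    frozen_from = np.inf if cfg.freeze_after_trial is None else cfg.freeze_after_trial
    prev: Optional[dict] = None

    for t in range(n):
        if t % snapshot_every == 0:
            weight_history.append((t, readout.copy()))
        if task == "econ":
            offers = env.draw_offers()
            schedule = make_econ_schedule(offers, tcfg)
        elif t == 0:
            # first trial: randomly selected choice input, environment-consistent
            # reward, no network decision and no update
            choice0 = int(choice_rng.integers(2))
            if task == "reversal":
                out = env.step(choice0)
                prev = {"choice": choice0, "reward": out["reward"]}
            else:
                out = env.step(choice0)
                prev = {"choice": choice0, "reward": out["reward"],
                        "intermediate": out["intermediate"]}
            rows.append({"trial": t, **out, "choice": choice0,
                         "p0": np.nan, "p1": np.nan,
                         "expected_reward": np.nan, "updated": False,
                         "input_choice": np.nan, "input_reward": np.nan})
            continue
        elif task == "reversal":
            schedule = make_reversal_schedule(prev["choice"], prev["reward"], tcfg)
        else:
            schedule = make_twostage_schedule(
                prev["choice"], prev["intermediate"], int(prev["reward"] > 0), tcfg
            )

        trace = integrate_with_rng(weights, schedule, cfg.reservoir, noise_rng)
        y = trace.decision_rates.astype(float)
        y_read = apply_inactivation(y, cfg.inactivate)
        probs = choice_probabilities(y_read, readout, cfg.decision.beta,
                                     cfg.decision.sign_convention)
        if task == "econ":
            er = econ_expected_value(probs, offers, tcfg.gamma) / tcfg.value_unit
        else:
            er = None
        outcome = sample_choice(probs, choice_rng, expected_reward=er)

        if task == "econ":
            out = env.step(outcome.chosen, offers)
        else:
            out = env.step(outcome.chosen)
        r = float(out["reward"])

        updated = False
        if t >= 1 and t < frozen_from:  # no update on a session's first trial
            readout = hebbian_update(readout, y_read, outcome, r, cfg.decision)
            updated = True

        row = {"trial": t, **out, "choice": outcome.chosen,
               "p0": probs[0], "p1": probs[1],
               "expected_reward": outcome.expected_reward, "updated": updated}
        if task != "econ":
            row["input_choice"] = prev["choice"]
            row["input_reward"] = int(prev["reward"] > 0)
            if task == "twostage":
                row["input_intermediate"] = prev["intermediate"]
        rows.append(row)

        if dec_rates is not None:
            dec_rates[t] = y
        if win_rates is not None:
            on = tcfg.stim_on
            win_rates[t] = trace.rates[on:on + 500].mean(axis=0)
        if cfg.collect_traces and t >= cfg.trace_from_trial and task != "econ":
            label = _condition_label(task, prev)
            sub = trace.rates[:: cfg.trace_stride].astype(np.float64)
            if label not in trace_sums:
                trace_sums[label] = np.zeros_like(sub)
                trace_counts[label] = 0
            trace_sums[label] += sub
            trace_counts[label] += 1
            if trace_times is None:
                trace_times = trace.times[:: cfg.trace_stride]

        if task == "reversal":
            prev = {"choice": outcome.chosen, "reward": out["reward"]}
        elif task == "twostage":
            prev = {"choice": outcome.chosen, "reward": out["reward"],
                    "intermediate": out["intermediate"]}

    weight_history.append((n, readout.copy()))
    log = pd.DataFrame(rows)
    traces = {k: trace_sums[k] / trace_counts[k] for k in trace_sums}
    return SessionResult(
        log=log, weights=weights, readout=readout,
        decision_rates=dec_rates, window_rates=win_rates,
        weight_history=weight_history, condition_traces=traces,
        trace_times=trace_times, config=cfg,
    )


def errors_to_criterion(
    log: pd.DataFrame,
    criterion_initial: tuple[int, int] = (28, 30),
    criterion_reversal: tuple[int, int] = (24, 30),
    initial_phase: bool = True,
) -> pd.DataFrame:
    """Per-block sliding-window learning criterion and errors before it.

    Within each block, the criterion is met at the first trial where the
    last ``n`` trials contain at least ``m`` correct ones (``(m, n)`` =
    ``criterion_initial`` for the session's first block when
    ``initial_phase``, else ``criterion_reversal``). Errors are counted
    strictly before that trial; blocks shorter than the window raise.
    """
    if "block" not in log.columns or "correct" not in log.columns:
        raise ValueError("log must carry 'block' and 'correct' columns")
    out = []
    for b, grp in log.groupby("block", sort=True):
        m, w = (
            criterion_initial if (initial_phase and b == log["block"].min())
            else criterion_reversal
        )
        correct = grp["correct"].to_numpy(dtype=int)
        if correct.size < w:
            raise ValueError(f"block {b} shorter than the {w}-trial window")
        csum = np.concatenate([[0], np.cumsum(correct)])
        met_at = None
        for i in range(w - 1, correct.size):
            if csum[i + 1] - csum[i + 1 - w] >= m:
                met_at = i
                break
        errors = int((1 - correct[:met_at]).sum()) if met_at is not None else int(
            (1 - correct).sum()
        )
        out.append({
            "block": int(b),
            "block_type": grp["block_type"].iloc[0] if "block_type" in grp else "",
            "criterion_met": met_at is not None,
            "trials_to_criterion": (met_at + 1) if met_at is not None else np.nan,
            "errors_before_criterion": errors,
            "n_trials": int(correct.size),
        })
    return pd.DataFrame(out)
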