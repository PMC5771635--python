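"""Miniature deterministic configurations for fast end-to-end testing.

A fixture shrinks the network (N=40) and the session (a couple of short
blocks) so the full simulate-then-analyze pipeline completes in seconds
while exercising every code path. Fixtures are generated, never stored.
"""
from __future__ import annotations

from .readout import DecisionParams
from .reservoir import ReservoirParams
from .session import SessionConfig, default_params
from .tasks import EconChoiceConfig, ReversalConfig, TwoStageConfig

__all__ = ["make_fixture"]


def make_fixture(kind: str, seed: int = 0) -> SessionConfig:
    """A tiny SessionConfig for the given task kind, deterministic in seed."""
    if kind == "reversal":
        task_config = ReversalConfig(block_length=40)
        n_trials = 80
    elif kind == "twostage":
        task_config = TwoStageConfig(block_length=20)
        n_trials = 60
    elif kind == "econ":
        task_config = EconChoiceConfig()
        n_trials = 60
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    reservoir, decision = default_params(kind)
    reservoir = reservoir.replace(N=40)
    return SessionConfig(
        task=kind, task_config=task_config, reservoir=reservoir,
        decision=decision, n_trials=n_trials, seed=seed,
        collect_traces=kind != "econ",
    )
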