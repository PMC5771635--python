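"""Drivers for the study's experiments and manipulations.

Each function composes sessions (:func:`taskspace.session.run_session`)
with the analysis battery: multi-seed reversal learning curves with and
without the reward input, decision-time inactivation of selectivity
groups, learning freezes, two-stage training with the factorial/stay
battery, and the economic-choice session. Replicate seeds are split from
a base seed with ``numpy`` SeedSequences so manipulations never shift
unrelated randomness.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .behavior import stay_table, ts_index
from .hybrid import HybridModel
from .population import classify_reversal_selectivity
from .session import (
    SessionConfig,
    SessionResult,
    default_params,
    errors_to_criterion,
    run_session,
    select_inactivation_group,
)
from .tasks import EconChoiceConfig, ReversalConfig, TwoStageConfig

__all__ = [
    "derive_seed",
    "reversal_learning_curves",
    "inactivation_experiment",
    "freeze_experiment",
    "twostage_experiment",
    "econ_experiment",
    "weight_difference_by_group",
    "ts_curve",
]


def derive_seed(*keys: int) -> int:
    """Deterministic child seed (< 2^31) from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2 ** 31))


def reversal_learning_curves(
    n_seeds: int = 10,
    n_blocks: int = 30,
    lesion: bool = False,
    base_seed: int = 0,
    block_length: int = 100,
    collect_traces_blocks: int = 0,
    keep_results: bool = False,
) -> tuple[pd.DataFrame, list]:
    """Errors-to-criterion learning curves across replicate networks.

    Each replicate builds an independent network and runs ``n_blocks``
    reversal blocks; with ``lesion`` the reward input is removed. Returns
    a tidy frame (seed x block) of the criterion analysis, plus the
    SessionResults when ``keep_results``.
    """
    cfg_task = ReversalConfig(block_length=block_length,
                              reward_input_present=not lesion)
    frames, results = [], []
    for s in range(n_seeds):
        n_trials = n_blocks * block_length
        cfg = SessionConfig(
            task="reversal", task_config=cfg_task, n_trials=n_trials,
            seed=derive_seed(base_seed, s, int(lesion)),
            collect_traces=collect_traces_blocks > 0,
            trace_from_trial=n_trials - collect_traces_blocks * block_length,
        )
        res = run_session(cfg)
        crit = errors_to_criterion(res.log, cfg_task.criterion_initial,
                                   cfg_task.criterion_reversal)
        crit.insert(0, "seed", s)
        frames.append(crit)
        if keep_results:
            results.append(res)
    return pd.concat(frames, ignore_index=True), results


def _selectivity_from_result(res: SessionResult, last_trials: int = 400):
    """Label neurons from the stored decision-time rates of the last trials."""
    log = res.log
    ok = np.isfinite(log["input_choice"].to_numpy(dtype=float))
    idx = log.index[ok][-last_trials:]
    rates = res.decision_rates[idx]
    conds = [
        f"{'AB'[int(c)]}{'NR'[int(r)]}"
        for c, r in zip(log.loc[idx, "input_choice"], log.loc[idx, "input_reward"])
    ]
    return classify_reversal_selectivity(rates, np.array(conds))


def inactivation_experiment(
    train_blocks: int = 30,
    test_blocks: int = 20,
    groups: Sequence[str] = ("random", "A", "AR"),
    count: int = 50,
    base_seed: int = 0,
    block_length: int = 100,
    trained: Optional[SessionResult] = None,
    skip_insufficient: bool = False,
) -> dict:
    """Decision-time silencing of selectivity groups in a trained network.

    Trains an intact network (or reuses ``trained``), freezes learning,
    classifies neurons by preferred input combination, then for each
    group zeroes ``count`` neurons at the readout stage only and runs
    further reversal blocks. Returns the selectivity frame and, per
    group, the per-block criterion analysis.
    """
    if trained is None:
        cfg = SessionConfig(
            task="reversal",
            task_config=ReversalConfig(block_length=block_length),
            n_trials=train_blocks * block_length,
            seed=derive_seed(base_seed, 901),
        )
        trained = run_session(cfg)
    sel = _selectivity_from_result(trained)
    labels = sel["label"].to_numpy()
    scores = sel["f_stat"].to_numpy()
    rng = np.random.default_rng(derive_seed(base_seed, 902))
    out = {"selectivity": sel, "groups": {}}
    tcfg = trained.config.task_config
    for g in groups:
        try:
            idx = select_inactivation_group(labels, g, count, rng=rng, scores=scores)
        except ValueError:
            if skip_insufficient:
                out["groups"][g] = {"indices": None, "criterion": None,
                                    "log": None, "skipped": True}
                continue
            raise
        test_cfg = SessionConfig(
            task="reversal", task_config=tcfg,
            n_trials=test_blocks * block_length,
            seed=derive_seed(base_seed, 903),   # same seed: matched test randomness
            freeze_after_trial=0, inactivate=idx,
            weights=trained.weights, readout=trained.readout,
        )
        res = run_session(test_cfg)
        crit = errors_to_criterion(res.log, initial_phase=False)
        out["groups"][g] = {"indices": idx, "criterion": crit, "log": res.log}
    return out


def freeze_experiment(
    pre_blocks: int = 50,
    post_blocks: int = 20,
    base_seed: int = 0,
    block_length: int = 100,
) -> pd.DataFrame:
    """Stop learning after ``pre_blocks`` reversals and keep testing.

    Returns the per-block criterion frame with a ``frozen`` column; the
    reversal adaptation established before the freeze should persist.
    """
    n_trials = (pre_blocks + post_blocks) * block_length
    cfg = SessionConfig(
        task="reversal", task_config=ReversalConfig(block_length=block_length),
        n_trials=n_trials, seed=derive_seed(base_seed, 905),
        freeze_after_trial=pre_blocks * block_length,
    )
    res = run_session(cfg)
    crit = errors_to_criterion(res.log)
    crit["frozen"] = crit["block"] >= pre_blocks
    return crit


def twostage_experiment(
    n_seeds: int = 10,
    n_train: int = 2000,
    n_analysis: int = 2000,
    lesion: bool = False,
    base_seed: int = 0,
    collect_traces: bool = False,
    fit_restarts: int = 10,
    keep_results: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list]:
    """Two-stage training with the factorial/stay/hybrid battery per seed.

    Learning continues through the analysis trials; the stay table, the
    task-structure index and the hybrid-model fit are computed on the
    final ``n_analysis`` trials. Returns one row per seed.
    """
    tcfg = TwoStageConfig(reward_input_present=not lesion,
                          nonreward_input_present=not lesion)
    rows, results = [], []
    for s in range(n_seeds):
        n_trials = n_train + n_analysis
        cfg = SessionConfig(
            task="twostage", task_config=tcfg, n_trials=n_trials,
            seed=derive_seed(base_seed, s, 10 + int(lesion)),
            collect_traces=collect_traces, trace_from_trial=n_train,
            record_decision_rates=collect_traces,
        )
        res = run_session(cfg)
        analysis = res.log.iloc[n_train:]
        table = stay_table(analysis)
        fit = HybridModel.from_log(analysis).fit(
            restarts=fit_restarts, seed=derive_seed(base_seed, s, 77)
        )
        rows.append({
            "seed": s, "lesion": lesion,
            **{f"p_stay_{k}": v for k, v in table.probs.items()},
            **{f"n_stay_{k}": table.counts[k][0] for k in table.counts},
            **{f"n_{k}": table.counts[k][1] for k in table.counts},
            "ts_index": ts_index(table),
            "w": fit.w,
            **{f"hybrid_{k}": v for k, v in fit.params.items() if k != "w"},
            "loglik": fit.loglik,
            "reward_rate": analysis["reward"].mean(),
        })
        if keep_results:
            results.append(res)
    frame = pd.DataFrame(rows)
    return (frame, results) if keep_results else frame


def _econ_training_healthy(analysis: pd.DataFrame) -> bool:
    """Convergence check for an economic-choice session.

    Training occasionally degenerates into one-sided, offer-independent
    choice (a documented sensitivity of the model to initialization);
    such runs carry no value signal to analyze. A run is healthy when
    both options are actually used and choice depends on the offers
    (psychometric slope reliably positive). The check is deliberately
    agnostic about the *value* of the fitted preference.
    """
    frac_a = (analysis["choice"] == 0).mean()
    if not 0.05 <= frac_a <= 0.95:
        return False
    try:
        from .behavior import PsychometricModel

        fit = PsychometricModel.from_log(analysis).fit()
    except ValueError:
        return False
    return fit.slope > 0.5


def econ_experiment(
    n_train: int = 8000,
    n_analysis: int = 2000,
    base_seed: int = 0,
    config: Optional[EconChoiceConfig] = None,
    max_attempts: int = 2,
) -> dict:
    """Train the economic-choice network and return the analysis inputs.

    The session runs ``n_train + n_analysis`` trials; post-training
    trials provide the psychometric choices and the post-offer rates for
    the value-selectivity taxonomy. Degenerate training runs (see
    :func:`_econ_training_healthy`) are retried with the next derived
    seed, up to ``max_attempts`` sessions; the attempt count is
    reported.
    """
    tcfg = config or EconChoiceConfig()
    res = analysis = window = None
    for attempt in range(max_attempts):
        cfg = SessionConfig(
            task="econ", task_config=tcfg, n_trials=n_train + n_analysis,
            seed=derive_seed(base_seed, 42, attempt), record_decision_rates=False,
        )
        res = run_session(cfg)
        analysis = res.log.iloc[n_train:].reset_index(drop=True)
        window = res.window_rates[n_train:]
        if _econ_training_healthy(analysis):
            break
    return {"result": res, "analysis_log": analysis, "window_rates": window,
            "config": tcfg, "attempts": attempt + 1}


def weight_difference_by_group(
    weight_history: list, labels: np.ndarray, unit_a: int = 0, unit_b: int = 1
) -> pd.DataFrame:
    """Mean readout-weight difference (to output A minus to output B) per
    selectivity group at each stored snapshot — the weight-evolution view
    of which neurons the learning recruits."""
    labels = np.asarray(labels)
    rows = []
    for trial, readout in weight_history:
        diff = readout.W2[:, unit_a] - readout.W2[:, unit_b]
        for g in pd.unique(labels):
            rows.append({"trial": trial, "group": g,
                         "weight_diff": float(diff[labels == g].mean())})
    return pd.DataFrame(rows)


def ts_curve(log: pd.DataFrame, bin_size: int = 500) -> pd.DataFrame:
    """Task-structure index in consecutive bins of trials (learning curve)."""
    rows = []
    for start in range(0, len(log) - bin_size + 1, bin_size):
        chunk = log.iloc[start:start + bin_size]
        try:
            idx = ts_index(stay_table(chunk))
        except ValueError:
            idx = np.nan
        rows.append({"trial_start": start, "trial_end": start + bin_size,
                     "ts_index": idx})
    return pd.DataFrame(rows)
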