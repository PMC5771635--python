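"""Configuration files, trial-log CSV round trips, and binary snapshots.

Configs are flat JSON/YAML mappings mirroring the dataclasses; unknown
keys are rejected with the offending name. Tabular outputs are CSV;
rate vectors and weight matrices live in HDF5 snapshot containers.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .readout import DecisionParams, ReadoutWeights
from .reservoir import ReservoirParams, ReservoirWeights
from .session import SessionConfig
from .tasks import EconChoiceConfig, ReversalConfig, TwoStageConfig

__all__ = [
    "load_config",
    "dump_config",
    "write_trial_log",
    "read_trial_log",
    "save_snapshot",
    "load_snapshot",
    "RunManifest",
]

_TASK_CONFIGS = {
    "reversal": ReversalConfig,
    "twostage": TwoStageConfig,
    "econ": EconChoiceConfig,
}

_SESSION_KEYS = {
    "task", "task_config", "reservoir", "decision", "n_trials", "seed",
    "freeze_after_trial", "inactivate", "collect_traces", "trace_from_trial",
    "trace_stride", "record_decision_rates", "snapshot_every",
}


def _build_dataclass(cls, mapping: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {context} key(s): {sorted(unknown)}")
    coerced = {}
    for k, v in mapping.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as err:
        raise ValueError(f"invalid {context} configuration: {err}") from err


def load_config(path: str | Path) -> SessionConfig:
    """Read a session config from JSON or YAML, with named validation."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    unknown = set(data) - _SESSION_KEYS
    if unknown:
        raise ValueError(f"unknown session key(s): {sorted(unknown)}")
    if "task" not in data:
        raise ValueError("config is missing required key 'task'")
    task = data["task"]
    if task not in _TASK_CONFIGS:
        raise ValueError(f"unknown task {task!r}")
    kwargs = dict(data)
    if "task_config" in kwargs:
        kwargs["task_config"] = _build_dataclass(
            _TASK_CONFIGS[task], kwargs["task_config"] or {}, f"{task} task"
        )
    if "reservoir" in kwargs:
        kwargs["reservoir"] = _build_dataclass(
            ReservoirParams, kwargs["reservoir"] or {}, "reservoir"
        )
    if "decision" in kwargs:
        kwargs["decision"] = _build_dataclass(
            DecisionParams, kwargs["decision"] or {}, "decision"
        )
    if kwargs.get("inactivate") is not None:
        kwargs["inactivate"] = np.asarray(kwargs["inactivate"], dtype=int)
    return SessionConfig(**kwargs)


def dump_config(cfg: SessionConfig, path: str | Path) -> None:
    """Write a session config as YAML (or JSON by extension); lossless."""
    data: dict = {
        "task": cfg.task,
        "task_config": dataclasses.asdict(cfg.task_config),
        "reservoir": dataclasses.asdict(cfg.reservoir),
        "decision": dataclasses.asdict(cfg.decision),
        "n_trials": cfg.n_trials,
        "seed": cfg.seed,
        "freeze_after_trial": cfg.freeze_after_trial,
        "inactivate": None if cfg.inactivate is None else [int(i) for i in cfg.inactivate],
        "collect_traces": cfg.collect_traces,
        "trace_from_trial": cfg.trace_from_trial,
        "trace_stride": cfg.trace_stride,
        "record_decision_rates": cfg.record_decision_rates,
        "snapshot_every": cfg.snapshot_every,
    }
    def _clean(obj):
        if isinstance(obj, tuple):
            return [_clean(x) for x in obj]
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        return obj
    data = _clean(data)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


_REQUIRED_LOG_COLUMNS = {"trial", "choice", "reward"}


def write_trial_log(log: pd.DataFrame, path: str | Path) -> None:
    missing = _REQUIRED_LOG_COLUMNS - set(log.columns)
    if missing:
        raise ValueError(f"trial log is missing column(s): {sorted(missing)}")
    log.to_csv(path, index=False)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    try:
        log = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed trial log {path}: {err}") from err
    missing = _REQUIRED_LOG_COLUMNS - set(log.columns)
    if missing:
        raise ValueError(f"trial log {path} is missing column(s): {sorted(missing)}")
    return log


def save_snapshot(
    path: str | Path,
    weights: Optional[ReservoirWeights] = None,
    readout: Optional[ReadoutWeights] = None,
    params: Optional[ReservoirParams] = None,
    arrays: Optional[dict] = None,
) -> None:
    """Store weights/rates in one HDF5 container for exact resumption."""
    import h5py

    with h5py.File(path, "w") as f:
        if weights is not None:
            grp = f.create_group("reservoir")
            grp.create_dataset("W_rec", data=weights.W_rec, compression="gzip")
            grp.create_dataset("W_in", data=weights.W_in, compression="gzip")
            grp.attrs["seed"] = weights.seed
        if readout is not None:
            grp = f.create_group("readout")
            grp.create_dataset("W2", data=readout.W2)
            grp.attrs["trial_index"] = readout.trial_index
        if params is not None:
            grp = f.require_group("reservoir")
            for fdef in dataclasses.fields(params):
                grp.attrs[f"param_{fdef.name}"] = getattr(params, fdef.name)
        for name, arr in (arrays or {}).items():
            f.create_dataset(name, data=arr, compression="gzip")


def load_snapshot(path: str | Path) -> dict:
    import h5py

    out: dict = {"weights": None, "readout": None, "params": None, "arrays": {}}
    with h5py.File(path, "r") as f:
        if "reservoir" in f:
            grp = f["reservoir"]
            if "W_rec" in grp:
                out["weights"] = ReservoirWeights(
                    W_rec=grp["W_rec"][...], W_in=grp["W_in"][...],
                    seed=int(grp.attrs.get("seed", -1)),
                )
            pkeys = {k[6:]: grp.attrs[k] for k in grp.attrs if k.startswith("param_")}
            if pkeys:
                for key in ("N",):
                    if key in pkeys:
                        pkeys[key] = int(pkeys[key])
                for key in ("literal_double_gain", "zero_mean_noise"):
                    if key in pkeys:
                        pkeys[key] = bool(pkeys[key])
                if "dtype" in pkeys:
                    pkeys["dtype"] = str(pkeys["dtype"])
                out["params"] = ReservoirParams(**pkeys)
        if "readout" in f:
            out["readout"] = ReadoutWeights(
                W2=f["readout"]["W2"][...],
                trial_index=int(f["readout"].attrs.get("trial_index", 0)),
            )
        for name in f:
            if name not in ("reservoir", "readout"):
                out["arrays"][name] = f[name][...]
    return out


@dataclass
class RunManifest:
    """Record of a composed run: config digest, seeds, output files."""

    config_hash: str
    seeds: list
    outputs: dict = field(default_factory=dict)
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))
    version: str = ""

    @classmethod
    def for_config(cls, cfg: SessionConfig, seeds: list) -> "RunManifest":
        from . import __version__

        digest = hashlib.sha256(
            json.dumps(
                {"task": cfg.task, "n_trials": cfg.n_trials, "seed": cfg.seed},
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16]
        return cls(config_hash=digest, seeds=list(seeds), version=__version__)

    def add_output(self, name: str, path: str | Path, rows: int | None = None) -> None:
        self.outputs[name] = {"path": str(path), "rows": rows}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def verify(self) -> bool:
        """All recorded outputs exist and match their recorded row counts."""
        for meta in self.outputs.values():
            p = Path(meta["path"])
            if not p.exists():
                return False
            if meta.get("rows") is not None and p.suffix == ".csv":
                n = sum(1 for _ in p.open()) - 1
                if n != meta["rows"]:
                    return False
        return True
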