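"""Run configuration, seed management, logging counters and CSV helpers.

A single YAML file (all keys optional) configures a whole run; unknown
keys are rejected by name so typos cannot silently fall back to defaults.
All randomness flows from one top-level seed, split deterministically per
stage, so every pipeline output is reproducible from one integer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .equilibrium import SolverOptions
from .trials import (
    CountModelParams,
    GeneratingParams,
    LatencyParams,
    TrialDesign,
)

__all__ = [
    "RunConfig",
    "parse_config",
    "config_hash",
    "run_logging",
    "WarningCounter",
    "split_seed",
    "write_csv",
    "read_csv",
]

log = logging.getLogger("kincontest")


@dataclass(frozen=True)
class SweepGrid:
    s_small: float = 0.1
    s_large_start: float = 0.1
    s_large_stop: float = 1.0
    s_large_step: float = 0.01
    r_values: tuple = (0.0, 0.25, 0.5)

    def s_large_values(self) -> np.ndarray:
        return np.round(
            np.arange(self.s_large_start, self.s_large_stop + 1e-9, self.s_large_step),
            10,
        )


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; defaults mirror the study design."""

    seed: int = 0
    out_dir: str = "results"
    solver: SolverOptions = field(default_factory=SolverOptions)
    sweep: SweepGrid = field(default_factory=SweepGrid)
    design: TrialDesign = field(default_factory=TrialDesign)
    generating_params: GeneratingParams = field(default_factory=GeneratingParams.default)
    n_replicates: int = 200


_NESTED = {
    "solver": SolverOptions,
    "sweep": SweepGrid,
    "design": TrialDesign,
}
_PARAM_ARMS = {
    "aggression": CountModelParams,
    "activity_experimental": CountModelParams,
    "activity_acclimation": CountModelParams,
    "latency": LatencyParams,
}


def _merge_dataclass(cls, base, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise KeyError(f"unknown config key(s) under '{path}': {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(getattr(base, k), tuple) and isinstance(v, list) else v
        for k, v in data.items()
    }
    return dataclasses.replace(base, **coerced)


def parse_config(path=None) -> RunConfig:
    """Load a RunConfig from YAML, merged over defaults; None -> full defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if raw is None:
        return cfg
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    top = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top
    if unknown:
        raise KeyError(f"unknown config key(s): {sorted(unknown)}")
    updates = {}
    for key, val in raw.items():
        if key in _NESTED:
            updates[key] = _merge_dataclass(
                _NESTED[key], getattr(cfg, key), val or {}, key
            )
        elif key == "generating_params":
            gp = cfg.generating_params
            sub = dict(val or {})
            share = sub.pop("share_random_effects", gp.share_random_effects)
            arms = {}
            unknown_arms = set(sub) - set(_PARAM_ARMS)
            if unknown_arms:
                raise KeyError(
                    f"unknown config key(s) under 'generating_params': "
                    f"{sorted(unknown_arms)}"
                )
            for arm, arm_cls in _PARAM_ARMS.items():
                arms[arm] = _merge_dataclass(
                    arm_cls, getattr(gp, arm), sub.get(arm, {}) or {},
                    f"generating_params.{arm}",
                )
            updates[key] = GeneratingParams(share_random_effects=share, **arms)
        else:
            updates[key] = val
    return dataclasses.replace(cfg, **updates)


def serialize_config(cfg: RunConfig) -> str:
    """YAML text that round-trips through :func:`parse_config`."""
    return yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the full configuration."""
    canon = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def split_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed derived from the single top-level seed."""
    stage_key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.SeedSequence(entropy=seed, spawn_key=(stage_key,))


class WarningCounter(logging.Handler):
    """Counts warnings/errors so a run can summarise them at exit."""

    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1


def run_logging(cfg: RunConfig, level=logging.INFO) -> WarningCounter:
    """Configure logging for a run: seed, config hash, version, warning counter."""
    from . import __version__

    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )
    counter = WarningCounter()
    log.addHandler(counter)
    log.info(
        "kincontest %s | seed=%d | config=%s", __version__, cfg.seed, config_hash(cfg)
    )
    return counter


def _header(cfg: RunConfig) -> str:
    from . import __version__

    return (
        f"# kincontest {__version__}\n"
        f"# seed: {cfg.seed}\n"
        f"# config_hash: {config_hash(cfg)}\n"
    )


def write_csv(df: pd.DataFrame, path, cfg: RunConfig) -> Path:
    """Write a CSV with the run's provenance in '#' comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, index=False)
    return path


def read_csv(path) -> pd.DataFrame:
    """Read back any CSV published by this package."""
    return pd.read_csv(path, comment="#")
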