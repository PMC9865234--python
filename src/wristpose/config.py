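"""Run configuration: one YAML document drives every pipeline stage.

A single global seed deterministically derives per-stage seeds
(hash-chained), so a full run is reproducible from its stored config
alone. Every emitted artifact embeds the config hash; stages refuse to
mix artifacts produced under different configs.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from wristpose.cohort import SimConfig, TaskProfile, DEFAULT_TASK_PROFILES
from wristpose.model import PhaseConfig, TrainConfig
from wristpose.resample import ResamplePlan


@dataclass(frozen=True)
class PreprocessConfig:
    cutoff_angles_hz: float = 5.0
    cutoff_imu_hz: float = 6.0
    window_len: int = 100
    overlap: int = 90
    include_rom_sweeps: bool = True


@dataclass(frozen=True)
class EvaluateConfig:
    targets: tuple[str, ...] = ("fe", "ru")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_participants: int = 10
    simulate: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    resample: ResamplePlan = field(default_factory=ResamplePlan)
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the single global seed."""
    import numpy as np

    ss = np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def with_derived_seeds(config: RunConfig) -> RunConfig:
    """Propagate the global seed into each stage's own seed field."""
    return replace(
        config,
        simulate=replace(config.simulate, seed=stage_seed(config.seed, "simulate")),
        resample=replace(config.resample, seed=stage_seed(config.seed, "resample")),
        train=replace(config.train, seed=stage_seed(config.seed, "train")),
    )


def config_to_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config_to_dict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def _task_profiles_from(d: dict) -> dict[str, TaskProfile]:
    return {name: TaskProfile(**p) for name, p in d.items()}


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    sim_raw = dict(raw.get("simulate", {}))
    if "task_profiles" in sim_raw:
        sim_raw["task_profiles"] = _task_profiles_from(sim_raw["task_profiles"])
    train_raw = dict(raw.get("train", {}))
    for phase in ("initial", "refine"):
        if phase in train_raw and isinstance(train_raw[phase], dict):
            train_raw[phase] = PhaseConfig(**train_raw[phase])
    eval_raw = dict(raw.get("evaluate", {}))
    if "targets" in eval_raw:
        eval_raw["targets"] = tuple(eval_raw["targets"])
    return RunConfig(
        seed=raw.get("seed", 0),
        n_participants=raw.get("n_participants", 10),
        simulate=SimConfig(**sim_raw),
        preprocess=PreprocessConfig(**raw.get("preprocess", {})),
        resample=ResamplePlan(**raw.get("resample", {})),
        train=TrainConfig(**train_raw),
        evaluate=EvaluateConfig(**eval_raw),
    )
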