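"""Shared fixtures: small synthetic cohorts and constructed window sets."""

from __future__ import annotations

import numpy as np
import pytest

from wristpose.cohort import (
    AngleTrace,
    ImuTrace,
    Recording,
    RecordingMeta,
    SimConfig,
    generate_cohort,
)
from wristpose.preprocess import WindowSet


QUIET_SIM = dict(
    gyro_noise_sd=0.2,
    acc_noise_sd=0.05,
    misalignment_sd_deg=0.0,
    duration_jitter=0.0,
)


@pytest.fixture(scope="session")
def tiny_cohort() -> list[Recording]:
    """One participant, short recordings; enough for structural checks."""
    sim = SimConfig(seed=7, duration_s={t: 12.0 for t in ("assembly", "checkout", "typing")},
                    **QUIET_SIM)
    return generate_cohort(1, sim)


@pytest.fixture(scope="session")
def small_cohort() -> list[Recording]:
    """Three participants at 20 s per task, mild noise; used by pipeline tests."""
    sim = SimConfig(seed=13, duration_s={t: 20.0 for t in ("assembly", "checkout", "typing")},
                    **QUIET_SIM)
    return generate_cohort(3, sim)


def constant_angle_recording(
    fe: float = 0.0, ru: float = 0.0, ps: float = 0.0, n: int = 500,
    meta: RecordingMeta | None = None,
    seed: int = 0,
) -> Recording:
    """A recording holding one posture; IMU is gravity plus small noise."""
    rng = np.random.default_rng(seed)
    angles = AngleTrace(
        theta_fe=np.full(n, fe), theta_ru=np.full(n, ru), theta_ps=np.full(n, ps)
    )
    data = rng.normal(0, 0.01, size=(12, n))
    data[2] += 9.81
    data[8] += 9.81
    return Recording(
        meta=meta or RecordingMeta(1, 1, 1, "typing"),
        angles=angles,
        imu=ImuTrace(data=data),
    )


def make_window_set(
    mean_fe: np.ndarray,
    mean_ru: np.ndarray | None = None,
    meta: RecordingMeta | None = None,
    seed: int = 0,
) -> WindowSet:
    """WindowSet with given labels and random inertial blocks."""
    rng = np.random.default_rng(seed)
    n = len(mean_fe)
    return WindowSet(
        x=rng.random((n, 12, 100)).astype(np.float32),
        mean_fe=np.asarray(mean_fe, dtype=float),
        mean_ru=np.zeros(n) if mean_ru is None else np.asarray(mean_ru, dtype=float),
        meta=[meta or RecordingMeta(1, 1, 1, "typing")] * n,
        start_index=np.arange(n) * 10,
    )
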