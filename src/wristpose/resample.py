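"""Class-balance resampling by single-degree range-of-motion histogram.

Raw window labels are heavily concentrated near neutral posture, which
biases a classifier toward the marginal class distribution. Each
recording is therefore rebalanced in three steps: round the target mean
angle of every window to the nearest degree; pick one representative
window per occupied 1-degree bin; then draw uniformly with replacement
from those representatives until a fixed number of examples (default
250) exists. A full participant (12 recordings) thus contributes
12 x 250 = 3000 examples approximately evenly spread over the range of
motion they actually used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from wristpose.cohort import RecordingMeta, TASKS
from wristpose.preprocess import WindowSet


@dataclass(frozen=True)
class ResamplePlan:
    """Which angular channel to balance on, and how many draws per recording."""

    target_channel: str = "fe"
    n_per_recording: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_channel not in ("fe", "ru"):
            raise ValueError("target_channel must be 'fe' or 'ru'")
        if self.n_per_recording < 1:
            raise ValueError("n_per_recording must be >= 1")


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (pinned for reproducibility)."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def balance_recording(
    windows: WindowSet,
    plan: ResamplePlan,
    rng: np.random.Generator,
    from_representatives: bool = True,
) -> WindowSet:
    """Resample one recording's windows to ``plan.n_per_recording`` examples.

    Step 1: single-degree binning of the target mean angle. Step 2: one
    window drawn uniformly from each occupied degree bin. Step 3: draws
    with replacement until the quota is filled. By default step 3 draws
    from the step-2 representatives, which keeps the output flat across
    the range of motion; ``from_representatives=False`` draws from all
    windows of occupied bins instead (which partially restores the raw
    imbalance). Output order is draw order; every output window is a
    member of the input set.
    """
    if len(windows) == 0:
        raise ValueError("cannot balance an empty window set")
    metas = {(m.participant_id, m.session, m.repetition, m.task) for m in windows.meta}
    if len(metas) > 1:
        raise ValueError(f"windows span multiple recordings: {sorted(metas)}")

    degrees = round_half_away(windows.angles(plan.target_channel)).astype(np.int64)
    occupied = np.unique(degrees)

    # step 2: one representative per occupied degree bin
    reps = np.array(
        [rng.choice(np.flatnonzero(degrees == d)) for d in occupied], dtype=np.int64
    )
    if len(reps) > plan.n_per_recording:
        # more occupied bins than the quota: uniformly subsample representatives
        reps = rng.choice(reps, size=plan.n_per_recording, replace=False)

    # step 3: fill the quota with replacement
    n_fill = plan.n_per_recording - len(reps)
    if from_representatives:
        fill = rng.choice(reps, size=n_fill, replace=True)
    else:
        pool = np.flatnonzero(np.isin(degrees, occupied))
        fill = rng.choice(pool, size=n_fill, replace=True)
    chosen = np.concatenate([reps, fill])
    return windows.select(chosen)


def balance_participant(
    recordings_windows: Sequence[WindowSet],
    plan: ResamplePlan,
    rng: np.random.Generator | None = None,
) -> WindowSet:
    """Balance and concatenate all 12 recordings of one participant.

    Requires the complete 2 sessions x 2 repetitions x 3 tasks design;
    missing recordings are reported explicitly. Output length is exactly
    ``12 * plan.n_per_recording``.
    """
    rng = rng if rng is not None else np.random.default_rng(plan.seed)
    present = set()
    for ws in recordings_windows:
        if len(ws):
            m = ws.meta[0]
            present.add((m.session, m.repetition, m.task))
    participants = {ws.meta[0].participant_id for ws in recordings_windows if len(ws)}
    if len(participants) != 1:
        raise ValueError(f"expected windows from one participant, got {sorted(participants)}")
    expected = {(s, r, t) for s in (1, 2) for r in (1, 2) for t in TASKS}
    missing = sorted(expected - present)
    if missing:
        raise ValueError(f"participant is missing recordings: {missing}")
    balanced = [balance_recording(ws, plan, rng) for ws in recordings_windows]
    return WindowSet.concatenate(balanced)


def balance_session(
    recordings_windows: Sequence[WindowSet],
    plan: ResamplePlan,
    rng: np.random.Generator | None = None,
) -> WindowSet:
    """Balance an arbitrary set of recordings (e.g. one session) and concatenate."""
    rng = rng if rng is not None else np.random.default_rng(plan.seed)
    if not recordings_windows:
        raise ValueError("no recordings to balance")
    return WindowSet.concatenate(
        [balance_recording(ws, plan, rng) for ws in recordings_windows]
    )


def degree_histogram(windows: WindowSet, target: str) -> dict[int, int]:
    """Occupied 1-degree bins -> window counts, for balance audits."""
    degrees = round_half_away(windows.angles(target)).astype(np.int64)
    vals, counts = np.unique(degrees, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}
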