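"""HDF5 persistence for windowed datasets.

One file holds the window tensor ``X`` (n x 12 x window_len, float32),
the label vectors ``mean_fe``/``mean_ru``/``fe_bin``/``ru_bin``, the
per-window metadata columns and the start offsets, plus a ``config_hash``
attribute so artifacts from different configurations cannot be mixed
silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from wristpose.cohort import TASKS, RecordingMeta
from wristpose.preprocess import WindowSet


def save_windows(ws: WindowSet, path: str | Path, config_hash: str = "") -> None:
    parts = np.array([m.participant_id for m in ws.meta], dtype=np.int32)
    sess = np.array([m.session for m in ws.meta], dtype=np.int8)
    reps = np.array([m.repetition for m in ws.meta], dtype=np.int8)
    task_idx = np.array([TASKS.index(m.task) for m in ws.meta], dtype=np.int8)
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=ws.x.astype(np.float32), compression="gzip", compression_opts=1)
        f.create_dataset("mean_fe", data=ws.mean_fe)
        f.create_dataset("mean_ru", data=ws.mean_ru)
        f.create_dataset("fe_bin", data=ws.fe_bin.astype(np.int8))
        f.create_dataset("ru_bin", data=ws.ru_bin.astype(np.int8))
        f.create_dataset("participant_id", data=parts)
        f.create_dataset("session", data=sess)
        f.create_dataset("repetition", data=reps)
        f.create_dataset("task", data=task_idx)
        f.create_dataset("start_index", data=ws.start_index)
        f.attrs["config_hash"] = config_hash


def load_windows(path: str | Path, expect_hash: str | None = None) -> WindowSet:
    with h5py.File(path, "r") as f:
        stored = f.attrs.get("config_hash", "")
        if expect_hash is not None and stored and stored != expect_hash:
            raise ValueError(
                f"config hash mismatch: artifact {path} was produced under "
                f"{stored}, expected {expect_hash}"
            )
        meta = [
            RecordingMeta(int(p), int(s), int(r), TASKS[int(t)])
            for p, s, r, t in zip(
                f["participant_id"][:], f["session"][:], f["repetition"][:], f["task"][:]
            )
        ]
        return WindowSet(
            x=f["X"][:],
            mean_fe=f["mean_fe"][:],
            mean_ru=f["mean_ru"][:],
            meta=meta,
            start_index=f["start_index"][:],
        )


def write_sidecar(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
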