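"""Filtering, normalization, 12x100 windowing and posture binning.

Pipeline order is fixed: zero-lag low-pass filter (5 Hz for angle
channels, 6 Hz for inertial channels), then per-channel min/max
normalization fitted on the training partition only, then restructuring
into 12x100 windows with a 90-sample overlap. Each window's posture
label is the mean of the 10 central angle samples, binned into 5 FE
classes or 3 RU classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from wristpose.cohort import AngleTrace, ImuTrace, Recording, RecordingMeta

log = logging.getLogger(__name__)

WINDOW_LEN = 100
WINDOW_OVERLAP = 90
#: 0-based indices of the 10 central samples of a 100-sample window
CENTER_SLICE = slice(45, 55)

ANGLE_CUTOFF_HZ = 5.0
IMU_CUTOFF_HZ = 6.0
BUTTER_ORDER = 4


# ---------------------------------------------------------------------------
# zero-lag filtering


def zero_lag_lowpass(
    signal: np.ndarray,
    cutoff_hz: float,
    fs: float = 100.0,
    order: int = BUTTER_ORDER,
) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero phase lag).

    The bidirectional pass squares the magnitude response and cancels the
    phase, so the effective attenuation is that of a ``2*order`` filter.
    Output length equals input length. Works on 1-D signals or on the
    last axis of a 2-D channel block.
    """
    signal = np.asarray(signal, dtype=float)
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff must lie in (0, {fs / 2}) Hz, got {cutoff_hz}")
    b, a = butter(order, cutoff_hz / (fs / 2.0), btype="low")
    min_len = 3 * max(len(a), len(b))  # filtfilt default padlen + 1
    if signal.shape[-1] <= min_len:
        raise ValueError(
            f"signal too short for zero-lag filtering: length {signal.shape[-1]}, "
            f"minimum {min_len + 1} samples"
        )
    return filtfilt(b, a, signal, axis=-1)


def filter_recording(recording: Recording) -> Recording:
    """Apply the standard cutoffs: 5 Hz to angles, 6 Hz to inertial data."""
    fs = recording.angles.fs
    angles = AngleTrace(
        theta_fe=zero_lag_lowpass(recording.angles.theta_fe, ANGLE_CUTOFF_HZ, fs),
        theta_ru=zero_lag_lowpass(recording.angles.theta_ru, ANGLE_CUTOFF_HZ, fs),
        theta_ps=zero_lag_lowpass(recording.angles.theta_ps, ANGLE_CUTOFF_HZ, fs),
        fs=fs,
    )
    imu = ImuTrace(data=zero_lag_lowpass(recording.imu.data, IMU_CUTOFF_HZ, fs), fs=fs)
    return Recording(meta=recording.meta, angles=angles, imu=imu)


# ---------------------------------------------------------------------------
# posture bins


@dataclass(frozen=True)
class BinScheme:
    """Ordered angular bins with an explicit boundary ownership rule.

    ``edges`` are interior boundaries in descending order; bin ``i``
    covers ``edges[i-1] >= theta > edges[i]`` (upper edge inclusive,
    lower exclusive), with the top bin open above and the bottom bin
    closed below at its upper edge.
    """

    name: str
    edges: tuple[float, ...]

    @property
    def n_classes(self) -> int:
        return len(self.edges) + 1

    def assign(self, theta) -> np.ndarray | int:
        theta_arr = np.asarray(theta, dtype=float)
        if not np.all(np.isfinite(theta_arr)):
            raise ValueError(f"non-finite angle passed to {self.name} binning")
        # descending edges, upper-inclusive: bin = #edges with theta <= edge,
        # so theta exactly on an edge falls in the bin whose lower bound it is
        idx = np.zeros(theta_arr.shape, dtype=np.int64)
        for e in self.edges:
            idx += (theta_arr <= e).astype(np.int64)
        if theta_arr.ndim == 0:
            return int(idx)
        return idx


#: 5-class flexion/extension scheme: theta>45, 45>=theta>15, 15>=theta>-15,
#: -15>=theta>-45, -45>=theta (flexion positive)
FE_BINS = BinScheme(name="FE5", edges=(45.0, 15.0, -15.0, -45.0))

#: 3-class radial/ulnar scheme: theta>=10, 10>theta>-10, -10>=theta.
#: The printed inequalities overlap at exactly +10 deg; the radial bin
#: owns that boundary here.
RU_BINS = BinScheme(name="RU3", edges=(10.0, -10.0))


def bin_fe(theta: float) -> int:
    """Flexion/extension bin index 0..4 (0 = >45 deg flexion)."""
    idx = FE_BINS.assign(theta)
    # default scheme rule already matches the printed FE inequalities
    return idx


def bin_ru(theta: float) -> int:
    """Radial/ulnar bin index 0..2; +10 deg exactly is radial (bin 0)."""
    theta_arr = np.asarray(theta, dtype=float)
    idx = RU_BINS.assign(theta)
    # theta >= 10 is radial: override the generic upper-inclusive rule at +10
    if theta_arr.ndim == 0:
        return 0 if theta_arr >= 10.0 else idx
    idx = np.asarray(idx)
    idx[theta_arr >= 10.0] = 0
    return idx


# ---------------------------------------------------------------------------
# normalization


@dataclass(frozen=True)
class NormalizationParams:
    """Per-channel min/max of the 12 inertial channels, train-partition only."""

    ch_min: np.ndarray
    ch_max: np.ndarray

    def __post_init__(self) -> None:
        if self.ch_min.shape != (12,) or self.ch_max.shape != (12,):
            raise ValueError("expected 12 per-channel min/max pairs")

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Map channel values to [0, 1], clipping unseen extremes.

        ``data`` is (..., 12, n); channels with max == min (degenerate)
        map to 0.
        """
        span = self.ch_max - self.ch_min
        degenerate = span <= 0
        safe_span = np.where(degenerate, 1.0, span)
        shape = (12, 1) if data.ndim >= 2 else (12,)
        out = (data - self.ch_min.reshape(shape)) / safe_span.reshape(shape)
        out = np.clip(out, 0.0, 1.0)
        if np.any(degenerate):
            out[..., degenerate, :] = 0.0
        return out


def fit_normalization(recordings: Iterable[Recording]) -> NormalizationParams:
    """Per-channel min/max over the training recordings' inertial data."""
    ch_min = np.full(12, np.inf)
    ch_max = np.full(12, -np.inf)
    count = 0
    for rec in recordings:
        ch_min = np.minimum(ch_min, rec.imu.data.min(axis=1))
        ch_max = np.maximum(ch_max, rec.imu.data.max(axis=1))
        count += 1
    if count == 0:
        raise ValueError("need at least one recording to fit normalization")
    degenerate = np.flatnonzero(ch_max <= ch_min)
    if degenerate.size:
        warnings.warn(
            f"degenerate (constant) channels {degenerate.tolist()}: mapped to 0",
            stacklevel=2,
        )
    return NormalizationParams(ch_min=ch_min, ch_max=ch_max)


def apply_normalization(imu: ImuTrace, params: NormalizationParams) -> ImuTrace:
    return ImuTrace(data=params.transform(imu.data), fs=imu.fs)


# ---------------------------------------------------------------------------
# windowing


@dataclass(frozen=True)
class Window:
    """One classifier example: a 12x100 inertial block and its labels."""

    x: np.ndarray
    mean_fe: float
    mean_ru: float
    fe_bin: int
    ru_bin: int
    meta: RecordingMeta
    start_index: int


class WindowSet:
    """Array-backed sequence of :class:`Window`.

    Stores the window tensor as one (n, 12, 100) float32 array plus
    parallel label vectors; indexing materializes a :class:`Window`.
    Keeping the block contiguous makes batching and normalization cheap.
    """

    def __init__(
        self,
        x: np.ndarray,
        mean_fe: np.ndarray,
        mean_ru: np.ndarray,
        meta: Sequence[RecordingMeta],
        start_index: np.ndarray,
    ) -> None:
        n = len(x)
        if not (len(mean_fe) == len(mean_ru) == len(meta) == len(start_index) == n):
            raise ValueError("WindowSet arrays must be parallel")
        self.x = x
        self.mean_fe = np.asarray(mean_fe, dtype=float)
        self.mean_ru = np.asarray(mean_ru, dtype=float)
        self.fe_bin = FE_BINS.assign(self.mean_fe) if n else np.zeros(0, dtype=np.int64)
        self.ru_bin = bin_ru(self.mean_ru) if n else np.zeros(0, dtype=np.int64)
        self.meta = list(meta)
        self.start_index = np.asarray(start_index, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.meta)

    def __getitem__(self, i: int) -> Window:
        return Window(
            x=self.x[i],
            mean_fe=float(self.mean_fe[i]),
            mean_ru=float(self.mean_ru[i]),
            fe_bin=int(self.fe_bin[i]),
            ru_bin=int(self.ru_bin[i]),
            meta=self.meta[i],
            start_index=int(self.start_index[i]),
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def labels(self, target: str) -> np.ndarray:
        if target == "fe":
            return self.fe_bin
        if target == "ru":
            return self.ru_bin
        raise ValueError(f"target must be 'fe' or 'ru', got {target!r}")

    def angles(self, target: str) -> np.ndarray:
        return self.mean_fe if target == "fe" else self.mean_ru

    def select(self, idx: np.ndarray | Sequence[int]) -> "WindowSet":
        idx = np.asarray(idx, dtype=np.int64)
        return WindowSet(
            x=self.x[idx],
            mean_fe=self.mean_fe[idx],
            mean_ru=self.mean_ru[idx],
            meta=[self.meta[i] for i in idx],
            start_index=self.start_index[idx],
        )

    @staticmethod
    def concatenate(sets: Sequence["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            raise ValueError("cannot concatenate zero non-empty WindowSets")
        return WindowSet(
            x=np.concatenate([s.x for s in sets], axis=0),
            mean_fe=np.concatenate([s.mean_fe for s in sets]),
            mean_ru=np.concatenate([s.mean_ru for s in sets]),
            meta=[m for s in sets for m in s.meta],
            start_index=np.concatenate([s.start_index for s in sets]),
        )


def window_count(n_samples: int, window_len: int = WINDOW_LEN, overlap: int = WINDOW_OVERLAP) -> int:
    """Number of windows for an n-sample recording: floor((n-L)/stride)+1."""
    stride = window_len - overlap
    if n_samples < window_len:
        return 0
    return (n_samples - window_len) // stride + 1


def make_windows(
    recording: Recording,
    window_len: int = WINDOW_LEN,
    overlap: int = WINDOW_OVERLAP,
    prefiltered: bool = False,
) -> WindowSet:
    """Restructure a recording into overlapping 12x(window_len) windows.

    With the defaults (100-sample windows, 90-sample overlap) the stride
    is 10 samples, i.e. 10 windows per second at 100 Hz. Each window's
    ``mean_fe``/``mean_ru`` is the mean of the 10 central samples of the
    filtered angle channels. Pass ``prefiltered=True`` when the
    recording has already gone through :func:`filter_recording`.
    """
    if not 0 <= overlap < window_len:
        raise ValueError("overlap must satisfy 0 <= overlap < window_len")
    stride = window_len - overlap
    n = len(recording.angles)
    if n < window_len:
        warnings.warn(
            f"recording {recording.meta.label} has {n} < {window_len} samples; no windows",
            stacklevel=2,
        )
        return WindowSet(
            x=np.zeros((0, 12, window_len), dtype=np.float32),
            mean_fe=np.zeros(0),
            mean_ru=np.zeros(0),
            meta=[],
            start_index=np.zeros(0, dtype=np.int64),
        )
    rec = recording if prefiltered else filter_recording(recording)

    starts = np.arange(0, n - window_len + 1, stride)
    sw = np.lib.stride_tricks.sliding_window_view(rec.imu.data, window_len, axis=1)
    x = np.ascontiguousarray(sw[:, starts].transpose(1, 0, 2), dtype=np.float32)

    center = np.arange(CENTER_SLICE.start, CENTER_SLICE.stop)
    center_idx = starts[:, None] + center[None, :]
    mean_fe = rec.angles.theta_fe[center_idx].mean(axis=1)
    mean_ru = rec.angles.theta_ru[center_idx].mean(axis=1)

    return WindowSet(
        x=x,
        mean_fe=mean_fe,
        mean_ru=mean_ru,
        meta=[recording.meta] * len(starts),
        start_index=starts,
    )


def window_labels(
    recording: Recording,
    window_len: int = WINDOW_LEN,
    overlap: int = WINDOW_OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window (mean_fe, mean_ru) without materializing the IMU blocks.

    Useful for distributional audits of large cohorts where only the
    labels matter.
    """
    stride = window_len - overlap
    n = len(recording.angles)
    if n < window_len:
        return np.zeros(0), np.zeros(0)
    fe = zero_lag_lowpass(recording.angles.theta_fe, ANGLE_CUTOFF_HZ, recording.angles.fs)
    ru = zero_lag_lowpass(recording.angles.theta_ru, ANGLE_CUTOFF_HZ, recording.angles.fs)
    starts = np.arange(0, n - window_len + 1, stride)
    center = np.arange(CENTER_SLICE.start, CENTER_SLICE.stop)
    idx = starts[:, None] + center[None, :]
    return fe[idx].mean(axis=1), ru[idx].mean(axis=1)
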