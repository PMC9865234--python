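"""Forward-kinematic synthetic cohort generator.

Real recordings of bench-top occupational tasks (assembly, checkout
scanning, typing) with paired optoelectronic ground truth are restricted,
so this module emulates them: it synthesizes smooth wrist-angle
trajectories per task, then drives a rigid-body sensor model to produce
the 12-channel inertial stream two 6-DOF IMUs (hand dorsum + distal
forearm) would have measured.

Conventions (fixed here because the field does not agree on signs):

- Anatomical axes of each segment frame: x distal, y radial, z dorsal.
- theta_ps rotates about x (pronation/supination), theta_fe about y
  (flexion positive), theta_ru about z (radial deviation positive).
- Hand orientation = forearm orientation composed with the intrinsic
  x-y-z rotation by (theta_ps, theta_fe, theta_ru).
- Gravity points along world -z; a static sensor reads +9.81 m/s^2 of
  specific force opposing it.

A ``sign_flip_fe`` / ``sign_flip_ru`` switch on :class:`SimConfig` negates
the exported angle channels for users preferring the opposite convention.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

FS_HZ = 100.0
GRAVITY = 9.81

TASKS = ("assembly", "checkout", "typing")

#: physiological clamps, degrees
FE_LIMIT = 90.0
RU_LIMIT = 45.0
PS_LIMIT = 100.0


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AngleTrace:
    """Ground-truth wrist angles in degrees, sampled at 100 Hz.

    ``theta_fe`` flexion positive, ``theta_ru`` radial positive,
    ``theta_ps`` pronation positive.
    """

    theta_fe: np.ndarray
    theta_ru: np.ndarray
    theta_ps: np.ndarray
    fs: float = FS_HZ

    def __post_init__(self) -> None:
        n = len(self.theta_fe)
        if not (len(self.theta_ru) == n == len(self.theta_ps)):
            raise ValueError("angle channels must have equal length")

    def __len__(self) -> int:
        return len(self.theta_fe)

    def validate(self) -> None:
        for name, arr, lim in (
            ("theta_fe", self.theta_fe, FE_LIMIT),
            ("theta_ru", self.theta_ru, RU_LIMIT),
            ("theta_ps", self.theta_ps, PS_LIMIT),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite samples")
            if np.any(np.abs(arr) > lim + 1e-9):
                raise ValueError(f"{name} exceeds physiological limit {lim} deg")


#: channel order of the inertial block
IMU_CHANNELS = (
    "hacc_x", "hacc_y", "hacc_z",
    "hgyr_x", "hgyr_y", "hgyr_z",
    "wacc_x", "wacc_y", "wacc_z",
    "wgyr_x", "wgyr_y", "wgyr_z",
)


@dataclass(frozen=True)
class ImuTrace:
    """12-channel inertial stream: hand acc/gyro then wrist acc/gyro.

    ``data`` has shape (12, n); accelerations in m/s^2, angular rates in
    deg/s, 100 Hz sampling.
    """

    data: np.ndarray
    fs: float = FS_HZ

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != 12:
            raise ValueError(f"expected (12, n) inertial block, got {self.data.shape}")

    def __len__(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True, order=True)
class RecordingMeta:
    participant_id: int
    session: int
    repetition: int
    task: str

    def __post_init__(self) -> None:
        if self.session not in (1, 2) or self.repetition not in (1, 2):
            raise ValueError("session and repetition must be 1 or 2")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")

    @property
    def label(self) -> str:
        return f"P{self.participant_id:02d}_S{self.session}_R{self.repetition}_{self.task}"


@dataclass(frozen=True)
class Recording:
    meta: RecordingMeta
    angles: AngleTrace
    imu: ImuTrace

    def __post_init__(self) -> None:
        if len(self.angles) != len(self.imu):
            raise ValueError("angles and imu must be sample-aligned")


@dataclass(frozen=True)
class TaskProfile:
    """Dwell/excursion parameters shaping a task's angle distributions.

    The dwell term is a slow band-limited wander about ``*_mean``;
    excursions are short smooth bumps (mostly toward flexion) occurring
    at ``excursion_rate_hz`` events per second.
    """

    fe_mean: float
    fe_sd: float
    ru_mean: float
    ru_sd: float
    ps_mean: float
    ps_sd: float
    excursion_rate_hz: float = 0.02
    excursion_amp_deg: float = 45.0
    excursion_width_s: float = 0.8
    dwell_bandwidth_hz: float = 0.3


# Defaults emulate bench work: postures concentrated slightly on the
# extension side of neutral, rare flexion peaks past 45 deg.
DEFAULT_TASK_PROFILES: dict[str, TaskProfile] = {
    "assembly": TaskProfile(
        fe_mean=-10.0, fe_sd=13.0, ru_mean=3.0, ru_sd=7.0,
        ps_mean=-20.0, ps_sd=20.0,
        excursion_rate_hz=0.030, excursion_amp_deg=50.0,
    ),
    "checkout": TaskProfile(
        fe_mean=-6.0, fe_sd=14.0, ru_mean=0.0, ru_sd=8.0,
        ps_mean=-40.0, ps_sd=25.0,
        excursion_rate_hz=0.040, excursion_amp_deg=48.0,
    ),
    "typing": TaskProfile(
        fe_mean=-14.0, fe_sd=8.0, ru_mean=5.0, ru_sd=5.0,
        ps_mean=-60.0, ps_sd=10.0,
        excursion_rate_hz=0.008, excursion_amp_deg=40.0,
    ),
}

DEFAULT_DURATIONS_S: dict[str, float] = {
    "assembly": 155.0,
    "checkout": 130.0,
    "typing": 175.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Everything the generator needs; a cohort is a pure function of this.

    ``misalignment_sd_deg`` models the uncalibrated visual-only sensor
    mounting: a fixed small rotation per sensor, drawn once per
    participant and held across all of that participant's recordings.
    """

    seed: int = 0
    duration_s: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DURATIONS_S))
    duration_jitter: float = 0.10
    gravity_g: float = GRAVITY
    gyro_noise_sd: float = 1.0       # deg/s
    acc_noise_sd: float = 0.15       # m/s^2
    misalignment_sd_deg: float = 5.0
    forearm_angle_sd_deg: float = 8.0
    forearm_pos_sd_m: float = 0.03
    task_profiles: dict[str, TaskProfile] = field(
        default_factory=lambda: dict(DEFAULT_TASK_PROFILES)
    )
    include_sweeps: bool = True
    sign_flip_fe: bool = False
    sign_flip_ru: bool = False

    def profile(self, task: str) -> TaskProfile:
        try:
            return self.task_profiles[task]
        except KeyError:
            raise ValueError(
                f"unknown task {task!r}; configured tasks: {sorted(self.task_profiles)}"
            ) from None


# ---------------------------------------------------------------------------
# angle trajectory synthesis


def _bandlimited_noise(n: int, bandwidth_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise low-passed to ``bandwidth_hz``."""
    white = rng.standard_normal(n + 400)  # pad to flush filter transients
    b, a = butter(2, bandwidth_hz / (FS_HZ / 2.0), btype="low")
    smooth = filtfilt(b, a, white)[200:-200]
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _excursions(
    n: int, rate_hz: float, amp_deg: float, width_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Sum of smooth Gaussian bumps; positive (flexion) with p=0.8."""
    out = np.zeros(n)
    n_events = rng.poisson(rate_hz * n / FS_HZ)
    if n_events == 0:
        return out
    t = np.arange(n)
    centers = rng.uniform(0, n, size=n_events)
    widths = rng.uniform(0.6, 1.6, size=n_events) * width_s * FS_HZ
    amps = rng.normal(amp_deg, 0.2 * amp_deg, size=n_events)
    signs = np.where(rng.random(n_events) < 0.8, 1.0, -1.0)
    for c, w, a, s in zip(centers, widths, amps, signs):
        out += s * a * np.exp(-0.5 * ((t - c) / w) ** 2)
    return out


def _rom_sweep(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scripted range-of-motion sweep: one full FE, RU, then PS cycle.

    Each axis sweeps 0 -> +A -> -A -> 0 as one sine period over ~2 s
    while the other axes rest at neutral, mimicking the pre/post-task
    instruction to move through the range of motion.
    """
    amps = {
        "fe": rng.uniform(55.0, 70.0),
        "ru": rng.uniform(18.0, 28.0),
        "ps": rng.uniform(65.0, 85.0),
    }
    seg_n = int(2.0 * FS_HZ)
    phase = np.sin(2.0 * np.pi * np.arange(seg_n) / seg_n)
    zeros = np.zeros(seg_n)
    fe = np.concatenate([amps["fe"] * phase, zeros, zeros])
    ru = np.concatenate([zeros, amps["ru"] * phase, zeros])
    ps = np.concatenate([zeros, zeros, amps["ps"] * phase])
    return fe, ru, ps


def simulate_angle_trajectory(
    task: str,
    duration_s: float,
    rng: np.random.Generator,
    config: SimConfig | None = None,
) -> AngleTrace:
    """Synthesize a smooth (band-limited below ~5 Hz) wrist-angle trace.

    The task's dwell/excursion profile shapes the long-run FE marginal so
    that most mass falls between 15 deg flexion and 45 deg extension with
    rare excursions past 45 deg flexion. When ``config.include_sweeps``
    is set (default) a scripted range-of-motion sweep is prepended and
    appended to the task portion.
    """
    if duration_s <= 1:
        raise ValueError("duration_s must exceed 1 second")
    config = config or SimConfig()
    prof = config.profile(task)

    n = int(round(duration_s * FS_HZ))
    chans = {}
    for name, mean, sd in (
        ("fe", prof.fe_mean, prof.fe_sd),
        ("ru", prof.ru_mean, prof.ru_sd),
        ("ps", prof.ps_mean, prof.ps_sd),
    ):
        x = mean + sd * _bandlimited_noise(n, prof.dwell_bandwidth_hz, rng)
        if name == "fe":
            x = x + _excursions(
                n, prof.excursion_rate_hz, prof.excursion_amp_deg,
                prof.excursion_width_s, rng,
            )
        chans[name] = x

    if config.include_sweeps:
        fe0, ru0, ps0 = _rom_sweep(rng)
        fe1, ru1, ps1 = _rom_sweep(rng)
        chans["fe"] = np.concatenate([fe0, chans["fe"], fe1])
        chans["ru"] = np.concatenate([ru0, chans["ru"], ru1])
        chans["ps"] = np.concatenate([ps0, chans["ps"], ps1])

    # final smoothing pass keeps concatenation seams band-limited
    b, a = butter(2, 4.0 / (FS_HZ / 2.0), btype="low")
    for name in chans:
        chans[name] = filtfilt(b, a, chans[name])

    fe = np.clip(chans["fe"], -FE_LIMIT, FE_LIMIT)
    ru = np.clip(chans["ru"], -RU_LIMIT, RU_LIMIT)
    ps = np.clip(chans["ps"], -PS_LIMIT, PS_LIMIT)
    if config.sign_flip_fe:
        fe = -fe
    if config.sign_flip_ru:
        ru = -ru
    return AngleTrace(theta_fe=fe, theta_ru=ru, theta_ps=ps)


# ---------------------------------------------------------------------------
# rigid-body sensor model


def _euler_xyz_matrices(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Stacked rotation matrices for the intrinsic x-y-z sequence (radians)."""
    eul = np.stack([a, b, c], axis=-1)
    return Rotation.from_euler("XYZ", eul).as_matrix()


def _euler_xyz_body_omega(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    da: np.ndarray, db: np.ndarray, dc: np.ndarray,
) -> np.ndarray:
    """Body-frame angular velocity of R = Rx(a) Ry(b) Rz(c).

    omega_body = Rz^T Ry^T (da x) + Rz^T (db y) + dc z, all rad/s.
    """
    sb, cb = np.sin(b), np.cos(b)
    sc, cc = np.sin(c), np.cos(c)
    # Rz^T Ry^T e_x = (cb*cc, -cb*sc, sb)^T ; Rz^T e_y = (sc, cc, 0)^T
    wx = da * cb * cc + db * sc
    wy = -da * cb * sc + db * cc
    wz = da * sb + dc
    return np.stack([wx, wy, wz], axis=-1)


def _small_rotation(rng: np.random.Generator, sd_deg: float) -> np.ndarray:
    """Fixed mounting misalignment: random small intrinsic x-y-z rotation."""
    ang = np.deg2rad(rng.normal(0.0, sd_deg, size=3))
    return Rotation.from_euler("XYZ", ang).as_matrix()


@dataclass(frozen=True)
class _Kinematics:
    """Intermediate rigid-body state exposed for validation."""

    R_forearm: np.ndarray  # (n, 3, 3), body -> world
    R_hand: np.ndarray
    omega_forearm: np.ndarray  # (n, 3) body frame, rad/s
    omega_hand: np.ndarray
    acc_wrist_world: np.ndarray  # (n, 3) m/s^2, linear acceleration
    acc_hand_world: np.ndarray


# sensor lever arms in their segment frames, metres
_WRIST_SENSOR_OFFSET = np.array([-0.05, 0.0, 0.02])
_HAND_SENSOR_OFFSET = np.array([0.08, 0.0, 0.02])


def _simulate_kinematics(
    angles: AngleTrace, config: SimConfig, rng: np.random.Generator
) -> _Kinematics:
    n = len(angles)
    fs = angles.fs

    sgn_fe = -1.0 if config.sign_flip_fe else 1.0
    sgn_ru = -1.0 if config.sign_flip_ru else 1.0
    ps = np.deg2rad(angles.theta_ps)
    fe = np.deg2rad(sgn_fe * angles.theta_fe)
    ru = np.deg2rad(sgn_ru * angles.theta_ru)

    # forearm: slow random walk in orientation and position (bench work)
    if config.forearm_angle_sd_deg > 0:
        eul_f = np.deg2rad(
            config.forearm_angle_sd_deg
            * np.stack([_bandlimited_noise(n, 0.2, rng) for _ in range(3)], axis=-1)
        )
    else:
        rng.standard_normal(3)  # keep the stream position stable
        eul_f = np.zeros((n, 3))
    if config.forearm_pos_sd_m > 0:
        p_joint = config.forearm_pos_sd_m * np.stack(
            [_bandlimited_noise(n, 0.8, rng) for _ in range(3)], axis=-1
        )
    else:
        p_joint = np.zeros((n, 3))

    R_f = _euler_xyz_matrices(eul_f[:, 0], eul_f[:, 1], eul_f[:, 2])
    R_joint = _euler_xyz_matrices(ps, fe, ru)
    R_h = R_f @ R_joint

    grad = lambda x: np.gradient(x, axis=0) * fs
    d_eul = grad(eul_f)
    omega_f = _euler_xyz_body_omega(
        eul_f[:, 0], eul_f[:, 1], eul_f[:, 2],
        d_eul[:, 0], d_eul[:, 1], d_eul[:, 2],
    )
    omega_joint = _euler_xyz_body_omega(ps, fe, ru, grad(ps), grad(fe), grad(ru))
    # omega_hand(body) = R_joint^T omega_forearm(body) + omega_joint(body)
    omega_h = np.einsum("nji,nj->ni", R_joint, omega_f) + omega_joint

    p_wrist = p_joint + np.einsum("nij,j->ni", R_f, _WRIST_SENSOR_OFFSET)
    p_hand = p_joint + np.einsum("nij,j->ni", R_h, _HAND_SENSOR_OFFSET)
    acc = lambda p: grad(grad(p))
    return _Kinematics(
        R_forearm=R_f,
        R_hand=R_h,
        omega_forearm=omega_f,
        omega_hand=omega_h,
        acc_wrist_world=acc(p_wrist),
        acc_hand_world=acc(p_hand),
    )


def forward_model(
    angles: AngleTrace,
    config: SimConfig,
    rng: np.random.Generator,
    misalign_hand: np.ndarray | None = None,
    misalign_wrist: np.ndarray | None = None,
) -> ImuTrace:
    """Render the 12-channel inertial stream for an angle trajectory.

    Gyroscopes report segment angular velocity in the (misaligned) sensor
    frame, deg/s. Accelerometers report specific force: gravity expressed
    in the sensor frame plus the sensor's linear acceleration, plus white
    noise. Misalignment matrices default to identity; in cohort
    generation they are drawn once per participant per sensor.
    """
    angles.validate()
    kin = _simulate_kinematics(angles, config, rng)
    n = len(angles)
    mis_h = np.eye(3) if misalign_hand is None else misalign_hand
    mis_w = np.eye(3) if misalign_wrist is None else misalign_wrist

    g_world = np.array([0.0, 0.0, -config.gravity_g])

    def sensor_channels(R_seg, omega_body, acc_world, mis):
        # specific force f = a - g, expressed in the sensor frame
        f_world = acc_world - g_world
        f_body = np.einsum("nji,nj->ni", R_seg, f_world)
        acc_sensor = f_body @ mis  # mis^T applied to each row
        gyro_sensor = np.rad2deg(omega_body @ mis)
        return acc_sensor, gyro_sensor

    hacc, hgyr = sensor_channels(kin.R_hand, kin.omega_hand, kin.acc_hand_world, mis_h)
    wacc, wgyr = sensor_channels(kin.R_forearm, kin.omega_forearm, kin.acc_wrist_world, mis_w)

    if config.acc_noise_sd > 0:
        hacc = hacc + rng.normal(0, config.acc_noise_sd, hacc.shape)
        wacc = wacc + rng.normal(0, config.acc_noise_sd, wacc.shape)
    if config.gyro_noise_sd > 0:
        hgyr = hgyr + rng.normal(0, config.gyro_noise_sd, hgyr.shape)
        wgyr = wgyr + rng.normal(0, config.gyro_noise_sd, wgyr.shape)

    data = np.concatenate([hacc.T, hgyr.T, wacc.T, wgyr.T], axis=0)
    return ImuTrace(data=np.ascontiguousarray(data))


# ---------------------------------------------------------------------------
# cohort assembly


def _child_rng(seed: int, *tags: int) -> np.random.Generator:
    """Deterministic per-recording stream, independent of iteration order."""
    return np.random.default_rng(np.random.SeedSequence([seed, *tags]))


def cohort_metas(n_participants: int) -> list[RecordingMeta]:
    """The full factorial design: participants x 2 sessions x 2 reps x 3 tasks."""
    return [
        RecordingMeta(p, s, r, task)
        for p in range(1, n_participants + 1)
        for s in (1, 2)
        for r in (1, 2)
        for task in TASKS
    ]


def simulate_recording(
    meta: RecordingMeta,
    config: SimConfig,
    misalign_hand: np.ndarray,
    misalign_wrist: np.ndarray,
) -> Recording:
    task_idx = TASKS.index(meta.task)
    rng = _child_rng(config.seed, meta.participant_id, meta.session, meta.repetition, task_idx)
    base = config.duration_s.get(meta.task, 120.0)
    jit = config.duration_jitter
    duration = base * (1.0 + rng.uniform(-jit, jit)) if jit > 0 else base
    angles = simulate_angle_trajectory(meta.task, duration, rng, config)
    imu = forward_model(angles, config, rng, misalign_hand, misalign_wrist)
    return Recording(meta=meta, angles=angles, imu=imu)


def participant_misalignments(
    config: SimConfig, participant_id: int
) -> tuple[np.ndarray, np.ndarray]:
    """Frozen per-participant mounting rotations for the hand and wrist sensor."""
    rng = _child_rng(config.seed, participant_id, 9001)
    if config.misalignment_sd_deg <= 0:
        return np.eye(3), np.eye(3)
    return (
        _small_rotation(rng, config.misalignment_sd_deg),
        _small_rotation(rng, config.misalignment_sd_deg),
    )


def generate_cohort(n_participants: int, config: SimConfig) -> list[Recording]:
    """Generate the full factorial cohort; pure function of its arguments."""
    if n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    recordings = []
    for p in range(1, n_participants + 1):
        mis_h, mis_w = participant_misalignments(config, p)
        for meta in cohort_metas(1):
            meta = replace(meta, participant_id=p)
            recordings.append(simulate_recording(meta, config, mis_h, mis_w))
    return recordings


# ---------------------------------------------------------------------------
# on-disk format

CSV_COLUMNS = ("t", "theta_fe", "theta_ru", "theta_ps") + IMU_CHANNELS


def write_recording_csv(recording: Recording, directory: Path) -> Path:
    """One CSV per recording: t, three angle channels, twelve IMU channels."""
    path = Path(directory) / f"{recording.meta.label}.csv"
    n = len(recording.angles)
    cols = np.column_stack(
        [
            np.arange(n),
            recording.angles.theta_fe,
            recording.angles.theta_ru,
            recording.angles.theta_ps,
            recording.imu.data.T,
        ]
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for row in cols:
            writer.writerow([int(row[0])] + [f"{v:.6f}" for v in row[1:]])
    return path


def read_recording_csv(path: Path) -> Recording:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    name = Path(path).stem
    part, sess, rep, task = name.split("_", 3)
    meta = RecordingMeta(int(part[1:]), int(sess[1:]), int(rep[1:]), task)
    angles = AngleTrace(theta_fe=arr[:, 1], theta_ru=arr[:, 2], theta_ps=arr[:, 3])
    imu = ImuTrace(data=np.ascontiguousarray(arr[:, 4:16].T))
    return Recording(meta=meta, angles=angles, imu=imu)


def write_manifest(
    recordings: Sequence[Recording], directory: Path, extra: dict | None = None
) -> Path:
    manifest = {
        "n_recordings": len(recordings),
        "recordings": [
            {
                "file": f"{r.meta.label}.csv",
                "participant_id": r.meta.participant_id,
                "session": r.meta.session,
                "repetition": r.meta.repetition,
                "task": r.meta.task,
                "n_samples": len(r.angles),
            }
            for r in recordings
        ],
    }
    if extra:
        manifest.update(extra)
    path = Path(directory) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path
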