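"""The convolutional posture classifier and its two-phase training protocol.

Training mirrors how the classifier is meant to be deployed: an initial
phase fits the network on the balanced windows of every participant
except the one held out, with a 10% validation split and early stopping
(patience 10, hard limit 500 epochs); a refinement phase then fine-tunes
on the held-out participant's first-session windows at a 10x lower
learning rate with patience 1 and a hard limit of 50 epochs. The weights
reported are always those of the best validation epoch.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from wristpose.nn import Adam, CnnParams, EarlyStopper, PostureCnn
from wristpose.preprocess import NormalizationParams, WindowSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CnnSpec:
    """Architecture description; identical across folds (only weights differ)."""

    n_classes: int
    input_shape: tuple[int, int, int] = (12, 100, 1)
    conv_filters: tuple[int, int] = (32, 64)
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 2)
    dense_units: int = 4096
    dropout_rate: float = 0.80

    def architecture_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class PhaseConfig:
    patience: int
    max_epochs: int
    learning_rate: float


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of both training phases.

    The refinement learning rate is pinned at one tenth of the initial
    rate; the constructor enforces it.
    """

    base_learning_rate: float = 1e-3
    val_fraction: float = 0.10
    batch_size: int = 64
    seed: int = 0
    initial: PhaseConfig = field(default=None)  # type: ignore[assignment]
    refine: PhaseConfig = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.initial is None:
            object.__setattr__(
                self, "initial", PhaseConfig(10, 500, self.base_learning_rate)
            )
        if self.refine is None:
            object.__setattr__(
                self, "refine", PhaseConfig(1, 50, self.base_learning_rate / 10.0)
            )
        expected = self.initial.learning_rate / 10.0
        if not np.isclose(self.refine.learning_rate, expected):
            raise ValueError(
                "refinement learning rate must be one tenth of the initial rate "
                f"({self.refine.learning_rate} vs {self.initial.learning_rate})"
            )


@dataclass
class FittedModel:
    """A (possibly trained) network plus everything needed to reuse it."""

    spec: CnnSpec
    cnn: PostureCnn
    target: str
    seed: int
    norm: NormalizationParams | None = None
    training_log: list[dict] = field(default_factory=list)
    trained: bool = False

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    def stop_epoch(self, phase: str) -> int | None:
        for entry in reversed(self.training_log):
            if entry.get("event") == "stop" and entry.get("phase") == phase:
                return entry["epoch"]
        return None


def build_model(n_classes: int, seed: int = 0, target: str | None = None) -> FittedModel:
    """Construct the untrained classifier with seeded initial weights."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    spec = CnnSpec(n_classes=n_classes)
    cnn = PostureCnn(
        n_classes=n_classes,
        seed=seed,
        conv_filters=spec.conv_filters,
        dense_units=spec.dense_units,
        dropout_rate=spec.dropout_rate,
    )
    if target is None:
        target = "fe" if n_classes == 5 else "ru"
    return FittedModel(spec=spec, cnn=cnn, target=target, seed=seed)


# ---------------------------------------------------------------------------
# training


def _model_inputs(model: FittedModel, windows: WindowSet) -> np.ndarray:
    x = windows.x
    if model.norm is not None:
        x = model.norm.transform(x).astype(np.float32)
    return x


def _run_phase(
    model: FittedModel,
    x: np.ndarray,
    y: np.ndarray,
    phase_name: str,
    phase: PhaseConfig,
    config: TrainConfig,
) -> None:
    """Minibatch Adam with a validation split, early stopping and
    best-epoch weight restoration."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(phase_name.encode())])
    )
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 windows to train")
    order = rng.permutation(n)
    n_val = min(n - 1, max(1, int(round(config.val_fraction * n))))
    train_idx, val_idx = order[:-n_val], order[-n_val:]
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    optimizer = Adam(model.cnn.params, learning_rate=phase.learning_rate)
    stopper = EarlyStopper(patience=phase.patience)
    best_params = model.cnn.params.copy()
    stop_reason = "max_epochs"
    stop_epoch = phase.max_epochs

    for epoch in range(1, phase.max_epochs + 1):
        perm = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        for i in range(0, len(perm), config.batch_size):
            batch = perm[i : i + config.batch_size]
            loss, grads = model.cnn.loss_and_grads(x_tr[batch], y_tr[batch], rng)
            optimizer.step(model.cnn.params, grads)
            epoch_loss += loss * len(batch)
        epoch_loss /= len(x_tr)
        val_loss = model.cnn.evaluate_loss(x_val, y_val)
        model.training_log.append(
            {
                "phase": phase_name,
                "epoch": epoch,
                "train_loss": round(epoch_loss, 6),
                "val_loss": round(val_loss, 6),
                "learning_rate": phase.learning_rate,
            }
        )
        should_stop = stopper.update(epoch, val_loss)
        if stopper.epochs_since_best == 0:
            best_params = model.cnn.params.copy()
        if should_stop:
            stop_reason = "early_stop"
            stop_epoch = epoch
            break

    model.cnn.params = best_params
    model.training_log.append(
        {
            "event": "stop",
            "phase": phase_name,
            "epoch": stop_epoch,
            "reason": stop_reason,
            "best_epoch": stopper.best_epoch,
            "best_val_loss": round(float(stopper.best_loss), 6),
        }
    )
    log.info(
        "%s phase: stopped at epoch %d (%s), best epoch %d",
        phase_name, stop_epoch, stop_reason, stopper.best_epoch,
    )


def _labels_for(model: FittedModel, windows: WindowSet) -> np.ndarray:
    y = windows.labels(model.target)
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"training labels contain fewer than 2 classes for target {model.target!r}"
        )
    if y.min() < 0 or y.max() >= model.n_classes:
        raise ValueError("label outside the model's class range")
    return y


def train_initial(model: FittedModel, windows: WindowSet, config: TrainConfig) -> FittedModel:
    """Initial phase on the balanced training windows (test subject excluded)."""
    y = _labels_for(model, windows)
    x = _model_inputs(model, windows)
    _run_phase(model, x, y, "initial", config.initial, config)
    model.trained = True
    return model


def refine(
    model: FittedModel,
    windows: WindowSet,
    config: TrainConfig,
    test_participant: int | None = None,
) -> FittedModel:
    """Refinement phase on the held-out participant's session-1 windows.

    Guards against leakage: the refinement set must come from exactly one
    participant's first session, and — when ``test_participant`` is given
    — from that participant.
    """
    participants = {m.participant_id for m in windows.meta}
    sessions = {m.session for m in windows.meta}
    if len(participants) != 1:
        raise ValueError(f"refinement windows span participants {sorted(participants)}")
    if sessions != {1}:
        raise ValueError(
            f"refinement windows must come from session 1 only, got sessions {sorted(sessions)}"
        )
    if test_participant is not None and participants != {test_participant}:
        raise ValueError(
            f"refinement windows belong to participant {participants.pop()}, "
            f"expected test participant {test_participant}"
        )
    y = _labels_for(model, windows)
    x = _model_inputs(model, windows)
    _run_phase(model, x, y, "refine", config.refine, config)
    return model


def predict_bins(model: FittedModel, windows: WindowSet | np.ndarray) -> np.ndarray:
    """Argmax class per window; ties break toward the lower class index."""
    if isinstance(windows, WindowSet):
        x = _model_inputs(model, windows)
    else:
        x = np.asarray(windows, dtype=np.float32)
        if model.norm is not None:
            x = model.norm.transform(x).astype(np.float32)
    if x.ndim != 3 or x.shape[1:] != (12, 100):
        raise ValueError(f"expected (n, 12, 100) input, got {x.shape}")
    probs = model.cnn.predict_proba(x)
    return probs.argmax(axis=1)


def predict_proba(model: FittedModel, windows: WindowSet | np.ndarray) -> np.ndarray:
    if isinstance(windows, WindowSet):
        x = _model_inputs(model, windows)
    else:
        x = np.asarray(windows, dtype=np.float32)
        if model.norm is not None:
            x = model.norm.transform(x).astype(np.float32)
    return model.cnn.predict_proba(x)


# ---------------------------------------------------------------------------
# model bundle serialization


def save_model(model: FittedModel, directory: str | Path) -> Path:
    """Weights, spec, normalization and training log in one directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.cnn.params.tensors)
    meta = {
        "spec": asdict(model.spec),
        "target": model.target,
        "seed": model.seed,
        "trained": model.trained,
        "architecture_hash": model.spec.architecture_hash(),
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=1))
    if model.norm is not None:
        np.savez(
            directory / "normalization.npz",
            ch_min=model.norm.ch_min,
            ch_max=model.norm.ch_max,
        )
    with open(directory / "training_log.jsonl", "w") as fh:
        for entry in model.training_log:
            fh.write(json.dumps(entry) + "\n")
    return directory


def load_model(directory: str | Path) -> FittedModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    spec_d = meta["spec"]
    spec = CnnSpec(
        n_classes=spec_d["n_classes"],
        input_shape=tuple(spec_d["input_shape"]),
        conv_filters=tuple(spec_d["conv_filters"]),
        kernel=tuple(spec_d["kernel"]),
        pool=tuple(spec_d["pool"]),
        dense_units=spec_d["dense_units"],
        dropout_rate=spec_d["dropout_rate"],
    )
    model = build_model(spec.n_classes, seed=meta["seed"], target=meta["target"])
    with np.load(directory / "weights.npz") as zf:
        model.cnn.params = CnnParams({k: zf[k] for k in zf.files})
    norm_path = directory / "normalization.npz"
    if norm_path.exists():
        with np.load(norm_path) as zf:
            model.norm = NormalizationParams(ch_min=zf["ch_min"], ch_max=zf["ch_max"])
    log_path = directory / "training_log.jsonl"
    if log_path.exists():
        model.training_log = [
            json.loads(line) for line in log_path.read_text().splitlines() if line
        ]
    model.trained = meta["trained"]
    return model
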