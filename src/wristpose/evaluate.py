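"""Leave-one-subject-out evaluation with refinement, and agreement statistics.

Each fold holds out one participant entirely: the network trains on the
balanced windows of everyone else, is refined on the balanced windows of
the held-out participant's first session, and is tested on ALL raw
(un-resampled) windows of their second session. Reported statistics are
accuracy, Cohen's kappa with its Landis-Koch qualitative label,
row-normalized contingency tables (true class on rows), and within-k-bin
rates; fold means carry the standard error across folds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from wristpose.cohort import Recording
from wristpose.model import (
    FittedModel,
    TrainConfig,
    build_model,
    predict_bins,
    refine,
    train_initial,
)
from wristpose.preprocess import (
    NormalizationParams,
    WindowSet,
    filter_recording,
    fit_normalization,
    make_windows,
)
from wristpose.resample import ResamplePlan, balance_participant, balance_session

log = logging.getLogger(__name__)

N_CLASSES = {"fe": 5, "ru": 3}


# ---------------------------------------------------------------------------
# agreement statistics


def cohen_kappa(true: Sequence[int], pred: Sequence[int]) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    ``p_o`` is the observed agreement fraction; ``p_e`` the chance
    agreement implied by the two label marginals. Degenerate case: when
    both marginals concentrate on one class (p_e == 1) agreement is
    perfect by construction and kappa is 1.
    """
    t = np.asarray(true)
    p = np.asarray(pred)
    if t.shape != p.shape or t.ndim != 1 or len(t) == 0:
        raise ValueError("true and pred must be equal-length non-empty 1-D sequences")
    n = len(t)
    p_o = float(np.mean(t == p))
    classes = np.union1d(t, p)
    p_e = 0.0
    for k in classes:
        p_e += float(np.sum(t == k)) / n * float(np.sum(p == k)) / n
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


_LANDIS_KOCH = (
    (0.00, "Poor"),        # kappa < 0
    (0.20, "Slight"),      # [0, 0.20]
    (0.40, "Fair"),        # (0.20, 0.40]
    (0.60, "Moderate"),    # (0.40, 0.60]
    (0.80, "Substantial"), # (0.60, 0.80]
    (1.00, "Almost Perfect"),
)


def landis_koch_label(kappa: float) -> str:
    """Qualitative agreement strength for a kappa in [-1, 1]."""
    if not np.isfinite(kappa) or kappa < -1.0 or kappa > 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0:
        return "Poor"
    for upper, name in _LANDIS_KOCH[1:]:
        if kappa <= upper:
            return name
    return "Almost Perfect"


def contingency_table(
    true: Sequence[int],
    pred: Sequence[int],
    n_classes: int,
    normalize: str = "none",
) -> np.ndarray:
    """K x K matrix with true class on rows, predicted class on columns.

    ``normalize='row'`` divides each non-empty row by its sum; empty
    rows become NaN and are flagged with a warning.
    """
    t = np.asarray(true, dtype=np.int64)
    p = np.asarray(pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("true and pred must have equal length")
    if len(t) and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels outside 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    if normalize == "none":
        return counts
    if normalize != "row":
        raise ValueError("normalize must be 'none' or 'row'")
    return normalize_rows(counts)


def normalize_rows(counts: np.ndarray) -> np.ndarray:
    """Row-normalize a count matrix; empty rows become NaN rows."""
    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=1, keepdims=True)
    empty = sums[:, 0] == 0
    if np.any(empty):
        warnings.warn(
            f"contingency rows {np.flatnonzero(empty).tolist()} are empty; "
            "reported as NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = counts / sums
    out[empty] = np.nan
    return out


def within_k_bins(row_normalized: np.ndarray, k: int = 1) -> np.ndarray:
    """Per true class, the fraction predicted within k bins of the truth.

    Input is a square row-normalized contingency matrix; NaN rows
    propagate to NaN rates.
    """
    m = np.asarray(row_normalized, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    n = m.shape[0]
    rates = np.empty(n)
    for i in range(n):
        cols = [j for j in range(n) if abs(i - j) <= k]
        rates[i] = m[i, cols].sum()
    return rates


# ---------------------------------------------------------------------------
# fold bookkeeping


@dataclass(frozen=True)
class FoldResult:
    test_participant: int
    target: str
    accuracy: float
    kappa: float
    contingency: np.ndarray  # raw counts, true rows x predicted columns
    n_test_windows: int
    y_true: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    y_pred: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        total = int(self.contingency.sum())
        if total != self.n_test_windows:
            raise ValueError("contingency total must equal n_test_windows")
        acc = np.trace(self.contingency) / total if total else float("nan")
        if not np.isclose(acc, self.accuracy):
            raise ValueError("accuracy inconsistent with contingency trace")


@dataclass
class TargetSummary:
    target: str
    mean_accuracy: float
    se_accuracy: float
    mean_kappa: float
    se_kappa: float
    landis_koch: str
    cumulative_counts: np.ndarray
    cumulative_row_normalized: np.ndarray
    within_1_bin: np.ndarray


@dataclass
class EvaluationReport:
    folds: list[FoldResult]
    summaries: dict[str, TargetSummary]
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(a):
            return np.where(np.isfinite(a), np.round(a, 6), None).tolist()

        return {
            "config": self.config,
            "folds": [
                {
                    "test_participant": f.test_participant,
                    "target": f.target,
                    "accuracy": round(f.accuracy, 6),
                    "kappa": round(f.kappa, 6),
                    "n_test_windows": f.n_test_windows,
                    "contingency": f.contingency.tolist(),
                }
                for f in self.folds
            ],
            "summaries": {
                t: {
                    "mean_accuracy": round(s.mean_accuracy, 6),
                    "se_accuracy": round(s.se_accuracy, 6),
                    "mean_kappa": round(s.mean_kappa, 6),
                    "se_kappa": round(s.se_kappa, 6),
                    "landis_koch": s.landis_koch,
                    "cumulative_counts": s.cumulative_counts.tolist(),
                    "cumulative_row_normalized": clean(s.cumulative_row_normalized),
                    "within_1_bin": clean(s.within_1_bin),
                }
                for t, s in self.summaries.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def summary_text(self) -> str:
        lines = []
        for t, s in self.summaries.items():
            lines.append(f"target {t}:")
            lines.append(
                f"  accuracy {s.mean_accuracy:.3f} +/- {s.se_accuracy:.3f} (SE), "
                f"kappa {s.mean_kappa:.3f} +/- {s.se_kappa:.3f} ({s.landis_koch})"
            )
            lines.append("  row-normalized contingency (true rows, predicted cols):")
            for row in s.cumulative_row_normalized:
                lines.append(
                    "    " + "  ".join("  -- " if not np.isfinite(v) else f"{v:5.2f}" for v in row)
                )
            w = ", ".join(
                "--" if not np.isfinite(v) else f"{v:.2f}" for v in s.within_1_bin
            )
            lines.append(f"  within-1-bin per true class: {w}")
        return "\n".join(lines)


def summarize_folds(folds: Sequence[FoldResult], target: str) -> TargetSummary:
    sel = [f for f in folds if f.target == target]
    if not sel:
        raise ValueError(f"no folds for target {target!r}")
    acc = np.array([f.accuracy for f in sel])
    kap = np.array([f.kappa for f in sel])
    nf = len(sel)
    se = lambda v: float(v.std(ddof=1) / np.sqrt(nf)) if nf > 1 else 0.0
    cum = np.sum([f.contingency for f in sel], axis=0)
    cum_norm = normalize_rows(cum)
    return TargetSummary(
        target=target,
        mean_accuracy=float(acc.mean()),
        se_accuracy=se(acc),
        mean_kappa=float(kap.mean()),
        se_kappa=se(kap),
        landis_koch=landis_koch_label(float(np.clip(kap.mean(), -1.0, 1.0))),
        cumulative_counts=cum,
        cumulative_row_normalized=cum_norm,
        within_1_bin=within_k_bins(cum_norm, k=1),
    )


# ---------------------------------------------------------------------------
# LOSO with refinement


def _window_hashes(ws: WindowSet) -> set[bytes]:
    return {
        hashlib.blake2b(np.ascontiguousarray(ws.x[i]).tobytes(), digest_size=16).digest()
        for i in range(len(ws))
    }


def _audit_fold_isolation(test: WindowSet, *others: WindowSet) -> None:
    """Hash-based proof that no test window entered training or refinement."""
    test_hashes = _window_hashes(test)
    for ws in others:
        overlap = test_hashes & _window_hashes(ws)
        if overlap:
            raise RuntimeError(
                f"fold isolation violated: {len(overlap)} test windows found "
                "in a training/refinement set"
            )


def loso_evaluate(
    recordings: Sequence[Recording],
    train_config: TrainConfig,
    plans: dict[str, ResamplePlan] | None = None,
    targets: Sequence[str] = ("fe", "ru"),
    do_refine: bool = True,
) -> EvaluationReport:
    """Leave-one-subject-out cross-validation with subject refinement.

    For every participant p: fit normalization and the network on the
    balanced windows of all other participants, refine on p's balanced
    session-1 windows, test on all raw windows of p's session-2
    recordings. Normalization is refitted per fold on the training
    participants only, so no statistic of the held-out subject leaks in.
    """
    participants = sorted({r.meta.participant_id for r in recordings})
    if len(participants) < 3:
        raise ValueError("LOSO needs at least 3 participants")
    if plans is None:
        plans = {t: ResamplePlan(target_channel=t, seed=train_config.seed) for t in targets}

    # filter once, window once; windows stay raw (normalization is per fold)
    filtered: dict[int, list[Recording]] = {p: [] for p in participants}
    windows: dict[int, list[WindowSet]] = {p: [] for p in participants}
    for rec in recordings:
        frec = filter_recording(rec)
        p = rec.meta.participant_id
        filtered[p].append(frec)
        windows[p].append(make_windows(frec, prefiltered=True))

    folds: list[FoldResult] = []
    for fold_idx, test_p in enumerate(participants):
        train_ps = [p for p in participants if p != test_p]
        norm = fit_normalization(
            rec for p in train_ps for rec in filtered[p]
        )
        test_s2 = [
            ws for ws in windows[test_p] if len(ws) and ws.meta[0].session == 2
        ]
        test_set = WindowSet.concatenate(test_s2)
        refine_s1 = [
            ws for ws in windows[test_p] if len(ws) and ws.meta[0].session == 1
        ]

        for target in targets:
            plan = plans[target]
            fold_seed = int(
                np.random.SeedSequence(
                    [train_config.seed, fold_idx, 0 if target == "fe" else 1]
                ).generate_state(1)[0] % (2**31)
            )
            rng = np.random.default_rng(fold_seed)
            train_set = WindowSet.concatenate(
                [balance_participant(windows[p], plan, rng) for p in train_ps]
            )
            refine_set = balance_session(refine_s1, plan, rng)
            _audit_fold_isolation(test_set, train_set, refine_set)

            model = build_model(N_CLASSES[target], seed=fold_seed, target=target)
            model.norm = norm
            fold_cfg = TrainConfig(
                base_learning_rate=train_config.base_learning_rate,
                val_fraction=train_config.val_fraction,
                batch_size=train_config.batch_size,
                seed=fold_seed,
                initial=train_config.initial,
                refine=train_config.refine,
            )
            train_initial(model, train_set, fold_cfg)
            if do_refine:
                refine(model, refine_set, fold_cfg, test_participant=test_p)

            y_true = test_set.labels(target)
            y_pred = predict_bins(model, test_set)
            counts = contingency_table(y_true, y_pred, N_CLASSES[target])
            folds.append(
                FoldResult(
                    test_participant=test_p,
                    target=target,
                    accuracy=float(np.mean(y_true == y_pred)),
                    kappa=cohen_kappa(y_true, y_pred),
                    contingency=counts,
                    n_test_windows=len(y_true),
                    y_true=np.asarray(y_true),
                    y_pred=np.asarray(y_pred),
                )
            )
            log.info(
                "fold %d (test participant %d, %s): acc %.3f kappa %.3f on %d windows",
                fold_idx, test_p, target, folds[-1].accuracy, folds[-1].kappa,
                folds[-1].n_test_windows,
            )

    summaries = {t: summarize_folds(folds, t) for t in targets}
    return EvaluationReport(
        folds=folds,
        summaries=summaries,
        config={
            "targets": list(targets),
            "n_participants": len(participants),
            "seed": train_config.seed,
            "refine": do_refine,
        },
    )
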