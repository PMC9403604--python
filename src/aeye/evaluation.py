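"""Detection metrics, constrained cross-validation splits, model
comparison statistics, and the degradation experiment harness.

Metric conventions follow the clinical-screening literature: AUROC from
the full threshold sweep (equivalently, the probability that a random
positive outscores a random negative, ties counted half), and
sensitivity / specificity / accuracy as percentages at a stated
operating threshold. The default operating threshold on the video score
is 0.5; the Youden-J-optimal threshold is reported alongside because
"operating point" is otherwise underdetermined.

Cross-validation is stratified by class first (each fold's class share
within one video of the global share) and balances patients second:
within each class a patient's videos are dealt round-robin across
folds, so each patient contributes both classes to every training set
where feasible. Patient balance is a soft constraint — infeasible cases
are logged and relaxed, class stratification is never relaxed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .videoio import VideoClip, degrade_grid, downscale, resample_rate

__all__ = [
    "MetricsReport",
    "FoldSplit",
    "ComparisonResult",
    "roc_auc",
    "youden_threshold",
    "metrics_at_threshold",
    "stratified_group_kfold",
    "compare_models_ttest",
    "run_degradation_experiment",
    "learning_curves",
]


@dataclass
class MetricsReport:
    """AUROC plus confusion-derived rates at one operating threshold.

    Rates are percentages; counts satisfy TP+FP+TN+FN = n_videos.
    """

    auroc: float
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int
    operating_threshold: float
    n_videos: int
    youden_threshold: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "operating_threshold": self.operating_threshold,
            "n_videos": self.n_videos,
        }


@dataclass
class FoldSplit:
    """Fold assignment plus a log of the balance constraints achieved."""

    k: int
    assignments: dict  # video_id → fold index
    constraints_log: list = field(default_factory=list)

    def fold_ids(self, fold: int) -> list:
        return [vid for vid, f in self.assignments.items() if f == fold]


@dataclass
class ComparisonResult:
    """Two-sample unpaired t-test between per-video probability sets."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


# ---------------------------------------------------------------------------
# ROC / threshold metrics


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC with the ROC curve points (fpr, tpr).

    Trapezoidal integration over all distinct score thresholds; equal to
    the pairwise concordance probability with ties counted 0.5.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Score cutoff maximising sensitivity + specificity − 1."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return float(thresholds[np.argmax(tpr - fpr)])


def metrics_at_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> MetricsReport:
    """Confusion counts and rates with predictions at score ≥ threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    n = len(labels)
    auc, _, _ = roc_auc(scores, labels)
    return MetricsReport(
        auroc=auc,
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        accuracy=100.0 * (tp + tn) / n,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        operating_threshold=float(threshold),
        n_videos=n,
        youden_threshold=youden_threshold(scores, labels),
    )


# ---------------------------------------------------------------------------
# Cross-validation


def stratified_group_kfold(
    labels: Sequence[int],
    patient_ids: Sequence[str],
    k: int = 3,
    seed: int = 0,
    video_ids: Optional[Sequence[str]] = None,
) -> FoldSplit:
    """Class-stratified folds with patients spread across folds.

    Within each class, videos are grouped by patient, patients visited
    in seeded random order, and each patient's videos dealt round-robin
    starting from the currently smallest fold. This yields per-fold
    class shares within ±1 video of the global share while distributing
    every patient's material over folds, so training portions retain
    both classes from each patient whenever the patient has ≥ 2 videos
    per class.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be ≥ 2: k=1 leaves no held-out data")
    if n < k:
        raise ValueError(f"cannot split {n} videos into {k} folds")
    _check_two_classes(labels)
    patient_ids = [str(p) for p in patient_ids]
    if video_ids is None:
        video_ids = [f"v{i:04d}" for i in range(n)]
    video_ids = list(video_ids)
    rng = np.random.default_rng(seed)

    assignments: dict = {}
    log: list = []
    class_fold_counts = {c: np.zeros(k, dtype=int) for c in (0, 1)}
    for cls in (1, 0):
        idx_cls = np.flatnonzero(labels == cls)
        by_patient: dict = {}
        for i in idx_cls:
            by_patient.setdefault(patient_ids[i], []).append(i)
        patients = sorted(by_patient)
        rng.shuffle(patients)
        counts = class_fold_counts[cls]
        for p in patients:
            vids = by_patient[p]
            rng.shuffle(vids)
            for i in vids:
                # smallest class-count fold; ties broken by fold order
                fold = int(np.argmin(counts))
                assignments[video_ids[i]] = fold
                counts[fold] += 1
            if len(vids) < k:
                log.append(
                    f"patient {p} class {cls}: {len(vids)} videos cannot "
                    f"reach all {k} folds"
                )
    for fold in range(k):
        pos = class_fold_counts[1][fold]
        neg = class_fold_counts[0][fold]
        log.append(f"fold {fold}: {pos} nystagmus / {neg} no-nystagmus")
    empty = [f for f in range(k) if class_fold_counts[1][f] == 0 or class_fold_counts[0][f] == 0]
    if empty:
        raise ValueError(f"folds {empty} would miss a class; reduce k")
    return FoldSplit(k=k, assignments=assignments, constraints_log=log)


# ---------------------------------------------------------------------------
# Model comparison


def compare_models_ttest(
    probs_a: Sequence[float], probs_b: Sequence[float]
) -> ComparisonResult:
    """Classical two-sample unpaired t-test on per-video probabilities.

    A degenerate zero-variance pair is handled as an exact-equality
    test: p = 1 for equal means, p = 0 otherwise.
    """
    a = np.asarray(probs_a, dtype=np.float64)
    b = np.asarray(probs_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a, sd_b = float(a.std(ddof=1)), float(b.std(ddof=1))
    if sd_a == 0.0 and sd_b == 0.0:
        equal = np.isclose(mean_a, mean_b)
        t_stat = 0.0 if equal else np.inf * np.sign(mean_a - mean_b)
        p = 1.0 if equal else 0.0
    else:
        res = sps.ttest_ind(a, b, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        mean_a=mean_a, sd_a=sd_a, mean_b=mean_b, sd_b=sd_b,
        t_statistic=float(t_stat), p_value=float(p),
    )


# ---------------------------------------------------------------------------
# Degradation experiment harness


def run_degradation_experiment(
    clips: Sequence[VideoClip],
    rates: Sequence[float],
    resolutions: Sequence[tuple[int, int]],
    pipeline_config: Optional[dict] = None,
    seed: int = 0,
) -> list[dict]:
    """Train and evaluate the full pipeline per (rate, resolution) cell.

    ``clips`` is a labeled dataset generated at the top rate and
    resolution. Each cell decimates/downscales every clip, then runs
    filter → train → vote → metrics with fixed seeds, producing one
    metrics row per cell (a degradation-grid table).
    """
    from .pipeline import train_eval_run  # local import: avoids cycle

    config = dict(pipeline_config or {})
    rows = []
    for rate in rates:
        for resolution in resolutions:
            degraded = [
                downscale(resample_rate(c, rate), tuple(resolution)) for c in clips
            ]
            result = train_eval_run(degraded, seed=seed, **config)
            row = {"rate": rate, "resolution": tuple(resolution)}
            row.update(result.report.as_dict())
            rows.append(row)
    return rows


def learning_curves(training_log: Sequence[dict], eps: float = 1e-3) -> dict:
    """Per-epoch series for plotting, with a convergence flag.

    The run is flagged converged when the mean loss slope over the final
    window (last quarter of epochs, min 3) is ≥ −eps per epoch.
    """
    if not training_log:
        raise ValueError("training log is empty")
    epochs = np.array([row["epoch"] for row in training_log], dtype=float)
    loss = np.array([row["train_loss"] for row in training_log], dtype=float)
    tail = max(3, len(loss) // 4)
    if len(loss) >= 2:
        slope = float(np.polyfit(epochs[-tail:], loss[-tail:], 1)[0]) if len(loss[-tail:]) >= 2 else 0.0
    else:
        slope = 0.0
    return {
        "epoch": epochs,
        "train_loss": loss,
        "final_slope": slope,
        "converged": bool(slope >= -eps),
    }
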