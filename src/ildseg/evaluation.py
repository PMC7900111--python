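"""Per-case detection/segmentation evaluation and between-model comparison.

The protocol, per test case: voxel-wise ROC/AUC over brain-mask voxels;
binarization at an operating threshold chosen by the Youden index on the
validation set; Dice / IoU / precision / recall / FPR from voxel counts;
lesion-wise false-positive counting on 26-connected components (voxels
touching by face, edge or corner belong to one lesion), both without a
size limit and keeping only components >= 10 mm^3; cohorts are compared
metric-by-metric with the two-sided Wilcoxon rank-sum test at alpha=0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve

from .inference import ProbabilityMap, binarize
from .volumes import MultisequenceStudy

__all__ = [
    "CaseMetrics",
    "LesionLabelMap",
    "RocCurve",
    "ComparisonResult",
    "CohortSummary",
    "roc_auc",
    "youden_threshold",
    "voxel_metrics",
    "label_components",
    "count_lesion_fp",
    "evaluate_case",
    "compare_models",
    "summarize_cohort",
    "plot_mean_roc",
]

DEFAULT_FPR_GRID = np.linspace(0.0, 1.0, 101)
DEFAULT_SIZE_LIMIT_MM3 = 10.0

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class SingleClassError(ValueError):
    """Ground truth contains only one class inside the brain mask."""


@dataclass
class RocCurve:
    """Empirical ROC resampled onto a fixed FPR grid for vertical averaging."""

    fpr_grid: np.ndarray
    tpr: np.ndarray


@dataclass
class CaseMetrics:
    """One test case's detection and segmentation record."""

    auc: float
    dice: float
    iou: float
    precision: float
    recall: float
    fpr: float
    fp_all: int
    fp_10mm3: int
    threshold_used: float
    subject_id: str = "subject"
    roc: RocCurve | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "subject": self.subject_id,
            "auc": self.auc,
            "dice": self.dice,
            "iou": self.iou,
            "precision": self.precision,
            "recall": self.recall,
            "fpr": self.fpr,
            "fp_all": self.fp_all,
            "fp_10mm3": self.fp_10mm3,
            "threshold_used": self.threshold_used,
        }


@dataclass
class LesionLabelMap:
    """26-connected components of a binary mask with per-component volumes (mm^3)."""

    labels: np.ndarray
    volumes_mm3: np.ndarray  # volumes_mm3[i] is the volume of label i+1
    connectivity: int = 26

    @property
    def n_components(self) -> int:
        return len(self.volumes_mm3)


@dataclass
class ComparisonResult:
    p_value: float
    significant: bool
    statistic: float
    metric: str


@dataclass
class CohortSummary:
    table: pd.DataFrame  # index = metric, columns = mean, sd
    n_cases: int
    fpr_grid: np.ndarray | None = None
    tpr_mean: np.ndarray | None = None
    tpr_lo: np.ndarray | None = None
    tpr_hi: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Voxel-wise ROC


def _as_values(prob_map) -> np.ndarray:
    return prob_map.values if isinstance(prob_map, ProbabilityMap) else np.asarray(prob_map)


def roc_auc(
    prob_map,
    ground_truth: np.ndarray,
    brain_mask: np.ndarray,
    fpr_grid: np.ndarray | None = None,
) -> tuple[float, RocCurve]:
    """Per-case AUC (trapezoidal, over brain-mask voxels) plus the gridded curve."""
    values = _as_values(prob_map)
    gt = np.asarray(ground_truth).astype(bool)
    mask = np.asarray(brain_mask).astype(bool)
    y = gt[mask].ravel()
    p = values[mask].ravel()
    if y.all() or not y.any():
        raise SingleClassError("ground truth has a single class within the brain mask")
    fpr, tpr, _ = sk_roc_curve(y, p)
    area = float(sk_auc(fpr, tpr))
    grid = DEFAULT_FPR_GRID if fpr_grid is None else np.asarray(fpr_grid)
    return area, RocCurve(fpr_grid=grid, tpr=np.interp(grid, fpr, tpr))


def youden_threshold(
    prob_maps: Sequence,
    ground_truths: Sequence[np.ndarray],
    brain_masks: Sequence[np.ndarray],
) -> float:
    """Operating threshold maximizing sensitivity + specificity - 1.

    Computed on validation voxels pooled across cases; candidate
    thresholds are the observed probability values plus {0, 1}; ties are
    broken toward the larger threshold.
    """
    pos_parts, neg_parts = [], []
    for pm, gt, mask in zip(prob_maps, ground_truths, brain_masks):
        values = _as_values(pm)
        gt = np.asarray(gt).astype(bool)
        mask = np.asarray(mask).astype(bool)
        pos_parts.append(values[gt & mask].ravel())
        neg_parts.append(values[~gt & mask].ravel())
    pos = np.sort(np.concatenate(pos_parts))
    neg = np.sort(np.concatenate(neg_parts))
    if len(pos) == 0 or len(neg) == 0:
        raise SingleClassError("validation voxels must contain both classes")
    candidates = np.unique(np.concatenate([pos, neg, [0.0, 1.0]]))
    # prediction rule is p >= t: tp(t) = #pos >= t, tn(t) = #neg < t
    sens = (len(pos) - np.searchsorted(pos, candidates, side="left")) / len(pos)
    spec = np.searchsorted(neg, candidates, side="left") / len(neg)
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max()).max()
    return float(candidates[best])


# ---------------------------------------------------------------------------
# Voxel counts


def voxel_metrics(
    prediction: np.ndarray,
    ground_truth: np.ndarray,
    brain_mask: np.ndarray,
) -> dict[str, float]:
    """Dice/IoU/precision/recall/FPR from TP/FP/FN/TN inside the brain mask.

    Degenerate-denominator conventions: precision = 1 when there are no
    predicted positives and no ground-truth voxels, otherwise 0 when
    nothing is predicted; recall = 1 whenever the ground truth is empty;
    dice and iou = 1 when both masks are empty and 0 when exactly one is;
    fpr = 0 when the mask holds no negatives.
    """
    pred = np.asarray(prediction).astype(bool)
    gt = np.asarray(ground_truth).astype(bool)
    mask = np.asarray(brain_mask).astype(bool)
    p = pred[mask]
    g = gt[mask]
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))

    if tp + fp + fn == 0:
        dice = iou = 1.0
    else:
        dice = 2 * tp / (2 * tp + fp + fn)
        iou = tp / (tp + fp + fn)
    precision = 1.0 if (tp + fp == 0 and fn == 0) else (tp / (tp + fp) if tp + fp else 0.0)
    recall = 1.0 if tp + fn == 0 else tp / (tp + fn)
    fpr = fp / (fp + tn) if fp + tn else 0.0
    return {"dice": dice, "iou": iou, "precision": precision, "recall": recall,
            "fpr": fpr, "tp": tp, "fp": fp, "fn": fn, "tn": tn}


# ---------------------------------------------------------------------------
# Lesion-wise counting


def label_components(
    binary_mask: np.ndarray, voxel_spacing: Sequence[float]
) -> LesionLabelMap:
    """Label maximal 26-connected components; volume = count x voxel volume."""
    mask = np.asarray(binary_mask).astype(bool)
    labels, n = ndimage.label(mask, structure=_CONN26)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    voxel_vol = float(np.prod(np.asarray(voxel_spacing, dtype=float)))
    return LesionLabelMap(labels=labels, volumes_mm3=counts * voxel_vol)


def count_lesion_fp(
    components: LesionLabelMap,
    ground_truth: np.ndarray,
    min_volume_mm3: float = 0.0,
) -> int:
    """Count predicted components with zero ground-truth overlap.

    Components smaller than ``min_volume_mm3`` are excluded before
    counting; 0 gives the no-size-limit count.
    """
    gt = np.asarray(ground_truth).astype(bool)
    if components.n_components == 0:
        return 0
    overlapping = np.unique(components.labels[gt])
    overlapping = set(int(x) for x in overlapping if x > 0)
    fp = 0
    for label_idx, vol in enumerate(components.volumes_mm3, start=1):
        if vol < min_volume_mm3:
            continue
        if label_idx not in overlapping:
            fp += 1
    return fp


# ---------------------------------------------------------------------------
# Composition and cohort statistics


def evaluate_case(
    prob_map: ProbabilityMap,
    study: MultisequenceStudy,
    threshold: float,
    size_limit_mm3: float = DEFAULT_SIZE_LIMIT_MM3,
    fpr_grid: np.ndarray | None = None,
) -> CaseMetrics:
    """Full per-case record: AUC, threshold metrics, FP counts with/without size limit."""
    area, curve = roc_auc(prob_map, study.ground_truth, study.brain_mask, fpr_grid)
    pred = binarize(prob_map, threshold)
    vm = voxel_metrics(pred, study.ground_truth, study.brain_mask)
    comps = label_components(pred, study.voxel_spacing)
    fp_all = count_lesion_fp(comps, study.ground_truth, 0.0)
    fp_limited = count_lesion_fp(comps, study.ground_truth, size_limit_mm3)
    return CaseMetrics(
        auc=area,
        dice=vm["dice"],
        iou=vm["iou"],
        precision=vm["precision"],
        recall=vm["recall"],
        fpr=vm["fpr"],
        fp_all=fp_all,
        fp_10mm3=fp_limited,
        threshold_used=float(threshold),
        subject_id=study.subject_id,
        roc=curve,
    )


def _metric_values(cases, metric: str) -> np.ndarray:
    if len(cases) and isinstance(cases[0], CaseMetrics):
        return np.asarray([getattr(c, metric) for c in cases], dtype=float)
    return np.asarray(cases, dtype=float)


def compare_models(
    metrics_a: Sequence, metrics_b: Sequence, metric: str = "dice",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test on per-case values.

    Exact for small tie-free samples; if every value across both groups is
    identical the comparison is vacuous and p = 1 by convention.
    """
    a = _metric_values(metrics_a, metric)
    b = _metric_values(metrics_b, metric)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ComparisonResult(p_value=1.0, significant=False, statistic=float("nan"),
                                metric=metric)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return ComparisonResult(
        p_value=float(res.pvalue),
        significant=bool(res.pvalue <= alpha),
        statistic=float(res.statistic),
        metric=metric,
    )


def summarize_cohort(cases: Sequence[CaseMetrics]) -> CohortSummary:
    """Mean +/- sample sd per metric, plus the vertically averaged ROC band.

    The band is mean +/- 1.96 * sd/sqrt(n) of per-case sensitivity at each
    FPR grid point (normal-approximation 95% CI).
    """
    if len(cases) < 2:
        raise ValueError("need at least two cases to summarize")
    names = ["auc", "dice", "iou", "precision", "recall", "fpr", "fp_all", "fp_10mm3"]
    table = pd.DataFrame(
        {
            "mean": [float(np.mean(_metric_values(cases, m))) for m in names],
            "sd": [float(np.std(_metric_values(cases, m), ddof=1)) for m in names],
        },
        index=names,
    )
    curves = [c.roc for c in cases if c.roc is not None]
    grid = tpr_mean = tpr_lo = tpr_hi = None
    if curves:
        grid = curves[0].fpr_grid
        tprs = np.stack([c.tpr for c in curves])
        tpr_mean = tprs.mean(axis=0)
        half = 1.96 * tprs.std(axis=0, ddof=1) / np.sqrt(len(curves))
        tpr_lo = np.clip(tpr_mean - half, 0.0, 1.0)
        tpr_hi = np.clip(tpr_mean + half, 0.0, 1.0)
    return CohortSummary(
        table=table,
        n_cases=len(cases),
        fpr_grid=grid,
        tpr_mean=tpr_mean,
        tpr_lo=tpr_lo,
        tpr_hi=tpr_hi,
    )


def plot_mean_roc(summary: CohortSummary, path: str, title: str = "Mean ROC") -> None:
    """Cohort-averaged ROC with its 95% confidence band, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if summary.fpr_grid is None:
        raise ValueError("summary carries no ROC curves")
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(summary.fpr_grid, summary.tpr_mean, color="tab:green", label="mean ROC")
    ax.fill_between(summary.fpr_grid, summary.tpr_lo, summary.tpr_hi,
                    color="tab:green", alpha=0.3, label="95% CI")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("Sensitivity")
    ax.set_title(f"{title} (n={summary.n_cases})")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
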