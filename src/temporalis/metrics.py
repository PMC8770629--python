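"""Segmentation evaluation: overlap metrics, Hausdorff distance, CSA error,
and manual-vs-automated area agreement statistics.

Conventions for degenerate masks are explicit: when prediction and ground
truth are both empty the overlap metrics are defined as 1 (a vacuously
perfect prediction); when exactly one is empty, DSC and Jaccard are 0 and
the undefined precision/recall ratio is reported as 0.  The Hausdorff
distance is the full (100th-percentile) symmetric distance between
foreground pixel-center point sets, in physical mm, and is undefined (an
error) if either mask is empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff
from scipy import stats

from .imaging_io import BinaryMask


@dataclass
class SegMetrics:
    """Per-image evaluation record."""

    dsc: float
    ji: float
    precision: float
    recall: float
    hd_mm: float
    csa_error_pct: float


@dataclass
class MetricSummary:
    """Per-metric mean and SD over a set of image pairs (mean ± SD style)."""

    mean: dict[str, float]
    sd: dict[str, float]
    n: int


def overlap_metrics(pred: BinaryMask, gt: BinaryMask) -> tuple[float, float, float, float]:
    """(DSC, Jaccard, precision, recall) from TP/FP/FN pixel counts."""
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    p = pred.labels.astype(bool)
    g = gt.labels.astype(bool)
    tp = int((p & g).sum())
    fp = int((p & ~g).sum())
    fn = int((~p & g).sum())
    if tp + fp + fn == 0:  # both empty
        return 1.0, 1.0, 1.0, 1.0
    dsc = 2 * tp / (2 * tp + fp + fn)
    ji = tp / (tp + fp + fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return dsc, ji, precision, recall


def _points_mm(mask: BinaryMask) -> np.ndarray:
    yy, xx = np.nonzero(mask.labels)
    return np.stack([yy * mask.spacing[0], xx * mask.spacing[1]], axis=1)


def hausdorff_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetric Hausdorff distance between foreground pixel centers, in mm."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.spacing != b.spacing:
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
    pa = _points_mm(a)
    pb = _points_mm(b)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


def csa_error(pred: BinaryMask, gt: BinaryMask) -> float:
    """Relative cross-sectional-area error |CSA_pred − CSA_gt| / CSA_gt × 100 (%)."""
    gt_area = float(gt.labels.sum()) * gt.pixel_area_mm2
    if gt_area == 0:
        raise ValueError("CSA error is undefined for an empty ground truth")
    pred_area = float(pred.labels.sum()) * pred.pixel_area_mm2
    return abs(pred_area - gt_area) / gt_area * 100.0


def evaluate_pair(pred: BinaryMask, gt: BinaryMask) -> SegMetrics:
    dsc, ji, precision, recall = overlap_metrics(pred, gt)
    return SegMetrics(
        dsc=dsc,
        ji=ji,
        precision=precision,
        recall=recall,
        hd_mm=hausdorff_distance(pred, gt),
        csa_error_pct=csa_error(pred, gt),
    )


def summarize(records: list[SegMetrics]) -> MetricSummary:
    if not records:
        raise ValueError("cannot summarize an empty metric list")
    names = ("dsc", "ji", "precision", "recall", "hd_mm", "csa_error_pct")
    arrays = {k: np.array([getattr(r, k) for r in records], dtype=float) for k in names}
    return MetricSummary(
        mean={k: float(v.mean()) for k, v in arrays.items()},
        sd={k: float(v.std(ddof=1)) if len(records) > 1 else 0.0 for k, v in arrays.items()},
        n=len(records),
    )


@dataclass
class BlandAltman:
    mean_difference: float
    loa_low: float
    loa_high: float


def agreement_stats(pred_areas, gt_areas) -> tuple[float, float, BlandAltman]:
    """Pearson r (two-sided p) and Bland–Altman limits for paired areas.

    Limits of agreement are the classical mean difference ± 1.96 × SD of
    the pairwise differences (prediction − ground truth).
    """
    x = np.asarray(pred_areas, dtype=float)
    y = np.asarray(gt_areas, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pred_areas and gt_areas must be equal-length 1D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson correlation is undefined for a zero-variance list")
    r, p = stats.pearsonr(x, y)
    diff = x - y
    d_mean = float(diff.mean())
    d_sd = float(diff.std(ddof=1))
    ba = BlandAltman(
        mean_difference=d_mean,
        loa_low=d_mean - 1.96 * d_sd,
        loa_high=d_mean + 1.96 * d_sd,
    )
    return float(r), float(p), ba
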