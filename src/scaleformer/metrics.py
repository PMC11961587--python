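"""Segmentation evaluation metrics and paired significance testing.

Implements the standard mask-overlap and boundary metrics used to score
2D medical segmentations — Dice similarity (DSC, in percent), the 95th
percentile Hausdorff distance (HD95) over pooled symmetric boundary
distances, and confusion-matrix rates (mIoU, accuracy, sensitivity,
specificity) — plus a paired two-sided t-test with 95% confidence
intervals for comparing two models case by case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

__all__ = ["dsc", "dsc_per_class", "hd95", "confusion_metrics",
           "TTestReport", "paired_t_test", "write_ttest_csv"]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def dsc(pred_mask, gt_mask) -> float:
    """Dice similarity of two binary masks, in percent.

    Masks are binarized on "nonzero".  Two empty masks agree perfectly
    and score 100.
    """
    p = np.asarray(pred_mask) != 0
    g = np.asarray(gt_mask) != 0
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    denom = p.sum() + g.sum()
    if denom == 0:
        return 100.0
    return float(200.0 * np.logical_and(p, g).sum() / denom)


def dsc_per_class(pred_mask, gt_mask, num_classes: int) -> np.ndarray:
    """Per-class Dice (percent) for integer-labeled masks."""
    return np.array([dsc(np.asarray(pred_mask) == c,
                         np.asarray(gt_mask) == c)
                     for c in range(num_classes)])


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates of boundary pixels (mask pixels with a 4-neighbor
    outside the mask; the image border counts as outside)."""
    interior = binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~interior)


def hd95(pred_mask, gt_mask, spacing=(1.0, 1.0), return_flag: bool = False):
    """95th percentile of pooled symmetric boundary distances.

    Distances from every predicted boundary point to the reference
    boundary and vice versa are pooled before taking the linearly
    interpolated 95th percentile; coordinates are scaled by ``spacing``.
    If either mask is empty the image diagonal is reported as a worst
    case — flagged via ``return_flag`` — never a silent zero.
    """
    p = np.asarray(pred_mask) != 0
    g = np.asarray(gt_mask) != 0
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    spacing = np.asarray(spacing, dtype=float)
    if not p.any() or not g.any():
        diag = float(np.linalg.norm((np.array(p.shape) - 1) * spacing))
        return (diag, True) if return_flag else diag
    bp = _boundary_points(p) * spacing
    bg = _boundary_points(g) * spacing
    d_pg = cKDTree(bg).query(bp)[0]
    d_gp = cKDTree(bp).query(bg)[0]
    value = float(np.percentile(np.concatenate([d_pg, d_gp]), 95))
    return (value, False) if return_flag else value


def confusion_metrics(pred_mask, gt_mask) -> dict:
    """Binary-task mIoU / Acc / Sen / Spe from the confusion matrix.

    Ratios with a zero denominator are reported as None (missing), not 0.
    """
    p = np.asarray(pred_mask) != 0
    g = np.asarray(gt_mask) != 0
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))

    def ratio(num, den):
        return num / den if den else None

    iou_fg = ratio(tp, tp + fp + fn)
    iou_bg = ratio(tn, tn + fn + fp)
    ious = [v for v in (iou_fg, iou_bg) if v is not None]
    return {
        "mIoU": float(np.mean(ious)) if ious else None,
        "Acc": ratio(tp + tn, tp + tn + fp + fn),
        "Sen": ratio(tp, tp + fn),
        "Spe": ratio(tn, tn + fp),
    }


@dataclass
class TTestReport:
    """Paired-comparison summary between two per-case score vectors."""

    t_stat: float
    p_value: float
    significant: bool
    mean_a: float
    mean_b: float
    ci_a: tuple
    ci_b: tuple
    n: int
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "t_stat": self.t_stat, "p_value": self.p_value,
            "significant": bool(self.significant),
            "mean_a": self.mean_a, "mean_b": self.mean_b,
            "ci_a": list(self.ci_a), "ci_b": list(self.ci_b),
            "n": self.n, "alpha": self.alpha,
        }


def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple:
    n = len(x)
    se = x.std(ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.5 + level / 2, n - 1) * se
    return (float(x.mean() - half), float(x.mean() + half))


def paired_t_test(scores_a, scores_b, alpha: float = 0.05) -> TTestReport:
    """Two-sided paired t-test on per-case score differences.

    Identical vectors (all differences zero) are reported as t=0, p=1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.ndim != 1 or a.shape != b.shape:
        raise ValueError("score vectors must be 1D with equal length")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs at least two cases")
    diffs = a - b
    if np.allclose(diffs, 0.0, atol=0.0):
        t_stat, p_value = 0.0, 1.0
    else:
        t_stat, p_value = stats.ttest_rel(a, b)
        t_stat, p_value = float(t_stat), float(p_value)
    return TTestReport(
        t_stat=t_stat, p_value=p_value, significant=bool(p_value < alpha),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        ci_a=_mean_ci(a), ci_b=_mean_ci(b), n=n, alpha=alpha)


def write_ttest_csv(reports: dict, path):
    """Write a comparison table (method, t, p, significant, CI) as CSV."""
    rows = []
    for method, rep in reports.items():
        rows.append({
            "method": method,
            "t_statistic": rep.t_stat,
            "p_value": rep.p_value,
            "significant": "Yes" if rep.significant else "No",
            "ci_low": rep.ci_b[0],
            "ci_high": rep.ci_b[1],
        })
    pd.DataFrame(rows).to_csv(path, index=False)
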