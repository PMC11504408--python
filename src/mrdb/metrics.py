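"""Evaluation metrics: DSC, Jaccard, sensitivity/FNR, HD95 and the pooled
precision–recall curve.

Conventions
-----------
* Mask metrics binarize predictions at 0.5.
* Both-empty mask pairs score DSC = Jaccard = 1 (perfect agreement).
* HD95 operates on boundary pixels (foreground pixels with at least one
  background 4-neighbour), Euclidean pixel distances, linear-interpolation
  percentile; the two directed distance distributions are reduced at the
  95th percentile separately and the maximum is returned.  Empty masks
  yield NaN, which aggregation skips.
* The PR curve pools pixels across the whole dataset and integrates by the
  trapezoidal rule over recall, anchored at recall 0 with the precision of
  the most selective threshold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "dsc",
    "jaccard",
    "sensitivity_fnr",
    "boundary_pixels",
    "hd95",
    "pr_curve",
    "evaluate_pair",
    "write_report_csv",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = ("image_id", "dsc", "jaccard", "sensitivity", "hd95", "fnr")

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    dsc: float
    jaccard: float
    sensitivity: float
    hd95: float
    fnr: float
    pr_auc: float | None = None


def _as_bool(m) -> np.ndarray:
    m = np.asarray(m)
    if m.dtype != bool:
        if not np.isin(np.unique(m), (0, 1)).all():
            raise ValueError("mask must be boolean or strictly {0, 1}-valued")
        m = m.astype(bool)
    return m


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")


def confusion_counts(gt, pred) -> ConfusionCounts:
    gt, pred = _as_bool(gt), _as_bool(pred)
    _check_shapes(gt, pred)
    tp = int(np.sum(gt & pred))
    fp = int(np.sum(~gt & pred))
    fn = int(np.sum(gt & ~pred))
    tn = int(np.sum(~gt & ~pred))
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(a, b) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A| + |B|)``."""
    a, b = _as_bool(a), _as_bool(b)
    _check_shapes(a, b)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * float(np.sum(a & b)) / (sa + sb)


def jaccard(a, b) -> float:
    """Jaccard index ``|A∩B| / |A∪B|``."""
    a, b = _as_bool(a), _as_bool(b)
    _check_shapes(a, b)
    union = int(np.sum(a | b))
    if union == 0:
        return 1.0
    return float(np.sum(a & b)) / union


def sensitivity_fnr(c: ConfusionCounts) -> tuple[float, float]:
    """``(TP/(TP+FN), FN/(TP+FN))``; the pair sums to 1 exactly.

    Returns ``(nan, nan)`` when there are no positive ground-truth pixels.
    """
    denom = c.tp + c.fn
    if denom == 0:
        return (float("nan"), float("nan"))
    sens = c.tp / denom
    return (sens, 1.0 - sens)


def boundary_pixels(mask) -> np.ndarray:
    """Coordinates (N, 2) of foreground pixels with a background 4-neighbour."""
    mask = _as_bool(mask)
    if not mask.any():
        return np.empty((0, 2))
    interior = binary_erosion(mask, structure=_CROSS, border_value=1)
    return np.argwhere(mask & ~interior).astype(float)


def hd95(a, b, percentile: float = 95.0) -> float:
    """95th-percentile symmetric boundary distance (pixels).

    ``max(P95 d(A→B), P95 d(B→A))`` over Euclidean distances between
    boundary pixel sets.  NaN when either mask is empty.
    """
    a, b = _as_bool(a), _as_bool(b)
    _check_shapes(a, b)
    pa, pb = boundary_pixels(a), boundary_pixels(b)
    if len(pa) == 0 or len(pb) == 0:
        return float("nan")
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def pr_curve(scores, gts) -> tuple[np.ndarray, float]:
    """Pooled pixel-level precision–recall curve and its trapezoidal AUC.

    ``scores``/``gts`` are single arrays or sequences of per-image arrays;
    all pixels are pooled.  Returns ``(points, auc)`` where ``points`` is an
    (M, 3) array of (threshold, precision, recall) rows ordered from the
    most to the least selective threshold.
    """
    if isinstance(scores, np.ndarray):
        scores = [scores]
    if isinstance(gts, np.ndarray):
        gts = [gts]
    s = np.concatenate([np.asarray(x, dtype=float).ravel() for x in scores])
    g = np.concatenate([_as_bool(x).ravel() for x in gts])
    if s.shape != g.shape:
        raise ValueError("scores and ground truths differ in pixel count")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    npos = int(g.sum())
    if npos == 0:
        raise ValueError("no positive pixels in the ground truth")

    order = np.argsort(-s, kind="stable")
    s_sorted, g_sorted = s[order], g[order]
    tp_cum = np.cumsum(g_sorted)
    pred_cum = np.arange(1, len(s_sorted) + 1)
    # one PR point per distinct threshold (last occurrence of each value)
    distinct = np.flatnonzero(np.diff(s_sorted, append=-np.inf))
    precision = tp_cum[distinct] / pred_cum[distinct]
    recall = tp_cum[distinct] / npos
    thresholds = s_sorted[distinct]
    points = np.column_stack([thresholds, precision, recall])

    rec = np.concatenate([[0.0], recall])
    prec = np.concatenate([[precision[0]], precision])
    auc = float(np.trapezoid(prec, rec))
    return points, auc


def evaluate_pair(gt, prob, threshold: float = 0.5) -> MetricsReport:
    """All mask metrics for one image given a probability map."""
    gt = _as_bool(gt)
    pred = np.asarray(prob) >= threshold
    c = confusion_counts(gt, pred)
    sens, fnr = sensitivity_fnr(c)
    return MetricsReport(
        dsc=dsc(gt, pred),
        jaccard=jaccard(gt, pred),
        sensitivity=sens,
        hd95=hd95(gt, pred),
        fnr=fnr,
    )


def write_report_csv(path, rows: list[tuple[str, MetricsReport]],
                     pr_auc: float | None = None) -> None:
    """Write one row per image plus a nanmean summary row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fields = ["dsc", "jaccard", "sensitivity", "hd95", "fnr"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = list(REPORT_COLUMNS) + (["pr_auc"] if pr_auc is not None else [])
        writer.writerow(header)
        for image_id, rep in rows:
            writer.writerow([image_id] + [f"{getattr(rep, f):.6f}" for f in fields])
        summary = []
        for f in fields:
            vals = np.array([getattr(rep, f) for _, rep in rows], dtype=float)
            vals = vals[~np.isnan(vals)]
            summary.append(f"{vals.mean():.6f}" if len(vals) else "nan")
        row = ["mean"] + summary
        if pr_auc is not None:
            row.append(f"{pr_auc:.6f}")
        writer.writerow(row)
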