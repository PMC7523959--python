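"""Detection / segmentation evaluation protocol.

Metrics follow the COCO-style convention for microscopy benchmarks:

* IoU of two pixel sets, ``IoU(A, B) = |A ∩ B| / |A ∪ B|``;
* greedy score-ordered matching of the top-100 detections per image against
  ground truth at an IoU threshold ``t``;
* 101-point interpolated average precision per threshold,
  ``AP(t) = 1/101 · Σ_{r ∈ {0, 0.01, …, 1}} p_interp(r)`` with
  ``p_interp(r) = max_{r̃ ≥ r} p(r̃)`` over the measured precision/recall
  points pooled over the whole test set;
* mean AP over the nine thresholds 0.50, 0.55, …, 0.90.

Matching is greedy in descending score order: each detection is assigned to
the not-yet-matched ground-truth object of highest IoU, provided that IoU
reaches the threshold; leftover detections are false positives and leftover
ground-truth objects false negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import InstanceSet

__all__ = [
    "IOU_THRESHOLDS",
    "MatchResult",
    "EvalReport",
    "mask_iou",
    "box_iou",
    "match_detections",
    "interpolated_ap",
    "mean_ap",
    "relative_improvement",
    "evaluate",
]

#: the nine IoU thresholds the mean AP averages over
IOU_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.901, 0.05), 2))

#: detections kept per image before matching
TOP_K = 100

#: recall grid of the interpolated AP
RECALL_GRID = np.arange(101) / 100.0


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks on the same raster."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return inter / union


def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two arrays of half-open boxes ``(x0, y0, x1, y1)``."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    x0 = np.maximum(a[:, None, 0], b[None, :, 0])
    y0 = np.maximum(a[:, None, 1], b[None, :, 1])
    x1 = np.minimum(a[:, None, 2], b[None, :, 2])
    y1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x1 - x0, 0, None) * np.clip(y1 - y0, 0, None)
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


@dataclass
class MatchResult:
    """Per-image matching outcome at one IoU threshold."""

    threshold: float
    scores: np.ndarray          # scores of the considered detections (desc order)
    is_tp: np.ndarray           # parallel TP flags
    n_gt: int

    @property
    def tp(self) -> int:
        return int(self.is_tp.sum())

    @property
    def fp(self) -> int:
        return int((~self.is_tp).sum())

    @property
    def fn(self) -> int:
        return self.n_gt - self.tp


def _pairwise_iou(dets: InstanceSet, gts: InstanceSet, mode: str) -> np.ndarray:
    if mode == "box":
        return box_iou(dets.boxes, gts.boxes)
    if mode == "mask":
        out = np.zeros((len(dets), len(gts)))
        for i, dm in enumerate(dets.masks):
            for j, gm in enumerate(gts.masks):
                out[i, j] = mask_iou(dm, gm)
        return out
    raise ValueError(f"mode must be 'box' or 'mask', got {mode!r}")


def match_detections(
    dets: InstanceSet,
    gts: InstanceSet,
    t: float,
    mode: str = "mask",
    top_k: int = TOP_K,
) -> MatchResult:
    """Greedily match the ``top_k`` highest-scoring detections to ground truth."""
    order = np.argsort(-dets.scores, kind="stable")[:top_k]
    dets = dets.subset(order)
    n_det, n_gt = len(dets), len(gts)
    is_tp = np.zeros(n_det, dtype=bool)
    if n_det and n_gt:
        iou = _pairwise_iou(dets, gts, mode)
        gt_taken = np.zeros(n_gt, dtype=bool)
        for i in range(n_det):
            row = np.where(gt_taken, -1.0, iou[i])
            j = int(np.argmax(row))
            if row[j] >= t:
                is_tp[i] = True
                gt_taken[j] = True
    return MatchResult(threshold=t, scores=dets.scores.copy(), is_tp=is_tp, n_gt=n_gt)


def interpolated_ap(matches: list[MatchResult], n_gt_total: int | None = None) -> float:
    """101-point interpolated AP over match results pooled across images."""
    if n_gt_total is None:
        n_gt_total = sum(m.n_gt for m in matches)
    if n_gt_total == 0:
        raise ValueError("AP undefined: no ground-truth instances")
    scores = np.concatenate([m.scores for m in matches]) if matches else np.zeros(0)
    is_tp = np.concatenate([m.is_tp for m in matches]) if matches else np.zeros(0, bool)
    order = np.argsort(-scores, kind="stable")
    is_tp = is_tp[order]
    if is_tp.size == 0:
        return 0.0
    tp_cum = np.cumsum(is_tp)
    fp_cum = np.cumsum(~is_tp)
    precision = tp_cum / (tp_cum + fp_cum)
    recall = tp_cum / n_gt_total
    # p_interp(r) = max precision over points with recall >= r:
    # running max of precision from the right, then lookup per grid point.
    p_ceil = np.maximum.accumulate(precision[::-1])[::-1]
    idx = np.searchsorted(recall, RECALL_GRID, side="left")
    p_interp = np.where(idx < recall.size, p_ceil[np.minimum(idx, recall.size - 1)], 0.0)
    return float(p_interp.mean())


def mean_ap(ap_by_threshold: dict[float, float | None], allow_missing: bool = False) -> float:
    """Arithmetic mean of AP over the nine IoU thresholds 0.50 … 0.90."""
    vals = []
    for t in IOU_THRESHOLDS:
        v = ap_by_threshold.get(round(float(t), 2))
        if v is None:
            if allow_missing:
                continue
            raise ValueError(f"AP missing for threshold {t}")
        vals.append(float(v))
    if not vals:
        raise ValueError("no AP values available")
    return float(np.mean(vals))


def relative_improvement(new_mean_ap: float, baseline_mean_ap: float) -> float:
    """Relative mean-AP gain over a baseline, in percent."""
    if baseline_mean_ap <= 0:
        raise ValueError("baseline mean AP must be positive")
    return 100.0 * (new_mean_ap - baseline_mean_ap) / baseline_mean_ap


@dataclass
class EvalReport:
    """Per-threshold APs, their mean, and count statistics at one threshold."""

    ap_by_threshold: dict[float, float]
    mean_ap: float
    detail_threshold: float
    tp: int
    fp: int
    fn: int
    precision: float = field(init=False)
    recall: float = field(init=False)

    def __post_init__(self) -> None:
        self.precision = self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0
        self.recall = self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0


def evaluate(
    predictions: list[InstanceSet],
    ground_truths: list[InstanceSet],
    mode: str = "mask",
    detail_threshold: float = 0.75,
) -> EvalReport:
    """Full protocol: AP per threshold, mean AP, and TP/FP/FN at one threshold."""
    if len(predictions) != len(ground_truths):
        raise ValueError("predictions and ground truths must pair up per image")
    ap_by_threshold: dict[float, float] = {}
    detail = (0, 0, 0)
    for t in IOU_THRESHOLDS:
        matches = [
            match_detections(p, g, float(t), mode=mode)
            for p, g in zip(predictions, ground_truths)
        ]
        ap_by_threshold[round(float(t), 2)] = interpolated_ap(matches)
        if abs(t - detail_threshold) < 1e-9:
            detail = (
                sum(m.tp for m in matches),
                sum(m.fp for m in matches),
                sum(m.fn for m in matches),
            )
    return EvalReport(
        ap_by_threshold=ap_by_threshold,
        mean_ap=mean_ap(ap_by_threshold),
        detail_threshold=detail_threshold,
        tp=detail[0],
        fp=detail[1],
        fn=detail[2],
    )
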