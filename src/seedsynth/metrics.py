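"""Detection and segmentation evaluation.

Predicted instances are matched to ground truth greedily in descending score
order at a fixed IoU threshold; recall at bbox IoU 0.5 (Recall_50) measures
how many true seeds were found, and mask-IoU average precision (AP_50, AP_75,
AP@[.5:.95]) summarizes the precision–recall trade-off over score-ranked
detections.  AP uses the monotone precision envelope: the precision at each
recall level is replaced by the maximum precision at equal-or-higher recall,
and the area under the resulting staircase is accumulated as
precision x recall-increment rectangles.  Dataset-level numbers are
unweighted (macro) means over images, since each image holds one cultivar.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

IOU_SWEEP = [round(0.50 + 0.05 * i, 2) for i in range(10)]  # 0.50 ... 0.95


@dataclasses.dataclass
class Detection:
    """A scored predicted instance."""

    bbox: tuple[float, float, float, float]  # (x0, y0, x1, y1), half-open
    mask: np.ndarray | None
    score: float


@dataclasses.dataclass
class MatchTable:
    """Per-detection outcome at one IoU threshold, in score-descending order."""

    order: list[int]  # detection indices sorted by descending score
    matched_gt: list[int | None]  # per ordered detection: gt index or None (FP)
    unmatched_gt: list[int]

    @property
    def n_matched(self) -> int:
        return sum(1 for g in self.matched_gt if g is not None)


@dataclasses.dataclass
class EvalSummary:
    recall_50: float
    ap_50: float
    ap_75: float
    ap_range: float
    per_image: dict = dataclasses.field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"image": k, **v} for k, v in sorted(self.per_image.items(), key=lambda t: str(t[0]))
        ]
        rows.append(
            {
                "image": "mean",
                "recall_50": self.recall_50,
                "ap_50": self.ap_50,
                "ap_75": self.ap_75,
                "ap_range": self.ap_range,
            }
        )
        return pd.DataFrame(rows)


def bbox_iou(a, b) -> float:
    """Intersection-over-union of two half-open boxes (x0, y0, x1, y1)."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    if ax0 >= ax1 or ay0 >= ay1 or bx0 >= bx1 or by0 >= by1:
        raise ValueError("degenerate bounding box")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks by pixel counts."""
    if a.shape != b.shape:
        raise ValueError("masks must share shape")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("both masks are empty")
    return np.count_nonzero(a & b) / union


def _iou_matrix(detections: list[dict], truths: list[dict], kind: str) -> np.ndarray:
    """Pairwise det x gt IoU, with a bbox prefilter for mask IoU.

    Mask IoU is counted inside the union of the two bboxes only (both masks
    are empty outside their own bbox), which keeps dense scenes cheap.
    """
    m = np.zeros((len(detections), len(truths)))
    for i, det in enumerate(detections):
        for j, gt in enumerate(truths):
            if kind == "bbox":
                m[i, j] = bbox_iou(det["bbox"], gt["bbox"])
                continue
            if bbox_iou(det["bbox"], gt["bbox"]) == 0.0:
                continue
            ax0, ay0, ax1, ay1 = det["bbox"]
            bx0, by0, bx1, by1 = gt["bbox"]
            sl = np.s_[
                int(min(ay0, by0)) : int(max(ay1, by1)),
                int(min(ax0, bx0)) : int(max(ax1, bx1)),
            ]
            m[i, j] = mask_iou(det["mask"][sl], gt["mask"][sl])
    return m


def match_instances(
    detections: list[dict],
    truths: list[dict],
    iou_threshold: float,
    iou_kind: str = "mask",
    _iou: np.ndarray | None = None,
) -> MatchTable:
    """Greedy score-ordered matching at one IoU threshold.

    Detections and truths are dicts with ``bbox``/``mask`` (and ``score`` for
    detections).  Each detection, visited in descending score (ties keep input
    order), matches the still-unmatched ground truth with the highest
    IoU >= threshold; lacking one it is a false positive.  GT ties break
    toward the lower index.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in (0, 1]")
    if iou_kind not in ("bbox", "mask"):
        raise ValueError("iou_kind must be 'bbox' or 'mask'")
    if _iou is None:
        _iou = _iou_matrix(detections, truths, iou_kind)
    order = sorted(range(len(detections)), key=lambda i: -detections[i]["score"])
    taken = [False] * len(truths)
    matched: list[int | None] = []
    for di in order:
        best_j, best_iou = None, -1.0
        for j in range(len(truths)):
            if taken[j]:
                continue
            iou = _iou[di, j]
            if iou >= iou_threshold and iou > best_iou:
                best_j, best_iou = j, iou
        if best_j is not None:
            taken[best_j] = True
        matched.append(best_j)
    unmatched = [j for j, t in enumerate(taken) if not t]
    return MatchTable(order=order, matched_gt=matched, unmatched_gt=unmatched)


def recall_at(table: MatchTable, n_truth: int) -> float:
    """Matched fraction of ground truth; 1.0 for an empty ground truth."""
    if n_truth < 0:
        raise ValueError("n_truth must be >= 0")
    if n_truth == 0:
        return 1.0
    return table.n_matched / n_truth


def average_precision(
    detections: list[dict],
    truths: list[dict],
    iou_threshold: float,
    iou_kind: str = "mask",
    _iou: np.ndarray | None = None,
) -> float:
    """All-points average precision at one IoU threshold.

    Builds the precision–recall sequence over score-descending prefixes,
    applies the monotone precision envelope and sums the staircase area.
    An empty ground truth scores 1.0 with no detections, else 0.0.
    """
    if not truths:
        return 1.0 if not detections else 0.0
    if not detections:
        return 0.0
    table = match_instances(detections, truths, iou_threshold, iou_kind, _iou=_iou)
    tp = np.cumsum([g is not None for g in table.matched_gt])
    fp = np.cumsum([g is None for g in table.matched_gt])
    recall = tp / len(truths)
    precision = tp / (tp + fp)
    # envelope: precision at each point = max precision at >= this recall
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def ap_sweep(detections: list[dict], truths: list[dict]) -> tuple[float, float, float]:
    """AP_50, AP_75 and the mean AP over mask-IoU thresholds 0.50:0.05:0.95."""
    iou = _iou_matrix(detections, truths, "mask") if detections and truths else None
    aps = {t: average_precision(detections, truths, t, "mask", _iou=iou) for t in IOU_SWEEP}
    return aps[0.5], aps[0.75], float(np.mean(list(aps.values())))


def evaluate_image(detections: list[dict], truths: list[dict]) -> dict:
    """The four summary metrics for one image.

    Recall_50 is computed on bounding boxes; the APs on masks.
    """
    if truths:
        table = match_instances(detections, truths, 0.5, "bbox")
        r50 = recall_at(table, len(truths))
    else:
        r50 = 1.0
    ap50, ap75, apr = ap_sweep(detections, truths)
    return {"recall_50": r50, "ap_50": ap50, "ap_75": ap75, "ap_range": apr}


def degrade_truths(
    truths: list[dict],
    rng: np.random.Generator,
    erode_px: int = 0,
    jitter_px: int = 0,
    drop_rate: float = 0.0,
) -> list[dict]:
    """Simulate an imperfect detector by degrading ground-truth instances.

    Masks are eroded by ``erode_px``, translated by a uniform integer jitter
    in [-jitter_px, jitter_px] per axis, and dropped with probability
    ``drop_rate``; each survivor gets a random confidence score.  Useful for
    calibrating evaluation pipelines: metrics must fall as degradation grows.
    """
    from scipy import ndimage

    out = []
    for gt in truths:
        if drop_rate and rng.random() < drop_rate:
            continue
        mask = gt["mask"].astype(bool)
        if erode_px:
            eroded = ndimage.binary_erosion(mask, iterations=erode_px, border_value=0)
            if eroded.any():
                mask = eroded
        if jitter_px:
            dx, dy = (int(v) for v in rng.integers(-jitter_px, jitter_px + 1, size=2))
            h, w = mask.shape
            shifted = np.zeros_like(mask)
            shifted[
                max(dy, 0) : h + min(dy, 0), max(dx, 0) : w + min(dx, 0)
            ] = mask[max(-dy, 0) : h + min(-dy, 0), max(-dx, 0) : w + min(-dx, 0)]
            if shifted.any():
                mask = shifted
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        bbox = (int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1)
        out.append({"mask": mask, "bbox": bbox, "score": float(rng.uniform(0.5, 1.0))})
    return out


def evaluate_dataset(
    detections_by_image: dict, truths_by_image: dict
) -> EvalSummary:
    """Per-image metrics plus their unweighted mean across images."""
    if set(detections_by_image) != set(truths_by_image):
        missing = set(detections_by_image) ^ set(truths_by_image)
        raise ValueError(f"image ids do not align; mismatched: {sorted(map(str, missing))}")
    per_image = {
        img: evaluate_image(detections_by_image[img], truths_by_image[img])
        for img in truths_by_image
    }
    means = {
        k: float(np.mean([v[k] for v in per_image.values()]))
        for k in ("recall_50", "ap_50", "ap_75", "ap_range")
    }
    return EvalSummary(per_image=per_image, **means)
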