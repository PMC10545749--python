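"""Object-detection evaluation: IOU, greedy TP/FP/FN matching, precision,
recall, all-point interpolated AP, mAP and F1.

A detection is a true positive when it has IOU >= threshold (default 0.5)
with a not-yet-matched ground-truth box of the same class; detections are
matched greedily in order of descending confidence and each ground-truth box
matches at most once.  Wrong-class or misplaced detections are false
positives; unmatched ground truths are false negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import pandas as pd

from .candidate_model import Box, GroundTruthSet

__all__ = [
    "iou",
    "Detection",
    "match_detections",
    "average_precision",
    "ClassStats",
    "MatchReport",
    "summarize",
    "evaluate_detections",
]

DEFAULT_IOU_THRESHOLD = 0.5


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 when equal."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclass(frozen=True)
class Detection:
    box: Box
    label: Hashable
    mu: float


def match_detections(
    preds: Sequence[Detection],
    gts: GroundTruthSet | Sequence[tuple],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> tuple[list[tuple[float, Hashable, bool]], int]:
    """Greedy same-class matching, highest confidence first.

    Returns ``(labels, fn)`` where ``labels`` is a list of
    ``(mu, class, is_tp)`` sorted by descending confidence and ``fn`` the
    number of unmatched ground-truth boxes.
    """
    gt_boxes = list(gts.boxes) if isinstance(gts, GroundTruthSet) else list(gts)
    matched = [False] * len(gt_boxes)
    order = sorted(range(len(preds)), key=lambda i: -preds[i].mu)
    labels: list[tuple[float, Hashable, bool]] = []
    for i in order:
        det = preds[i]
        best_j, best_iou = -1, 0.0
        for j, (gbox, glabel) in enumerate(gt_boxes):
            if matched[j] or glabel != det.label:
                continue
            v = iou(det.box, gbox)
            if v > best_iou:
                best_j, best_iou = j, v
        is_tp = best_iou >= iou_threshold
        if is_tp:
            matched[best_j] = True
        labels.append((det.mu, det.label, is_tp))
    fn = matched.count(False)
    return labels, fn


def average_precision(labels: Sequence[tuple[float, bool]], n_gt: int) -> float:
    """All-point interpolated AP.

    ``labels`` is (confidence, is_tp) pairs; they are (re)sorted by descending
    confidence.  AP = sum over recall steps of (R_{n+1} - R_n) * max precision
    at recall >= R_{n+1}.  With no ground truth, AP is 0 (never the
    undefined-as-1 convention).
    """
    if n_gt == 0:
        return 0.0
    ordered = sorted(labels, key=lambda t: -t[0])
    precisions, recalls = [], []
    tp = fp = 0
    for _, is_tp in ordered:
        if is_tp:
            tp += 1
        else:
            fp += 1
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_gt)
    ap = 0.0
    prev_r = 0.0
    for i, r in enumerate(recalls):
        if r > prev_r:
            p_interp = max(precisions[i:])
            ap += (r - prev_r) * p_interp
            prev_r = r
    return ap


@dataclass
class ClassStats:
    n_gt: int = 0
    tp: int = 0
    fp: int = 0
    labels: list = field(default_factory=list)  # (mu, is_tp) across scenes

    @property
    def fn(self) -> int:
        return self.n_gt - self.tp

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / self.n_gt if self.n_gt else 0.0

    @property
    def ap(self) -> float:
        return average_precision(self.labels, self.n_gt)


@dataclass
class MatchReport:
    per_class: dict
    map: float
    micro_precision: float
    micro_recall: float
    micro_f1: float

    def to_dataframe(self) -> pd.DataFrame:
        """Per-class rows (instances, TP, FP, precision, recall, AP) plus a
        summary row."""
        rows = []
        for cls in sorted(self.per_class, key=str):
            s = self.per_class[cls]
            rows.append(
                {
                    "class": str(cls),
                    "instances": s.n_gt,
                    "TP": s.tp,
                    "FP": s.fp,
                    "precision": s.precision,
                    "recall": s.recall,
                    "AP": s.ap,
                }
            )
        rows.append(
            {
                "class": "summary",
                "instances": sum(s.n_gt for s in self.per_class.values()),
                "TP": sum(s.tp for s in self.per_class.values()),
                "FP": sum(s.fp for s in self.per_class.values()),
                "precision": self.micro_precision,
                "recall": self.micro_recall,
                "AP": self.map,
            }
        )
        return pd.DataFrame(rows)


def f1_score(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


def summarize(stats: dict) -> MatchReport:
    """Aggregate per-class stats into a report.

    mAP averages AP over classes present in the ground truth; classes with
    detections but no ground truth contribute AP = 0, classes with neither
    are excluded.
    """
    ap_classes = {
        cls: s for cls, s in stats.items() if s.n_gt > 0 or (s.tp + s.fp) > 0
    }
    mean_ap = (
        sum(s.ap for s in ap_classes.values()) / len(ap_classes) if ap_classes else 0.0
    )
    tp = sum(s.tp for s in stats.values())
    fp = sum(s.fp for s in stats.values())
    n_gt = sum(s.n_gt for s in stats.values())
    micro_p = tp / (tp + fp) if tp + fp else 0.0
    micro_r = tp / n_gt if n_gt else 0.0
    return MatchReport(stats, mean_ap, micro_p, micro_r, f1_score(micro_p, micro_r))


def evaluate_detections(
    scenes: Iterable[tuple[Sequence[Detection], GroundTruthSet | Sequence[tuple]]],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> MatchReport:
    """Match and score detections over one or more (preds, ground-truth)
    pairs, pooling counts and confidence-ranked labels per class."""
    stats: dict = {}
    for preds, gts in scenes:
        gt_boxes = list(gts.boxes) if isinstance(gts, GroundTruthSet) else list(gts)
        for _, glabel in gt_boxes:
            stats.setdefault(glabel, ClassStats()).n_gt += 1
        labels, _ = match_detections(preds, gt_boxes, iou_threshold)
        for mu, label, is_tp in labels:
            s = stats.setdefault(label, ClassStats())
            s.labels.append((mu, is_tp))
            if is_tp:
                s.tp += 1
            else:
                s.fp += 1
    return summarize(stats)
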