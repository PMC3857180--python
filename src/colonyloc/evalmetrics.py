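"""Detection scoring: greedy matching against ground truth, precision/recall."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["DetectionMetrics", "match_detections", "precision_recall"]


@dataclass
class DetectionMetrics:
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    match_tolerance_px: float | None = None

    @property
    def precision_pct(self) -> float | None:
        return None if self.precision is None else round(100.0 * self.precision, 1)

    @property
    def recall_pct(self) -> float | None:
        return None if self.recall is None else round(100.0 * self.recall, 1)

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall,
                "precision_pct": self.precision_pct, "recall_pct": self.recall_pct,
                "match_tolerance_px": self.match_tolerance_px}


def _as_xy_score(detections) -> list[tuple[float, float, float]]:
    out = []
    for d in detections:
        if hasattr(d, "center"):
            out.append((float(d.center[0]), float(d.center[1]), float(d.score)))
        elif len(d) >= 3:
            out.append((float(d[0]), float(d[1]), float(d[2])))
        else:
            out.append((float(d[0]), float(d[1]), 0.0))
    return out


def match_detections(detections, truth, tolerance_px: float) -> tuple[int, int, int]:
    """Greedy one-to-one matching in descending detection-score order.

    Each detection (in score order, ties by y then x) claims the nearest
    still-unmatched truth point within ``tolerance_px``.  Returns
    (tp, fp, fn).  ``detections`` may be SpotDetection objects or (x, y[,
    score]) tuples; ``truth`` is a sequence of (x, y) points.
    """
    if tolerance_px <= 0:
        raise ValueError("tolerance_px must be > 0")
    dets = _as_xy_score(detections)
    truth_pts = [(float(t[0]), float(t[1])) for t in truth]
    order = sorted(range(len(dets)), key=lambda i: (-dets[i][2], dets[i][1], dets[i][0]))
    matched = [False] * len(truth_pts)
    tp = 0
    for i in order:
        x, y, _ = dets[i]
        best_j, best_d = -1, tolerance_px
        for j, (tx, ty) in enumerate(truth_pts):
            if matched[j]:
                continue
            d = math.hypot(x - tx, y - ty)
            if d <= best_d:
                best_j, best_d = j, d
        if best_j >= 0:
            matched[best_j] = True
            tp += 1
    fp = len(dets) - tp
    fn = len(truth_pts) - tp
    return tp, fp, fn


def precision_recall(tp: int, fp: int, fn: int,
                     match_tolerance_px: float | None = None) -> DetectionMetrics:
    """precision = tp/(tp+fp), recall = tp/(tp+fn); zero denominators -> None."""
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return DetectionMetrics(tp=tp, fp=fp, fn=fn, precision=precision,
                            recall=recall, match_tolerance_px=match_tolerance_px)
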