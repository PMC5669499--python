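"""Detection scoring: IoU, non-maxima suppression, PASCAL-style average
precision, the sliding-window baseline and the dot-product cost ledger.

All boxes are ``(w, h, x, y)`` with ``(x, y)`` the top-left corner and
half-open pixel extents.  AP is reported on the percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np


def iou(a, b) -> float:
    """Intersection-over-union of two (w, h, x, y) boxes; 0 for zero-area."""
    wa, ha, xa, ya = a
    wb, hb, xb, yb = b
    if wa <= 0 or ha <= 0 or wb <= 0 or hb <= 0:
        return 0.0
    ix = max(0.0, min(xa + wa, xb + wb) - max(xa, xb))
    iy = max(0.0, min(ya + ha, yb + hb) - max(ya, yb))
    inter = ix * iy
    union = wa * ha + wb * hb - inter
    return inter / union


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (n, 4) and (m, 4) arrays of (w, h, x, y) boxes."""
    a = np.asarray(boxes_a, dtype=float).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=float).reshape(-1, 4)
    wa, ha, xa, ya = a.T
    wb, hb, xb, yb = b.T
    ix = np.clip(np.minimum(xa[:, None] + wa[:, None], xb + wb)
                 - np.maximum(xa[:, None], xb), 0, None)
    iy = np.clip(np.minimum(ya[:, None] + ha[:, None], yb + hb)
                 - np.maximum(ya[:, None], yb), 0, None)
    inter = ix * iy
    union = (wa * ha)[:, None] + wb * hb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def nms(detections, iou_thresh: float = 0.5):
    """Greedy non-maxima suppression.

    ``detections`` is a sequence of objects with ``score`` and ``box``
    attributes (or (score, box) tuples).  Kept detections are returned in
    descending score order; any detection overlapping a kept one with
    IoU > ``iou_thresh`` is discarded.
    """
    items = list(detections)
    if not items:
        return []

    def _score(d):
        return d.score if hasattr(d, "score") else d[0]

    def _box(d):
        return d.box if hasattr(d, "box") else d[1]

    order = sorted(range(len(items)), key=lambda i: -_score(items[i]))
    boxes = np.array([_box(items[i]) for i in order], dtype=float)
    keep = []
    suppressed = np.zeros(len(order), dtype=bool)
    for i in range(len(order)):
        if suppressed[i]:
            continue
        keep.append(items[order[i]])
        if i + 1 < len(order):
            ious = iou_matrix(boxes[i:i + 1], boxes[i + 1:])[0]
            suppressed[i + 1:] |= ious > iou_thresh
    return keep


@dataclass
class PRCurve:
    """Recall/precision sweep and its area (percent AP)."""

    recall: np.ndarray
    precision: np.ndarray
    ap: float
    n_ground_truth: int


def average_precision(detections, ground_truth, iou_thresh: float = 0.5,
                      method: str = "area") -> PRCurve:
    """PASCAL-protocol AP for one class.

    Parameters
    ----------
    detections:
        iterable of ``(image_id, score, box)``.
    ground_truth:
        mapping ``image_id -> list of boxes``.
    method:
        ``"area"`` integrates the trapezoidal area under the full
        recall-precision curve; ``"11point"`` uses the 11-point
        interpolated variant of the 2007 benchmark protocol.

    Each ground-truth box is matched at most once, greedily in descending
    score order, requiring IoU > ``iou_thresh``.
    """
    n_gt = sum(len(v) for v in ground_truth.values())
    if n_gt == 0:
        raise ValueError("AP is undefined for empty ground truth")
    dets = sorted(detections, key=lambda d: -d[1])
    matched = {k: np.zeros(len(v), dtype=bool) for k, v in ground_truth.items()}
    tp = np.zeros(len(dets))
    fp = np.zeros(len(dets))
    for i, (img, _, box) in enumerate(dets):
        gts = ground_truth.get(img, [])
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gts):
            v = iou(box, g)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_iou > iou_thresh and not matched[img][best_j]:
            matched[img][best_j] = True
            tp[i] = 1
        else:
            fp[i] = 1
    if len(dets) == 0:
        return PRCurve(recall=np.zeros(1), precision=np.ones(1), ap=0.0,
                       n_ground_truth=n_gt)
    ctp = np.cumsum(tp)
    cfp = np.cumsum(fp)
    recall = ctp / n_gt
    precision = ctp / np.maximum(ctp + cfp, 1e-12)
    if method == "area":
        r = np.concatenate([[0.0], recall])
        p = np.concatenate([[precision[0]], precision])
        ap = float(np.trapezoid(p, r))
    elif method == "11point":
        ap = float(np.mean([
            precision[recall >= t].max() if (recall >= t).any() else 0.0
            for t in np.linspace(0, 1, 11)]))
    else:
        raise ValueError(f"unknown AP method {method!r}")
    return PRCurve(recall=recall, precision=precision, ap=100.0 * ap,
                   n_ground_truth=n_gt)


def mean_ap(per_class_ap) -> float:
    """Arithmetic mean of per-class percent-AP values."""
    aps = np.asarray(list(per_class_ap), dtype=float)
    if aps.size == 0:
        raise ValueError("mean AP needs at least one class")
    return float(aps.mean())


# ---------------------------------------------------------------------------
# cost accounting


@dataclass
class CostLedger:
    """Counts template-evaluation operations in spatial-cell units.

    One evaluation of a P x K-cell high-resolution template costs P * K
    operations; one evaluation of a pooled template costs one operation
    per pooling region it covers (feature pooling and the dot product are
    fused into a single template).  Feature extraction is not counted.
    """

    ops: float = 0.0
    by_stage: dict = dc_field(default_factory=dict)

    def add(self, n_ops: float, stage: str = "detect"):
        if n_ops < 0:
            raise ValueError("operation counts are nonnegative")
        self.ops += n_ops
        self.by_stage[stage] = self.by_stage.get(stage, 0.0) + n_ops

    @staticmethod
    def template_cost(p_cells: int, k_cells: int) -> int:
        """Cost of one evaluation of a P x K-cell template."""
        return int(p_cells) * int(k_cells)


def relative_cost(fod_ops: float, sw_ops: float) -> float:
    """FOD cost normalized so the sliding-window baseline is 100."""
    if sw_ops <= 0:
        raise ValueError("sliding-window operation count must be positive")
    return 100.0 * fod_ops / sw_ops


# ---------------------------------------------------------------------------
# sliding-window baseline


def sliding_window_detect(model, image=None, pyramid=None,
                          ledger: CostLedger | None = None,
                          max_detections: int = 100, nms_thresh: float = 0.5):
    """Evaluate the model's foveal-resolution templates at every cell
    position of every pyramid level (the non-foveated baseline).

    ``model`` must provide ``foveal_templates()`` yielding
    ``(template (P, K, D), bias)`` pairs and a ``pyramid_of(image)``
    helper (a :class:`fovod.detector.FodModel` does).  Returns a list of
    :class:`fovod.detector.Detection`; the ledger is incremented by
    P * K per template evaluation.
    """
    from .detector import Detection  # local import to avoid a cycle

    if pyramid is None:
        pyramid = model.pyramid_of(image)
    cell = model.field.config.cell_px
    dets = []
    for sigma, fmap in pyramid:
        M, N, D = fmap.array.shape
        for shape_id, (tmpl, bias) in enumerate(model.foveal_templates()):
            P, K, _ = tmpl.shape
            if M < P or N < K:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(
                fmap.array, (P, K), axis=(0, 1))
            scores = np.einsum("mndpk,pkd->mn", windows, tmpl) + bias
            if ledger is not None:
                ledger.add(scores.size * CostLedger.template_cost(P, K), "sw")
            # keep the strongest responses per level to bound NMS cost
            flat = scores.ravel()
            n_keep = min(flat.size, max_detections)
            idx = np.argpartition(-flat, n_keep - 1)[:n_keep]
            for ij in idx:
                i, j = divmod(int(ij), scores.shape[1])
                box = model.report_box(
                    np.array([K * cell, P * cell, j * cell, i * cell]) / sigma)
                dets.append(Detection(box=box, score=float(flat[ij]),
                                      sigma=sigma, component_id=-1,
                                      shape_id=shape_id))
    dets = nms(dets, nms_thresh)
    return dets[:max_detections]
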