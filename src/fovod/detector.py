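"""The foveated object detector: retino-specific components and scoring.

A *component* is a linear template bound to a fixed box in the visual
field (relative to the fixation point).  Its features are the pooled
responses of the pooling regions under that box, so peripheral templates
are lower-dimensional than foveal ones of the same spatial size.  Because
pooling and the template dot product are both linear, each component is
precompiled to an equivalent cell-space template ``w_eff`` applied
directly to the raw HoG window under its box; one evaluation is still
ledgered at one operation per *pooling region* covered, which is what
makes peripheral evaluations cheap.

The single-fixation detection score of a box ``b`` is the maximum of the
calibrated template responses over all pyramid scales and all components
whose projected box overlaps ``b`` (IoU >= 0.7); scale and component are
latent variables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import features as F
from .evaluation import CostLedger, iou_matrix
from .visual_field import (FieldConfig, PoolingMatrix, VisualField,
                           box_region_coverage, build_field, pooling_matrix,
                           snap_fixation_to_cell)

OVERLAP_CREATE = 0.75      # mean region coverage required to create a component
INTERSECT_FRACTION = 0.2   # region counts as intersected above this coverage
IOU_ADMISSIBLE = 0.7       # component admissible for a box at this IoU


@dataclass
class Component:
    """One retino-specific classifier at a fixed field location."""

    id: int
    shape_id: int
    p_cells: int
    k_cells: int
    anchor: tuple[int, int]            # (r0, c0) cell offsets from fixation cell
    pooling: PoolingMatrix
    is_foveal: bool                    # all covered regions are foveal
    w_lda: np.ndarray | None = None    # (n_regions * D,) raw LDA direction
    alpha: float = 1.0
    beta: float = 0.0
    group: int = -1                    # calibration group
    w_eff: np.ndarray | None = None    # (p, k, D) calibrated cell-space template

    @property
    def n_regions(self) -> int:
        return self.pooling.n_regions

    @property
    def dim(self) -> int:
        """Template length (regions x channels)."""
        d = self.w_lda.size // self.n_regions if self.w_lda is not None else 0
        return self.n_regions * d if d else self.n_regions

    def field_box(self, cell_px: int) -> np.ndarray:
        """(w, h, x, y) of the component box relative to the fixation point."""
        r0, c0 = self.anchor
        return np.array([self.k_cells * cell_px, self.p_cells * cell_px,
                         (c0 - 0.5) * cell_px, (r0 - 0.5) * cell_px])

    def image_box(self, fix_cell: tuple[int, int], cell_px: int) -> np.ndarray:
        """(w, h, x, y) of the box in image pixels for a snapped fixation."""
        fr, fc = fix_cell
        r0, c0 = self.anchor
        return np.array([self.k_cells * cell_px, self.p_cells * cell_px,
                         (fc + c0) * cell_px, (fr + r0) * cell_px], dtype=float)

    def compile(self, n_channels: int):
        """Precompute the calibrated cell-space template."""
        w = self.alpha * self.w_lda.reshape(self.n_regions, n_channels)
        eff = self.pooling.spatial.T @ w
        self.w_eff = eff.reshape(self.p_cells, self.k_cells, n_channels)


@dataclass
class Detection:
    """A scored box in original-image coordinates."""

    box: np.ndarray                    # (w, h, x, y), image pixels
    score: float
    sigma: float
    component_id: int
    shape_id: int = -1
    fixation_index: int = -1


@dataclass
class FodModel:
    """Visual field + retino-specific components for one object class."""

    field: VisualField
    components: list[Component]
    shapes: list[tuple[int, int]]                  # (p_cells, k_cells) per shape
    class_label: str = "object"
    n_scales: int = 12
    scales_per_octave: int = 5
    context_frac: float = 0.0          # background context ring of templates;
    #                                    reported boxes shrink it away
    # per shape: full-resolution (foveal) LDA template and calibration
    foveal_w_lda: list[np.ndarray] = dc_field(default_factory=list)
    foveal_alpha: list[float] = dc_field(default_factory=list)
    foveal_beta: list[float] = dc_field(default_factory=list)
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self._grouped = None

    @property
    def n_components(self) -> int:
        return len(self.components)

    def pyramid_of(self, image) -> F.FeaturePyramid:
        return F.build_pyramid(image, self.n_scales, self.scales_per_octave,
                               self.field.config.cell_px)

    def report_box(self, box):
        """Object box reported for a template box (context ring removed)."""
        if self.context_frac == 0:
            return np.asarray(box, dtype=float)
        w, h, x, y = box
        s = 1 + 2 * self.context_frac
        return np.array([w / s, h / s, x + (w - w / s) / 2,
                         y + (h - h / s) / 2])

    def expand_target(self, box):
        """Pad an object box to template extent for admissibility tests."""
        if box is None or self.context_frac == 0:
            return box
        w, h, x, y = box
        f = self.context_frac
        return np.array([w * (1 + 2 * f), h * (1 + 2 * f),
                         x - f * w, y - f * h])

    def foveal_templates(self):
        """(template (P, K, D), bias) per shape for sliding-window use."""
        out = []
        for s, (p, k) in enumerate(self.shapes):
            w = self.foveal_alpha[s] * self.foveal_w_lda[s]
            out.append((w.reshape(p, k, -1), self.foveal_beta[s]))
        return out

    def compile(self, n_channels: int = F.N_CHANNELS):
        for c in self.components:
            c.compile(n_channels)
        self._grouped = None

    def _by_shape(self):
        """Stack compiled templates per shape for vectorized scoring."""
        if self._grouped is None:
            grouped = {}
            for c in self.components:
                if c.w_eff is None:
                    raise RuntimeError("model not compiled; call compile()")
                grouped.setdefault(c.shape_id, []).append(c)
            self._grouped = {
                s: (np.stack([c.w_eff for c in comps]),
                    np.array([c.beta for c in comps]),
                    np.array([c.anchor for c in comps], dtype=int),
                    np.array([c.n_regions for c in comps]),
                    np.array([c.id for c in comps]))
                for s, comps in grouped.items()}
        return self._grouped

    # -- serialization -------------------------------------------------

    def save(self, path):
        cfg = self.field.config
        manifest = {
            "class_label": self.class_label,
            "shapes": [list(s) for s in self.shapes],
            "n_scales": self.n_scales,
            "scales_per_octave": self.scales_per_octave,
            "field_config": cfg.__dict__,
            "context_frac": self.context_frac,
            "foveal_alpha": self.foveal_alpha,
            "foveal_beta": self.foveal_beta,
            "components": [
                {"id": c.id, "shape_id": c.shape_id, "p": c.p_cells,
                 "k": c.k_cells, "anchor": list(c.anchor),
                 "is_foveal": bool(c.is_foveal), "alpha": c.alpha,
                 "beta": c.beta, "group": c.group}
                for c in self.components],
            "meta": self.meta,
        }
        arrays = {f"w_lda_{c.id}": c.w_lda for c in self.components}
        arrays.update({f"fov_w_{s}": w for s, w in enumerate(self.foveal_w_lda)})
        arrays["manifest"] = np.frombuffer(
            json.dumps(manifest).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "FodModel":
        data = np.load(path)
        man = json.loads(bytes(data["manifest"]).decode())
        field = build_field(FieldConfig(**man["field_config"]))
        cell = field.config.cell_px
        comps = []
        for cm in man["components"]:
            box = _anchor_box(cm["anchor"], cm["p"], cm["k"], cell)
            comps.append(Component(
                id=cm["id"], shape_id=cm["shape_id"], p_cells=cm["p"],
                k_cells=cm["k"], anchor=tuple(cm["anchor"]),
                pooling=pooling_matrix(field, box, INTERSECT_FRACTION),
                is_foveal=cm["is_foveal"], w_lda=data[f"w_lda_{cm['id']}"],
                alpha=cm["alpha"], beta=cm["beta"], group=cm["group"]))
        model = cls(field=field, components=comps,
                    shapes=[tuple(s) for s in man["shapes"]],
                    class_label=man["class_label"], n_scales=man["n_scales"],
                    scales_per_octave=man["scales_per_octave"],
                    foveal_w_lda=[data[f"fov_w_{s}"]
                                  for s in range(len(man["shapes"]))],
                    foveal_alpha=man["foveal_alpha"],
                    foveal_beta=man["foveal_beta"], meta=man["meta"],
                    context_frac=man.get("context_frac", 0.0))
        model.compile()
        return model


def _anchor_box(anchor, p, k, cell):
    r0, c0 = anchor
    return np.array([k * cell, p * cell, (c0 - 0.5) * cell, (r0 - 0.5) * cell])


def init_components(box_stats, field: VisualField,
                    shapes_in_cells: bool = False) -> list[Component]:
    """Create components tiling the visual field for each template shape.

    ``box_stats`` is a list of (w, h) template dimensions in pixels (or in
    cells with ``shapes_in_cells``).  Anchors step one pooling-region
    center apart.  A candidate box intersects a region if it covers more
    than one fifth of the region's weight mass; the box becomes a
    component only if the mean coverage over intersected regions exceeds
    0.75 and the box lies inside the field.
    """
    cell = field.config.cell_px
    comps: list[Component] = []
    foveal_set = set(int(i) for i in field.foveal_ids)
    centers = field.region_centers_px()
    rid = 0
    for shape_id, dims in enumerate(box_stats):
        if shapes_in_cells:
            p, k = int(dims[0]), int(dims[1])     # (rows, cols) in cells
        else:
            w, h = dims                           # (w, h) in pixels
            p = max(1, int(round(h / cell)))
            k = max(1, int(round(w / cell)))
        seen = set()
        created = 0
        for cx, cy in centers:
            r0 = int(round(cy / cell - p / 2 + 0.5))
            c0 = int(round(cx / cell - k / 2 + 0.5))
            if (r0, c0) in seen:
                continue
            seen.add((r0, c0))
            box = _anchor_box((r0, c0), p, k, cell)
            # inside the field: all corners within the field radius
            xs = np.array([box[2], box[2] + box[0]])
            ys = np.array([box[3], box[3] + box[1]])
            corners = np.hypot(xs[:, None], ys[None, :])
            if corners.max() > field.config.field_radius_px:
                continue
            ids, cov = box_region_coverage(field, box)
            inter = cov > INTERSECT_FRACTION
            if not inter.any():
                continue
            if cov[inter].mean() <= OVERLAP_CREATE:
                continue
            pm = pooling_matrix(field, box, INTERSECT_FRACTION)
            comps.append(Component(
                id=rid, shape_id=shape_id, p_cells=p, k_cells=k,
                anchor=(r0, c0), pooling=pm,
                is_foveal=all(int(i) in foveal_set for i in pm.region_ids)))
            rid += 1
            created += 1
        if created == 0:
            warnings.warn(f"no surviving component placements for shape "
                          f"{tuple(dims)}; shape skipped")
    return comps


def init_model(field: VisualField, shapes, rng=None, n_scales: int = 12,
               scales_per_octave: int = 5, class_label: str = "object",
               context_frac: float = 0.0) -> FodModel:
    """An initialized (untrained) model: components tile the field and
    template weights are arbitrary unit-norm values (or zero without a
    generator).  Foveal components of a shape share the central template,
    so the model is consistent with its own sliding-window baseline;
    training replaces the weights, calibration the scales and biases.
    """
    comps = init_components(list(shapes), field, shapes_in_cells=True)
    fov_w = []
    for p, k in shapes:
        w = np.zeros(p * k * F.N_CHANNELS) if rng is None else             rng.standard_normal(p * k * F.N_CHANNELS)
        n = np.linalg.norm(w)
        fov_w.append(w / n if n > 0 else w)
    for c in comps:
        src = fov_w[c.shape_id].reshape(-1, F.N_CHANNELS)
        if c.is_foveal:
            c.w_lda = (c.pooling.spatial @ src).ravel()
        else:
            w = np.zeros(c.n_regions * F.N_CHANNELS) if rng is None else                 rng.standard_normal(c.n_regions * F.N_CHANNELS)
            n = np.linalg.norm(w)
            c.w_lda = w / n if n > 0 else w
        c.alpha, c.beta = 1.0, 0.0
        c.group = c.shape_id if c.is_foveal else -1
    model = FodModel(field=field, components=comps, shapes=list(shapes),
                     class_label=class_label, n_scales=n_scales,
                     scales_per_octave=scales_per_octave,
                     context_frac=context_frac,
                     foveal_w_lda=fov_w,
                     foveal_alpha=[1.0] * len(shapes),
                     foveal_beta=[0.0] * len(shapes))
    model.compile()
    return model


def overlapping_components(model: FodModel, b_sigma, f_sigma) -> list[Component]:
    """Components admissible for box ``b_sigma`` at fixation ``f_sigma``.

    ``b_sigma`` is a (w, h, x, y) box in the scaled image; ``None`` (the
    null box) returns all components.  Admissibility requires IoU >= 0.7
    between the component's projected box and ``b_sigma``.
    """
    if b_sigma is None:
        return list(model.components)
    cell = model.field.config.cell_px
    fix_cell = snap_fixation_to_cell(f_sigma, cell)
    boxes = np.stack([c.image_box(fix_cell, cell) for c in model.components])
    ious = iou_matrix(np.asarray(b_sigma)[None, :], boxes)[0]
    return [c for c, v in zip(model.components, ious) if v >= IOU_ADMISSIBLE]


def score_all(model: FodModel, pyramid: F.FeaturePyramid, fixation_px,
              ledger: CostLedger | None = None, fixation_index: int = -1
              ) -> list[Detection]:
    """Evaluate every component at every scale for one fixation.

    Returns one Detection per (component, scale) whose projected box lies
    inside the scaled image, with boxes mapped back to original-image
    coordinates.  Deterministic; detections are ordered by scale then
    component id.
    """
    cell = model.field.config.cell_px
    dets: list[Detection] = []
    for sigma, fmap in pyramid:
        M, N, _ = fmap.array.shape
        f_sigma = (fixation_px[0] * sigma, fixation_px[1] * sigma)
        if not (0 <= f_sigma[0] < N * cell and 0 <= f_sigma[1] < M * cell):
            continue
        fr, fc = snap_fixation_to_cell(f_sigma, cell)
        for shape_id, (W, betas, anchors, nregs, ids) in model._by_shape().items():
            p, k = model.shapes[shape_id]
            if M < p or N < k:
                continue
            rows = anchors[:, 0] + fr
            cols = anchors[:, 1] + fc
            ok = (rows >= 0) & (rows <= M - p) & (cols >= 0) & (cols <= N - k)
            if not ok.any():
                continue
            windows = np.lib.stride_tricks.sliding_window_view(
                fmap.array, (p, k), axis=(0, 1))
            sel = windows[rows[ok], cols[ok]]          # (n, D, p, k)
            scores = np.einsum("ndpk,npkd->n", sel, W[ok]) + betas[ok]
            if ledger is not None:
                ledger.add(float(nregs[ok].sum()), "fod")
            for cid, r, c, s in zip(ids[ok], rows[ok], cols[ok], scores):
                box = model.report_box(
                    np.array([k * cell, p * cell, c * cell, r * cell]) / sigma)
                dets.append(Detection(box=box, score=float(s), sigma=sigma,
                                      component_id=int(cid), shape_id=shape_id,
                                      fixation_index=fixation_index))
    return dets


def score_box(model: FodModel, pyramid: F.FeaturePyramid, b, fixation_px,
              ledger: CostLedger | None = None):
    """Single-fixation detection score of box ``b`` (image coordinates).

    Maximizes the calibrated template response over scales and admissible
    components; ties break toward the lowest scale index, then the lowest
    component id.  Returns ``(score, sigma, component)`` or
    ``(None, None, None)`` when no admissible component is evaluable
    (an *uncovered* box, which contributes no evidence).
    """
    cell = model.field.config.cell_px
    best = (None, None, None)
    best_score = -np.inf
    b = np.asarray(model.expand_target(b), dtype=float)
    for sigma, fmap in pyramid:
        M, N, _ = fmap.array.shape
        f_sigma = (fixation_px[0] * sigma, fixation_px[1] * sigma)
        if not (0 <= f_sigma[0] < N * cell and 0 <= f_sigma[1] < M * cell):
            continue
        fix_cell = snap_fixation_to_cell(f_sigma, cell)
        b_sigma = b * sigma
        for comp in overlapping_components(model, b_sigma, f_sigma):
            r = fix_cell[0] + comp.anchor[0]
            c = fix_cell[1] + comp.anchor[1]
            p, k = comp.p_cells, comp.k_cells
            if not (0 <= r <= M - p and 0 <= c <= N - k):
                continue
            window = fmap.array[r:r + p, c:c + k]
            s = float((window * comp.w_eff).sum() + comp.beta)
            if ledger is not None:
                ledger.add(comp.n_regions, "fod")
            if s > best_score:
                best_score = s
                best = (s, sigma, comp)
    return best
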