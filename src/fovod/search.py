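"""Multi-fixation visual search: evidence integration and saccade control.

Per fixation the detector produces raw scores; the sigmoid of a score is
the posterior probability of target presence at that box given that
fixation, so under conditional independence across fixations the log
posterior ratio of a box is simply the *sum* of its per-fixation scores.
The maximum-a-posteriori (MAP) strategy saccades to the box center with
the highest accumulated score among locations not yet inhibited;
inhibition of return excludes a disc around every previous fixation from
re-selection (it does not alter the integrated scores used for the final
perceptual decision).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.special import expit

from .detector import Detection, FodModel, score_all
from .evaluation import CostLedger, nms


class NoCandidateError(RuntimeError):
    """All candidate locations are inhibited."""


def score_to_posterior(score) -> np.ndarray:
    """Sigmoid transfer from raw detection score to P(target | fixation)."""
    return expit(score)


@dataclass
class SearchConfig:
    """Saccade strategy and budget."""

    strategy: str = "MAP"             # "MAP" or "RAND"
    n_fixations: int = 5
    initial: str | tuple = "center"   # "center", "edge-left", "edge-right",
    #                                   or an explicit (x, y) in pixels
    ior_radius_deg: float = 2.0
    # guidance-only score reduction: each previous fixation lying inside a
    # candidate box lowers that box's priority for saccade selection (the
    # evidence there has already been collected); the final perceptual
    # decision uses the unmodified integrated scores
    ior_score_penalty: float = 2.0
    seed: int = 0
    nms_thresh: float = 0.5
    box_bin_px: float = 4.0           # accumulator quantization of box coords

    def __post_init__(self):
        if self.n_fixations < 1:
            raise ValueError("n_fixations must be >= 1")
        if self.strategy not in ("MAP", "RAND"):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    def initial_fixation(self, image_shape) -> tuple[float, float]:
        H, W = image_shape[:2]
        if isinstance(self.initial, str):
            frac = {"center": (0.5, 0.5), "edge-left": (0.1, 0.5),
                    "edge-right": (0.9, 0.5)}[self.initial]
            return (frac[0] * W, frac[1] * H)
        return tuple(self.initial)


@dataclass
class FixationState:
    """Fixation history and per-box accumulated log posterior ratios."""

    pixels_per_degree: float
    ior_radius_deg: float
    fixations: list = dc_field(default_factory=list)
    accumulator: dict = dc_field(default_factory=dict)  # key -> summed score
    boxes: dict = dc_field(default_factory=dict)        # key -> representative box
    _order: dict = dc_field(default_factory=dict)       # key -> creation rank
    _seen: dict = dc_field(default_factory=dict)        # key -> observation ids

    def box_key(self, box, bin_px: float = 4.0):
        """Canonical location key, tolerant of small scale/position jitter.

        Sizes are quantized in quarter octaves and positions relative to
        the box size, so that observations of the same physical location
        from different fixations and pyramid levels (foveal and
        peripheral components of slightly different geometry) fall into
        the same accumulator slot — which is what lets a later foveal
        look confirm or cancel earlier peripheral evidence.
        """
        w, h, x, y = box
        qw = round(4 * np.log2(max(w, 1e-6)))
        qh = round(4 * np.log2(max(h, 1e-6)))
        return (int(qw), int(qh),
                int(round((x + w / 2) / (0.25 * w))),
                int(round((y + h / 2) / (0.25 * h))))

    def integrate(self, detections, bin_px: float = 4.0):
        """Add one fixation's scores into the accumulator.

        Per fixation a box receives exactly one term: the maximum score
        over its admissible (scale, component) observations — scale and
        component are latent in the single-fixation score — so the
        accumulated value is the sum over fixations of per-fixation
        scores.  Boxes not covered at this fixation receive no term
        (posterior ratio 1, indifference).  An observation already
        integrated for a box at an earlier fixation (same component and
        scale, as happens when nearby fixations snap to the same cell at
        coarse pyramid levels) is not counted again: repeating the
        identical measurement carries no new evidence.
        """
        best: dict = {}
        batch_obs: dict = {}
        for d in detections:
            key = self.box_key(d.box, bin_px)
            obs = (d.component_id, round(float(d.sigma), 6))
            seen = self._seen.get(key, ())
            batch_obs.setdefault(key, set()).add(obs)
            if obs in seen:
                continue
            if key not in best or d.score > best[key][0]:
                best[key] = (d.score, d.box)
        for key, (score, box) in best.items():
            if key not in self.accumulator:
                self.accumulator[key] = 0.0
                self.boxes[key] = np.asarray(box, dtype=float)
                self._order[key] = len(self._order)
                self._seen[key] = set()
            self.accumulator[key] += score
        for key, obs_set in batch_obs.items():
            if key in self._seen:
                self._seen[key] |= obs_set

    def add_fixation(self, point):
        self.fixations.append(tuple(point))

    def _inhibited(self, point) -> bool:
        r_px = self.ior_radius_deg * self.pixels_per_degree
        return any(np.hypot(point[0] - fx, point[1] - fy) < r_px
                   for fx, fy in self.fixations)

    def uninhibited_candidates(self):
        """(key, center, accumulated score) of selectable boxes, in
        creation order."""
        out = []
        for key in sorted(self.accumulator, key=self._order.get):
            b = self.boxes[key]
            center = (b[2] + b[0] / 2, b[3] + b[1] / 2)
            if not self._inhibited(center):
                out.append((key, center, self.accumulator[key]))
        return out

    def final_detections(self, nms_thresh: float = 0.5):
        dets = [Detection(box=self.boxes[k], score=s, sigma=np.nan,
                          component_id=-1)
                for k, s in self.accumulator.items()]
        return nms(dets, nms_thresh)


def next_fixation_map(state: FixationState,
                      score_penalty: float = 0.0) -> tuple[float, float]:
    """Center of the uninhibited box with the highest posterior.

    The sigmoid is monotone, so the argmax of the posterior equals the
    argmax of the accumulated log posterior ratio.  With a nonzero
    ``score_penalty``, each previous fixation lying inside a candidate
    box reduces its selection score (inhibition of return on scores:
    already-foveated locations should not keep attracting the eye); the
    integrated scores themselves are untouched.  Ties break toward the
    earliest-created box.
    """
    cands = state.uninhibited_candidates()
    if not cands:
        raise NoCandidateError("every candidate location is inhibited")

    def _selection_score(key, score):
        if score_penalty == 0.0 or not state.fixations:
            return score
        w, h, x, y = state.boxes[key]
        inside = sum(1 for fx, fy in state.fixations
                     if x <= fx < x + w and y <= fy < y + h)
        return score - score_penalty * inside

    best = cands[0]
    best_s = _selection_score(best[0], best[2])
    for c in cands[1:]:
        s = _selection_score(c[0], c[2])
        if s > best_s:
            best, best_s = c, s
    return best[1]


def next_fixation_random(state: FixationState, rng: np.random.Generator,
                         image_shape=None) -> tuple[float, float]:
    """Unguided saccade: a uniform draw over uninhibited locations.

    With ``image_shape`` the draw is uniform over the uninhibited image
    area (rejection sampling), so the baseline carries no information
    about scene content or its spatial statistics; otherwise it falls
    back to a uniform draw over the distinct uninhibited candidate
    locations.  Seeded and reproducible.
    """
    if image_shape is not None:
        H, W = image_shape[:2]
        for _ in range(1000):
            p = (float(rng.uniform(0, W)), float(rng.uniform(0, H)))
            if not state._inhibited(p):
                return p
        raise NoCandidateError("every image location is inhibited")
    cands = state.uninhibited_candidates()
    if not cands:
        raise NoCandidateError("every candidate location is inhibited")
    return cands[int(rng.integers(len(cands)))][1]


def trace_table(trace):
    """Per-fixation trace (point, cumulative cost) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(trace, columns=["index", "x", "y", "cumulative_ops"])


def plot_search(image, detections, trace, ax=None, max_boxes: int = 3):
    """Overlay the fixation sequence and the final boxes on the image."""
    import matplotlib.pyplot as plt
    from matplotlib import patches

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image, cmap="gray", vmin=0, vmax=1)
    for d in detections[:max_boxes]:
        w, h, x, y = d.box
        ax.add_patch(patches.Rectangle((x, y), w, h, fill=False,
                                       edgecolor="lime", lw=2))
    xs = [t["x"] for t in trace]
    ys = [t["y"] for t in trace]
    ax.plot(xs, ys, "y.-", markersize=10)
    for i, (x, y) in enumerate(zip(xs, ys)):
        ax.annotate(str(i + 1), (x, y), color="yellow", fontsize=12,
                    xytext=(4, -4), textcoords="offset points")
    ax.set_axis_off()
    return ax


def run_search(model: FodModel, image=None, config: SearchConfig | None = None,
               pyramid=None, ledger: CostLedger | None = None):
    """Execute a multi-fixation search on one image.

    Returns ``(detections, trace)``: the non-maxima-suppressed integrated
    detections and a per-fixation trace (fixation point, cumulative
    operation count).  Stops early if every candidate is inhibited.
    """
    config = config or SearchConfig()
    if pyramid is None:
        pyramid = model.pyramid_of(image)
    cell = model.field.config.cell_px
    if image is not None:
        shape = image.shape
    else:
        _, f0 = pyramid.levels[0]
        shape = (f0.array.shape[0] * cell, f0.array.shape[1] * cell)
    rng = np.random.default_rng(config.seed)
    state = FixationState(
        pixels_per_degree=model.field.config.pixels_per_degree,
        ior_radius_deg=config.ior_radius_deg)
    ledger = ledger if ledger is not None else CostLedger()
    fix = config.initial_fixation(shape)
    trace = []
    for m in range(config.n_fixations):
        dets = score_all(model, pyramid, fix, ledger=ledger, fixation_index=m)
        state.add_fixation(fix)
        state.integrate(dets, config.box_bin_px)
        trace.append({"index": m, "x": fix[0], "y": fix[1],
                      "cumulative_ops": ledger.ops})
        if m + 1 < config.n_fixations:
            try:
                if config.strategy == "MAP":
                    fix = next_fixation_map(state, config.ior_score_penalty)
                else:
                    fix = next_fixation_random(state, rng, shape)
            except NoCandidateError:
                break
            # clamp to image bounds
            fix = (float(np.clip(fix[0], 0, shape[1] - 1)),
                   float(np.clip(fix[1], 0, shape[0] - 1)))
    return state.final_detections(config.nms_thresh), trace
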