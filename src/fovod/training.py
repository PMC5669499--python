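"""Latent-LDA training of retino-specific templates.

Each template direction is the LDA solution ``Sigma_t^{-1} (mu_pos -
mu_neg)`` for its own pooled feature space.  Foveal statistics are
estimated once from background images as a *stationary* spatial
autocovariance of HoG cell features; covariances (and means) for
peripheral templates are obtained by pushing the foveal statistics
through the pooling transform, so no per-template estimation and no
hard-negative mining is needed.  A final convex calibration jointly fits
a per-template scale ``alpha_t`` and bias ``beta_t`` under a hinge-loss
objective with latent scale/component/fixation assignments for the
positives (coordinate descent: alternate latent assignment and convex
optimization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import linalg
from skimage.transform import resize

from . import features as F
from .detector import Component, FodModel, init_components
from .evaluation import iou
from .visual_field import VisualField, pooling_matrix

D = F.N_CHANNELS


class CovarianceError(RuntimeError):
    """Raised when the regularized covariance is not positive definite."""


class TrainingError(RuntimeError):
    """Raised when the coordinate-descent contract is violated."""


# ---------------------------------------------------------------------------
# global stationary statistics


@dataclass
class LdaStats:
    """Stationary background model of HoG cell features.

    ``gamma[dy + max_dy, dx + max_dx]`` holds the D x D cross-covariance
    between a cell and the cell offset by (dy, dx); ``mu`` the mean cell
    feature.  Covariance matrices for any template extent up to
    (max_dy + 1) x (max_dx + 1) cells follow by block-Toeplitz assembly.
    """

    mu: np.ndarray                    # (D,)
    gamma: np.ndarray                 # (2*max_dy+1, 2*max_dx+1, D, D)
    max_dy: int
    max_dx: int
    n_samples: int
    ridge_frac: float = 0.01

    def ridge(self) -> float:
        d = self.gamma.shape[-1]
        return self.ridge_frac * float(np.trace(self.gamma[self.max_dy,
                                                           self.max_dx]) / d)

    def build_cov(self, p: int, k: int, ridge: float | None = None,
                  check: bool = True) -> np.ndarray:
        """(p*k*D)^2 covariance for a p x k-cell template, regularized."""
        if p > self.max_dy + 1 or k > self.max_dx + 1:
            raise ValueError("template extent exceeds estimated offsets")
        d = self.gamma.shape[-1]
        n = p * k
        sig = np.empty((n, d, n, d))
        cells = [(r, c) for r in range(p) for c in range(k)]
        for i, (r1, c1) in enumerate(cells):
            for j, (r2, c2) in enumerate(cells):
                sig[i, :, j, :] = self.gamma[r2 - r1 + self.max_dy,
                                             c2 - c1 + self.max_dx]
        sig = sig.reshape(n * d, n * d)
        sig = 0.5 * (sig + sig.T)
        lam = self.ridge() if ridge is None else ridge
        sig[np.diag_indices_from(sig)] += lam
        if check:
            try:
                linalg.cholesky(sig, lower=True)
            except linalg.LinAlgError as e:
                raise CovarianceError(
                    f"covariance for {p}x{k} template not positive definite "
                    f"(ridge={lam:.3g}); more background samples or a larger "
                    f"ridge are needed") from e
        return sig

    def mean_cells(self, p: int, k: int) -> np.ndarray:
        """Stationary mean tiled over a p x k-cell template."""
        return np.broadcast_to(self.mu, (p, k, self.mu.size)).copy()


def stats_from_feature_maps(maps, max_extent: tuple[int, int],
                            ridge_frac: float = 0.01) -> LdaStats:
    """Estimate stationary mean and autocovariance from cell-feature maps.

    ``maps`` is an iterable of (M, N, D) arrays; offsets are estimated up
    to ``max_extent = (p, k)`` cells.  Uses the symmetry
    Gamma(-dy, -dx) = Gamma(dy, dx)^T.
    """
    maps = [np.asarray(m, dtype=float) for m in maps]
    d = maps[0].shape[2]
    n_cells = sum(m.shape[0] * m.shape[1] for m in maps)
    if n_cells < 100:
        raise ValueError(f"need >= 100 background cell samples, got {n_cells}")
    mu = (sum(m.sum(axis=(0, 1)) for m in maps) / n_cells)
    p, k = max_extent
    # biased (zero-padded) autocovariance of centered features: every
    # offset shares the lag-0 divisor, which makes the assembled
    # block-Toeplitz covariance positive semidefinite by construction
    centered = [m - mu for m in maps]
    gamma = np.zeros((2 * p - 1, 2 * k - 1, d, d))
    for dy in range(p):
        for dx in range(-(k - 1), k):
            if dy == 0 and dx < 0:
                continue
            acc = np.zeros((d, d))
            for m in centered:
                M, N, _ = m.shape
                if dy >= M or abs(dx) >= N:
                    continue
                if dx >= 0:
                    a = m[:M - dy, :N - dx].reshape(-1, d)
                    b = m[dy:, dx:].reshape(-1, d)
                else:
                    a = m[:M - dy, -dx:].reshape(-1, d)
                    b = m[dy:, :N + dx].reshape(-1, d)
                acc += a.T @ b
            g = acc / n_cells
            gamma[dy + p - 1, dx + k - 1] = g
            gamma[p - 1 - dy, k - 1 - dx] = g.T
    return LdaStats(mu=mu, gamma=gamma, max_dy=p - 1, max_dx=k - 1,
                    n_samples=n_cells, ridge_frac=ridge_frac)


def estimate_global_stats(backgrounds, max_extent: tuple[int, int],
                          cell_px: int = 8, ridge_frac: float = 0.01
                          ) -> LdaStats:
    """Stationary HoG statistics from background raster images."""
    maps = [F.compute_hog(img, cell_px).array for img in backgrounds]
    return stats_from_feature_maps(maps, max_extent, ridge_frac)


def lda_template(cov: np.ndarray, mu_pos: np.ndarray, mu_neg: np.ndarray,
                 normalize: bool = False) -> np.ndarray:
    """Solve ``cov @ w = mu_pos - mu_neg`` (never explicit inversion).

    With ``normalize`` the direction is rescaled to unit norm: the length
    of an LDA discriminant is arbitrary and is absorbed by the per-
    template affine calibration, which keeps the calibration objective
    well-scaled.
    """
    diff = (np.asarray(mu_pos) - np.asarray(mu_neg)).ravel()
    try:
        w = linalg.solve(cov, diff, assume_a="pos")
    except linalg.LinAlgError as e:
        raise CovarianceError(
            f"LDA system unsolvable; condition number "
            f"{np.linalg.cond(cov):.3g}") from e
    if normalize:
        n = np.linalg.norm(w)
        if n > 0:
            w = w / n
    return w


def pooled_stats(stats: LdaStats, component: Component, field: VisualField,
                 cov_fov: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """(Sigma_t, mu_t_neg) of a component via the pooling transform.

    Sigma_t = P Sigma_fov P^T (+ ridge), mu_t_neg = P mu_fov_neg, where P
    is the component's pooling operator.
    """
    p, k = component.p_cells, component.k_cells
    if cov_fov is None:
        cov_fov = stats.build_cov(p, k)
    P = component.pooling.spatial.toarray()
    n = p * k
    sig4 = cov_fov.reshape(n, D, n, D)
    t1 = np.tensordot(P, sig4, axes=(1, 0))          # (nreg, D, n, D)
    sig_t = np.tensordot(t1, P, axes=([2], [1]))     # (nreg, D, D, nreg)
    sig_t = sig_t.transpose(0, 1, 3, 2).reshape(P.shape[0] * D, P.shape[0] * D)
    sig_t = 0.5 * (sig_t + sig_t.T)
    sig_t[np.diag_indices_from(sig_t)] += stats.ridge()
    mu_neg = P @ stats.mean_cells(p, k).reshape(n, D)
    return sig_t, mu_neg


# ---------------------------------------------------------------------------
# training configuration and orchestration


@dataclass
class TrainConfig:
    """Knobs of the latent-LDA trainer."""

    C: float = 1.0                    # hinge weight of the calibration
    #                                   objective; O(1) is the natural scale
    #                                   for unit-norm LDA directions
    ridge_frac: float = 0.01          # covariance ridge, fraction of mean diag
    outer_iters: int = 5
    inner_iters: int = 200
    inner_step: float = 0.5
    tol: float = 1e-3                 # relative objective change to stop
    n_scales: int = 12
    scales_per_octave: int = 5
    n_shapes: int = 2
    target_template_px: float = 80.0  # template long-side budget in pixels
    context_frac: float = 0.15        # background context per side, fraction
    #                                   of object size (templates model the
    #                                   object plus a surrounding ring)
    min_shape_cells: int = 3
    max_shape_cells: int = 11
    seed: int = 0


def cluster_shapes(boxes, config: TrainConfig, cell_px: int = 8
                   ) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Viewpoint clustering of training boxes into template shapes.

    k-means (k = n_shapes) on log aspect ratio, seeded; each cluster's
    geometric-mean box is rescaled to the template pixel budget and
    snapped to whole cells.  Returns shapes as (p, k) cells and the
    cluster label of every box.
    """
    boxes = np.asarray(boxes, dtype=float)
    la = np.log(boxes[:, 0] / boxes[:, 1])          # log(w / h)
    rng = np.random.default_rng(config.seed)
    k = min(config.n_shapes, len(np.unique(np.round(la, 6))))
    centers = np.sort(rng.choice(np.unique(la), size=k, replace=False))
    labels = np.zeros(len(la), dtype=int)
    for _ in range(50):
        labels = np.argmin(np.abs(la[:, None] - centers[None, :]), axis=1)
        new = np.array([la[labels == j].mean() if (labels == j).any()
                        else centers[j] for j in range(k)])
        if np.allclose(new, centers):
            break
        centers = new
    shapes = []
    pad = 1.0 + 2.0 * config.context_frac
    for j in range(k):
        sel = boxes[labels == j]
        if len(sel) == 0:
            continue
        gw = np.exp(np.log(sel[:, 0]).mean()) * pad
        gh = np.exp(np.log(sel[:, 1]).mean()) * pad
        s0 = min(1.0, config.target_template_px / max(gw, gh))
        pk = []
        for dim in (gh, gw):
            pk.append(int(np.clip(round(dim * s0 / cell_px),
                                  config.min_shape_cells,
                                  config.max_shape_cells)))
        shapes.append((pk[0], pk[1]))
    return shapes, labels


def expand_box(box, frac: float):
    """Grow a (w, h, x, y) box by ``frac`` of its size on every side."""
    w, h, x, y = box
    return (w * (1 + 2 * frac), h * (1 + 2 * frac),
            x - frac * w, y - frac * h)


def shrink_box(box, frac: float):
    """Inverse of :func:`expand_box`."""
    w, h, x, y = box
    s = 1 + 2 * frac
    return np.array([w / s, h / s, x + frac * w / s, y + frac * h / s])


def warped_positive_mean(positives, labels, shapes, cell_px: int = 8,
                         context_frac: float = 0.0
                         ) -> list[np.ndarray | None]:
    """Mean HoG of positives anisotropically warped to each shape's box.

    Each crop includes ``context_frac`` of surrounding background per
    side; the context ring makes templates reject partial object views.
    """
    out = []
    for s, (p, k) in enumerate(shapes):
        feats = []
        for (img, box), lab in zip(positives, labels):
            if lab != s:
                continue
            w, h, x, y = expand_box(box, context_frac)
            w, h, x, y = [int(round(v)) for v in (w, h, x, y)]
            H, W = img.shape[:2]
            padn = max(0, -x, -y, x + w - W, y + h - H)
            im = np.pad(img, padn, mode="edge") if padn else img
            crop = im[y + padn:y + padn + h, x + padn:x + padn + w]
            if crop.shape[0] < 2 or crop.shape[1] < 2:
                continue
            warped = resize(crop, (p * cell_px, k * cell_px), order=1,
                            anti_aliasing=True, preserve_range=True)
            feats.append(F.compute_hog(warped, cell_px).array)
        out.append(np.mean(feats, axis=0) if feats else None)
    return out


@dataclass
class _LatentCache:
    """Aligned-placement score candidates of the positive examples."""

    pos_index: np.ndarray       # candidate -> positive example index
    tmpl_index: np.ndarray      # candidate -> template index
    r: np.ndarray               # raw (uncalibrated) LDA score
    sigma: np.ndarray
    fix: np.ndarray             # (n, 2) fixation (x, y), original image px
    slices: list[slice]         # per-positive contiguous slice


def _raw_templates(model: FodModel):
    """Per-component uncalibrated cell-space templates, stacked per shape."""
    by_shape = {}
    for c in model.components:
        w = c.w_lda.reshape(c.n_regions, D)
        eff = (c.pooling.spatial.T @ w).reshape(c.p_cells, c.k_cells, D)
        by_shape.setdefault(c.shape_id, []).append((c, eff))
    return by_shape


def build_latent_cache(model: FodModel, positives, config: TrainConfig
                       ) -> tuple[_LatentCache, np.ndarray, list]:
    """Enumerate feasible aligned placements and raw scores per positive.

    For every scale and every component, the candidate fixation aligns
    the component's box center with the example box center (snapped to
    the cell grid); the candidate survives if the fixation falls inside
    the scaled image and the projected box has IoU >= 0.7 with the scaled
    example box.  Central foveal templates (one per shape, template
    indices 0..n_shapes-1) are aligned the same way.
    """
    cell = model.field.config.cell_px
    n_shapes = len(model.shapes)
    raw_by_shape = _raw_templates(model)
    fov_raw = [model.foveal_w_lda[s].reshape(model.shapes[s][0],
                                             model.shapes[s][1], D)
               for s in range(n_shapes)]
    comp_tmpl_index = {c.id: n_shapes + i
                       for i, c in enumerate(model.components)}

    pi, ti, rs, sg, fx = [], [], [], [], []
    slices = []
    for i, (img, box) in enumerate(positives):
        start = len(rs)
        pyr = model.pyramid_of(img)
        b = np.asarray(expand_box(box, model.context_frac), dtype=float)
        for sigma, fmap in pyr:
            M, N, _ = fmap.array.shape
            bs = b * sigma
            xc, yc = bs[2] + bs[0] / 2, bs[3] + bs[1] / 2
            for shape_id in range(n_shapes):
                p, k = model.shapes[shape_id]
                r0 = int(round(yc / cell - p / 2))
                c0 = int(round(xc / cell - k / 2))
                if not (0 <= r0 <= M - p and 0 <= c0 <= N - k):
                    continue
                proj = (k * cell, p * cell, c0 * cell, r0 * cell)
                if iou(proj, bs) < 0.7:
                    continue
                window = fmap.array[r0:r0 + p, c0:c0 + k]
                # central foveal template: fixation at the box center
                pi.append(i)
                ti.append(shape_id)
                rs.append(float((window * fov_raw[shape_id]).sum()))
                sg.append(sigma)
                fx.append((xc / sigma, yc / sigma))
                for comp, eff in raw_by_shape.get(shape_id, []):
                    fr = r0 - comp.anchor[0]
                    fc = c0 - comp.anchor[1]
                    fpx = ((fc + 0.5) * cell, (fr + 0.5) * cell)
                    if not (0 <= fpx[0] < N * cell and 0 <= fpx[1] < M * cell):
                        continue
                    pi.append(i)
                    ti.append(comp_tmpl_index[comp.id])
                    rs.append(float((window * eff).sum()))
                    sg.append(sigma)
                    fx.append((fpx[0] / sigma, fpx[1] / sigma))
        slices.append(slice(start, len(rs)))
    cache = _LatentCache(pos_index=np.array(pi, dtype=int),
                         tmpl_index=np.array(ti, dtype=int),
                         r=np.array(rs), sigma=np.array(sg),
                         fix=np.array(fx).reshape(-1, 2), slices=slices)
    covered = np.array([sl.stop > sl.start for sl in slices])
    return cache, covered, list(raw_by_shape)


def _group_objectives(a, b, C, cw_neg, t_group, t_norm2, t_m,
                      pos_group, pos_r, n_groups):
    """Per-group objective contributions (the problem is separable).

    ``cw_neg`` weights each template's negative-mean hinge so that the
    total negative weight of a group balances its positive hinge count
    (class balance: one background-mean constraint faces many feasible-
    fixation positive terms).
    """
    reg = 0.5 * np.bincount(t_group, weights=a[t_group] ** 2 * t_norm2
                            + b[t_group] ** 2, minlength=n_groups)
    neg = np.bincount(t_group, weights=cw_neg * np.maximum(
        0, 1 + a[t_group] * t_m + b[t_group]), minlength=n_groups)
    pos = C * np.bincount(pos_group, weights=np.maximum(
        0, 1 - (a[pos_group] * pos_r + b[pos_group])), minlength=n_groups)
    return reg + neg + pos


def _inner_solve(a, b, C, cw_neg, t_group, t_norm2, t_m, pos_group, pos_r,
                 n_groups, iters, step0):
    """Projected subgradient descent on the convex (alpha, beta) problem.

    The objective is separable across calibration groups, so steps are
    normalized and the best iterate is tracked per group; the returned
    objective never exceeds the starting one.  Alpha is projected onto
    [0, inf): the calibration rescales the discriminant, it must not
    invert it.
    """
    best_obj = _group_objectives(a, b, C, cw_neg, t_group, t_norm2, t_m,
                                 pos_group, pos_r, n_groups)
    best_a, best_b = a.copy(), b.copy()
    for it in range(1, iters + 1):
        ga = np.bincount(t_group, weights=a[t_group] * t_norm2,
                         minlength=n_groups)
        gb = np.bincount(t_group, weights=b[t_group], minlength=n_groups)
        neg_active = (1 + a[t_group] * t_m + b[t_group]) > 0
        ga += np.bincount(t_group[neg_active],
                          weights=(cw_neg * t_m)[neg_active],
                          minlength=n_groups)
        gb += np.bincount(t_group[neg_active], weights=cw_neg[neg_active],
                          minlength=n_groups)
        pos_active = (1 - (a[pos_group] * pos_r + b[pos_group])) > 0
        ga -= C * np.bincount(pos_group[pos_active],
                              weights=pos_r[pos_active], minlength=n_groups)
        gb -= C * np.bincount(pos_group[pos_active], minlength=n_groups)
        gn = np.sqrt(ga ** 2 + gb ** 2) + 1e-12
        eta = step0 / np.sqrt(it)
        a = np.maximum(a - eta * ga / gn, 0.0)
        b = b - eta * gb / gn
        obj = _group_objectives(a, b, C, cw_neg, t_group, t_norm2, t_m,
                                pos_group, pos_r, n_groups)
        improved = obj < best_obj
        best_obj[improved] = obj[improved]
        best_a[improved] = a[improved]
        best_b[improved] = b[improved]
    return float(best_obj.sum()), best_a, best_b


def calibrate(model: FodModel, positives, stats: LdaStats,
              config: TrainConfig) -> FodModel:
    """Latent-LDA calibration of per-template scale and bias.

    Coordinate descent alternating (i) latent assignment of each positive
    to its best (scale, component, fixation) with the calibration fixed
    and (ii) convex optimization of all (alpha_t, beta_t) with the
    latents fixed.  The objective is non-increasing across outer
    iterations by construction; a violation raises ``TrainingError``.
    Calibration parameters are shared among fully foveal components of a
    shape (their LDA directions are identical), which also makes the
    sliding-window baseline use exactly the same calibrated foveal
    templates.
    """
    n_shapes = len(model.shapes)
    cache, covered, _ = build_latent_cache(model, positives, config)
    if not covered.all():
        warnings.warn(f"{(~covered).sum()} positive example(s) have no "
                      "feasible fixation and were dropped")

    # one hinge term per (positive, template): the example must be
    # detected from every feasible fixation, and each feasible fixation
    # selects its admissible template; the scale sigma stays latent
    pair_key = cache.pos_index.astype(np.int64) * (len(model.components)
                                                   + n_shapes) \
        + cache.tmpl_index
    order = np.argsort(pair_key, kind="stable")
    uniq, starts = np.unique(pair_key[order], return_index=True)
    r_sorted = cache.r[order]
    bounds = np.append(starts, len(order))
    pair_tmpl = (uniq % (len(model.components) + n_shapes)).astype(int)
    r_max = np.array([r_sorted[bounds[i]:bounds[i + 1]].max()
                      for i in range(len(uniq))])
    r_min = np.array([r_sorted[bounds[i]:bounds[i + 1]].min()
                      for i in range(len(uniq))])

    # template table: centrals first (template index == shape id), then comps
    t_group, t_norm2, t_m = [], [], []
    for s in range(n_shapes):
        p, k = model.shapes[s]
        t_group.append(s)
        t_norm2.append(float(model.foveal_w_lda[s] @ model.foveal_w_lda[s]))
        t_m.append(float(model.foveal_w_lda[s]
                         @ stats.mean_cells(p, k).ravel()))
    next_group = n_shapes
    for c in model.components:
        if c.is_foveal:
            c.group = c.shape_id
        else:
            c.group = next_group
            next_group += 1
        t_group.append(c.group)
        t_norm2.append(float(c.w_lda @ c.w_lda))
        mu_neg = np.broadcast_to(stats.mu, (c.n_regions, D)).ravel()
        t_m.append(float(c.w_lda @ mu_neg))
    t_group = np.array(t_group, dtype=int)
    t_norm2 = np.array(t_norm2)
    t_m = np.array(t_m)
    n_groups = next_group

    # init: unit scale, midpoint bias per group (LDA bias of its first template)
    a = np.ones(n_groups)
    b = np.zeros(n_groups)
    first = {}
    for idx, g in enumerate(t_group):
        first.setdefault(int(g), idx)
    # midpoint bias uses the raw positive scores actually observed
    for g, idx in first.items():
        sel = cache.tmpl_index == idx
        if sel.any():
            b[g] = -0.5 * (cache.r[sel].mean() + t_m[idx])
        else:
            b[g] = -t_m[idx]

    trace = []
    prev = np.inf
    pos_group = t_group[pair_tmpl]
    # class balance: each group's single background-mean hinge carries
    # the same total weight as its positive hinge terms
    n_pos_g = np.bincount(pos_group, minlength=n_groups).astype(float)
    n_tmpl_g = np.bincount(t_group, minlength=n_groups).astype(float)
    cw_neg = config.C * (np.maximum(n_pos_g, 1.0)
                         / np.maximum(n_tmpl_g, 1.0))[t_group]
    for outer in range(config.outer_iters):
        # (i) latent scale assignment with calibration fixed: the best
        # sigma maximizes alpha * r, i.e. r_max for alpha >= 0
        pos_r = np.where(a[pos_group] >= 0, r_max, r_min)

        # (ii) convex calibration with latents fixed
        obj, a, b = _inner_solve(a, b, config.C, cw_neg, t_group, t_norm2,
                                 t_m, pos_group, pos_r, n_groups,
                                 config.inner_iters, config.inner_step)
        trace.append(obj)
        if obj > prev * (1 + 1e-8) + 1e-12:
            raise TrainingError(
                f"objective increased across outer iterations "
                f"({prev:.6g} -> {obj:.6g})")
        if prev < np.inf and abs(prev - obj) <= config.tol * max(abs(prev), 1e-12):
            prev = obj
            break
        prev = obj

    for s in range(n_shapes):
        model.foveal_alpha[s] = float(a[s])
        model.foveal_beta[s] = float(b[s])
    for c in model.components:
        c.alpha = float(a[c.group])
        c.beta = float(b[c.group])
    model.meta["objective_trace"] = trace
    model.compile()
    return model


def assign_latents(model: FodModel, image, box, config: TrainConfig | None = None):
    """Best (sigma, component, fixation) for a positive example.

    Maximizes the calibrated detection score over the enumerated feasible
    fixations; returns ``None`` if the example is uncovered.  Component
    ``None`` denotes the central foveal template of a shape.
    """
    config = config or TrainConfig(n_scales=model.n_scales,
                                   scales_per_octave=model.scales_per_octave)
    cache, covered, _ = build_latent_cache(model, [(image, box)], config)
    if not covered[0]:
        return None
    n_shapes = len(model.shapes)
    alphas = np.array([model.foveal_alpha[s] for s in range(n_shapes)]
                      + [c.alpha for c in model.components])
    betas = np.array([model.foveal_beta[s] for s in range(n_shapes)]
                     + [c.beta for c in model.components])
    s = alphas[cache.tmpl_index] * cache.r + betas[cache.tmpl_index]
    j = int(np.argmax(s))
    ti = int(cache.tmpl_index[j])
    comp = None if ti < n_shapes else model.components[ti - n_shapes]
    return float(cache.sigma[j]), comp, tuple(cache.fix[j])


def train_fod(positives, negatives, field: VisualField,
              config: TrainConfig | None = None,
              class_label: str = "object") -> FodModel:
    """Full training pipeline for one object class.

    ``positives`` is a list of (image, (w, h, x, y) box); ``negatives``
    a list of background images (examples with the null box).  Steps:
    viewpoint clustering, component initialization over the field,
    stationary covariance estimation, per-template LDA via the pooling
    transform, and latent-LDA calibration.
    """
    config = config or TrainConfig()
    if not positives or not negatives:
        raise ValueError("need at least one positive and one negative")
    cell = field.config.cell_px
    boxes = np.array([np.asarray(b, dtype=float)[:2] for _, b in positives])
    shapes, labels = cluster_shapes(boxes, config, cell)

    comps = init_components(shapes, field, shapes_in_cells=True)
    pmax = max(p for p, _ in shapes)
    kmax = max(k for _, k in shapes)
    stats = estimate_global_stats(negatives, (pmax, kmax), cell,
                                  config.ridge_frac)

    mu_pos = warped_positive_mean(positives, labels, shapes, cell,
                                  config.context_frac)
    fov_w, cov_cache = [], {}
    for s, (p, k) in enumerate(shapes):
        if mu_pos[s] is None:
            raise ValueError(f"no usable positives for shape {shapes[s]}")
        cov = stats.build_cov(p, k)
        cov_cache[(p, k)] = cov
        fov_w.append(lda_template(cov, mu_pos[s].ravel(),
                                  stats.mean_cells(p, k).ravel(),
                                  normalize=True))

    for c in comps:
        p, k = c.p_cells, c.k_cells
        P = c.pooling.spatial
        if c.is_foveal:
            # identity/permutation pooling: the foveal solution, permuted
            c.w_lda = (P @ fov_w[c.shape_id].reshape(p * k, D)).ravel()
        else:
            sig_t, mu_neg_t = pooled_stats(stats, c, field, cov_cache[(p, k)])
            mu_pos_t = P @ mu_pos[c.shape_id].reshape(p * k, D)
            c.w_lda = lda_template(sig_t, mu_pos_t.ravel(), mu_neg_t.ravel(),
                                   normalize=True)

    model = FodModel(field=field, components=comps, shapes=shapes,
                     class_label=class_label, n_scales=config.n_scales,
                     scales_per_octave=config.scales_per_octave,
                     context_frac=config.context_frac,
                     foveal_w_lda=fov_w,
                     foveal_alpha=[1.0] * len(shapes),
                     foveal_beta=[0.0] * len(shapes),
                     meta={"seed": config.seed, "C": config.C,
                           "n_positives": len(positives),
                           "n_negatives": len(negatives)})
    model = calibrate(model, positives, stats, config)
    return model
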