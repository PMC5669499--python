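"""Bottom-up saliency via iso-orientation surround suppression.

Gabor energy (4 scales x 8 orientations by default) is pooled into cells;
a cell's response at an orientation is suppressed by the pooled response
of its neighbours at the *same* orientation, so homogeneous oriented
texture cancels and orientation contrast pops out.  The non-foveated
model suppresses every full-resolution cell by its 8 nearest neighbours;
the foveated model computes the identical quantity inside the fovea but
pools the periphery through the visual-field regions, each suppressed by
its 4 nearest neighbouring regions, and explores the image with
max-saliency saccades under inhibition of return.  The cost of a model
is its number of suppression operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

from .visual_field import VisualField, pool_features, snap_fixation_to_cell


@dataclass
class GaborBank:
    """Quadrature Gabor filters over scales x orientations."""

    kernels: list                      # complex 2-D arrays
    n_scales: int
    n_orientations: int
    wavelengths: tuple

    @property
    def margin_px(self) -> int:
        """Half-extent of the largest kernel: cells closer than this to
        the image border have incomplete receptive fields."""
        return max(max(k.shape) for k in self.kernels) // 2


def make_gabor_bank(n_scales: int = 4, n_orientations: int = 8,
                    base_wavelength: float = 4.0) -> GaborBank:
    """Bank with wavelengths one octave apart and 1-octave bandwidth."""
    kernels = []
    wavelengths = tuple(base_wavelength * 2 ** s for s in range(n_scales))
    for lam in wavelengths:
        for o in range(n_orientations):
            theta = np.pi * o / n_orientations
            k = gabor_kernel(frequency=1.0 / lam, theta=theta, bandwidth=1.0)
            k = k - k.mean()           # exactly zero-mean (offset invariance)
            kernels.append(k)
    return GaborBank(kernels=kernels, n_scales=n_scales,
                     n_orientations=n_orientations, wavelengths=wavelengths)


def orientation_energy(image: np.ndarray, bank: GaborBank) -> np.ndarray:
    """(H, W, n_orientations) Gabor energy summed over scales."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    H, W = img.shape
    out = np.zeros((H, W, bank.n_orientations))
    for i, k in enumerate(bank.kernels):
        if min(k.shape) > min(H, W):
            raise ValueError("image smaller than the largest Gabor filter")
        o = i % bank.n_orientations
        resp = fftconvolve(img, k, mode="same")
        out[:, :, o] += np.abs(resp) ** 2
    return out


def cell_responses(energy: np.ndarray, cell_px: int = 8,
                   margin_px: int = 0) -> np.ndarray:
    """Sum-pool per-pixel orientation energy into cells.

    Cells within ``margin_px`` of the image border (incomplete receptive
    fields, convolution boundary artifacts) are set to NaN and excluded
    from every downstream saliency computation.
    """
    H, W, O = energy.shape
    n_r, n_c = H // cell_px, W // cell_px
    e = energy[:n_r * cell_px, :n_c * cell_px]
    out = e.reshape(n_r, cell_px, n_c, cell_px, O).sum(axis=(1, 3))
    if margin_px > 0:
        m = int(np.ceil(margin_px / cell_px))
        out[:m] = np.nan
        out[-m:] = np.nan
        out[:, :m] = np.nan
        out[:, -m:] = np.nan
    return out


_RING8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float) / 8.0


@dataclass
class SaliencyCellMap:
    """Per-cell (or per-region) saliency after iso-orientation suppression."""

    saliency: np.ndarray               # cells: (n_r, n_c); regions: (n_regions,)
    suppressed: np.ndarray             # same leading shape + orientation axis
    n_ops: int
    cell_px: int = 8

    def top_location_px(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.nanargmax(self.saliency),
                                self.saliency.shape)
        return ((j + 0.5) * self.cell_px, (i + 0.5) * self.cell_px)


def saliency_nonfoveated(image: np.ndarray, bank: GaborBank,
                         cell_px: int = 8, combine: str = "max",
                         _cells: np.ndarray | None = None) -> SaliencyCellMap:
    """Full-resolution saliency: 8-neighbour same-orientation suppression."""
    R = cell_responses(orientation_energy(image, bank), cell_px,
                       bank.margin_px) if _cells is None else _cells
    nb = np.stack([ndimage.convolve(R[:, :, o], _RING8, mode="nearest")
                   for o in range(R.shape[2])], axis=2)
    sup = R - nb
    with np.errstate(invalid="ignore"):
        sal = (np.nanmax(sup, axis=2) if combine == "max"
               else np.nansum(sup, axis=2))
        sal[np.isnan(sup).all(axis=2)] = np.nan
    n_ops = int((~np.isnan(sup).any(axis=2)).sum())
    return SaliencyCellMap(saliency=sal, suppressed=sup,
                           n_ops=n_ops, cell_px=cell_px)


def _region_neighbours(field: VisualField, k: int = 4) -> np.ndarray:
    """Indices of the k nearest other regions of every region."""
    c = field.region_centers_px()
    d = np.hypot(c[:, 0:1] - c[None, :, 0], c[:, 1:2] - c[None, :, 1])
    np.fill_diagonal(d, np.inf)
    return np.argsort(d, axis=1)[:, :k]


def saliency_foveated_step(image: np.ndarray, bank: GaborBank,
                           field: VisualField, fixation_px,
                           combine: str = "max",
                           _cells: np.ndarray | None = None,
                           _nonfov: SaliencyCellMap | None = None,
                           _neighbours: np.ndarray | None = None):
    """One fixation of the foveated saliency model.

    Foveal cells reproduce the full-resolution 8-neighbour suppression
    exactly; peripheral regions pool orientation energy through the
    visual field and are suppressed by the mean of their 4 nearest
    neighbouring regions.  Returns ``(region_map, valid)``.
    """
    cell_px = field.config.cell_px
    R = cell_responses(orientation_energy(image, bank), cell_px,
                       bank.margin_px) if _cells is None else _cells
    nonfov = _nonfov if _nonfov is not None else \
        saliency_nonfoveated(image, bank, cell_px, combine, _cells=R)
    pooled, valid = pool_features(field, R, fixation_px)
    nbrs = _neighbours if _neighbours is not None else _region_neighbours(field)

    n_reg, O = pooled.shape
    sup = np.full((n_reg, O), np.nan)
    fr, fc = snap_fixation_to_cell(fixation_px, cell_px)
    n_ops = 0
    for rid in range(n_reg):
        if not valid[rid]:
            continue
        region = field.regions[rid]
        if region.is_foveal:
            val = nonfov.suppressed[fr + region.offsets[0][0],
                                    fc + region.offsets[0][1]]
        else:
            vn = [j for j in nbrs[rid] if valid[j]]
            if not vn:
                continue
            val = pooled[rid] - pooled[vn].mean(axis=0)
        if np.isnan(val).any():
            continue                    # incomplete receptive field
        sup[rid] = val
        n_ops += 1
    with np.errstate(invalid="ignore"):
        sal = np.nanmax(sup, axis=1) if combine == "max" else np.nansum(sup, axis=1)
    return SaliencyCellMap(saliency=sal, suppressed=sup, n_ops=n_ops,
                           cell_px=cell_px), valid


@dataclass
class SaliencyRunResult:
    """Foveated-vs-non-foveated agreement as fixations accumulate."""

    fixations: list                    # fixation points (px)
    s1_px: list                        # top foveated location after each fixation
    s2_px: tuple                       # fixed non-foveated top location
    distance_deg: list
    op_ratio: list                     # cumulative foveated / non-foveated ops
    n_ops_nonfoveated: int


def run_foveated_saliency(image: np.ndarray, bank: GaborBank,
                          field: VisualField, n_fixations: int,
                          seed: int = 0, combine: str = "max",
                          ior_radius_deg: float = 2.0) -> SaliencyRunResult:
    """Saccadic saliency exploration with inhibition of return.

    Saccades go to the currently most salient uninhibited location; a
    2-degree disc around each fixation is inhibited.  Every cell keeps
    the saliency value observed at its smallest eccentricity so far (the
    finest available estimate); the top integrated location S1 after each
    fixation is compared with the non-foveated top location S2.
    """
    if n_fixations < 1:
        raise ValueError("n_fixations must be >= 1")
    cfg = field.config
    cell_px = cfg.cell_px
    R = cell_responses(orientation_energy(image, bank), cell_px,
                       bank.margin_px)
    nonfov = saliency_nonfoveated(image, bank, cell_px, combine, _cells=R)
    s2 = nonfov.top_location_px()
    nbrs = _region_neighbours(field)
    n_r, n_c = R.shape[:2]
    value = np.full((n_r, n_c), np.nan)
    best_ecc = np.full((n_r, n_c), np.inf)
    H, W = (np.asarray(image).shape[0], np.asarray(image).shape[1])
    fix = (W / 2.0, H / 2.0)
    fixations, s1s, dists, ratios = [], [], [], []
    ops = 0
    for m in range(n_fixations):
        step, valid = saliency_foveated_step(
            image, bank, field, fix, combine, _cells=R, _nonfov=nonfov,
            _neighbours=nbrs)
        ops += step.n_ops
        fr, fc = snap_fixation_to_cell(fix, cell_px)
        for rid in range(field.n_regions):
            if not valid[rid] or np.isnan(step.saliency[rid]):
                continue
            region = field.regions[rid]
            rr = region.offsets[:, 0] + fr
            cc = region.offsets[:, 1] + fc
            upd = region.eccentricity_deg < best_ecc[rr, cc]
            value[rr[upd], cc[upd]] = step.saliency[rid]
            best_ecc[rr[upd], cc[upd]] = region.eccentricity_deg
        fixations.append(fix)
        if np.isnan(value).all():
            raise RuntimeError("no saliency observation; field outside image?")
        i, j = np.unravel_index(np.nanargmax(value), value.shape)
        s1 = ((j + 0.5) * cell_px, (i + 0.5) * cell_px)
        s1s.append(s1)
        dists.append(np.hypot(s1[0] - s2[0], s1[1] - s2[1])
                     / cfg.pixels_per_degree)
        ratios.append(ops / nonfov.n_ops)
        if m + 1 < n_fixations:
            fix = _next_saliency_fixation(value, fixations, cfg, cell_px,
                                          ior_radius_deg)
            if fix is None:
                break
    return SaliencyRunResult(fixations=fixations, s1_px=s1s, s2_px=s2,
                             distance_deg=dists, op_ratio=ratios,
                             n_ops_nonfoveated=nonfov.n_ops)


def _next_saliency_fixation(value, fixations, cfg, cell_px,
                            ior_radius_deg: float = 2.0):
    n_r, n_c = value.shape
    jj, ii = np.meshgrid(np.arange(n_c), np.arange(n_r))
    cx = (jj + 0.5) * cell_px
    cy = (ii + 0.5) * cell_px
    ok = ~np.isnan(value)
    r_px = ior_radius_deg * cfg.pixels_per_degree
    for fx, fy in fixations:
        ok &= np.hypot(cx - fx, cy - fy) >= r_px
    if not ok.any():
        return None
    masked = np.where(ok, value, -np.inf)
    i, j = np.unravel_index(np.argmax(masked), masked.shape)
    return ((j + 0.5) * cell_px, (i + 0.5) * cell_px)
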