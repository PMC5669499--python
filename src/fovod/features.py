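"""HoG feature extraction and the multi-scale feature pyramid.

The feature dialect is the 31-channel histogram-of-oriented-gradients
variant used by mixture-of-templates detectors: 18 contrast-sensitive
orientation channels, 9 contrast-insensitive channels and 4 texture
(gradient-energy) channels per 8x8-pixel cell, block-normalized by the
l2 energy of the four 2x2 cell blocks containing the cell, with values
clipped at 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.transform import resize

N_SENSITIVE = 18
N_INSENSITIVE = 9
N_CHANNELS = N_SENSITIVE + N_INSENSITIVE + 4   # = 31
CLIP = 0.2
EPS = 1e-4
TEXTURE_GAIN = 1.0 / np.sqrt(N_SENSITIVE)


@dataclass
class FeatureMap:
    """M x N x D per-cell feature array plus its pixel geometry."""

    array: np.ndarray
    cell_px: int
    origin_px: tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self):
        return self.array.shape


@dataclass
class FeaturePyramid:
    """Feature maps of an image resampled at geometrically spaced scales."""

    levels: list[tuple[float, FeatureMap]] = dc_field(default_factory=list)

    @property
    def scales(self) -> list[float]:
        return [s for s, _ in self.levels]

    def __iter__(self):
        return iter(self.levels)

    def __len__(self):
        return len(self.levels)


def _to_gray_stack(image: np.ndarray) -> np.ndarray:
    """Return (H, W, n_channels) float stack; gradients use the max-norm channel."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img[:, :, None]
    return img


def compute_hog(image: np.ndarray, cell_px: int = 8) -> FeatureMap:
    """Per-cell orientation histograms with 2x2 block normalization.

    The image is convolved with the point-derivative kernels [-1, 0, 1]
    and its transpose; per-pixel gradient orientation is snapped to the
    nearest of 18 contrast-sensitive directions and the magnitude is
    distributed bilinearly over the four nearest cells.  Deterministic.
    """
    img = _to_gray_stack(image)
    H, W = img.shape[:2]
    if H < 2 * cell_px or W < 2 * cell_px:
        raise ValueError(
            f"image {H}x{W} too small for {cell_px}px cells (need >= 2 cells)")
    n_r, n_c = H // cell_px, W // cell_px
    img = img[:n_r * cell_px, :n_c * cell_px]

    pad = np.pad(img, ((1, 1), (1, 1), (0, 0)), mode="edge")
    dx = pad[1:-1, 2:] - pad[1:-1, :-2]
    dy = pad[2:, 1:-1] - pad[:-2, 1:-1]
    mag2 = dx * dx + dy * dy
    best = np.argmax(mag2, axis=2)
    ii, jj = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]),
                         indexing="ij")
    dx = dx[ii, jj, best]
    dy = dy[ii, jj, best]
    mag = np.sqrt(mag2[ii, jj, best])

    theta = np.arctan2(dy, dx) % (2 * np.pi)
    ori = np.round(theta * N_SENSITIVE / (2 * np.pi)).astype(int) % N_SENSITIVE

    # bilinear interpolation of magnitudes into cells
    yc = (ii + 0.5) / cell_px - 0.5
    xc = (jj + 0.5) / cell_px - 0.5
    y0 = np.floor(yc).astype(int)
    x0 = np.floor(xc).astype(int)
    wy1 = yc - y0
    wx1 = xc - x0
    hist = np.zeros((n_r + 2, n_c + 2, N_SENSITIVE))
    for dyc, dxc, wgt in ((0, 0, (1 - wy1) * (1 - wx1)),
                          (0, 1, (1 - wy1) * wx1),
                          (1, 0, wy1 * (1 - wx1)),
                          (1, 1, wy1 * wx1)):
        np.add.at(hist, (y0 + 1 + dyc, x0 + 1 + dxc, ori), wgt * mag)
    hist = hist[1:-1, 1:-1]

    insens = hist[:, :, :N_INSENSITIVE] + hist[:, :, N_INSENSITIVE:]
    energy = (insens ** 2).sum(axis=2)
    epad = np.pad(energy, 1, mode="edge")
    # four 2x2-block normalizers containing each cell
    norms = np.empty((n_r, n_c, 4))
    blocks = (epad[:-1, :-1] + epad[:-1, 1:] + epad[1:, :-1] + epad[1:, 1:])
    norms[:, :, 0] = blocks[:-1, :-1]   # block up-left
    norms[:, :, 1] = blocks[:-1, 1:]    # up-right
    norms[:, :, 2] = blocks[1:, :-1]    # down-left
    norms[:, :, 3] = blocks[1:, 1:]     # down-right
    norms = np.sqrt(norms + EPS)

    out = np.zeros((n_r, n_c, N_CHANNELS))
    sens_n = np.minimum(hist[:, :, :, None] / norms[:, :, None, :], CLIP)
    insens_n = np.minimum(insens[:, :, :, None] / norms[:, :, None, :], CLIP)
    out[:, :, :N_SENSITIVE] = 0.5 * sens_n.sum(axis=3)
    out[:, :, N_SENSITIVE:N_SENSITIVE + N_INSENSITIVE] = 0.5 * insens_n.sum(axis=3)
    out[:, :, -4:] = TEXTURE_GAIN * sens_n.sum(axis=2)
    return FeatureMap(array=out, cell_px=cell_px)


def build_pyramid(image: np.ndarray, n_scales: int = 40,
                  scales_per_octave: int = 10, cell_px: int = 8
                  ) -> FeaturePyramid:
    """Feature maps of ``image`` at scales sigma_i = 2^(-i / scales_per_octave).

    Levels whose resampled image is smaller than two cells in either
    dimension are dropped.
    """
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    img = np.asarray(image, dtype=float)
    H, W = img.shape[:2]
    pyramid = FeaturePyramid()
    for i in range(n_scales):
        sigma = 2.0 ** (-i / scales_per_octave)
        h, w = int(round(H * sigma)), int(round(W * sigma))
        if min(h, w) < 2 * cell_px:
            break
        if sigma == 1.0:
            scaled = img
        else:
            out_shape = (h, w) + img.shape[2:]
            scaled = resize(img, out_shape, order=1, anti_aliasing=True,
                            preserve_range=True)
        pyramid.levels.append((sigma, compute_hog(scaled, cell_px)))
    return pyramid


def scale_box(box, sigma: float) -> np.ndarray:
    """Scale a (w, h, x, y) box by sigma."""
    return np.asarray(box, dtype=float) * sigma


def scale_point(point, sigma: float) -> np.ndarray:
    return np.asarray(point, dtype=float) * sigma
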