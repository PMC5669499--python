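"""Simplified V1 pooling geometry of a foveated visual field.

The visual field is a set of spatial pooling regions laid over the
histogram-of-gradients (HoG) cell grid, centered on the current fixation
point.  Inside the fovea every pooling region is a single 8x8-pixel HoG
cell (identity pooling).  In the periphery, regions sit on a log-polar
lattice whose radial and angular extents grow linearly with eccentricity,
with raised-cosine weight profiles that blend into neighbouring regions.
This mirrors the construction of V1 population receptive-field models in
which receptive-field diameter scales linearly with distance from the
fovea.

Coordinates
-----------
Pixel coordinates are 0-based, ``x`` rightward, ``y`` downward.  Boxes are
``(w, h, x, y)`` with ``(x, y)`` the top-left corner and half-open extents.
Region weights are indexed by HoG-cell offsets ``(drow, dcol)`` relative to
the cell containing the fixation point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from typing import Sequence

import numpy as np
from scipy import sparse


class FieldConfigError(ValueError):
    """Raised for geometrically inconsistent field configurations."""


@dataclass(frozen=True)
class FieldConfig:
    """Geometry of the foveated visual field.

    Parameters
    ----------
    pixels_per_degree:
        Display scale; the default 12.5 px/deg corresponds to a pixel
        subtending 0.08 degrees of visual angle.
    fovea_radius_deg:
        Radius of the fovea (identity pooling) in degrees.
    field_radius_deg:
        Outer radius of the modelled visual field in degrees.
    cell_px:
        Side of one HoG cell in pixels; foveal pooling regions are single
        cells of this size.
    v1_scaling:
        Slope of pooling-region diameter versus eccentricity (the V1
        value of the receptive-field scaling literature is about 0.25).
    n_angle_bins:
        Number of polar-angle bins in the periphery.  ``None`` chooses the
        count so that the angular bin width at the foveal border matches
        the foveal cell size.
    region_overlap:
        Fraction of each pooling window occupied by the raised-cosine
        transition shared with its neighbour, in [0, 1).
    """

    pixels_per_degree: float = 12.5
    fovea_radius_deg: float = 2.0
    field_radius_deg: float = 10.0
    cell_px: int = 8
    v1_scaling: float = 0.25
    n_angle_bins: int | None = None
    region_overlap: float = 0.5

    def __post_init__(self):
        if min(self.pixels_per_degree, self.fovea_radius_deg,
               self.field_radius_deg, self.cell_px, self.v1_scaling) <= 0:
            raise FieldConfigError("all field parameters must be positive")
        if self.fovea_radius_deg >= self.field_radius_deg:
            raise FieldConfigError(
                f"fovea radius ({self.fovea_radius_deg} deg) must be smaller "
                f"than the field radius ({self.field_radius_deg} deg)")
        if not (0 <= self.region_overlap < 1):
            raise FieldConfigError("region_overlap must be in [0, 1)")

    @property
    def fovea_radius_px(self) -> float:
        return self.fovea_radius_deg * self.pixels_per_degree

    @property
    def field_radius_px(self) -> float:
        return self.field_radius_deg * self.pixels_per_degree

    def resolved_angle_bins(self) -> int:
        if self.n_angle_bins is not None:
            return int(self.n_angle_bins)
        # angular arc length at the foveal border ~ one foveal cell
        return max(4, int(round(2 * np.pi * self.fovea_radius_px / self.cell_px)))

    @classmethod
    def preset_52px(cls) -> "FieldConfig":
        """Variant with a 52-pixel foveal radius subtending 4 degrees."""
        return cls(pixels_per_degree=13.0, fovea_radius_deg=4.0)


@dataclass
class PoolingRegion:
    """One pooling region: a normalized weighting over HoG-cell offsets."""

    id: int
    center_px: tuple[float, float]       # (x, y) offset from fixation
    eccentricity_deg: float
    angle_deg: float
    offsets: np.ndarray                  # (n, 2) int cell offsets (drow, dcol)
    weights: np.ndarray                  # (n,) nonnegative, sums to 1
    is_foveal: bool
    area_deg2: float = 0.0

    def __post_init__(self):
        s = float(self.weights.sum())
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"region {self.id} weights sum to {s}, not 1")
        if (self.weights < 0).any():
            raise ValueError(f"region {self.id} has negative weights")


@dataclass
class VisualField:
    """An ordered collection of pooling regions plus index structure."""

    config: FieldConfig
    regions: list[PoolingRegion]
    foveal_ids: np.ndarray = dc_field(default=None)
    peripheral_ids: np.ndarray = dc_field(default=None)

    def __post_init__(self):
        if self.foveal_ids is None:
            self.foveal_ids = np.array(
                [r.id for r in self.regions if r.is_foveal], dtype=int)
        if self.peripheral_ids is None:
            self.peripheral_ids = np.array(
                [r.id for r in self.regions if not r.is_foveal], dtype=int)
        # flat arrays for fast pooling
        self._rows = np.concatenate(
            [np.full(len(r.weights), r.id) for r in self.regions])
        self._drow = np.concatenate([r.offsets[:, 0] for r in self.regions])
        self._dcol = np.concatenate([r.offsets[:, 1] for r in self.regions])
        self._w = np.concatenate([r.weights for r in self.regions])
        self._centers = np.array([r.center_px for r in self.regions])
        self._ecc = np.array([r.eccentricity_deg for r in self.regions])

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def region_centers_px(self) -> np.ndarray:
        """(n, 2) array of (x, y) region centers relative to fixation."""
        return self._centers

    def eccentricities_deg(self) -> np.ndarray:
        return self._ecc

    # -- serialization -------------------------------------------------

    def save(self, path):
        meta = {"config": asdict(self.config),
                "n_regions": self.n_regions,
                "foveal_ids": self.foveal_ids.tolist()}
        arrays = {"rows": self._rows, "drow": self._drow,
                  "dcol": self._dcol, "w": self._w,
                  "centers": self._centers, "ecc": self._ecc,
                  "angle": np.array([r.angle_deg for r in self.regions]),
                  "area": np.array([r.area_deg2 for r in self.regions]),
                  "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "VisualField":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = FieldConfig(**meta["config"])
        foveal = set(meta["foveal_ids"])
        regions = []
        rows = data["rows"]
        for rid in range(meta["n_regions"]):
            m = rows == rid
            regions.append(PoolingRegion(
                id=rid,
                center_px=tuple(data["centers"][rid]),
                eccentricity_deg=float(data["ecc"][rid]),
                angle_deg=float(data["angle"][rid]),
                offsets=np.stack([data["drow"][m], data["dcol"][m]], axis=1),
                weights=data["w"][m],
                is_foveal=rid in foveal,
                area_deg2=float(data["area"][rid])))
        return cls(config=cfg, regions=regions)


def _raised_cosine(x: np.ndarray, t: float) -> np.ndarray:
    """Flat-top window with cosine-squared flanks, unit-width partition.

    ``x`` is the signed distance from the window center in units of the
    bin spacing; ``t`` the transition fraction.  Adjacent windows offset
    by 1 sum to 1 (partition of unity) for any ``t`` in (0, 1].
    """
    t = max(t, 1e-6)
    ax = np.abs(x)
    w = np.zeros_like(ax)
    w[ax <= (1 - t) / 2] = 1.0
    trans = (ax > (1 - t) / 2) & (ax <= (1 + t) / 2)
    w[trans] = np.cos(np.pi / (2 * t) * (ax[trans] - (1 - t) / 2)) ** 2
    return w


def build_field(config: FieldConfig) -> VisualField:
    """Construct the foveated visual field for a configuration.

    Foveal regions are unit-weight single HoG cells tiling the disc of
    radius ``fovea_radius_deg``; peripheral regions form a log-polar
    lattice out to ``field_radius_deg`` with raised-cosine weights
    evaluated at cell centers.  Deterministic for a fixed config.
    """
    c = config
    cell = c.cell_px
    regions: list[PoolingRegion] = []
    rid = 0

    # --- foveal cells: cells whose center lies within the foveal disc
    max_cells = int(np.ceil(c.fovea_radius_px / cell)) + 1
    cell_area_deg2 = (cell / c.pixels_per_degree) ** 2
    for drow in range(-max_cells, max_cells + 1):
        for dcol in range(-max_cells, max_cells + 1):
            cx = dcol * cell          # cell-center offset from fixation cell
            cy = drow * cell
            ecc_px = np.hypot(cx, cy)
            if ecc_px <= c.fovea_radius_px:
                regions.append(PoolingRegion(
                    id=rid, center_px=(cx, cy),
                    eccentricity_deg=ecc_px / c.pixels_per_degree,
                    angle_deg=float(np.degrees(np.arctan2(cy, cx))),
                    offsets=np.array([[drow, dcol]], dtype=int),
                    weights=np.array([1.0]),
                    is_foveal=True,
                    area_deg2=cell_area_deg2))
                rid += 1

    # --- peripheral log-polar lattice
    e0, e1 = c.fovea_radius_deg, c.field_radius_deg
    # ring spacing in log-eccentricity chosen from the diameter-vs-
    # eccentricity slope: a region of diameter v1_scaling * e has log-width
    # log((1 + s/2) / (1 - s/2))
    s = c.v1_scaling
    du_target = np.log((1 + s / 2) / (1 - s / 2))
    n_rings = max(1, int(np.ceil(np.log(e1 / e0) / du_target)))
    du = np.log(e1 / e0) / n_rings
    n_ang = c.resolved_angle_bins()
    dth = 2 * np.pi / n_ang

    # candidate cell grid covering the field
    max_cells = int(np.ceil(c.field_radius_px / cell)) + 2
    g = np.arange(-max_cells, max_cells + 1)
    drow_g, dcol_g = np.meshgrid(g, g, indexing="ij")
    cx_g = dcol_g * cell
    cy_g = drow_g * cell
    ecc_px_g = np.hypot(cx_g, cy_g)
    ecc_deg_g = ecc_px_g / c.pixels_per_degree
    theta_g = np.arctan2(cy_g, cx_g)    # [-pi, pi]

    periph = (ecc_deg_g >= e0) & (ecc_deg_g <= e1)
    u_g = np.where(ecc_deg_g > 0, np.log(np.maximum(ecc_deg_g, 1e-12) / e0), -np.inf)

    t = max(c.region_overlap, 1e-6)
    for k in range(n_rings):
        u_k = (k + 0.5) * du
        e_k = e0 * np.exp(u_k)
        wu = _raised_cosine((u_g - u_k) / du, t)
        # area of the full raised-cosine support: the window extends
        # (1 + t) bins in each of log-eccentricity and angle
        ring_area = ((e0 * np.exp((k + 1) * du)) ** 2 -
                     (e0 * np.exp(k * du)) ** 2) * np.pi * (1 + t) ** 2
        for j in range(n_ang):
            th_j = -np.pi + (j + 0.5) * dth
            dtheta = np.angle(np.exp(1j * (theta_g - th_j)))
            wth = _raised_cosine(dtheta / dth, t)
            w = wu * wth
            w[~periph] = 0.0
            mask = w > 1e-3
            if not mask.any():
                continue
            wm = w[mask]
            wm = wm / wm.sum()
            regions.append(PoolingRegion(
                id=rid,
                center_px=(float(e_k * np.cos(th_j) * c.pixels_per_degree),
                           float(e_k * np.sin(th_j) * c.pixels_per_degree)),
                eccentricity_deg=float(e_k),
                angle_deg=float(np.degrees(th_j)),
                offsets=np.stack([drow_g[mask], dcol_g[mask]], axis=1),
                weights=wm,
                is_foveal=False,
                area_deg2=ring_area / n_ang))
            rid += 1

    return VisualField(config=config, regions=regions)


# ---------------------------------------------------------------------------
# pooling operators


class EmptyOperatorError(ValueError):
    """Raised when a box intersects no pooling region of the field."""


def box_region_coverage(field: VisualField, box: Sequence[float]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Weight mass of each region lying under a field box.

    ``box`` is ``(w, h, x, y)`` in pixels relative to the fixation point.
    Returns (region ids with nonzero mass, fraction of each region's
    weight mass covered by the box).  A cell counts as inside the box by
    the fraction of its area the box covers.
    """
    w, h, x, y = box
    cell = field.config.cell_px
    # cell (drow, dcol) spans x in [dcol*c - c/2 + c/2 ...]; cell centers are
    # at (dcol*cell, drow*cell), extents +/- cell/2
    cx = field._dcol * cell
    cy = field._drow * cell
    ox = np.clip(np.minimum(x + w, cx + cell / 2) - np.maximum(x, cx - cell / 2),
                 0, cell)
    oy = np.clip(np.minimum(y + h, cy + cell / 2) - np.maximum(y, cy - cell / 2),
                 0, cell)
    frac = (ox * oy) / (cell * cell)
    mass = np.bincount(field._rows, weights=field._w * frac,
                       minlength=field.n_regions)
    ids = np.nonzero(mass > 1e-12)[0]
    return ids, mass[ids]


@dataclass
class PoolingMatrix:
    """Linear map from raw cell features under a box to pooled features.

    ``spatial`` is a sparse (n_regions_in_box, n_cells_in_box) matrix with
    rows summing to 1; the full operator on D-channel features is its
    Kronecker product with the D-dimensional identity.
    """

    region_ids: np.ndarray
    cell_offsets: np.ndarray          # (n_cells, 2) (drow, dcol) of box cells
    spatial: sparse.csr_matrix

    @property
    def n_regions(self) -> int:
        return self.spatial.shape[0]

    def apply(self, cell_features: np.ndarray) -> np.ndarray:
        """Pool (n_cells, D) cell features to (n_regions, D)."""
        return self.spatial @ cell_features

    def dense(self, n_channels: int) -> np.ndarray:
        """Full dense operator on stacked (cell, channel) coordinates."""
        return np.kron(self.spatial.toarray(), np.eye(n_channels))


def pooling_matrix(field: VisualField, box: Sequence[float],
                   intersect_threshold: float = 0.2) -> PoolingMatrix:
    """Pooling operator of the component occupying ``box``.

    Rows are the regions whose weight mass under the box exceeds
    ``intersect_threshold``; their weights are restricted to the cells
    under the box and renormalized so each row sums to 1 (a constant
    feature map pools to the same constant).
    """
    ids, cov = box_region_coverage(field, box)
    keep = ids[cov > intersect_threshold]
    if keep.size == 0:
        raise EmptyOperatorError(
            f"box {tuple(box)} covers no pooling region of the field")
    w, h, x, y = box
    cell = field.config.cell_px
    # cells (centers) whose area overlaps the box
    r0 = int(np.floor((y - cell / 2) / cell)) + 1
    r1 = int(np.ceil((y + h + cell / 2) / cell)) - 1
    c0 = int(np.floor((x - cell / 2) / cell)) + 1
    c1 = int(np.ceil((x + w + cell / 2) / cell)) - 1
    rows_g = np.arange(r0, r1 + 1)
    cols_g = np.arange(c0, c1 + 1)
    n_cells = len(rows_g) * len(cols_g)
    cell_index = {(r, c): i for i, (r, c) in enumerate(
        (r, c) for r in rows_g for c in cols_g)}
    offsets = np.array([[r, c] for r in rows_g for c in cols_g], dtype=int)

    data, ri, ci = [], [], []
    keep_pos = {int(rid): i for i, rid in enumerate(keep)}
    mask = np.isin(field._rows, keep)
    for rid, dr, dc, wt in zip(field._rows[mask], field._drow[mask],
                               field._dcol[mask], field._w[mask]):
        key = (int(dr), int(dc))
        if key in cell_index:
            ri.append(keep_pos[int(rid)])
            ci.append(cell_index[key])
            data.append(wt)
    sp = sparse.coo_matrix((data, (ri, ci)),
                           shape=(len(keep), n_cells)).tocsr()
    row_sums = np.asarray(sp.sum(axis=1)).ravel()
    if (row_sums <= 0).any():
        raise EmptyOperatorError("a selected region has no cell under the box")
    sp = sparse.diags(1.0 / row_sums) @ sp
    return PoolingMatrix(region_ids=keep, cell_offsets=offsets, spatial=sp.tocsr())


def snap_fixation_to_cell(fixation_px: Sequence[float], cell_px: int
                          ) -> tuple[int, int]:
    """(row, col) of the HoG cell containing the fixation point.

    The containing cell is the nearest cell center except exactly on a
    boundary, where flooring keeps the choice deterministic.
    """
    fx, fy = fixation_px
    return (int(np.floor(fy / cell_px)), int(np.floor(fx / cell_px)))


def pool_features(field: VisualField, fmap: np.ndarray,
                  fixation_px: Sequence[float]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Pool a (M, N, D) cell-feature map around a fixation point.

    The field is centered on the HoG cell nearest the fixation.  Returns
    ``(pooled, valid)`` where ``pooled`` is (n_regions, D) and ``valid``
    flags regions whose support lies entirely inside the map; invalid
    regions hold zeros and must be excluded downstream rather than read.
    """
    M, N, D = fmap.shape
    fr, fc = snap_fixation_to_cell(fixation_px, field.config.cell_px)
    if not (0 <= fixation_px[0] < N * field.config.cell_px and
            0 <= fixation_px[1] < M * field.config.cell_px):
        raise ValueError(f"fixation {tuple(fixation_px)} outside image bounds")
    rows = field._rows
    ar = field._drow + fr
    ac = field._dcol + fc
    inside = (ar >= 0) & (ar < M) & (ac >= 0) & (ac < N)
    pooled = np.zeros((field.n_regions, D))
    np.add.at(pooled, rows[inside],
              field._w[inside, None] * fmap[ar[inside], ac[inside], :])
    n_total = np.bincount(rows, minlength=field.n_regions)
    n_in = np.bincount(rows[inside], minlength=field.n_regions)
    valid = n_in == n_total
    pooled[~valid] = 0.0
    return pooled, valid


def plot_field(field: VisualField, ax=None):
    """Render the field: foveal squares plus peripheral weight maps."""
    import matplotlib.pyplot as plt
    from matplotlib import patches

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    cell = field.config.cell_px
    R = int(np.ceil(field.config.field_radius_px / cell)) + 2
    canvas = np.zeros((2 * R + 1, 2 * R + 1))
    for r in field.regions:
        if r.is_foveal:
            continue
        rr = r.offsets[:, 0] + R
        cc = r.offsets[:, 1] + R
        canvas[rr, cc] = np.maximum(canvas[rr, cc], r.weights / r.weights.max())
    extent = [(-R - 0.5) * cell, (R + 0.5) * cell,
              (R + 0.5) * cell, (-R - 0.5) * cell]
    ax.imshow(canvas, extent=extent, cmap="viridis")
    for rid in field.foveal_ids:
        cx, cy = field.regions[rid].center_px
        ax.add_patch(patches.Rectangle(
            (cx - cell / 2, cy - cell / 2), cell, cell,
            fill=True, facecolor="tab:blue", edgecolor="white", lw=0.5))
    ax.set_xlabel("x offset from fixation (px)")
    ax.set_ylabel("y offset from fixation (px)")
    ax.set_title("Foveated visual field")
    return ax
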