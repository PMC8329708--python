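"""Compound-eye ray casting and back-projection of spike rates onto terrain.

A honey bee's compound eye covers roughly 300 degrees of horizontal field of
view. Each ommatidium is modeled as a single viewing direction; for a given
copter pose the rays are cast against a terrain height grid and the first
intersection is classified as belonging to the experimental field, outside
it, or no hit at all. Spike rates can then be accumulated per terrain pixel
over a flight, producing a map of where the bee was "looking" while the
recorded unit was active.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .session import Session

if TYPE_CHECKING:  # pragma: no cover
    from .rateanalysis import RateSeries

__all__ = [
    "EyeModel",
    "TerrainModel",
    "ActivityMap",
    "RayHit",
    "HIT_FIELD",
    "HIT_OUTSIDE",
    "HIT_NONE",
    "build_eye_model",
    "raycast",
    "project_rates",
    "read_ascii_grid",
    "write_ascii_grid",
]

GOLDEN_RATIO = (1.0 + 5.0**0.5) / 2.0

HIT_FIELD = 1
HIT_OUTSIDE = 0
HIT_NONE = -1


@dataclass
class EyeModel:
    """Set of ommatidial viewing directions in the head frame.

    Head frame: x forward, y left, z up; azimuth measured counterclockwise
    from +x about +z, elevation from the horizontal plane.
    """

    ommatidia_dirs: np.ndarray  # (n, 3) unit vectors
    horizontal_fov_rad: float
    vertical_fov_rad: float

    @property
    def n_ommatidia(self) -> int:
        return len(self.ommatidia_dirs)


@dataclass
class TerrainModel:
    """Height grid with a boolean field mask.

    Row-major grid; row 0 is the north edge (largest y), consistent with the
    usual raster convention. Cells are half-open squares of side ``cell_m``;
    ``origin_xy_m`` is the outer corner of the south-west cell (min x, min y).
    """

    origin_xy_m: tuple
    cell_m: float
    heights: np.ndarray
    field_mask: np.ndarray

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        self.field_mask = np.asarray(self.field_mask, dtype=bool)
        if self.heights.shape != self.field_mask.shape:
            raise ValueError("heights and field_mask shapes differ")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.cell_m <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple:
        return self.heights.shape

    def xy_to_rowcol(self, x, y):
        """Map metric coordinates to (row, col) by floor division."""
        n_rows = self.heights.shape[0]
        col = np.floor((np.asarray(x) - self.origin_xy_m[0]) / self.cell_m).astype(int)
        row = n_rows - 1 - np.floor(
            (np.asarray(y) - self.origin_xy_m[1]) / self.cell_m
        ).astype(int)
        return row, col

    def in_bounds(self, row, col):
        n_rows, n_cols = self.heights.shape
        return (row >= 0) & (row < n_rows) & (col >= 0) & (col < n_cols)

    def height_at(self, x, y):
        """Terrain height at metric coordinates (nearest-cell lookup)."""
        row, col = self.xy_to_rowcol(x, y)
        ok = self.in_bounds(row, col)
        h = np.full(np.shape(ok), -np.inf, dtype=float)
        h[ok] = self.heights[row[ok], col[ok]]
        return h

    @property
    def extent_m(self) -> tuple:
        n_rows, n_cols = self.heights.shape
        return (n_cols * self.cell_m, n_rows * self.cell_m)


@dataclass
class RayHit:
    """Per-ommatidium ray casting result.

    ``x_m``/``y_m`` hold the refined ground intersection point (NaN where a
    ray did not hit); ``rows``/``cols`` are the grid cell containing it.
    """

    rows: np.ndarray
    cols: np.ndarray
    classes: np.ndarray  # HIT_FIELD / HIT_OUTSIDE / HIT_NONE per ray
    x_m: np.ndarray
    y_m: np.ndarray


@dataclass
class ActivityMap:
    """Per-pixel accumulated spike rate: running sum and visit count."""

    sum_grid: np.ndarray
    count_grid: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "ActivityMap":
        return cls(np.zeros(shape, dtype=float), np.zeros(shape, dtype=np.int64))

    @property
    def mean_grid(self) -> np.ndarray:
        """Mean rate where a pixel was seen at least once, NaN elsewhere."""
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = self.sum_grid / self.count_grid
        mean[self.count_grid == 0] = np.nan
        return mean


def build_eye_model(
    n_ommatidia: int = 5000,
    h_fov_rad: float = np.deg2rad(300.0),
    v_fov_rad: float = np.deg2rad(160.0),
) -> EyeModel:
    """Quasi-uniform ommatidial directions on the field-of-view wedge.

    Directions are placed with a Fibonacci (golden-angle) lattice restricted
    to the wedge: elevation sampled uniformly in sin(elevation) over the
    vertical field of view and azimuth by golden-ratio steps folded into the
    horizontal field of view, which is centered on the forward axis so that
    a 300 degree horizontal span leaves a 60 degree blind wedge to the rear.
    Deterministic: no randomness involved.
    """
    if n_ommatidia < 1:
        raise ValueError("need at least one ommatidium")
    for fov in (h_fov_rad, v_fov_rad):
        if not 0.0 < fov <= 2.0 * np.pi:
            raise ValueError("field of view must be in (0, 2*pi]")
    i = np.arange(n_ommatidia)
    # uniform in sin(elevation) => uniform area density on the sphere band
    s0, s1 = np.sin(-v_fov_rad / 2.0), np.sin(v_fov_rad / 2.0)
    sin_el = s0 + (s1 - s0) * (i + 0.5) / n_ommatidia
    el = np.arcsin(np.clip(sin_el, -1.0, 1.0))
    az = -h_fov_rad / 2.0 + np.mod(i / GOLDEN_RATIO, 1.0) * h_fov_rad
    dirs = np.column_stack(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )
    return EyeModel(
        ommatidia_dirs=dirs, horizontal_fov_rad=h_fov_rad, vertical_fov_rad=v_fov_rad
    )


def raycast(
    eye: EyeModel,
    pose: tuple,
    terrain: TerrainModel,
    max_range_m: float | None = None,
) -> RayHit:
    """Cast all ommatidial rays from a pose against the terrain.

    ``pose`` is (x, y, alt, yaw): position in metric terrain coordinates,
    altitude above the height datum, and yaw rotating the head frame into
    the world frame (ENU, counterclockwise positive). Rays are marched in
    steps of half a grid cell until a sample falls at or below the terrain
    surface; the intersection is then refined by solving the ray-to-surface
    crossing for the local cell height, so on smooth terrain the reported
    point is accurate well below the cell size. Rays that leave the grid
    extent or never descend to the surface are class ``HIT_NONE``; hits are
    classified by the field mask into ``HIT_FIELD`` / ``HIT_OUTSIDE``.
    """
    x0, y0, alt, yaw = (float(v) for v in pose)
    ground = terrain.height_at(np.array([x0]), np.array([y0]))[0]
    if np.isfinite(ground) and alt <= ground:
        raise ValueError("pose altitude is at or below the terrain surface")

    c, s = np.cos(yaw), np.sin(yaw)
    d = eye.ommatidia_dirs
    dx = c * d[:, 0] - s * d[:, 1]
    dy = s * d[:, 0] + c * d[:, 1]
    dz = d[:, 2]

    n = eye.n_ommatidia
    rows = np.full(n, -1, dtype=int)
    cols = np.full(n, -1, dtype=int)
    classes = np.full(n, HIT_NONE, dtype=int)
    hx = np.full(n, np.nan)
    hy = np.full(n, np.nan)

    step = terrain.cell_m / 2.0
    if max_range_m is None:
        ex, ey = terrain.extent_m
        max_range_m = float(np.hypot(ex, ey)) + alt
    n_steps = int(np.ceil(max_range_m / step))

    active = dz < 0  # over terrain below the pose only descending rays can hit
    t = np.full(n, step)
    for _ in range(n_steps):
        if not np.any(active):
            break
        idx = np.nonzero(active)[0]
        px = x0 + t[idx] * dx[idx]
        py = y0 + t[idx] * dy[idx]
        pz = alt + t[idx] * dz[idx]
        r, c_ = terrain.xy_to_rowcol(px, py)
        inb = terrain.in_bounds(r, c_)
        # rays off the grid can never return (convex extent): drop them
        active[idx[~inb]] = False
        if np.any(inb):
            hgt = terrain.heights[r[inb], c_[inb]]
            below = pz[inb] <= hgt
            sub = idx[inb][below]
            if len(sub):
                # refine: exact crossing of the local cell's height plane,
                # clamped to the last marching step
                h_loc = hgt[below]
                tau = (h_loc - alt) / dz[sub]
                tau = np.clip(tau, t[sub] - step, t[sub])
                px_r = x0 + tau * dx[sub]
                py_r = y0 + tau * dy[sub]
                rr, cc = terrain.xy_to_rowcol(px_r, py_r)
                ok = terrain.in_bounds(rr, cc)
                rr = np.where(ok, rr, r[inb][below])
                cc = np.where(ok, cc, c_[inb][below])
                rows[sub] = rr
                cols[sub] = cc
                hx[sub] = px_r
                hy[sub] = py_r
                classes[sub] = np.where(
                    terrain.field_mask[rows[sub], cols[sub]],
                    HIT_FIELD,
                    HIT_OUTSIDE,
                )
                active[sub] = False
        t[idx] = t[idx] + step
    return RayHit(rows=rows, cols=cols, classes=classes, x_m=hx, y_m=hy)


def project_rates(
    session: Session,
    rate_series: "RateSeries",
    eye: EyeModel,
    terrain: TerrainModel,
    turn_exclusion_rad_s: float | None = 0.3,
) -> ActivityMap:
    """Accumulate spike rates onto the terrain pixels the bee could see.

    For every rate bin the copter pose at the bin center is looked up, the
    eye model is ray cast, and each distinct field-class pixel in view
    accumulates the bin's spike rate once. Bins whose |yaw rate| exceeds
    ``turn_exclusion_rad_s`` are skipped (pass ``None`` to keep turns), so
    the map highlights activity during straight flight.
    """
    amap = ActivityMap.zeros(terrain.shape)
    centers = rate_series.bin_centers()
    tel = session.telemetry
    for t_c, rate in zip(centers, rate_series.rates):
        t_tel = t_c + session.clock_offset_s
        if t_tel < tel.t_s[0] or t_tel > tel.t_s[-1]:
            continue
        state = session.lookup(t_c)
        if (
            turn_exclusion_rad_s is not None
            and abs(state.yaw_rate_rad_s) > turn_exclusion_rad_s
        ):
            continue
        hit = raycast(eye, (state.x_m, state.y_m, state.alt_m, state.yaw_rad), terrain)
        sel = hit.classes == HIT_FIELD
        if not np.any(sel):
            continue
        pix = np.unique(
            hit.rows[sel].astype(np.int64) * terrain.shape[1] + hit.cols[sel]
        )
        r, c = pix // terrain.shape[1], pix % terrain.shape[1]
        amap.sum_grid[r, c] += rate
        amap.count_grid[r, c] += 1
    return amap


# --- terrain I/O (ESRI-style ASCII grid + JSON mask polygon) ----------------


def write_ascii_grid(terrain: TerrainModel, path, mask_path=None) -> None:
    """Write heights as an ESRI ASCII grid; mask optionally as JSON polygon
    raster (row-major 0/1 list) alongside."""
    n_rows, n_cols = terrain.heights.shape
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {terrain.origin_xy_m[0]:.6f}\n"
        f"yllcorner {terrain.origin_xy_m[1]:.6f}\n"
        f"cellsize {terrain.cell_m:.6f}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, terrain.heights, fmt="%.6g")
    if mask_path is not None:
        with open(mask_path, "w", encoding="utf-8") as fh:
            json.dump({"field_mask": terrain.field_mask.astype(int).tolist()}, fh)


def read_ascii_grid(path, mask_path=None) -> TerrainModel:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        heights = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(meta["nrows"]), int(meta["ncols"])
    if heights.shape != (n_rows, n_cols):
        raise ValueError("grid body does not match declared dimensions")
    if mask_path is not None:
        with open(mask_path, "r", encoding="utf-8") as fh:
            mask = np.asarray(json.load(fh)["field_mask"], dtype=bool)
    else:
        mask = np.ones_like(heights, dtype=bool)
    return TerrainModel(
        origin_xy_m=(meta["xllcorner"], meta["yllcorner"]),
        cell_m=meta["cellsize"],
        heights=heights,
        field_mask=mask,
    )
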