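"""Joint-kernel utilization distribution and pseudo-absence generation.

The available area is defined as the 99% volume contour of a bivariate-normal
kernel UD estimated from the pooled fixes of all individuals, with the
classical "ad hoc" (reference) bandwidth h = sigma * n^(-1/6) where sigma is
the mean of the marginal standard deviations. Land is masked from the contour
polygon. Pseudo-absences sample the resulting polygon on a deterministic
square lattice whose spacing is chosen so the interior point count matches
the target subgroup count as closely as possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon
from skimage import measure

from .raster import Raster

__all__ = [
    "UtilizationDistribution",
    "AvailabilityPolygon",
    "reference_bandwidth",
    "estimate_ud",
    "ud_contour",
    "generate_pseudo_absences",
]

log = logging.getLogger(__name__)

MAX_CELLS = 4_000_000


@dataclass
class UtilizationDistribution:
    grid: Raster            # density values, integrates to ~1
    bandwidth: float        # m
    n_points: int

    @property
    def cell_size(self) -> float:
        return self.grid.cell

    def total_volume(self) -> float:
        return float(np.nansum(self.grid.values) * self.grid.cell**2)


@dataclass
class AvailabilityPolygon:
    polygon: Polygon | MultiPolygon
    level: float

    @property
    def area_km2(self) -> float:
        return self.polygon.area / 1e6


def reference_bandwidth(points: np.ndarray) -> float:
    """Ad hoc bivariate-normal reference bandwidth h = sigma * n^(-1/6)."""
    n = len(points)
    sigma = 0.5 * (points[:, 0].std(ddof=1) + points[:, 1].std(ddof=1))
    return float(sigma * n ** (-1.0 / 6.0))


def estimate_ud(
    points: np.ndarray,
    bandwidth: float | None = None,
    extent_factor: float = 1.0,
    cell_size: float | None = None,
) -> UtilizationDistribution:
    """Bivariate-normal kernel density of pooled fixes on a raster grid.

    The grid covers the point bounding box extended by ``extent_factor`` times
    the coordinate range on each side; cell size defaults to bandwidth/4,
    capped so the grid stays under 4e6 cells and refined so each axis has at
    least 200 cells. Density is computed by binning the points and convolving
    with a Gaussian kernel (exact up to the cell quantisation).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 10:
        raise ValueError("need at least 10 points for a UD")
    if points[:, 0].std() == 0 or points[:, 1].std() == 0:
        raise ValueError("degenerate (collinear/identical) points")
    h = bandwidth if bandwidth is not None else reference_bandwidth(points)

    xmin, ymin = points.min(axis=0)
    xmax, ymax = points.max(axis=0)
    rx, ry = xmax - xmin, ymax - ymin
    x0, x1 = xmin - extent_factor * rx, xmax + extent_factor * rx
    y0, y1 = ymin - extent_factor * ry, ymax + extent_factor * ry

    cell = cell_size if cell_size is not None else h / 4.0
    span = max(x1 - x0, y1 - y0)
    cell = min(cell, span / 200.0)                      # >= 200 cells per axis
    while ((x1 - x0) / cell) * ((y1 - y0) / cell) > MAX_CELLS:
        cell *= 1.25

    ncols = int(np.ceil((x1 - x0) / cell))
    nrows = int(np.ceil((y1 - y0) / cell))

    counts, _, _ = np.histogram2d(
        points[:, 1], points[:, 0],
        bins=[nrows, ncols],
        range=[[y0, y0 + nrows * cell], [x0, x0 + ncols * cell]],
    )
    density = ndimage.gaussian_filter(counts, sigma=h / cell, mode="constant")
    density /= density.sum() * cell**2
    density = density[::-1]  # row 0 at top

    grid = Raster(values=density, x0=x0, y0=y0, cell=cell)
    return UtilizationDistribution(grid=grid, bandwidth=h, n_points=len(points))


def _rings_to_polygons(rings: list[np.ndarray]) -> MultiPolygon:
    """Assemble closed iso-contour rings into polygons with holes."""
    polys = [Polygon(r) for r in rings if len(r) >= 4]
    polys = [p if p.is_valid else p.buffer(0) for p in polys]
    polys = [p for p in polys if not p.is_empty]
    polys.sort(key=lambda p: p.area, reverse=True)
    shells: list[Polygon] = []
    holes: list[list] = []
    for p in polys:
        pt = p.representative_point()
        depth = sum(1 for q in polys if q.area > p.area and q.contains(pt))
        if depth % 2 == 0:
            shells.append(p)
            holes.append([])
        else:
            # hole in the smallest enclosing shell
            encl = min(
                (i for i, s in enumerate(shells) if s.contains(pt)),
                key=lambda i: shells[i].area,
                default=None,
            )
            if encl is not None:
                holes[encl].append(p.exterior.coords)
    out = [Polygon(s.exterior.coords, hs) for s, hs in zip(shells, holes)]
    out = [p if p.is_valid else p.buffer(0) for p in out]
    geom = shapely.union_all(out)
    if isinstance(geom, Polygon):
        geom = MultiPolygon([geom])
    return geom


def ud_contour(
    ud: UtilizationDistribution, level: float, land_mask=None
) -> AvailabilityPolygon:
    """Smallest-density iso-contour enclosing ``level`` of the UD volume.

    The density threshold is found from the cumulative cell-mass curve; the
    iso-line is traced at sub-cell resolution and vectorised to polygons,
    then any land geometry is differenced out.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    dens = ud.grid.values
    cell_area = ud.grid.cell**2
    flat = np.sort(dens.ravel())[::-1]
    cmass = np.cumsum(flat) * cell_area
    idx = int(np.searchsorted(cmass, level * cmass[-1]))
    if idx >= len(flat):
        raise ValueError("requested volume level unreachable; use a finer grid")
    threshold = flat[idx]

    padded = np.pad(dens, 1, constant_values=0.0)
    rings = measure.find_contours(padded, threshold)
    # contour coords are (row, col) in padded array; convert to x, y
    xy_rings = []
    for r in rings:
        rows = r[:, 0] - 1.0
        cols = r[:, 1] - 1.0
        x = ud.grid.x0 + (cols + 0.5) * ud.grid.cell
        y = ud.grid.y0 + (ud.grid.nrows - 1 - rows + 0.5) * ud.grid.cell
        xy_rings.append(np.column_stack([x, y]))
    geom = _rings_to_polygons(xy_rings)
    if land_mask is not None:
        geom = geom.difference(land_mask)
    return AvailabilityPolygon(polygon=geom, level=level)


def _lattice_count(poly, spacing: float) -> int:
    return len(_lattice_points(poly, spacing))


def _lattice_points(poly, spacing: float) -> np.ndarray:
    xmin, ymin, xmax, ymax = poly.bounds
    xs = np.arange(xmin, xmax + spacing / 2, spacing)
    ys = np.arange(ymin, ymax + spacing / 2, spacing)
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    return pts[inside]


def generate_pseudo_absences(
    poly: AvailabilityPolygon | Polygon | MultiPolygon,
    n_target: int,
    subgroup: dict | None = None,
) -> np.ndarray:
    """Regular-grid pseudo-absence points inside the availability polygon.

    The lattice origin sits at the polygon bounding-box lower-left corner and
    the spacing is found by bisection so the interior point count is as close
    as possible to ``n_target`` (ties broken toward the denser grid). Fully
    deterministic: no random number generation is involved, so the same
    polygon and target always give the same points. Returns an (n, 2) array;
    minor deviations from ``n_target`` reflect the irregular polygon shape.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    geom = poly.polygon if isinstance(poly, AvailabilityPolygon) else poly
    if geom.is_empty:
        raise ValueError("empty availability polygon")

    area = geom.area
    s_guess = np.sqrt(area / max(n_target, 1))
    lo, hi = s_guess / 20.0, s_guess * 20.0
    # ensure bracketing: count(lo) >= target >= count(hi)
    for _ in range(30):
        if _lattice_count(geom, lo) >= n_target:
            break
        lo /= 2.0
    for _ in range(30):
        if _lattice_count(geom, hi) <= n_target:
            break
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _lattice_count(geom, mid) >= n_target:
            lo = mid
        else:
            hi = mid
    # local refinement around the bracket; prefer denser grid on ties
    best_s, best_err = None, None
    for s in np.linspace(lo * 0.98, hi * 1.02, 41):
        err = abs(_lattice_count(geom, s) - n_target)
        if best_err is None or err < best_err or (err == best_err and s < best_s):
            best_s, best_err = float(s), err
    pts = _lattice_points(geom, best_s)
    if len(pts) == 0:
        log.info("polygon too small for lattice; using centroid point")
        c = geom.representative_point()
        pts = np.array([[c.x, c.y]])
    return pts
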