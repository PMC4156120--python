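"""Directional and sky-integrated STAR over a turtle-sky dome.

STAR = PLA / TLA: the silhouette (projected) leaf area, counting
overlaps once, divided by the total leaf area.  Directional STAR values
over a discretization of the sky hemisphere into equal-solid-angle
sectors are combined with weights derived from the standard overcast
sky (SOC) radiance distribution, giving a single diffuse-light
interception efficiency index in [0, 1].

Projection is an orthographic rasterization of the leaf polygons onto
the plane perpendicular to each direction (z-buffer style occupancy
grid); an independent Monte-Carlo ray-sampling estimator and an exact
polygon-union area are provided for cross-checking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import Leaf, total_leaf_area

__all__ = [
    "SkySector",
    "SkyDome",
    "StarResult",
    "turtle_sky",
    "soc_weights",
    "projected_area",
    "projected_area_mc",
    "projected_area_exact",
    "directional_star",
    "integrated_star",
]


@dataclass
class SkySector:
    direction: np.ndarray  # unit vector, sector centre
    elevation: float  # degrees above horizon
    azimuth: float  # degrees clockwise from +y (north)
    solid_angle: float  # sr
    weight: float = 0.0


@dataclass
class SkyDome:
    sectors: list[SkySector]

    @property
    def n_sectors(self) -> int:
        return len(self.sectors)


@dataclass
class StarResult:
    tla: float
    per_direction: list[tuple[np.ndarray, float, float]]  # (direction, pla, star_d)
    star_integrated: float


def _direction(elev_deg: float, azim_deg: float) -> np.ndarray:
    e = np.radians(elev_deg)
    a = np.radians(azim_deg)
    # azimuth clockwise from +y (north)
    return np.array([np.sin(a) * np.cos(e), np.cos(a) * np.cos(e), np.sin(e)])


def turtle_sky(n_sectors: int = 46) -> SkyDome:
    """Partition the sky hemisphere into `n_sectors` equal solid angles.

    Ring construction: the hemisphere is sliced into elevation rings, and
    each ring into sectors of exactly 2*pi/n sr.  Ring sector counts are
    chosen so cells are roughly as tall as they are wide; a single-sector
    top ring is a zenith cap.  Sector centres sit at the ring's equal-area
    median elevation, azimuths evenly spaced with a half-step offset.
    """
    if n_sectors < 1:
        raise ValueError("n_sectors must be >= 1")
    n = n_sectors
    omega = 2 * np.pi / n
    rings: list[tuple[float, float, int]] = []  # (sin_lo, sin_hi, count)
    s_lo = 0.0
    remaining = n
    while remaining > 0:
        best_c, best_cost = remaining, np.inf
        for c in range(1, remaining + 1):
            s_hi = s_lo + c / n
            if s_hi > 1.0 + 1e-12:
                continue
            e_lo, e_hi = np.arcsin(min(s_lo, 1.0)), np.arcsin(min(s_hi, 1.0))
            e_c = 0.5 * (e_lo + e_hi)
            height = e_hi - e_lo
            width = (2 * np.pi / c) * max(np.cos(e_c), 1e-9)
            cost = abs(np.log(height / width))
            if cost < best_cost:
                best_cost, best_c = cost, c
        c = best_c
        rings.append((s_lo, s_lo + c / n, c))
        s_lo += c / n
        remaining -= c
    sectors: list[SkySector] = []
    for s0, s1, c in rings:
        if c == 1 and s1 >= 1.0 - 1e-9:
            # azimuthally symmetric cap: centroid direction is the zenith
            sectors.append(
                SkySector(np.array([0.0, 0.0, 1.0]), 90.0, 0.0, omega)
            )
            continue
        elev_c = np.degrees(np.arcsin(min(0.5 * (s0 + s1), 1.0)))
        for j in range(c):
            az = (j + 0.5) * 360.0 / c
            sectors.append(SkySector(_direction(elev_c, az), elev_c, az, omega))
    return SkyDome(sectors)


def soc_weights(dome: SkyDome, flux_term: bool = True) -> SkyDome:
    """Assign normalized standard-overcast-sky weights to the dome.

    weight_i is proportional to L(e_i) * sin(e_i) * omega_i with the SOC
    gradation L(e) = (1 + 2 sin e) / 3; `flux_term=False` drops the
    sin(e) horizontal-flux cosine factor (radiance-only weighting).
    """
    raw = []
    for s in dome.sectors:
        sin_e = np.sin(np.radians(s.elevation))
        L = (1.0 + 2.0 * sin_e) / 3.0
        w = L * s.solid_angle * (sin_e if flux_term else 1.0)
        raw.append(w)
    tot = float(np.sum(raw))
    for s, w in zip(dome.sectors, raw):
        s.weight = w / tot
    return dome


@njit(cache=True)
def _fill_polygons(vx, vy, offsets, grid, x0, y0, res):  # pragma: no cover
    ny, nx = grid.shape
    xs = np.empty(64)
    for p in range(len(offsets) - 1):
        a, b = offsets[p], offsets[p + 1]
        ymin, ymax = 1e30, -1e30
        for k in range(a, b):
            if vy[k] < ymin:
                ymin = vy[k]
            if vy[k] > ymax:
                ymax = vy[k]
        r0 = max(0, int(np.floor((ymin - y0) / res - 0.5)))
        r1 = min(ny - 1, int(np.ceil((ymax - y0) / res)))
        for row in range(r0, r1 + 1):
            yc = y0 + (row + 0.5) * res
            m = 0
            for k in range(a, b):
                k2 = a if k == b - 1 else k + 1
                y1, y2 = vy[k], vy[k2]
                if (y1 <= yc < y2) or (y2 <= yc < y1):
                    x1, x2 = vx[k], vx[k2]
                    xs[m] = x1 + (yc - y1) * (x2 - x1) / (y2 - y1)
                    m += 1
            if m < 2:
                continue
            # insertion sort of the crossings
            for i in range(1, m):
                key = xs[i]
                j = i - 1
                while j >= 0 and xs[j] > key:
                    xs[j + 1] = xs[j]
                    j -= 1
                xs[j + 1] = key
            for i in range(0, m - 1, 2):
                c0 = int(np.ceil((xs[i] - x0) / res - 0.5))
                c1 = int(np.floor((xs[i + 1] - x0) / res - 0.5))
                if c0 < 0:
                    c0 = 0
                if c1 > nx - 1:
                    c1 = nx - 1
                for col in range(c0, c1 + 1):
                    grid[row, col] = True


def _projection_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(d, ref)) > 0.999:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _project_2d(leaves: list[Leaf], direction: np.ndarray) -> np.ndarray:
    """Stack of projected polygons, shape (n_leaves, n_vertices, 2)."""
    u, v = _projection_basis(direction)
    P = np.stack([lf.polygon for lf in leaves])  # (N, k, 3)
    return np.stack([P @ u, P @ v], axis=-1)


_MAX_GRID = 1536  # per side; resolution is coarsened beyond this


def projected_area(
    leaves: list[Leaf], direction: np.ndarray, resolution: float = 2e-3
) -> float:
    """PLA for one direction: rasterized silhouette area in m^2.

    Overlapping leaves count once.  `resolution` is metres per pixel; it
    is tightened to a tenth of the smallest leaf width when coarser, and
    relaxed if the canopy extent would exceed the maximum grid size.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if not leaves:
        return 0.0
    median_area = float(np.median([lf.area for lf in leaves]))
    width = 2.0 * np.sqrt(median_area / (2.0 * np.pi))  # minor axis, 2:1 ellipse
    if resolution > width / 2.0:
        warnings.warn(
            "projection resolution is coarser than half the typical leaf "
            "width; accuracy contract void",
            stacklevel=2,
        )
    res = min(resolution, max(width / 10.0, 1e-5))
    pts = _project_2d(leaves, direction)
    lo = pts.reshape(-1, 2).min(axis=0) - res
    hi = pts.reshape(-1, 2).max(axis=0) + res
    extent = float(max(hi - lo))
    if extent / res > _MAX_GRID:
        res = extent / _MAX_GRID
    nx = int(np.ceil((hi[0] - lo[0]) / res)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / res)) + 1
    grid = np.zeros((ny, nx), dtype=np.bool_)
    k = pts.shape[1]
    vx = np.ascontiguousarray(pts[:, :, 0].ravel())
    vy = np.ascontiguousarray(pts[:, :, 1].ravel())
    offsets = np.arange(0, (pts.shape[0] + 1) * k, k, dtype=np.int64)
    _fill_polygons(vx, vy, offsets, grid, float(lo[0]), float(lo[1]), res)
    return float(grid.sum()) * res * res


def projected_area_mc(
    leaves: list[Leaf],
    direction: np.ndarray,
    n_rays: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo ray-sampling PLA estimate (independent of the rasterizer).

    Uniform rays over the projected bounding box; a ray hits the crown if
    its footprint lies inside any projected leaf polygon (point-in-polygon
    via shapely, a separate geometry kernel).
    """
    import shapely
    from shapely.geometry import Polygon
    from shapely.ops import unary_union

    if not leaves:
        return 0.0
    rng = rng or np.random.default_rng(0)
    pts = _project_2d(leaves, direction)
    union = unary_union([Polygon(p) for p in pts])
    lo = pts.reshape(-1, 2).min(axis=0)
    hi = pts.reshape(-1, 2).max(axis=0)
    box_area = float(np.prod(hi - lo))
    xs = rng.uniform(lo[0], hi[0], n_rays)
    ys = rng.uniform(lo[1], hi[1], n_rays)
    hits = shapely.contains_xy(union, xs, ys)
    return box_area * float(np.mean(hits))


def projected_area_exact(leaves: list[Leaf], direction: np.ndarray) -> float:
    """Exact PLA via polygon union (cross-check oracle)."""
    from shapely.geometry import Polygon
    from shapely.ops import unary_union

    if not leaves:
        return 0.0
    pts = _project_2d(leaves, direction)
    return float(unary_union([Polygon(p) for p in pts]).area)


def directional_star(
    leaves: list[Leaf], direction: np.ndarray, resolution: float = 2e-3
) -> float:
    """STAR for one direction: projected over total leaf area, in [0, 1]."""
    tla = total_leaf_area(leaves)
    if tla <= 0:
        raise ValueError("directional STAR undefined for zero total leaf area")
    return min(projected_area(leaves, direction, resolution) / tla, 1.0)


def integrated_star(
    leaves: list[Leaf], dome: SkyDome, resolution: float = 2e-3
) -> StarResult:
    """Sky-integrated STAR: weighted sum of the per-sector directional STARs."""
    tla = total_leaf_area(leaves)
    if tla <= 0:
        raise ValueError("integrated STAR undefined for zero total leaf area")
    wsum = sum(s.weight for s in dome.sectors)
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError("dome weights must be set (sum to 1); call soc_weights")
    per = []
    total = 0.0
    for s in dome.sectors:
        pla = projected_area(leaves, s.direction, resolution)
        star_d = min(pla / tla, 1.0)
        per.append((s.direction, pla, star_d))
        total += s.weight * star_d
    return StarResult(tla=tla, per_direction=per, star_integrated=total)
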