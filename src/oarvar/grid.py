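"""Voxel grids, rasterization and signed-distance fields.

Volumes for the statistical endpoints are computed grid-free from polygon
areas (slab summation); the overlap and surface endpoints work on binary
masks rasterized on a shared :class:`GridSpec`.  Arrays are indexed
``[ix, iy, iz]`` matching the (x, y, z) LPS axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.validation import make_valid

from .contours import Delineation, Polygon2D

logger = logging.getLogger(__name__)

DEFAULT_SPACING = (1.0, 1.0, 2.0)


class GridExtentError(ValueError):
    """A delineation's bounding box is not covered by the grid."""


class DegenerateMaskError(ValueError):
    """Operation undefined on an empty or full mask."""


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid; ``origin`` is the centre of voxel (0, 0, 0), mm."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        origin = tuple(float(v) for v in self.origin)
        spacing = tuple(float(v) for v in self.spacing)
        shape = tuple(int(v) for v in self.shape)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {spacing}")
        if any(n < 1 for n in shape):
            raise ValueError(f"shape must be >= 1 per axis, got {shape}")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "shape", shape)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis, mm."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer (voxel-edge) bounding box of the grid: (low, high), mm."""
        o = np.asarray(self.origin)
        sp = np.asarray(self.spacing)
        n = np.asarray(self.shape)
        return o - sp / 2.0, o + (n - 0.5) * sp

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel-index coordinates of world points (n, 3)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    @classmethod
    def from_bounds(
        cls,
        low: Sequence[float],
        high: Sequence[float],
        spacing: Sequence[float] = DEFAULT_SPACING,
        margin: float = 2.0,
    ) -> "GridSpec":
        """Smallest grid whose voxel centres cover [low - margin, high + margin]."""
        low = np.asarray(low, dtype=float) - margin
        high = np.asarray(high, dtype=float) + margin
        sp = np.asarray(spacing, dtype=float)
        shape = np.maximum(1, np.ceil((high - low) / sp).astype(int) + 1)
        return cls(tuple(low), tuple(sp), tuple(int(n) for n in shape))


@dataclass(frozen=True)
class BinaryMask:
    """Boolean occupancy per voxel of ``grid``."""

    grid: GridSpec
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != self.grid.shape:
            raise ValueError(
                f"occupancy shape {occ.shape} != grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "occupancy", occ)

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not self.occupancy.any()

    def is_full(self) -> bool:
        return bool(self.occupancy.all())


@dataclass(frozen=True)
class ScalarField:
    """Finite real value per voxel; mm units when a distance field."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.shape:
            raise ValueError(
                f"values shape {vals.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("scalar field contains non-finite values")
        object.__setattr__(self, "values", vals)

    def sample(self, xyz: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at world points (n, 3); clamps at edges."""
        idx = self.grid.world_to_index(xyz)
        return ndimage.map_coordinates(
            self.values, idx.T, order=1, mode="nearest"
        )


# ---------------------------------------------------------------------------
# areas and volumes (grid-free)
# ---------------------------------------------------------------------------


def polygon_area(p: Polygon2D) -> float:
    """Shoelace area in mm^2, orientation-independent."""
    v = p.as_array()
    x, y = v[:, 0], v[:, 1]
    return abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _slice_net_area(polygons: Iterable[Polygon2D]) -> float:
    """Even-odd net area of the polygons on one slice, mm^2.

    The symmetric difference (XOR) of the polygon interiors realises the
    even-odd rule for nested, disjoint and overlapping parts.
    """
    shapes = []
    for p in polygons:
        g = _ShapelyPolygon(p.vertices)
        if not g.is_valid:
            g = make_valid(g)
        shapes.append(g)
    if not shapes:
        return 0.0
    return reduce(lambda a, b: a.symmetric_difference(b), shapes).area


def delineation_volume(d: Delineation) -> float:
    """Slab-sum volume of a delineation in cm^3, independent of any grid."""
    if d.is_empty():
        logger.warning("empty delineation %s: volume 0", d.key)
        return 0.0
    total_mm3 = sum(
        _slice_net_area(s.polygons) * d.slice_spacing for s in d.slices
    )
    return total_mm3 / 1000.0


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _polygon_parity(
    poly: Polygon2D, xs: np.ndarray, ys: np.ndarray
) -> np.ndarray:
    """Crossing-number parity of one polygon on the (xs × ys) point lattice.

    Half-open convention: a point exactly on an edge counts as inside iff a
    ray in +x from it crosses the edge under the strict ``(y1 > y) != (y2 > y)``
    rule, which admits "lower" edges and excludes "upper" ones.
    """
    v = poly.as_array()
    n = len(v)
    inside = np.zeros((xs.size, ys.size), dtype=bool)
    X = xs[:, None]
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if y1 == y2:
            continue
        straddles = (y1 > ys) != (y2 > ys)  # (ny,)
        with np.errstate(invalid="ignore"):
            xint = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        inside ^= straddles & (X < xint)
    return inside


def rasterize(d: Delineation, grid: GridSpec) -> BinaryMask:
    """Voxelize a delineation: centre-in-polygon under the even-odd rule.

    Each contour slice is matched to the nearest grid z-plane within dz/2.
    Raises :class:`GridExtentError` if the delineation's bounding box is not
    covered by the grid.
    """
    occ = np.zeros(grid.shape, dtype=bool)
    if d.is_empty():
        return BinaryMask(grid, occ)
    _check_extent(d, grid)
    xs = grid.axis_centers(0)
    ys = grid.axis_centers(1)
    dz = grid.spacing[2]
    z0 = grid.origin[2]
    for s in d.slices:
        k = int(round((s.z - z0) / dz))
        if k < 0 or k >= grid.shape[2] or abs(s.z - (z0 + k * dz)) > dz / 2 + 1e-9:
            raise GridExtentError(
                f"slice z={s.z} mm has no grid plane within dz/2 (axis z)"
            )
        plane = np.zeros((grid.shape[0], grid.shape[1]), dtype=bool)
        for poly in s.polygons:
            plane ^= _polygon_parity(poly, xs, ys)
        occ[:, :, k] |= plane
    return BinaryMask(grid, occ)


def _check_extent(d: Delineation, grid: GridSpec) -> None:
    lo, hi = grid.bounds()
    pts = np.concatenate(
        [p.as_array() for s in d.slices for p in s.polygons], axis=0
    )
    zmin, zmax = d.slices[0].z, d.slices[-1].z
    bbox_lo = np.array([pts[:, 0].min(), pts[:, 1].min(), zmin])
    bbox_hi = np.array([pts[:, 0].max(), pts[:, 1].max(), zmax])
    overflow = [
        "xyz"[a]
        for a in range(3)
        if bbox_lo[a] < lo[a] - 1e-9 or bbox_hi[a] > hi[a] + 1e-9
    ]
    if overflow:
        raise GridExtentError(
            f"delineation bounding box exceeds grid on axes {overflow}"
        )


def delineation_bounds(d: Delineation) -> tuple[np.ndarray, np.ndarray]:
    """(low, high) corners of a delineation's bounding box in mm."""
    pts = np.concatenate(
        [p.as_array() for s in d.slices for p in s.polygons], axis=0
    )
    lo = np.array([pts[:, 0].min(), pts[:, 1].min(), d.slices[0].z])
    hi = np.array([pts[:, 0].max(), pts[:, 1].max(), d.slices[-1].z])
    return lo, hi


# ---------------------------------------------------------------------------
# signed distance
# ---------------------------------------------------------------------------


def mask_surface_points(m: BinaryMask) -> np.ndarray:
    """Vertices (n, 3 mm) of the 0.5-isosurface of a mask's occupancy.

    The field is zero-padded by one voxel so the surface is closed even when
    the structure touches the grid edge.
    """
    from skimage.measure import marching_cubes

    occ = np.pad(m.occupancy.astype(float), 1)
    verts, _, _, _ = marching_cubes(occ, level=0.5, spacing=m.grid.spacing)
    origin = np.asarray(m.grid.origin) - np.asarray(m.grid.spacing)
    return verts + origin


def signed_distance(m: BinaryMask) -> ScalarField:
    """Signed Euclidean distance (mm) to the mask's 0.5-isosurface.

    Negative inside, positive outside; anisotropic voxel spacing respected.
    Distances are measured to the marching-cubes surface of the occupancy
    field, which places the boundary sub-voxel (midway between the last
    occupied and first free voxel centre) instead of on voxel centres, so
    values are unbiased to ~half a voxel.
    """
    from scipy.spatial import cKDTree

    if m.is_empty() or m.is_full():
        raise DegenerateMaskError("signed distance undefined for empty/full mask")
    surface = mask_surface_points(m)
    tree = cKDTree(surface)
    xs, ys, zs = (m.grid.axis_centers(a) for a in range(3))
    centers = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    dist, _ = tree.query(centers.reshape(-1, 3), workers=-1)
    dist = dist.reshape(m.grid.shape)
    return ScalarField(m.grid, np.where(m.occupancy, -dist, dist))
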