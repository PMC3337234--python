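"""Median contour surface over observers and regional 3D standard deviations.

The consensus ("median") surface is the 0.5 iso-surface of the mean
occupancy over observer masks — for five observers the boundary of the
3-of-5 majority region, extracted with marching cubes for sub-voxel
placement.  At each surface vertex the signed distances to every observer's
structure are sampled; their sample SD (n-1) is the local 3D SD, averaged
over vertices for the global value and per anatomical sub-region for the
regional values.

Sub-region rules supported:

* cap rule — the top / bottom N occupied z-planes are cranial / caudal;
* landmark rule — z thresholds split cranial / medial / caudal (spinal cord);
* closed-slice rule — contiguous runs of "unclosed" planes (no enclosed
  background in the transverse majority mask) at the top / bottom become the
  cranial / caudal caps (thyroid cartilage);
* quadrant rule — remaining vertices are split into medial / lateral /
  anterior / posterior around the per-slice centroid, with the medial
  quadrant facing the patient midline according to laterality (LPS frame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes

from .grid import BinaryMask, DegenerateMaskError, GridSpec, signed_distance

logger = logging.getLogger(__name__)

REGION_LABELS = ("cranial", "caudal", "medial", "lateral", "anterior", "posterior")


@dataclass(frozen=True)
class MedianSurface:
    """Triangulated consensus surface in mm patient coordinates."""

    vertices: np.ndarray  # (n, 3) float
    triangles: np.ndarray  # (m, 3) int
    grid: GridSpec
    vertex_region: np.ndarray | None = None  # (n,) str labels

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.triangles, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def enclosed_volume_mm3(self) -> float:
        """Volume enclosed by the surface (divergence theorem over tetrahedra)."""
        v = self.vertices
        t = self.triangles
        a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
        return abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0

    def edge_face_counts(self) -> dict[tuple[int, int], int]:
        """How many triangles share each undirected edge (2 iff watertight)."""
        counts: dict[tuple[int, int], int] = {}
        for tri in self.triangles:
            for i, j in ((0, 1), (1, 2), (2, 0)):
                e = (min(tri[i], tri[j]), max(tri[i], tri[j]))
                counts[e] = counts.get(e, 0) + 1
        return counts


@dataclass(frozen=True)
class LocalSDField:
    """Per-vertex SD of observer distances plus its global/regional means."""

    vertex_sd: np.ndarray  # (n,) mm
    global_sd: float  # mm
    n_observers: int
    regional_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sd = np.asarray(self.vertex_sd, dtype=float)
        if np.any(sd < 0):
            raise ValueError("vertex sd must be >= 0")
        object.__setattr__(self, "vertex_sd", sd)


@dataclass(frozen=True)
class RegionSpec:
    """Parameters of the sub-region rules for one organ."""

    organ: str
    cranial_slices: int | None = None
    caudal_slices: int | None = None
    landmarks: tuple[float, float] | None = None  # (z_c1_bottom, z_t1_bottom), mm
    quadrants: bool = True
    closed_slice_rule: bool = False
    caps_exclusive: bool = True

    def __post_init__(self) -> None:
        for n in (self.cranial_slices, self.caudal_slices):
            if n is not None and n < 1:
                raise ValueError("cap slice counts must be >= 1")
        if self.landmarks is not None:
            hi, lo = self.landmarks
            if not hi > lo:
                raise ValueError(
                    f"landmarks must be strictly decreasing in z, got {self.landmarks}"
                )


def default_region_specs(
    cord_landmarks: tuple[float, float] = (40.0, -60.0),
) -> dict[str, RegionSpec]:
    """Region rules for the seven studied structures, keyed by organ label."""
    specs = {
        "parotid_left": RegionSpec("parotid_left", 5, 5),
        "parotid_right": RegionSpec("parotid_right", 5, 5),
        "submandibular_left": RegionSpec("submandibular_left", 3, 3),
        "submandibular_right": RegionSpec("submandibular_right", 3, 3),
        "spinal_cord": RegionSpec(
            "spinal_cord", landmarks=cord_landmarks, quadrants=False
        ),
        "thyroid_cartilage": RegionSpec("thyroid_cartilage", closed_slice_rule=True),
        "glottic_larynx": RegionSpec("glottic_larynx", 1, 1),
    }
    return specs


# ---------------------------------------------------------------------------
# surface construction and distances
# ---------------------------------------------------------------------------


def mean_occupancy(masks: Sequence[BinaryMask]) -> np.ndarray:
    if len(masks) < 2:
        raise ValueError("need >= 2 observer masks")
    grid = masks[0].grid
    for m in masks[1:]:
        if m.grid != grid:
            raise ValueError("all masks must share one grid")
    return np.mean([m.occupancy for m in masks], axis=0)


def compute_median_surface(masks: Sequence[BinaryMask]) -> MedianSurface:
    """0.5 iso-surface of the mean observer occupancy.

    Voxels where the occupancy fraction is exactly 0.5 (possible for even
    observer counts) fall *outside*: the interior is the strict majority.
    Raises :class:`DegenerateMaskError` when no voxel has strict majority.
    """
    grid = masks[0].grid
    occ = mean_occupancy(masks)
    if not np.any(occ > 0.5):
        raise DegenerateMaskError("no strict-majority voxel; median surface undefined")
    # ties (exactly half the observers) are non-majority: they drop to 0 so
    # the iso-surface hugs the strict-majority region instead of being
    # dragged a voxel outward by interpolation against a 0.5-epsilon shell
    occ = np.where(np.isclose(occ, 0.5), 0.0, occ)
    padded = np.pad(occ, 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=grid.spacing)
    origin = np.asarray(grid.origin) - np.asarray(grid.spacing)
    return MedianSurface(vertices=verts + origin, triangles=faces, grid=grid)


def majority_mask(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Strict-majority occupancy voxels (> 0.5 mean occupancy)."""
    return BinaryMask(masks[0].grid, mean_occupancy(masks) > 0.5)


def local_sd(
    surface: MedianSurface,
    observer_masks: Sequence[BinaryMask],
    signed: bool = True,
) -> LocalSDField:
    """Per-vertex SD of the observers' (signed) distances to each vertex.

    Each observer's signed-distance field is sampled at the vertices by
    trilinear interpolation; degenerate observer masks are excluded with a
    warning.  ``signed=False`` switches to absolute distances.
    """
    dists = []
    for i, m in enumerate(observer_masks):
        try:
            sdf = signed_distance(m)
        except DegenerateMaskError:
            logger.warning("observer mask %d degenerate; excluded from local SD", i)
            continue
        d = sdf.sample(surface.vertices)
        dists.append(np.abs(d) if not signed else d)
    if len(dists) < 2:
        raise DegenerateMaskError("need >= 2 usable observer masks for local SD")
    stack = np.vstack(dists)
    vertex_sd = stack.std(axis=0, ddof=1)
    return LocalSDField(
        vertex_sd=vertex_sd,
        global_sd=float(vertex_sd.mean()),
        n_observers=len(dists),
    )


# ---------------------------------------------------------------------------
# sub-region assignment
# ---------------------------------------------------------------------------


def _plane_indices(surface: MedianSurface) -> np.ndarray:
    """Nearest grid z-plane index for every vertex."""
    z0 = surface.grid.origin[2]
    dz = surface.grid.spacing[2]
    idx = np.round((surface.vertices[:, 2] - z0) / dz).astype(int)
    # marching-cubes vertices can sit half a voxel beyond the outermost plane
    return np.clip(idx, 0, surface.grid.shape[2] - 1)


def _closed_planes(mask: BinaryMask, planes: np.ndarray) -> dict[int, bool]:
    """A plane is 'closed' iff its transverse slice encloses background."""
    closed = {}
    for k in planes:
        sl = mask.occupancy[:, :, k]
        if not sl.any():
            closed[int(k)] = False
            continue
        closed[int(k)] = bool((ndimage.binary_fill_holes(sl) & ~sl).any())
    return closed


def assign_regions(
    surface: MedianSurface,
    spec: RegionSpec,
    laterality: str,
    majority: BinaryMask | None = None,
) -> np.ndarray:
    """Label every vertex with exactly one sub-region.

    ``majority`` (the strict-majority mask) is only needed for the
    closed-slice rule.  Returns an (n,) array of labels.
    """
    n = surface.n_vertices
    labels = np.empty(n, dtype=object)
    v = surface.vertices

    if spec.landmarks is not None:
        z_hi, z_lo = spec.landmarks
        labels[:] = "medial"
        labels[v[:, 2] > z_hi] = "cranial"
        labels[v[:, 2] < z_lo] = "caudal"
        return labels.astype(str)

    plane_of_vertex = _plane_indices(surface)
    occupied = np.unique(plane_of_vertex)

    if spec.closed_slice_rule:
        if majority is None:
            raise ValueError("closed-slice rule needs the strict-majority mask")
        closed = _closed_planes(majority, occupied)
        cranial_planes, caudal_planes = set(), set()
        for k in occupied[::-1]:  # from the top down
            if closed[int(k)]:
                break
            cranial_planes.add(int(k))
        for k in occupied:  # from the bottom up
            if closed[int(k)] or int(k) in cranial_planes:
                break
            caudal_planes.add(int(k))
    else:
        n_cr = spec.cranial_slices or 0
        n_ca = spec.caudal_slices or 0
        if n_cr + n_ca >= len(occupied):
            logger.warning(
                "organ %s: only %d occupied planes for %d cap slices; "
                "splitting caps at the midplane",
                spec.organ, len(occupied), n_cr + n_ca,
            )
            mid = occupied[len(occupied) // 2]
            cranial_planes = {int(k) for k in occupied if k >= mid}
            caudal_planes = {int(k) for k in occupied if k < mid}
        else:
            cranial_planes = {int(k) for k in occupied[len(occupied) - n_cr:]}
            caudal_planes = {int(k) for k in occupied[:n_ca]}

    is_cranial = np.isin(plane_of_vertex, list(cranial_planes))
    is_caudal = np.isin(plane_of_vertex, list(caudal_planes))
    labels[is_cranial] = "cranial"
    labels[is_caudal] = "caudal"

    body = ~(is_cranial | is_caudal) if spec.caps_exclusive else np.ones(n, bool)
    if spec.quadrants:
        _assign_quadrants(v, plane_of_vertex, body, labels, laterality)
    else:
        labels[body & (labels == None)] = "medial"  # noqa: E711
    # caps always win when not exclusive
    labels[is_cranial] = "cranial"
    labels[is_caudal] = "caudal"
    unset = labels == None  # noqa: E711
    if unset.any():
        labels[unset] = "medial"
    return labels.astype(str)


def _assign_quadrants(
    v: np.ndarray,
    plane_of_vertex: np.ndarray,
    which: np.ndarray,
    labels: np.ndarray,
    laterality: str,
) -> None:
    """Medial/lateral/anterior/posterior around the per-slice centroid (LPS).

    The midline sits at the patient's centre: for a left-sided organ (+x
    half-space) the medial quadrant faces -x, for a right-sided organ +x.
    Midline organs use the left convention.
    """
    medial_sign = -1.0 if laterality in ("left", "midline") else 1.0
    for k in np.unique(plane_of_vertex[which]):
        on_plane = which & (plane_of_vertex == k)
        if not on_plane.any():
            continue
        cx, cy = v[on_plane, 0].mean(), v[on_plane, 1].mean()
        dx = v[on_plane, 0] - cx
        dy = v[on_plane, 1] - cy
        lateral_first = np.abs(dx) >= np.abs(dy)
        sub = np.empty(on_plane.sum(), dtype=object)
        sub[lateral_first & (medial_sign * dx >= 0)] = "medial"
        sub[lateral_first & (medial_sign * dx < 0)] = "lateral"
        sub[~lateral_first & (dy < 0)] = "anterior"
        sub[~lateral_first & (dy >= 0)] = "posterior"
        labels[on_plane] = sub


def regional_sd(field_: LocalSDField, labels: np.ndarray) -> dict[str, float]:
    """Unweighted mean of the per-vertex SD within each region label."""
    labels = np.asarray(labels)
    if labels.shape[0] != field_.vertex_sd.shape[0]:
        raise ValueError("labels must cover all vertices")
    out = {}
    for label in np.unique(labels):
        sel = labels == label
        if sel.any():
            out[str(label)] = float(field_.vertex_sd[sel].mean())
    return out


def with_regions(
    surface: MedianSurface, labels: np.ndarray
) -> MedianSurface:
    return replace(surface, vertex_region=np.asarray(labels, dtype=object))


# ---------------------------------------------------------------------------
# PLY export
# ---------------------------------------------------------------------------


def write_ply(
    surface: MedianSurface,
    path: str | Path,
    vertex_sd: np.ndarray | None = None,
) -> None:
    """ASCII PLY export with per-vertex sd and region-code properties."""
    n, m = surface.n_vertices, len(surface.triangles)
    sd = np.zeros(n) if vertex_sd is None else np.asarray(vertex_sd, dtype=float)
    if surface.vertex_region is not None:
        region_names = sorted({str(r) for r in surface.vertex_region})
        codes = {r: i for i, r in enumerate(region_names)}
        region_code = [codes[str(r)] for r in surface.vertex_region]
    else:
        region_names, region_code = [], [0] * n
    lines = [
        "ply",
        "format ascii 1.0",
        f"comment region codes: {', '.join(f'{i}={r}' for r, i in sorted(codes.items(), key=lambda kv: kv[1])) if region_names else 'none'}",
        f"element vertex {n}",
        "property float x",
        "property float y",
        "property float z",
        "property float sd",
        "property uchar region",
        f"element face {m}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for (x, y, z), s, c in zip(surface.vertices, sd, region_code):
        lines.append(f"{x:.4f} {y:.4f} {z:.4f} {s:.4f} {c}")
    for a, b, c in surface.triangles:
        lines.append(f"3 {a} {b} {c}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
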