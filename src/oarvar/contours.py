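"""Planar contour data model and bespoke JSON on-disk format.

A :class:`Delineation` is one observer's contour stack for one organ on one
scan: closed planar polygons at fixed axial (z) levels, in the DICOM LPS
patient frame (+x patient-left, +y posterior, +z cranial), all coordinates
in millimetres.  Multiple polygons on one slice are combined with the
even-odd rule, so holes and disjoint parts need no orientation bookkeeping.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping

import numpy as np

logger = logging.getLogger(__name__)

SCAN_TIMES = ("plan", "rep")
LATERALITIES = ("left", "right", "midline")

#: absolute tolerance (mm) used when checking slice-spacing commensurability
_SPACING_ATOL = 1e-6


class ContourValidationError(ValueError):
    """A contour object violates a structural invariant."""


class ContourParseError(ValueError):
    """An on-disk contour file does not conform to the schema."""


@dataclass(frozen=True)
class Polygon2D:
    """Implicitly closed planar polygon; vertices in mm, counter- or clockwise."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) >= 2 and verts[0] == verts[-1]:
            logger.warning("dropping explicitly repeated closing vertex")
            verts = verts[:-1]
        if len(verts) < 3:
            raise ContourValidationError(
                f"polygon needs >= 3 vertices, got {len(verts)}"
            )
        for (x0, y0), (x1, y1) in zip(verts, verts[1:]):
            if x0 == x1 and y0 == y1:
                raise ContourValidationError("consecutive duplicate vertices")
        for x, y in verts:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ContourValidationError(f"non-finite coordinate ({x}, {y})")
        object.__setattr__(self, "vertices", verts)

    def __len__(self) -> int:
        return len(self.vertices)

    def as_array(self) -> np.ndarray:
        """Vertices as an (n, 2) float array."""
        return np.asarray(self.vertices, dtype=float)


@dataclass(frozen=True)
class ContourSlice:
    """All polygons of one structure on one axial plane (even-odd semantics)."""

    z: float
    polygons: tuple[Polygon2D, ...]

    def __post_init__(self) -> None:
        z = float(self.z)
        if not math.isfinite(z):
            raise ContourValidationError(f"non-finite slice z {z!r}")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "polygons", tuple(self.polygons))


@dataclass(frozen=True)
class Delineation:
    """One observer's contour stack for one organ on one scan.

    Slices are stored sorted ascending in z; occupied slices need not be
    contiguous but must sit on a lattice of pitch ``slice_spacing``.
    """

    patient_id: str
    scan_time: str
    observer_id: str
    organ: str
    laterality: str
    slice_spacing: float
    slices: tuple[ContourSlice, ...]

    def __post_init__(self) -> None:
        if self.scan_time not in SCAN_TIMES:
            raise ContourValidationError(
                f"scan_time must be one of {SCAN_TIMES}, got {self.scan_time!r}"
            )
        if self.laterality not in LATERALITIES:
            raise ContourValidationError(
                f"laterality must be one of {LATERALITIES}, got {self.laterality!r}"
            )
        spacing = float(self.slice_spacing)
        if not (math.isfinite(spacing) and spacing > 0):
            raise ContourValidationError(f"slice_spacing must be > 0, got {spacing}")
        slices = tuple(sorted(self.slices, key=lambda s: s.z))
        zs = [s.z for s in slices]
        for z0, z1 in zip(zs, zs[1:]):
            if z1 <= z0:
                raise ContourValidationError(
                    f"slice z values must be strictly increasing, found {z0} then {z1}"
                )
            gap = z1 - z0
            n = round(gap / spacing)
            if n < 1 or abs(gap - n * spacing) > _SPACING_ATOL:
                raise ContourValidationError(
                    f"slice gap {gap} mm is not an integer multiple of "
                    f"slice_spacing {spacing} mm"
                )
        object.__setattr__(self, "slice_spacing", spacing)
        object.__setattr__(self, "slices", slices)

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.patient_id, self.scan_time, self.observer_id, self.organ)

    @property
    def z_values(self) -> np.ndarray:
        return np.asarray([s.z for s in self.slices], dtype=float)

    def is_empty(self) -> bool:
        return len(self.slices) == 0


@dataclass
class DelineationSet:
    """A collection of delineations sharing one patient coordinate frame."""

    delineations: list[Delineation] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str, str]] = set()
        for d in self.delineations:
            if d.key in seen:
                raise ContourValidationError(
                    f"duplicate delineation key {d.key}"
                )
            seen.add(d.key)

    def __len__(self) -> int:
        return len(self.delineations)

    def __iter__(self) -> Iterator[Delineation]:
        return iter(self.delineations)

    def organs(self) -> list[str]:
        return sorted({d.organ for d in self.delineations})

    def observers(self) -> list[str]:
        return sorted({d.observer_id for d in self.delineations})

    def patients(self) -> list[str]:
        return sorted({d.patient_id for d in self.delineations})

    def subset(self, **filters: str) -> "DelineationSet":
        """Filter by any of patient_id / scan_time / observer_id / organ."""
        kept = [
            d
            for d in self.delineations
            if all(getattr(d, k) == v for k, v in filters.items())
        ]
        return DelineationSet(kept, dict(self.metadata))


# ---------------------------------------------------------------------------
# bespoke JSON format
# ---------------------------------------------------------------------------


def _round6(x: float) -> float:
    if not math.isfinite(x):
        raise ContourValidationError(f"non-finite coordinate {x!r}")
    return round(float(x), 6)


def _delineation_to_json(d: Delineation) -> dict[str, Any]:
    return {
        "patient_id": d.patient_id,
        "scan_time": d.scan_time,
        "observer_id": d.observer_id,
        "organ": d.organ,
        "laterality": d.laterality,
        "slice_spacing_mm": _round6(d.slice_spacing),
        "slices": [
            {
                "z_mm": _round6(s.z),
                "polygons": [
                    [[_round6(x), _round6(y)] for x, y in p.vertices]
                    for p in s.polygons
                ],
            }
            for s in d.slices
        ],
    }


def write_contour_set(cset: DelineationSet, path: str | Path) -> None:
    """Write a :class:`DelineationSet` as canonical JSON.

    Keys are sorted, floats rounded to 6 decimals, so re-exporting an
    unchanged set is byte-identical.
    """
    doc = {
        "metadata": cset.metadata,
        "delineations": [_delineation_to_json(d) for d in cset.delineations],
    }
    text = json.dumps(doc, sort_keys=True, indent=1, ensure_ascii=False)
    Path(path).write_text(text + "\n", encoding="utf-8")


def _parse_delineation(rec: Mapping[str, Any], index: int) -> Delineation:
    try:
        slices = tuple(
            ContourSlice(
                z=s["z_mm"],
                polygons=tuple(Polygon2D(tuple(map(tuple, poly))) for poly in s["polygons"]),
            )
            for s in rec["slices"]
        )
        return Delineation(
            patient_id=str(rec["patient_id"]),
            scan_time=str(rec["scan_time"]),
            observer_id=str(rec["observer_id"]),
            organ=str(rec["organ"]),
            laterality=str(rec["laterality"]),
            slice_spacing=rec["slice_spacing_mm"],
            slices=slices,
        )
    except KeyError as exc:
        raise ContourParseError(
            f"delineation record {index}: missing field {exc}"
        ) from exc
    except (TypeError, ContourValidationError) as exc:
        raise ContourValidationError(
            f"delineation record {index}: {exc}"
        ) from exc


def load_contour_set(path: str | Path) -> DelineationSet:
    """Load and validate a contour set from the bespoke JSON format."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ContourParseError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "delineations" not in doc:
        raise ContourParseError(f"{path}: missing top-level 'delineations' list")
    records = doc["delineations"]
    if not isinstance(records, list):
        raise ContourParseError(f"{path}: 'delineations' must be a list")
    delins = [_parse_delineation(rec, i) for i, rec in enumerate(records)]
    return DelineationSet(delins, dict(doc.get("metadata", {})))
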