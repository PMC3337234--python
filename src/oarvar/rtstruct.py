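"""Read-only DICOM RT Structure Set adapter (requires the optional pydicom).

Each ROI of the structure set becomes one :class:`Delineation`; contour
triplets are interpreted in the LPS patient frame (mm).  Only planar axial
contours are supported.  Install with ``pip install oarvar[dicom]``.
"""

from __future__ import annotations

import logging
from collections import defaultdict

from .contours import (
    ContourParseError,
    ContourSlice,
    Delineation,
    DelineationSet,
    Polygon2D,
)

logger = logging.getLogger(__name__)

_Z_PLANARITY_TOL = 1e-3  # mm


class UnsupportedGeometryError(ValueError):
    """Contour data is not planar-axial."""


def _guess_laterality(roi_name: str) -> str:
    lowered = roi_name.lower()
    if any(tag in lowered for tag in ("_l", " l", "left", "lt_")):
        return "left"
    if any(tag in lowered for tag in ("_r", " r", "right", "rt_")):
        return "right"
    return "midline"


def load_rtstruct(
    path,
    ct_slice_spacing: float,
    patient_id: str | None = None,
    observer_id: str | None = None,
    scan_time: str = "plan",
) -> DelineationSet:
    """Load a DICOM RT Structure Set into a :class:`DelineationSet`.

    ``patient_id`` / ``observer_id`` default to the PatientID and
    OperatorsName tags.  ROIs without a name are skipped with a warning;
    non-axial contour planes raise :class:`UnsupportedGeometryError`.
    """
    try:
        import pydicom
        from pydicom.errors import InvalidDicomError
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading RT Structure Sets requires pydicom "
            "(pip install oarvar[dicom])"
        ) from exc

    try:
        ds = pydicom.dcmread(path)
    except InvalidDicomError as exc:
        raise ContourParseError(f"{path}: not a DICOM file: {exc}") from exc
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise ContourParseError(f"{path}: not an RT Structure Set (Modality)")

    patient_id = patient_id or str(getattr(ds, "PatientID", "unknown"))
    observer_id = observer_id or str(getattr(ds, "OperatorsName", "unknown"))

    roi_names = {}
    for roi in getattr(ds, "StructureSetROISequence", []):
        name = getattr(roi, "ROIName", None)
        if not name:
            logger.warning("ROI %s has no name; skipped", roi.ROINumber)
            continue
        roi_names[int(roi.ROINumber)] = str(name)

    delins = []
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        number = int(roi_contour.ReferencedROINumber)
        if number not in roi_names:
            continue
        by_z: dict[float, list[Polygon2D]] = defaultdict(list)
        for contour in getattr(roi_contour, "ContourSequence", []):
            geom = getattr(contour, "ContourGeometricType", "CLOSED_PLANAR")
            if geom not in ("CLOSED_PLANAR", "CLOSEDPLANAR_XOR"):
                raise UnsupportedGeometryError(
                    f"ROI {roi_names[number]!r}: geometry {geom} unsupported"
                )
            data = [float(v) for v in contour.ContourData]
            pts = [(data[i], data[i + 1], data[i + 2]) for i in range(0, len(data), 3)]
            zs = {round(p[2] / _Z_PLANARITY_TOL) for p in pts}
            if len(zs) > 1:
                raise UnsupportedGeometryError(
                    f"ROI {roi_names[number]!r}: contour not in an axial plane"
                )
            z = pts[0][2]
            by_z[round(z, 3)].append(Polygon2D(tuple((p[0], p[1]) for p in pts)))
        slices = tuple(
            ContourSlice(z=z, polygons=tuple(polys))
            for z, polys in sorted(by_z.items())
        )
        delins.append(
            Delineation(
                patient_id=patient_id,
                scan_time=scan_time,
                observer_id=observer_id,
                organ=roi_names[number],
                laterality=_guess_laterality(roi_names[number]),
                slice_spacing=ct_slice_spacing,
                slices=slices,
            )
        )
    if not delins:
        logger.warning("%s: structure set contains no named ROIs", path)
    return DelineationSet(
        delins,
        {"source": "rtstruct", "file": str(path), "patient_id": patient_id},
    )
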