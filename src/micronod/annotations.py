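"""Parsing of LIDC-dialect annotation XML into typed lesion marks.

Each scan's XML holds up to four reading sessions, one per expert reader.
Within a session, lesions appear either as nodule elements carrying an
edge map (one or more ``roi`` blocks of ``edgeMap`` points) or as
non-nodule elements carrying a single ``locus`` point.  The lesion
taxonomy follows the reader protocol:

* **nodule** (3-30 mm): contoured, at least one closed edge map;
* **micro-nodule** (< 3 mm): no contour, a nodule element whose region of
  interest reduces to a single distinct point (the 3-D centre of mass);
* **non-nodule**: a single ``locus`` point — the ``Locus`` keyword is
  unique to this category.

Marks from different readers are kept separate; downstream patch
extraction emits one patch per mark, not per lesion.  Scans duplicated in
the archive (identical slice-identifier sets) are dropped by
:func:`exclude_duplicates`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from lxml import etree

__all__ = [
    "SliceRef",
    "LesionMark",
    "ScanAnnotation",
    "AnnotationParseError",
    "parse_annotation_xml",
    "exclude_duplicates",
    "center_of_mass",
    "marks_to_manifest",
    "CATEGORIES",
]

CATEGORIES = ("nodule", "micro_nodule", "non_nodule")

MANIFEST_COLUMNS = [
    "patient_id", "reader_index", "mark_id", "category",
    "x", "y", "sop_uid", "z_mm",
]


class AnnotationParseError(ValueError):
    """Malformed annotation XML; message names the location of the fault."""


@dataclass(frozen=True)
class SliceRef:
    """Reference to one axial slice by SOP instance UID and/or z position."""

    sop_uid: str | None = None
    z_mm: float | None = None

    def __post_init__(self) -> None:
        if self.sop_uid is None and self.z_mm is None:
            raise ValueError("SliceRef needs a SOP UID or a z position")
        if self.z_mm is not None and not float("-inf") < self.z_mm < float("inf"):
            raise ValueError(f"z_mm must be finite, got {self.z_mm}")


@dataclass(frozen=True)
class LesionMark:
    """One expert's mark on one lesion."""

    mark_id: str
    reader_index: int
    category: str
    points: tuple[tuple[float, float, SliceRef], ...]
    contours: tuple[tuple[SliceRef, tuple[tuple[float, float], ...]], ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not 0 <= self.reader_index <= 3:
            raise ValueError("reader_index must be in 0..3")
        if self.category in ("micro_nodule", "non_nodule"):
            if len(self.points) != 1:
                raise ValueError(
                    f"{self.category} marks carry exactly one centre-of-mass "
                    f"point, got {len(self.points)}"
                )
        elif self.category == "nodule":
            if not any(len(c) >= 3 for _, c in self.contours):
                raise ValueError("nodule marks need a contour with >= 3 points")


@dataclass
class ScanAnnotation:
    """All reading sessions of one scan, plus a series fingerprint."""

    patient_id: str
    series_fingerprint: str
    reading_sessions: list[list[LesionMark]]
    errors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.reading_sessions) > 4:
            raise ValueError("at most four reading sessions per scan")

    def iter_marks(self):
        for session in self.reading_sessions:
            yield from session


def _local(tag) -> str:
    """Tag name with any XML namespace stripped."""
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _find(elem, name):
    for child in elem:
        if _local(child.tag) == name:
            return child
    return None


def _findall(elem, name):
    return [c for c in elem if _local(c.tag) == name]


def _text(elem, name, default=None):
    child = _find(elem, name)
    if child is None or child.text is None:
        return default
    return child.text.strip()


def _slice_ref(roi_elem) -> SliceRef:
    sop = _text(roi_elem, "imageSOP_UID")
    z = _text(roi_elem, "imageZposition")
    return SliceRef(sop_uid=sop, z_mm=float(z) if z is not None else None)


def _parse_nodule(elem, reader_index: int) -> LesionMark:
    mark_id = _text(elem, "noduleID", default="")
    rois = _findall(elem, "roi")
    contours: list[tuple[SliceRef, tuple[tuple[float, float], ...]]] = []
    all_points: list[tuple[float, float, SliceRef]] = []
    for roi in rois:
        ref = _slice_ref(roi)
        pts = []
        for edge in _findall(roi, "edgeMap"):
            x = float(_text(edge, "xCoord"))
            y = float(_text(edge, "yCoord"))
            pts.append((x, y))
            all_points.append((x, y, ref))
        if pts:
            contours.append((ref, tuple(pts)))
    if not all_points:
        raise AnnotationParseError(
            f"nodule element {mark_id!r} has no edge points"
        )
    distinct = {(x, y, ref) for x, y, ref in all_points}
    if len(distinct) == 1:
        # no contour, a single centre-of-mass point: micro-nodule
        return LesionMark(mark_id, reader_index, "micro_nodule",
                          points=(all_points[0],))
    return LesionMark(mark_id, reader_index, "nodule",
                      points=tuple(all_points), contours=tuple(contours))


def _parse_non_nodule(elem, reader_index: int) -> LesionMark:
    mark_id = _text(elem, "nonNoduleID", default="")
    locus = _find(elem, "locus")
    if locus is None:
        raise AnnotationParseError(
            f"non-nodule element {mark_id!r} has no locus"
        )
    ref = _slice_ref(elem)
    x = float(_text(locus, "xCoord"))
    y = float(_text(locus, "yCoord"))
    return LesionMark(mark_id, reader_index, "non_nodule",
                      points=((x, y, ref),))


def parse_annotation_xml(source) -> ScanAnnotation:
    """Parse one scan's annotation XML into a :class:`ScanAnnotation`.

    ``source`` may be a path, bytes, or a string of XML.  Lesion elements
    that carry neither edge points nor a locus are recorded in
    ``ScanAnnotation.errors`` and skipped; the scan is still returned.

    Raises :class:`AnnotationParseError` (naming line, column and
    approximate byte offset) if the document is not well-formed XML.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        data = Path(source).read_bytes()
    elif isinstance(source, bytes):
        data = source
    else:
        data = str(source).encode()
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        line, col = exc.position
        offset = sum(len(l) + 1 for l in data.splitlines()[: line - 1]) + col
        raise AnnotationParseError(
            f"malformed XML at line {line}, column {col} "
            f"(~byte offset {offset}): {exc.msg}"
        ) from exc

    header = _find(root, "ResponseHeader")
    patient_id = ""
    series_uid = ""
    if header is not None:
        patient_id = _text(header, "PatientID", default="") or \
            _text(header, "SeriesInstanceUid", default="")
        series_uid = _text(header, "SeriesInstanceUid", default="") or ""

    sessions: list[list[LesionMark]] = []
    errors: list[str] = []
    sop_uids: set[str] = set()
    for session_elem in _findall(root, "readingSession"):
        reader_index = len(sessions)
        if reader_index > 3:
            raise AnnotationParseError("more than four reading sessions")
        marks: list[LesionMark] = []
        for child in session_elem:
            name = _local(child.tag)
            try:
                if name == "unblindedReadNodule":
                    marks.append(_parse_nodule(child, reader_index))
                elif name == "nonNodule":
                    marks.append(_parse_non_nodule(child, reader_index))
            except (AnnotationParseError, TypeError, ValueError) as exc:
                errors.append(f"session {reader_index}: {exc}")
        for mark in marks:
            for _, _, ref in mark.points:
                if ref.sop_uid:
                    sop_uids.add(ref.sop_uid)
        sessions.append(marks)

    fingerprint_src = ",".join(sorted(sop_uids)) or series_uid
    fingerprint = hashlib.sha256(fingerprint_src.encode()).hexdigest()
    return ScanAnnotation(
        patient_id=patient_id,
        series_fingerprint=fingerprint,
        reading_sessions=sessions,
        errors=errors,
    )


def exclude_duplicates(scans: list[ScanAnnotation]) -> list[ScanAnnotation]:
    """Keep one scan per distinct series fingerprint.

    Among scans sharing a fingerprint the survivor is the one with the
    lexicographically smallest ``patient_id + fingerprint`` key; input
    order is preserved.  Idempotent.
    """
    survivor: dict[str, ScanAnnotation] = {}
    for scan in scans:
        key = scan.series_fingerprint
        if key not in survivor or (
            scan.patient_id + scan.series_fingerprint
            < survivor[key].patient_id + survivor[key].series_fingerprint
        ):
            survivor[key] = scan
    kept = set(map(id, survivor.values()))
    return [s for s in scans if id(s) in kept]


def center_of_mass(mark: LesionMark) -> tuple[float, float, SliceRef]:
    """Centre of mass of a mark.

    Single-point marks return their point unchanged.  Contoured marks
    return the unweighted mean over all contour vertices, with the slice
    reference of the contour slice nearest the mean z (falling back to the
    first contour slice when no z coordinates are available).
    """
    if not mark.points:
        raise ValueError("mark has no points")
    if len(mark.points) == 1:
        return mark.points[0]
    xs = [x for x, _, _ in mark.points]
    ys = [y for _, y, _ in mark.points]
    cx = sum(xs) / len(xs)
    cy = sum(ys) / len(ys)
    refs = [ref for _, _, ref in mark.points]
    zs = [r.z_mm for r in refs if r.z_mm is not None]
    if zs:
        mean_z = sum(zs) / len(zs)
        ref = min((r for r in refs if r.z_mm is not None),
                  key=lambda r: abs(r.z_mm - mean_z))
    else:
        ref = refs[0]
    return cx, cy, ref


def marks_to_manifest(scans: list[ScanAnnotation]) -> pd.DataFrame:
    """Flatten scans into the tabular mark manifest (one row per mark)."""
    rows = []
    for scan in scans:
        for mark in scan.iter_marks():
            x, y, ref = center_of_mass(mark)
            rows.append({
                "patient_id": scan.patient_id,
                "reader_index": mark.reader_index,
                "mark_id": mark.mark_id,
                "category": mark.category,
                "x": x,
                "y": y,
                "sop_uid": ref.sop_uid,
                "z_mm": ref.z_mm,
            })
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
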