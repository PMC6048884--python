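"""LIDC-dialect XML parsing: lesion taxonomy, duplicates, centre of mass."""

import pytest

from micronod.annotations import (
    AnnotationParseError,
    LesionMark,
    ScanAnnotation,
    SliceRef,
    center_of_mass,
    exclude_duplicates,
    marks_to_manifest,
    parse_annotation_xml,
)

NS = 'xmlns="http://www.nih.gov"'


def wrap(body, patient="P1", series="1.2.3"):
    return f"""<?xml version="1.0"?>
<LidcReadMessage {NS}>
  <ResponseHeader>
    <SeriesInstanceUid>{series}</SeriesInstanceUid>
    <PatientID>{patient}</PatientID>
  </ResponseHeader>
  {body}
</LidcReadMessage>"""


def roi(sop, z, points):
    edges = "".join(
        f"<edgeMap><xCoord>{x}</xCoord><yCoord>{y}</yCoord></edgeMap>"
        for x, y in points
    )
    return (f"<roi><imageZposition>{z}</imageZposition>"
            f"<imageSOP_UID>{sop}</imageSOP_UID>"
            f"<inclusion>TRUE</inclusion>{edges}</roi>")


CONTOUR_12 = [(300 + dx, 250 + dy) for dx, dy in
              [(0, 0), (3, 0), (6, 1), (8, 3), (8, 6), (6, 8),
               (3, 9), (0, 9), (-2, 7), (-3, 4), (-3, 2), (-1, 0)]]


class TestCategoryAssignment:
    def test_contoured_nodule(self):
        body = ("<readingSession><unblindedReadNodule>"
                "<noduleID>N1</noduleID>" + roi("S1", 0.0, CONTOUR_12) +
                "</unblindedReadNodule></readingSession>")
        scan = parse_annotation_xml(wrap(body))
        (mark,) = list(scan.iter_marks())
        assert mark.category == "nodule"
        assert len(mark.contours[0][1]) == 12

    def test_locus_element_is_non_nodule(self):
        body = ("<readingSession><nonNodule>"
                "<nonNoduleID>NN1</nonNoduleID>"
                "<imageZposition>2.5</imageZposition>"
                "<imageSOP_UID>S2</imageSOP_UID>"
                "<locus><xCoord>100</xCoord><yCoord>120</yCoord></locus>"
                "</nonNodule></readingSession>")
        scan = parse_annotation_xml(wrap(body))
        (mark,) = list(scan.iter_marks())
        assert mark.category == "non_nodule"
        assert mark.points == ((100.0, 120.0, SliceRef("S2", 2.5)),)

    def test_single_edge_point_is_micro_nodule(self):
        body = ("<readingSession><unblindedReadNodule>"
                "<noduleID>MN1</noduleID>" + roi("S1", 0.0, [(40, 50)]) +
                "</unblindedReadNodule></readingSession>")
        scan = parse_annotation_xml(wrap(body))
        (mark,) = list(scan.iter_marks())
        assert mark.category == "micro_nodule"
        assert mark.points[0][:2] == (40.0, 50.0)

    def test_empty_reading_session_kept(self):
        scan = parse_annotation_xml(wrap("<readingSession></readingSession>"))
        assert len(scan.reading_sessions) == 1
        assert scan.reading_sessions[0] == []

    def test_category_partition_counts(self):
        """Every lesion element maps to exactly one category."""
        body = "<readingSession>"
        for i in range(3):
            body += ("<unblindedReadNodule><noduleID>M%d</noduleID>" % i
                     + roi("S1", 0.0, [(10 + i, 20)]) + "</unblindedReadNodule>")
        body += ("<unblindedReadNodule><noduleID>N0</noduleID>"
                 + roi("S1", 0.0, CONTOUR_12) + "</unblindedReadNodule>")
        for i in range(2):
            body += ("<nonNodule><nonNoduleID>NN%d</nonNoduleID>"
                     "<imageSOP_UID>S1</imageSOP_UID>"
                     "<locus><xCoord>5</xCoord><yCoord>6</yCoord></locus>"
                     "</nonNodule>" % i)
        body += "</readingSession>"
        scan = parse_annotation_xml(wrap(body))
        cats = [m.category for m in scan.iter_marks()]
        assert cats.count("micro_nodule") == 3
        assert cats.count("nodule") == 1
        assert cats.count("non_nodule") == 2


class TestErrorHandling:
    def test_malformed_xml_names_offset(self):
        with pytest.raises(AnnotationParseError, match="byte offset"):
            parse_annotation_xml("<LidcReadMessage><unclosed>")

    def test_lesion_without_points_recorded_not_fatal(self):
        body = ("<readingSession>"
                "<unblindedReadNodule><noduleID>BAD</noduleID></unblindedReadNodule>"
                "<nonNodule><nonNoduleID>NN1</nonNoduleID>"
                "<imageSOP_UID>S1</imageSOP_UID>"
                "<locus><xCoord>1</xCoord><yCoord>2</yCoord></locus>"
                "</nonNodule></readingSession>")
        scan = parse_annotation_xml(wrap(body))
        assert len(list(scan.iter_marks())) == 1
        assert len(scan.errors) == 1 and "BAD" in scan.errors[0]

    def test_too_many_sessions_rejected(self):
        body = "<readingSession/>" * 5
        with pytest.raises((AnnotationParseError, ValueError)):
            parse_annotation_xml(wrap(body))


class TestExcludeDuplicates:
    def mk(self, patient, fingerprint):
        return ScanAnnotation(patient_id=patient,
                              series_fingerprint=fingerprint,
                              reading_sessions=[])

    def test_identical_fingerprints_collapse(self):
        scans = [self.mk("B", "f1"), self.mk("A", "f1")]
        kept = exclude_duplicates(scans)
        assert len(kept) == 1 and kept[0].patient_id == "A"

    def test_distinct_scans_unchanged(self):
        scans = [self.mk("A", "f1"), self.mk("B", "f2")]
        assert exclude_duplicates(scans) == scans

    def test_triplicate_keeps_exactly_one_and_idempotent(self):
        scans = [self.mk("C", "f1"), self.mk("A", "f1"), self.mk("B", "f1")]
        once = exclude_duplicates(scans)
        assert len(once) == 1
        assert exclude_duplicates(once) == once

    def test_fingerprint_from_slice_uids(self):
        body = ("<readingSession><nonNodule>"
                "<nonNoduleID>NN1</nonNoduleID><imageSOP_UID>S9</imageSOP_UID>"
                "<locus><xCoord>1</xCoord><yCoord>2</yCoord></locus>"
                "</nonNodule></readingSession>")
        a = parse_annotation_xml(wrap(body, patient="PA"))
        b = parse_annotation_xml(wrap(body, patient="PB"))
        assert a.series_fingerprint == b.series_fingerprint
        assert len(exclude_duplicates([a, b])) == 1


class TestCenterOfMass:
    def test_single_point_identity(self):
        ref = SliceRef("S", 1.0)
        mark = LesionMark("m", 0, "micro_nodule", points=((100, 120, ref),))
        assert center_of_mass(mark) == (100, 120, ref)

    def test_square_contour_symmetry(self):
        ref = SliceRef("S", 0.0)
        pts = tuple((x, y, ref) for x, y in
                    [(10, 10), (10, 12), (12, 10), (12, 12)])
        mark = LesionMark("m", 0, "nodule", points=pts,
                          contours=((ref, tuple((x, y) for x, y, _ in pts)),))
        cx, cy, r = center_of_mass(mark)
        assert (cx, cy, r) == (11, 11, ref)

    def test_irregular_contour_matches_bruteforce_mean(self):
        ref = SliceRef("S", 0.0)
        vertices = [(3.0, 7.0), (10.0, 2.0), (14.0, 9.0), (8.0, 15.0), (1.0, 11.0)]
        pts = tuple((x, y, ref) for x, y in vertices)
        mark = LesionMark("m", 1, "nodule", points=pts,
                          contours=((ref, tuple(vertices)),))
        cx, cy, _ = center_of_mass(mark)
        assert cx == pytest.approx(sum(x for x, _ in vertices) / 5)
        assert cy == pytest.approx(sum(y for _, y in vertices) / 5)

    def test_multi_slice_contour_picks_slice_nearest_mean_z(self):
        refs = [SliceRef(f"S{k}", float(k)) for k in range(3)]
        pts = tuple((10, 10, r) for r in refs)
        mark = LesionMark("m", 0, "nodule", points=pts,
                          contours=tuple((r, ((9, 9), (11, 9), (10, 11)))
                                         for r in refs))
        _, _, ref = center_of_mass(mark)
        assert ref.z_mm == 1.0

    def test_mark_invariants(self):
        with pytest.raises(ValueError):
            LesionMark("m", 0, "micro_nodule", points=())
        with pytest.raises(ValueError):
            LesionMark("m", 0, "nodule",
                       points=((1, 2, SliceRef("S", 0.0)),), contours=())


def test_manifest_has_one_row_per_mark():
    body = ("<readingSession>"
            "<unblindedReadNodule><noduleID>M1</noduleID>"
            + roi("S1", 0.0, [(40, 50)]) + "</unblindedReadNodule>"
            "<nonNodule><nonNoduleID>NN1</nonNoduleID>"
            "<imageZposition>2.5</imageZposition><imageSOP_UID>S2</imageSOP_UID>"
            "<locus><xCoord>7</xCoord><yCoord>8</yCoord></locus>"
            "</nonNodule></readingSession>")
    scan = parse_annotation_xml(wrap(body))
    df = marks_to_manifest([scan])
    assert list(df.columns) == ["patient_id", "reader_index", "mark_id",
                                "category", "x", "y", "sop_uid", "z_mm"]
    assert len(df) == 2
    assert set(df.category) == {"micro_nodule", "non_nodule"}
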