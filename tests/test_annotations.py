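"""Overlay extraction: caliper/ellipse detection and measurement-text parsing."""

import numpy as np
import pytest

from fetalbiom.annotations import (
    CaliperMark,
    caliper_pair_length,
    detect_calipers,
    detect_dotted_ellipse,
    parse_measurement_text,
)
from fetalbiom.errors import DegenerateFitError
from fetalbiom.imaging_io import Frame
from fetalbiom.phantom import (
    PhantomSpec,
    _draw_cross,
    _draw_dot,
    generate_biometry_loop,
    render_annotations,
)

YELLOW = (255, 255, 0)
CYAN = (0, 255, 255)


def _blank_rgb(shape=(200, 200)):
    return np.full(shape + (3,), 40, dtype=np.uint8)


class TestDetectCalipers:
    def test_two_rendered_crosses_recovered_within_one_pixel(self):
        img = _blank_rgb()
        _draw_cross(img, 100, 50, YELLOW)
        _draw_cross(img, 100, 150, YELLOW)
        marks = detect_calipers(img, palette=[YELLOW])
        assert len(marks) == 2
        positions = sorted(m.position for m in marks)
        assert positions[0] == pytest.approx((100.0, 50.0), abs=1.0)
        assert positions[1] == pytest.approx((100.0, 150.0), abs=1.0)
        assert all(m.glyph == "cross" for m in marks)

    def test_grayscale_image_yields_empty_list(self):
        assert detect_calipers(np.zeros((50, 50), np.uint8)) == []

    def test_solid_rectangle_rejected_by_template_gate(self):
        img = _blank_rgb()
        img[80:95, 60:75] = YELLOW  # palette-colored but not cross-shaped
        assert detect_calipers(img, palette=[YELLOW]) == []


class TestDetectDottedEllipse:
    def _dotted_image(self, a=80, b=55, theta=15.0, cr=100.0, cc=100.0, n=24):
        import math

        img = _blank_rgb((220, 220))
        th = math.radians(theta)
        for t in np.linspace(0, 2 * np.pi, n, endpoint=False):
            x = a * np.cos(t)
            y = b * np.sin(t)
            col = cc + x * np.cos(th) - y * np.sin(th)
            row = cr + x * np.sin(th) + y * np.cos(th)
            _draw_dot(img, row, col, CYAN)
        return img

    def test_24_dots_recover_parameters_within_one_percent(self):
        img = self._dotted_image()
        ell, mask = detect_dotted_ellipse(img, palette=[CYAN])
        assert ell.semi_major_a == pytest.approx(80, rel=0.01)
        assert ell.semi_minor_b == pytest.approx(55, rel=0.01)
        assert ell.center_row == pytest.approx(100, abs=1.0)
        assert mask.count > 0

    def test_four_dots_insufficient(self):
        img = _blank_rgb()
        for pos in ((50, 50), (50, 100), (100, 50), (100, 100)):
            _draw_dot(img, *pos, CYAN)
        with pytest.raises(DegenerateFitError):
            detect_dotted_ellipse(img, palette=[CYAN])

    def test_stray_pixels_rejected_by_refit(self):
        img = self._dotted_image()
        img[10, 10] = CYAN  # stray palette pixels far off the ellipse
        img[210, 15] = CYAN
        ell, _ = detect_dotted_ellipse(img, palette=[CYAN])
        assert ell.semi_major_a == pytest.approx(80, rel=0.01)
        assert ell.semi_minor_b == pytest.approx(55, rel=0.01)


class TestRenderDetectRoundTrip:
    def test_cephalic_annotations_roundtrip(self):
        loop, labels, truth = generate_biometry_loop(
            PhantomSpec(kind="cephalic", seed=21)
        )
        frame = loop.frames[truth.best_frame]
        rgb, lines = render_annotations(frame, truth)
        # calipers at the minor-axis endpoints
        marks = detect_calipers(rgb, palette=[YELLOW])
        assert len(marks) == 2
        dist = np.hypot(
            marks[0].position[0] - marks[1].position[0],
            marks[0].position[1] - marks[1].position[1],
        )
        assert dist == pytest.approx(2 * truth.ellipse.semi_minor_b, abs=2.0)
        # dotted ellipse
        ell, _ = detect_dotted_ellipse(rgb, palette=[CYAN])
        assert ell.semi_major_a == pytest.approx(truth.ellipse.semi_major_a, rel=0.01)
        assert ell.semi_minor_b == pytest.approx(truth.ellipse.semi_minor_b, rel=0.01)
        # text block parses back to the planted measurements
        parsed = {p.acronym: p.value for p in parse_measurement_text(lines)}
        assert parsed["HC"] == pytest.approx(truth.hc_cm, abs=0.01)
        assert parsed["BPD"] == pytest.approx(truth.bpd_cm, abs=0.01)

    def test_empty_truth_leaves_frame_unmodified(self):
        from fetalbiom.phantom import PhantomTruth

        pixels = np.full((64, 64), 77, np.uint8)
        frame = Frame(0, pixels, 0.05, 0.05)
        truth = PhantomTruth(kind="amniotic", best_frame=0, spacing_cm=0.05,
                             scales=(1.0,), flags=({},), confidences=(0.9,))
        rgb, lines = render_annotations(frame, truth)
        assert lines == []
        assert np.array_equal(rgb[..., 0], pixels)


class TestParseMeasurementText:
    def test_standard_and_locale_forms(self):
        parsed = parse_measurement_text(["AC 23.98cm", "FL 5,28 cm"])
        assert [(p.acronym, p.value, p.unit) for p in parsed] == [
            ("AC", 23.98, "cm"), ("FL", 5.28, "cm"),
        ]

    def test_unknown_acronym_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="EFP"):
            assert parse_measurement_text(["EFP 123 g"]) == []

    def test_af_normalized_to_sdp(self):
        (p,) = parse_measurement_text(["AF 5.2 cm"])
        assert p.acronym == "SDP"

    def test_ga_weeks_days_form(self):
        (p,) = parse_measurement_text(["GA 30w3d"])
        assert (p.value, p.unit) == (213.0, "weeks_days")

    def test_unit_acronym_mismatch_skipped(self):
        with pytest.warns(UserWarning, match="inconsistent"):
            assert parse_measurement_text(["EFW 12 cm"]) == []

    def test_idempotent_and_order_preserving(self):
        lines = ["HC 30.1 cm", "BPD 8.4 cm", "EFW 1600 g"]
        first = parse_measurement_text(lines)
        second = parse_measurement_text(lines)
        assert first == second
        assert [p.acronym for p in first] == ["HC", "BPD", "EFW"]


class TestCaliperPairLength:
    def _mark(self, r, c):
        return CaliperMark(position=(r, c), color=YELLOW, glyph="cross")

    def test_hundred_pixels_at_half_mm(self):
        marks = [self._mark(0, 0), self._mark(0, 100)]
        assert caliper_pair_length(marks, 0.05, 0.05) == pytest.approx(5.0)

    def test_coincident_marks_zero(self):
        marks = [self._mark(10, 10), self._mark(10, 10)]
        assert caliper_pair_length(marks, 0.05, 0.05) == 0.0

    def test_three_marks_arity_error(self):
        marks = [self._mark(0, 0)] * 3
        with pytest.raises(ValueError, match="exactly two"):
            caliper_pair_length(marks, 0.05, 0.05)
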