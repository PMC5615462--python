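"""Zig-zag geometry, calibration and line-mask rasterization."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lasertrace import (CalibrationError, Calibration, CornerSet, GeometryError,
                        SimConfig, ZigZagPattern, build_default_pattern,
                        calibrate, line_mask, make_camera)
from lasertrace._geometry import apply_homography, polyline_length


def straight_pattern(y=150.3, width_mm=1.0):
    """A single straight horizontal 1000 mm trace (for analytic mask areas)."""
    return ZigZagPattern(
        apex_points_mm=[[10.0, y], [1010.0, y]],
        board_width_mm=1020.0, board_height_mm=300.0,
        line_width_mm=width_mm, trace_length_mm=1000.0,
    )


def identity_calibration():
    return Calibration(np.eye(3))


class TestBuildDefaultPattern:
    def test_closed_form_amplitude(self):
        # 5 segments over a 400 mm span with a 1000 mm trace: each segment
        # runs 80 mm horizontally and is 200 mm long, so the level
        # separation is sqrt(200^2 - 80^2) ~ 183.30 mm
        p = build_default_pattern(n_segments=5)
        ys = p.apex_points_mm[:, 1]
        amplitude = ys.max() - ys.min()
        assert amplitude == pytest.approx(np.sqrt(200.0**2 - 80.0**2), abs=1e-9)
        assert polyline_length(p.apex_points_mm) == pytest.approx(1000.0, rel=1e-9)

    def test_two_segments_on_a3_infeasible(self):
        # amplitude sqrt(500^2 - 200^2) ~ 458 mm exceeds the A3 height
        with pytest.raises(GeometryError):
            build_default_pattern(n_segments=2)

    def test_single_segment_rejected(self):
        with pytest.raises(GeometryError):
            build_default_pattern(n_segments=1)

    def test_trace_shorter_than_span_rejected(self):
        with pytest.raises(GeometryError):
            build_default_pattern(n_segments=5, trace_length_mm=300.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(n=st.integers(2, 12), trace=st.floats(450.0, 2600.0))
    def test_length_constraint_all_feasible_triples(self, n, trace):
        try:
            p = build_default_pattern(n_segments=n, trace_length_mm=trace)
        except GeometryError:
            return
        assert polyline_length(p.apex_points_mm) == pytest.approx(trace, rel=1e-9)
        assert (p.apex_points_mm[:, 0] >= 0).all()
        assert (p.apex_points_mm[:, 1] <= p.board_height_mm).all()

    def test_center_cross_at_board_center(self):
        p = build_default_pattern()
        assert p.center_cross_mm == pytest.approx([210.0, 148.5])

    def test_invariant_violations_rejected(self):
        with pytest.raises(GeometryError):
            ZigZagPattern(apex_points_mm=[[0, 0], [500, 0]],  # outside board
                          trace_length_mm=500.0)
        with pytest.raises(GeometryError):
            ZigZagPattern(apex_points_mm=[[10, 10], [110, 10]],
                          trace_length_mm=999.0)  # wrong declared length
        with pytest.raises(GeometryError):
            ZigZagPattern(apex_points_mm=[[10, 10], [110, 10]],
                          trace_length_mm=100.0, line_width_mm=0.0)


class TestCalibrate:
    def test_identity_when_corners_match_mm(self, pattern):
        corners = CornerSet(*pattern.corner_points_mm())
        cal = calibrate(corners, pattern)
        assert cal.rms_reprojection_px < 1e-8
        pts = np.array([[50.0, 60.0], [300.0, 200.0]])
        np.testing.assert_allclose(cal.to_mm(pts), pts, atol=1e-8)

    def test_recovers_synthetic_camera_warp(self, pattern):
        camera = make_camera((1280, 720), pattern, perspective=0.05,
                             rotation_deg=2.0)
        corners_px = apply_homography(camera, pattern.corner_points_mm())
        cal = calibrate(CornerSet(*corners_px), pattern)
        assert cal.rms_reprojection_px < 0.5
        # round-trip px -> mm -> px is the identity
        probe = np.array([[100.0, 100.0], [640.0, 360.0], [1000.0, 600.0]])
        np.testing.assert_allclose(cal.to_px(cal.to_mm(probe)), probe, atol=1e-6)

    def test_collinear_corners_rejected(self, pattern):
        with pytest.raises(CalibrationError):
            calibrate(CornerSet([0, 0], [100, 0], [200, 0], [300, 0]), pattern)


class TestLineMask:
    def test_straight_line_area_matches_analytic(self):
        p = straight_pattern()
        mask = line_mask(p, identity_calibration(), (1020, 300))
        # 1000 mm x 1 mm at 1 px/mm: one pixel row within half-width
        assert 900 <= mask.sum() <= 1150

    def test_zero_width_limit_empty(self):
        p = straight_pattern(width_mm=1e-9)
        assert line_mask(p, identity_calibration(), (1020, 300)).sum() == 0

    def test_area_scales_linearly_with_width(self):
        areas = [line_mask(straight_pattern(width_mm=w),
                           identity_calibration(), (1020, 300)).sum()
                 for w in (4.0, 8.0, 16.0)]
        assert areas[1] / areas[0] == pytest.approx(2.0, rel=0.05)
        assert areas[2] / areas[1] == pytest.approx(2.0, rel=0.05)

    def test_covers_rendered_polyline(self, pattern):
        # every pixel the renderer paints as line must be inside the mask
        # built from the true camera at matching tolerance
        sim = SimConfig(image_dims=(640, 360), seed=0)
        from lasertrace import render_scene
        sim2 = SimConfig(image_dims=(640, 360), seed=0, pixel_noise_sd=0.0)
        frame = render_scene(sim2)
        rendered_line = np.all(frame == np.array(sim2.line_color), axis=-1)
        cal = Calibration(np.linalg.inv(sim2.camera))
        mask = line_mask(pattern, cal, (640, 360), tolerance_mm=0.0)
        assert (rendered_line & ~mask).sum() == 0


def test_pattern_json_roundtrip(tmp_path, pattern):
    path = tmp_path / "pattern.json"
    pattern.to_json(path)
    back = ZigZagPattern.from_json(path)
    np.testing.assert_allclose(back.apex_points_mm, pattern.apex_points_mm)
    assert back.trace_length_mm == pattern.trace_length_mm
    # string form parses too
    back2 = ZigZagPattern.from_json(pattern.to_json())
    assert back2.line_width_mm == pattern.line_width_mm
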