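import dataclasses
import math

import numpy as np
import pytest

from sonoquant import synth
from sonoquant.detect import detect_structures, binarize_bbox, refine_contour, validate_order
from sonoquant.errors import EllipseFitError, OrderingError
from sonoquant.geometry import (
    Calibration,
    EllipseParams,
    ellipse_area,
    ellipse_points,
    fit_ellipse_direct,
    measure,
    rect_area,
    thickness,
    zone_width,
)
from sonoquant.preprocess import (
    ROIBox,
    bilateral_filter,
    compute_roi,
    rescale_to_byte,
    to_unit_interval,
)

CAL = Calibration(cm_per_px=0.01, source="config")


def _pipeline_detections(image, templates, descriptor, kernel_radius=2):
    roi = compute_roi(image)
    byte = rescale_to_byte(bilateral_filter(to_unit_interval(roi.crop(image.pixels))))
    dets = validate_order(detect_structures(byte, templates, descriptor), templates)
    refined = [refine_contour(binarize_bbox(byte, d.match.bbox), d, kernel_radius) for d in dets]
    return roi, byte, refined


def _fake_detection(sid, row):
    from sonoquant.detect import MatchResult, StructureDetection

    bbox = ROIBox(0, 20, int(row) - 5, int(row) + 6)
    return StructureDetection(
        match=MatchResult(structure_id=sid, score=1.0, bbox=bbox),
        contour=np.zeros((0, 2)),
        interface_row=float(row),
    )


class TestScalars:
    def test_thickness_arithmetic_and_ordering(self):
        up, lo = _fake_detection("a", 100), _fake_detection("b", 220)
        assert thickness(up, lo, CAL) == pytest.approx(1.20)
        assert thickness(up, up, CAL) == 0.0
        with pytest.raises(OrderingError):
            thickness(lo, up, CAL)

    def test_zone_width_and_rect_area(self):
        roi = ROIBox(30, 70, 0, 10)
        assert zone_width(roi, CAL) == pytest.approx(0.40)
        assert zone_width(roi, Calibration()) == 40
        assert rect_area(1.2, 0.4) == pytest.approx(0.48)
        assert rect_area(0.0, 5.0) == 0.0


class TestEllipseFit:
    def _params(self, **kw):
        defaults = dict(center=(50.0, 60.0), semi_axis_a=30.0, semi_axis_b=20.0, orientation=0.5)
        defaults.update(kw)
        return EllipseParams(**defaults)

    def test_exact_points_recovered_to_1e6(self):
        truth = self._params()
        fit = fit_ellipse_direct(ellipse_points(truth, 40))
        assert fit.center[0] == pytest.approx(50.0, abs=1e-6)
        assert fit.center[1] == pytest.approx(60.0, abs=1e-6)
        assert fit.semi_axis_a == pytest.approx(30.0, abs=1e-6)
        assert fit.semi_axis_b == pytest.approx(20.0, abs=1e-6)
        assert fit.orientation == pytest.approx(0.5, abs=1e-6)

    def test_every_input_point_satisfies_fitted_conic(self):
        pts = ellipse_points(self._params(), 40)
        fit = fit_ellipse_direct(pts)
        # residual of the implicit ellipse equation at each input point
        ct, st = math.cos(fit.orientation), math.sin(fit.orientation)
        dy = pts[:, 0] - fit.center[0]
        dx = pts[:, 1] - fit.center[1]
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        resid = (u / fit.semi_axis_a) ** 2 + (v / fit.semi_axis_b) ** 2 - 1.0
        assert np.abs(resid).max() < 1e-8

    def test_circle_any_orientation(self):
        fit = fit_ellipse_direct(ellipse_points(
            EllipseParams((0.0, 0.0), 10.0, 10.0, 0.0), 40))
        assert fit.semi_axis_a == pytest.approx(10.0, abs=1e-6)
        assert fit.semi_axis_b == pytest.approx(10.0, abs=1e-6)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(6.0), 2.0 * np.arange(6.0)])
        with pytest.raises(EllipseFitError):
            fit_ellipse_direct(pts)

    def test_rigid_motion_invariance(self, rng):
        truth = self._params()
        pts = ellipse_points(truth, 50)
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        moved = pts @ rot.T + np.array([13.0, -4.5])
        fit = fit_ellipse_direct(moved)
        assert fit.semi_axis_a == pytest.approx(truth.semi_axis_a, abs=1e-6)
        assert fit.semi_axis_b == pytest.approx(truth.semi_axis_b, abs=1e-6)

    def test_agrees_with_independent_library_fit(self, rng):
        from skimage.measure import EllipseModel

        pts = ellipse_points(self._params(), 60)
        pts_noisy = pts + rng.normal(0, 0.3, pts.shape)
        fit = fit_ellipse_direct(pts_noisy)
        model = EllipseModel.from_estimate(pts_noisy[:, ::-1])  # skimage wants (x, y)
        assert bool(model)
        a_sk, b_sk = sorted(model.axis_lengths, reverse=True)
        assert fit.semi_axis_a == pytest.approx(a_sk, rel=0.02)
        assert fit.semi_axis_b == pytest.approx(b_sk, rel=0.02)


class TestEllipseArea:
    def test_closed_forms(self):
        p = EllipseParams((0, 0), 3.0, 2.0, 0.0)
        assert ellipse_area(p, Calibration()) == pytest.approx(6 * math.pi)
        circ = EllipseParams((0, 0), 1.0, 1.0, 0.0)
        assert ellipse_area(circ, Calibration()) == pytest.approx(math.pi)

    def test_matches_monte_carlo_estimate(self, rng):
        p = EllipseParams((0.0, 0.0), 7.0, 3.0, 0.9)
        n = 10**6
        pts = rng.uniform(-8, 8, size=(n, 2))  # (row, col) box covers the ellipse
        ct, st = math.cos(p.orientation), math.sin(p.orientation)
        u = pts[:, 1] * ct + pts[:, 0] * st
        v = -pts[:, 1] * st + pts[:, 0] * ct
        inside = (u / p.semi_axis_a) ** 2 + (v / p.semi_axis_b) ** 2 <= 1.0
        mc = inside.mean() * 16.0 * 16.0
        assert ellipse_area(p, Calibration()) == pytest.approx(mc, rel=0.01)

    def test_monotone_in_both_axes(self):
        base = ellipse_area(EllipseParams((0, 0), 3.0, 2.0, 0.0), Calibration())
        assert ellipse_area(EllipseParams((0, 0), 3.5, 2.0, 0.0), Calibration()) > base
        assert ellipse_area(EllipseParams((0, 0), 3.0, 2.5, 0.0), Calibration()) > base


class TestMeasure:
    def test_abdomen_phantom_thicknesses_match_truth(self, noiseless_abdomen):
        image, truth = noiseless_abdomen
        templates = synth.extract_templates(image, truth)
        roi, byte, dets = _pipeline_detections(image, templates, truth.descriptor)
        rec = measure(dets, roi, truth.descriptor, CAL, roi_image=byte)
        for name, expected in truth.variables.items():
            assert rec.values[name] == pytest.approx(expected, abs=0.05), name
        assert rec.units == "cm"
        assert not rec.flags

    def test_total_fat_bounds_superficial_fat(self, abdomen_phantom, abdomen_templates):
        image, truth = abdomen_phantom
        roi, byte, dets = _pipeline_detections(image, abdomen_templates, truth.descriptor)
        rec = measure(dets, roi, truth.descriptor, CAL, roi_image=byte)
        assert rec.values["Total Subcutaneous Fat"] >= rec.values["Superficial Subcutaneous Fat"]

    def test_leg_transverse_rectus_area_via_ellipse(self, leg_transverse_phantom,
                                                    leg_transverse_templates):
        image, truth = leg_transverse_phantom
        roi, byte, dets = _pipeline_detections(image, leg_transverse_templates, truth.descriptor)
        rec = measure(dets, roi, truth.descriptor, CAL, roi_image=byte)
        assert rec.provenance["area_modes"]["Anterior Rectus"] == "ellipse"
        true_area = truth.variables["Anterior Rectus Area"]
        assert rec.values["Anterior Rectus Area"] == pytest.approx(true_area, rel=0.10)

    def test_missing_deep_interface_leaves_variable_absent(self, noiseless_abdomen):
        image, truth = noiseless_abdomen
        templates = synth.extract_templates(image, truth)
        roi, byte, dets = _pipeline_detections(image, templates, truth.descriptor)
        partial = [d for d in dets if d.structure_id != "peritoneum"]
        rec = measure(partial, roi, truth.descriptor, CAL, roi_image=byte)
        assert "Peritoneal Fat" not in rec.values
        assert any(f.startswith("incomplete") for f in rec.flags)
        assert rec.values["Total Subcutaneous Fat"] == pytest.approx(
            truth.variables["Total Subcutaneous Fat"], abs=0.05
        )

    def test_lengths_and_areas_scale_with_calibration(self, noiseless_abdomen,
                                                      leg_transverse_phantom,
                                                      leg_transverse_templates):
        image, truth = leg_transverse_phantom
        roi, byte, dets = _pipeline_detections(image, leg_transverse_templates, truth.descriptor)
        cal2 = Calibration(cm_per_px=0.02, source="config")
        r1 = measure(dets, roi, truth.descriptor, CAL, roi_image=byte)
        r2 = measure(dets, roi, truth.descriptor, cal2, roi_image=byte)
        assert r2.values["Y-axis Anterior Rectus"] == pytest.approx(
            2 * r1.values["Y-axis Anterior Rectus"])
        assert r2.values["Anterior Rectus Area"] == pytest.approx(
            4 * r1.values["Anterior Rectus Area"], rel=1e-9)
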