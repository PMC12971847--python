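"""Checkerboard calibration and landmark-distance extraction."""

import json

import numpy as np
import pytest

from suturemetrics import (
    CalibrationError,
    CalibrationModel,
    DistanceSet,
    InputError,
    SutureAnnotation,
    calibrate_from_checkerboard,
    extract_distances,
    point_to_margin_distance,
    read_annotation_csv,
    read_annotation_json,
    write_annotation_csv,
    write_annotation_json,
)
from oracles import point_to_polyline_dense


def rot(deg):
    t = np.radians(deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


SQUARE = [[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]]


class TestCalibration:
    def test_uniform_lattice_scale(self):
        cal = calibrate_from_checkerboard(SQUARE, square_mm=5.0)
        assert cal.mm_per_px == pytest.approx(0.5)
        assert cal.residual_rms_px == pytest.approx(0.0)
        assert cal.n_corners_used == 4

    def test_rigid_motion_invariance(self):
        pts = np.asarray(SQUARE)
        moved = (pts - pts.mean(0)) @ rot(30).T + pts.mean(0) + [17.0, -4.0]
        cal = calibrate_from_checkerboard(moved, square_mm=5.0)
        assert cal.mm_per_px == pytest.approx(0.5, abs=1e-9)

    def test_two_corners_minimal_case(self):
        cal = calibrate_from_checkerboard([[0, 0], [0, 25]], square_mm=5.0)
        assert cal.mm_per_px == pytest.approx(0.2)

    def test_jittered_lattice_matches_brute_force_median(self, rng):
        """Mean estimate over jittered 2x2 grids stays within 2% of truth."""
        base = 20.0 * np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
        estimates, oracle = [], []
        for _ in range(300):
            pts = base + rng.normal(0, 0.1, base.shape)
            cal = calibrate_from_checkerboard(pts, square_mm=5.0)
            estimates.append(cal.mm_per_px)
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            oracle.append(5.0 / np.median(d.min(axis=1)))
        assert np.allclose(estimates, oracle)  # estimator == brute-force definition
        assert np.mean(estimates) == pytest.approx(0.25, rel=0.02)

    @pytest.mark.parametrize(
        "corners,err",
        [
            ([[0, 0]], InputError),  # fewer than 2
            ([[0, 0], [0, 0], [0, 0]], CalibrationError),  # coincident
            ([[0, 0], [1, 1], [2, 2], [3, 3]], CalibrationError),  # collinear
        ],
    )
    def test_degenerate_geometry_rejected(self, corners, err):
        with pytest.raises(err):
            calibrate_from_checkerboard(corners, square_mm=5.0)

    def test_nonpositive_square_rejected(self):
        with pytest.raises(InputError):
            calibrate_from_checkerboard(SQUARE, square_mm=0.0)

    def test_model_invariants(self):
        with pytest.raises(InputError):
            CalibrationModel(mm_per_px=-1.0, residual_rms_px=0.0, n_corners_used=4)


class TestPointToMargin:
    def test_perpendicular_drop(self):
        assert point_to_margin_distance([3, 4], [[0, 0], [10, 0]]) == pytest.approx(4.0)

    def test_nearest_endpoint(self):
        assert point_to_margin_distance([-2, 3], [[0, 0], [10, 0]]) == pytest.approx(np.sqrt(13))

    def test_matches_dense_sampling_oracle(self, rng):
        poly = rng.uniform(-10, 10, size=(5, 2))
        for _ in range(100):
            p = rng.uniform(-15, 15, size=2)
            got = point_to_margin_distance(p, poly)
            assert got == pytest.approx(point_to_polyline_dense(p, poly), abs=1e-3)

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(InputError):
            point_to_margin_distance([0, 0], [[1, 1], [1, 1]])


def make_annotation(entry, exit_, incision, corners=None, square=None, trial="t1"):
    return SutureAnnotation(trial, entry, exit_, incision,
                            checkerboard_corners=corners, checkerboard_square_mm=square)


class TestExtractDistances:
    def test_axis_aligned_ideal_suture(self):
        ann = make_annotation([[0, 5], [5, 5]], [[0, -5], [5, -5]], [[-10, 0], [20, 0]])
        cal = CalibrationModel(mm_per_px=1.0, residual_rms_px=0.0, n_corners_used=4)
        d = extract_distances(ann, cal)
        assert d.units == "mm"
        assert d.pm.tolist() == [5, 5, 5, 5]
        assert d.pp.tolist() == [5, 5]

    def test_no_calibration_keeps_pixels(self):
        ann = make_annotation([[0, 5], [5, 5]], [[0, -5], [5, -5]], [[-10, 0], [20, 0]])
        d = extract_distances(ann, None)
        assert d.units == "px"
        assert d.pm.tolist() == [5, 5, 5, 5]

    def test_rigid_motion_invariance(self, rng):
        entry = rng.uniform(0, 50, (7, 2))
        exit_ = rng.uniform(0, 50, (7, 2))
        incision = rng.uniform(0, 50, (4, 2))
        ann = make_annotation(entry, exit_, incision)
        ref = extract_distances(ann, None)
        R, t = rot(73.0), np.array([120.0, -40.0])
        ann2 = make_annotation(entry @ R.T + t, exit_ @ R.T + t, incision @ R.T + t)
        moved = extract_distances(ann2, None)
        np.testing.assert_allclose(moved.pm, ref.pm, rtol=1e-6)
        np.testing.assert_allclose(moved.pp, ref.pp, rtol=1e-6)

    def test_scaling_covariance(self, rng):
        """Scaling pixels and lattice together leaves mm distances unchanged."""
        entry = rng.uniform(0, 50, (7, 2))
        exit_ = rng.uniform(0, 50, (7, 2))
        incision = np.array([[-10.0, 0.0], [60.0, 0.0]])
        corners = 10.0 * np.array([[0, 0], [1, 0], [0, 1], [1, 1]]) + [200, 200]
        for s in (1.0, 3.7):
            ann = make_annotation(s * entry, s * exit_, s * incision, s * corners, 5.0)
            cal = calibrate_from_checkerboard(ann.checkerboard_corners, 5.0)
            d = extract_distances(ann, cal)
            if s == 1.0:
                ref = d
            else:
                np.testing.assert_allclose(d.pm, ref.pm, rtol=1e-9)
                np.testing.assert_allclose(d.pp, ref.pp, rtol=1e-9)

    def test_single_point_side_yields_no_gaps(self):
        ann = make_annotation([[0, 5]], [[0, -5], [5, -5]], [[-10, 0], [20, 0]])
        d = extract_distances(ann, None)
        assert len(d.pp) == 1  # only the exit side contributes
        assert len(d.pm) == 3

    def test_protocol_lengths(self, rng):
        entry = np.column_stack([np.arange(7) * 5.0, np.full(7, 5.0)])
        ann = make_annotation(entry, entry * [1, -1], [[-5, 0], [40, 0]])
        d = extract_distances(ann, None)
        assert len(d.pm) == 14 and len(d.pp) == 12


class TestAnnotationValidation:
    def test_zero_length_incision_rejected(self):
        with pytest.raises(InputError):
            make_annotation([[0, 5]], [[0, -5]], [[1, 1], [1, 1]])

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(InputError):
            make_annotation([[np.nan, 5]], [[0, -5]], [[0, 0], [1, 0]])

    def test_distance_set_rejects_negatives(self):
        with pytest.raises(InputError):
            DistanceSet("t", [-1.0], [5.0], "mm")


class TestAnnotationIO:
    def test_json_roundtrip(self, tmp_path, rng):
        ann = make_annotation(rng.uniform(0, 9, (7, 2)), rng.uniform(0, 9, (7, 2)),
                              rng.uniform(0, 9, (3, 2)), SQUARE, 5.0)
        path = tmp_path / "a.json"
        write_annotation_json(ann, path)
        back = read_annotation_json(path)
        np.testing.assert_array_equal(back.entry_points, ann.entry_points)
        np.testing.assert_array_equal(back.checkerboard_corners, ann.checkerboard_corners)
        assert back.checkerboard_square_mm == 5.0

    def test_csv_roundtrip(self, tmp_path, rng):
        ann = make_annotation(rng.uniform(0, 9, (7, 2)), rng.uniform(0, 9, (7, 2)),
                              rng.uniform(0, 9, (3, 2)), SQUARE, 5.0)
        path = tmp_path / "a.csv"
        write_annotation_csv(ann, path)
        back = read_annotation_csv(path, checkerboard_square_mm=5.0)
        np.testing.assert_array_equal(back.exit_points, ann.exit_points)
        np.testing.assert_array_equal(back.incision, ann.incision)

    def test_malformed_json_reports_file(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(InputError, match="bad.json"):
            read_annotation_json(bad)

    def test_missing_keys_reported(self, tmp_path):
        f = tmp_path / "m.json"
        f.write_text(json.dumps({"trial_id": "x", "entry_points": [[0, 0]]}))
        with pytest.raises(InputError, match="missing keys"):
            read_annotation_json(f)
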