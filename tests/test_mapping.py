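"""Trajectory recording, overlay rendering and quadrant coverage."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from probemap import (RigidPose, Trajectory, coverage_report, line_marker,
                      record, rect_marker, render_overlay, score_to_color,
                      transform_points)
from probemap.errors import OpenPath
from probemap.mapping import Marker, quadrant_of


@pytest.fixture()
def setup(calibs, phantom):
    traj = Trajectory.for_setup(phantom.center_px, calibs["surface"],
                                phantom.calibration)
    marker = line_marker(calibs["surface"], phantom.calibration,
                         calibs["lcoct_vertical"])
    return traj, marker


def pose_at(x, y, theta=0.0, marker=None):
    """Pose placing the marker centroid at (x, y)."""
    p = RigidPose(theta, 0.0, 0.0)
    c = transform_points(p, marker.centroid())
    return RigidPose(theta, x - c[0], y - c[1])


class TestRecord:
    def test_grows_by_one(self, setup):
        traj, marker = setup
        record(traj, RigidPose(), marker, 10.0)
        assert len(traj) == 1
        assert traj.samples[0].score == 10.0

    def test_lost_frame_skipped(self, setup):
        traj, marker = setup
        record(traj, None, marker, 50.0)
        assert len(traj) == 0

    def test_score_bounds_enforced(self, setup):
        traj, marker = setup
        with pytest.raises(ValueError):
            record(traj, RigidPose(), marker, 120.0)

    def test_indices_ordered(self, setup):
        traj, marker = setup
        record(traj, RigidPose(), marker, 1.0)
        record(traj, RigidPose(), marker, 2.0)
        assert [s.index for s in traj.samples] == [0, 1]


class TestMarkers:
    def test_line_marker_spans_section_width(self, calibs, phantom):
        m = line_marker(calibs["surface"], phantom.calibration,
                        calibs["lcoct_vertical"])
        length = np.linalg.norm(m.points[1] - m.points[0])
        expected = 1.2 * 1000.0 / phantom.calibration.mean_pitch_um
        assert length == pytest.approx(expected, rel=1e-6)

    def test_rect_marker_footprint(self, calibs, phantom):
        m = rect_marker(calibs["surface"], phantom.calibration,
                        calibs["lcoct_horizontal"])
        w = np.linalg.norm(m.points[1] - m.points[0])
        h = np.linalg.norm(m.points[2] - m.points[1])
        pitch = phantom.calibration.mean_pitch_um
        assert w == pytest.approx(1.2 * 1000 / pitch, rel=1e-6)
        assert h == pytest.approx(0.5 * 1000 / pitch, rel=1e-6)


class TestRenderOverlay:
    def test_single_blue_marker(self, setup, phantom):
        traj, marker = setup
        pose = pose_at(300.0, 300.0, marker=marker)
        record(traj, pose, marker, 0.0)
        out = render_overlay(phantom.image, traj)
        assert tuple(out[300, 300]) == score_to_color(0.0)

    def test_blue_and_yellow_pair(self, setup, phantom):
        traj, marker = setup
        record(traj, pose_at(250.0, 200.0, marker=marker), marker, 0.0)
        record(traj, pose_at(700.0, 500.0, marker=marker), marker, 100.0)
        out = render_overlay(phantom.image, traj)
        assert tuple(out[200, 250]) == (0, 0, 255)
        assert tuple(out[500, 700]) == (255, 255, 0)

    def test_deterministic_bytes(self, setup, phantom):
        traj, marker = setup
        record(traj, pose_at(300.0, 300.0, 0.4, marker), marker, 30.0)
        record(traj, pose_at(330.0, 310.0, 0.5, marker), marker, 70.0)
        a = render_overlay(phantom.image, traj)
        b = render_overlay(phantom.image, traj)
        assert np.array_equal(a, b)

    def test_extrapolated_drawn_dashed(self, setup, phantom):
        traj, marker = setup
        record(traj, pose_at(300.0, 300.0, marker=marker), marker, 0.0,
               source="extrapolated")
        solid = Trajectory(lesion_center_px=traj.lesion_center_px,
                           fov_radius_px=traj.fov_radius_px)
        record(solid, pose_at(300.0, 300.0, marker=marker), marker, 0.0)
        a = render_overlay(phantom.image, traj)
        b = render_overlay(phantom.image, solid)
        na = (a == np.array([0, 0, 255])).all(axis=2).sum()
        nb = (b == np.array([0, 0, 255])).all(axis=2).sum()
        assert 0 < na < nb  # dashes paint strictly fewer pixels

    def test_empty_trajectory_rejected(self, setup, phantom):
        traj, _ = setup
        with pytest.raises(ValueError):
            render_overlay(phantom.image, traj)

    def test_nearby_samples_connected_distant_not(self, setup, phantom):
        traj, marker = setup
        record(traj, pose_at(300.0, 300.0, marker=marker), marker, 50.0)
        record(traj, pose_at(320.0, 300.0, marker=marker), marker, 50.0)
        record(traj, pose_at(900.0, 600.0, marker=marker), marker, 50.0)
        out = render_overlay(phantom.image, traj)
        gray = (128, 128, 128)
        assert tuple(out[300, 310]) == gray  # midpoint of the short hop
        # midpoint of the long jump left untouched
        mid = ((320 + 900) // 2, (300 + 600) // 2)
        assert tuple(out[mid[1], mid[0]]) != gray


def circle_path(center, radius_px, n=240):
    ang = np.linspace(0, 2 * np.pi, n + 1)
    return np.column_stack([center[0] + radius_px * np.sin(ang),
                            center[1] - radius_px * np.cos(ang)])


class TestQuadrants:
    def test_clock_convention(self):
        c = np.array([0.0, 0.0])
        assert quadrant_of(np.array([[0.5, -1.0]]), c)[0] == 0   # ~ 1 o'clock
        assert quadrant_of(np.array([[1.0, 1.0]]), c)[0] == 1    # ~ 4:30
        assert quadrant_of(np.array([[-0.5, 1.0]]), c)[0] == 2   # ~ 7:30
        assert quadrant_of(np.array([[-1.0, -0.5]]), c)[0] == 3  # ~ 10:30


class TestCoverage:
    GAP_TOL_MM = 0.3

    def _marker_segments(self, traj):
        segs = []
        for s in traj.samples:
            pts = transform_points(s.pose, s.marker.points)
            segs.append(LineString(pts))
        return segs

    def _oracle(self, traj, path, tol_px, center, n=2000):
        """Brute-force shapely point-to-segment coverage per quadrant."""
        ring = LineString(path)
        total = ring.length
        ss = np.arange(n) * total / n
        pts = [ring.interpolate(s) for s in ss]
        segs = self._marker_segments(traj)
        frac = {}
        covered = np.array([min((seg.distance(p) for seg in segs),
                                default=np.inf) <= tol_px for p in pts])
        q = quadrant_of(np.array([[p.x, p.y] for p in pts]), center)
        from probemap.mapping import QUADRANT_NAMES
        for k, name in enumerate(QUADRANT_NAMES):
            m = q == k
            frac[name] = covered[m].mean() if m.any() else 0.0
        return frac

    def test_dense_full_coverage(self, setup, phantom):
        traj, marker = setup
        c = phantom.center_px
        r = 3.0 * 1000 / phantom.calibration.mean_pitch_um
        for ang in np.linspace(0, 2 * np.pi, 60, endpoint=False):
            x = c[0] + r * np.sin(ang)
            y = c[1] - r * np.cos(ang)
            record(traj, pose_at(x, y, ang, marker), marker, 0.0)
        rep = coverage_report(traj, circle_path(c, r), self.GAP_TOL_MM,
                              phantom.calibration)
        assert all(v == pytest.approx(1.0, abs=1e-9)
                   for v in rep.fractions.values())
        assert rep.gaps == []

    def test_partial_coverage_matches_oracle(self, setup, phantom):
        traj, marker = setup
        c = phantom.center_px
        r = 3.0 * 1000 / phantom.calibration.mean_pitch_um
        # cover only the 12-3 o'clock arc
        for ang in np.linspace(0, np.pi / 2, 20):
            x = c[0] + r * np.sin(ang)
            y = c[1] - r * np.cos(ang)
            record(traj, pose_at(x, y, ang, marker), marker, 0.0)
        path = circle_path(c, r)
        rep = coverage_report(traj, path, self.GAP_TOL_MM, phantom.calibration)
        tol_px = self.GAP_TOL_MM * 1000 / phantom.calibration.mean_pitch_um
        oracle = self._oracle(traj, path, tol_px, c)
        for name in rep.fractions:
            assert rep.fractions[name] == pytest.approx(oracle[name], abs=0.02)
        assert rep.fractions["12-3"] > 0.95
        assert rep.fractions["6-9"] < 0.05
        assert len(rep.gaps) >= 1

    def test_empty_trajectory_zero_coverage(self, setup, phantom):
        traj, _ = setup
        c = phantom.center_px
        rep = coverage_report(traj, circle_path(c, 200.0), self.GAP_TOL_MM,
                              phantom.calibration)
        assert all(v == 0.0 for v in rep.fractions.values())
        assert len(rep.gaps) == 1
        s0, s1 = rep.gaps[0]
        assert (s1 - s0) == pytest.approx(rep.arc_length_mm, rel=1e-6)

    def test_open_path_rejected(self, setup, phantom):
        traj, marker = setup
        record(traj, RigidPose(), marker, 0.0)
        path = circle_path(phantom.center_px, 100.0)[:-5]
        with pytest.raises(OpenPath):
            coverage_report(traj, path, self.GAP_TOL_MM, phantom.calibration)

    def test_coverage_monotone_in_samples(self, setup, phantom):
        traj, marker = setup
        c = phantom.center_px
        r = 3.0 * 1000 / phantom.calibration.mean_pitch_um
        path = circle_path(c, r)
        prev = {k: 0.0 for k in ("12-3", "3-6", "6-9", "9-12")}
        for ang in np.linspace(0, np.pi, 10):
            record(traj, pose_at(c[0] + r * np.sin(ang),
                                 c[1] - r * np.cos(ang), ang, marker),
                   marker, 0.0)
            rep = coverage_report(traj, path, self.GAP_TOL_MM,
                                  phantom.calibration)
            for k, v in rep.fractions.items():
                assert v >= prev[k] - 1e-12
            prev = rep.fractions
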