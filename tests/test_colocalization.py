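"""Keypoint extraction, matching, RANSAC rigid estimation and the gate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from probemap import (MatchSet, PipelineConfig, RigidPose, colocalize,
                      estimate_rigid, gate_reliability, init_reference,
                      procrustes_rigid, transform_points)
from probemap.errors import DegenerateGeometry, EmptyFrame, EmptyReference
from probemap.features import (KeypointSet, detect_keypoints,
                               extract_surface_features, match_nearest)

from conftest import angle_diff_deg


def procrustes_oracle(src, dst):
    """Independent closed-form rigid fit via scipy's orthogonal Procrustes,
    projected onto proper rotations."""
    from scipy.linalg import svd
    P, Q = np.asarray(src, float), np.asarray(dst, float)
    cp, cq = P.mean(0), Q.mean(0)
    U, _s, Vt = svd((P - cp).T @ (Q - cq))
    d = np.sign(np.linalg.det(Vt.T @ U.T)) or 1.0
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = cq - R @ cp
    return np.arctan2(R[1, 0], R[0, 0]), t


class TestReferenceInit:
    def test_uniform_image_raises(self, cfg):
        with pytest.raises(EmptyReference):
            init_reference(np.full((128, 128), 128, np.uint8), cfg)

    def test_deterministic(self, phantom, cfg, ref_features):
        again = init_reference(phantom.image, cfg)
        assert len(again) == len(ref_features)
        assert np.array_equal(again.positions, ref_features.positions)
        assert np.array_equal(again.descriptors, ref_features.descriptors)

    def test_rotation_invariant_count(self, phantom, cfg, ref_features):
        """A 180-degree rotation leaves the keypoint count essentially
        unchanged (the detector's resampling grid is not perfectly
        symmetric, so exact equality is not expected)."""
        rotated = phantom.image[::-1, ::-1].copy()
        kps = init_reference(rotated, cfg)
        assert abs(len(kps) - len(ref_features)) <= 0.02 * len(ref_features)


class TestSurfaceFeatures:
    def test_blank_frame_raises(self, cfg, calibs, phantom):
        blank = np.zeros((400, 400, 3), np.uint8)
        with pytest.raises(EmptyFrame):
            extract_surface_features(blank, calibs["surface"],
                                     phantom.calibration, cfg)

    def test_shape_mismatch(self, cfg, calibs, phantom):
        with pytest.raises(ValueError, match="does not match"):
            extract_surface_features(np.zeros((100, 100), np.uint8),
                                     calibs["surface"], phantom.calibration, cfg)

    def test_deterministic(self, sweep, cfg, calibs, phantom):
        a = extract_surface_features(sweep.frames[0], calibs["surface"],
                                     phantom.calibration, cfg)
        b = extract_surface_features(sweep.frames[0], calibs["surface"],
                                     phantom.calibration, cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.descriptors, b.descriptors)

    def test_keypoints_inside_circle(self, sweep, cfg, calibs, phantom):
        kps = extract_surface_features(sweep.frames[0], calibs["surface"],
                                       phantom.calibration, cfg)
        # normalized frame is 208x208 for the default calibrations
        c = np.array([103.5, 103.5])
        r = np.linalg.norm(kps.positions - c, axis=1)
        assert (r < 104 - cfg.mask_edge_margin_px).all()

    def test_positions_consistent_with_reference(self, sweep, cfg, calibs,
                                                 phantom, ref_features):
        """Most frame keypoints, mapped through the true pose, land on a
        reference keypoint within a small tolerance (self-crop check)."""
        kps = extract_surface_features(sweep.frames[0], calibs["surface"],
                                       phantom.calibration, cfg)
        mapped = transform_points(sweep.poses[0], kps.positions)
        d = np.linalg.norm(mapped[:, None] - ref_features.positions[None],
                           axis=2).min(axis=1)
        assert np.median(d) < 1.5


def _kpset(desc):
    desc = np.asarray(desc, float)
    n = len(desc)
    return KeypointSet(positions=np.zeros((n, 2)), scales=np.zeros(n),
                       orientations=np.zeros(n), descriptors=desc)


class TestMatching:
    def test_identity_matches_self(self):
        rng = np.random.default_rng(0)
        desc = rng.random((20, 16))
        m = match_nearest(_kpset(desc), _kpset(desc))
        assert np.array_equal(m.pairs[:, 0], m.pairs[:, 1])
        assert np.allclose(m.distances, 0.0)

    def test_against_exhaustive_search(self):
        rng = np.random.default_rng(1)
        q, r = rng.random((5, 8)), rng.random((3, 8))
        m = match_nearest(_kpset(q), _kpset(r))
        for qi, ri in m.pairs:
            dists = [np.linalg.norm(q[qi] - rv) for rv in r]
            assert ri == int(np.argmin(dists))
        # larger randomized instance
        q, r = rng.random((50, 32)), rng.random((80, 32))
        m = match_nearest(_kpset(q), _kpset(r))
        assert len(m) == 50
        for qi, ri in m.pairs:
            assert ri == int(np.argmin(np.linalg.norm(q[qi] - r, axis=1)))

    def test_tie_breaks_to_lowest_index(self):
        q = np.eye(4)[:1]          # one unit vector
        r = np.eye(4)[1:]          # three orthogonal unit vectors
        m = match_nearest(_kpset(q), _kpset(r))
        assert np.allclose(m.distances, np.sqrt(2.0))
        assert m.pairs[0, 1] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            match_nearest(_kpset(np.zeros((0, 8))), _kpset(np.ones((3, 8))))


def _exact_problem(n, pose, seed=0, n_outliers=0, span=1000.0):
    rng = np.random.default_rng(seed)
    q = rng.uniform(0, span, size=(n, 2))
    r = transform_points(pose, q)
    if n_outliers:
        q = np.vstack([q, rng.uniform(0, span, size=(n_outliers, 2))])
        r = np.vstack([r, rng.uniform(0, span, size=(n_outliers, 2))])
    pairs = np.column_stack([np.arange(len(q)), np.arange(len(q))])
    return MatchSet(pairs=pairs, distances=np.zeros(len(q))), q, r


class TestEstimateRigid:
    def test_exact_recovery(self):
        true = RigidPose(0.3, 40.0, -12.0)
        m, q, r = _exact_problem(10, true, seed=2)
        pose, inl = estimate_rigid(m, q, r, tol_px=3.0, max_iters=500, seed=0)
        assert len(inl) == 10
        assert abs(pose.theta - true.theta) < 1e-6
        assert abs(pose.tx - true.tx) < 1e-6 and abs(pose.ty - true.ty) < 1e-6

    def test_contaminated_recovery(self):
        true = RigidPose(0.3, 40.0, -12.0)
        m, q, r = _exact_problem(10, true, seed=3, n_outliers=20)
        pose, inl = estimate_rigid(m, q, r, tol_px=3.0, max_iters=2000, seed=1)
        assert set(inl) == set(range(10))
        assert abs(pose.theta - true.theta) < 1e-6
        assert np.hypot(pose.tx - true.tx, pose.ty - true.ty) < 1e-6

    def test_identity_on_identical_positions(self):
        rng = np.random.default_rng(4)
        q = rng.uniform(0, 100, size=(8, 2))
        pairs = np.column_stack([np.arange(8), np.arange(8)])
        pose, inl = estimate_rigid(MatchSet(pairs, np.zeros(8)), q, q,
                                   tol_px=3.0, max_iters=200, seed=0)
        assert pose.almost_equal(RigidPose(), tol=1e-9)
        assert len(inl) == 8

    def test_coincident_points_degenerate(self):
        q = np.zeros((5, 2))
        pairs = np.column_stack([np.arange(5), np.arange(5)])
        with pytest.raises(DegenerateGeometry):
            estimate_rigid(MatchSet(pairs, np.zeros(5)), q, q + 10.0,
                           tol_px=3.0, max_iters=100, seed=0)

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateGeometry):
            estimate_rigid(MatchSet(np.zeros((1, 2), int), np.zeros(1)),
                           np.zeros((1, 2)), np.zeros((1, 2)),
                           tol_px=3.0, max_iters=10, seed=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_refined_pose_is_procrustes_on_inliers(self, seed):
        """The returned pose equals the independent closed-form solution on
        the returned inlier set, even under noise + outliers."""
        rng = np.random.default_rng(seed)
        true = RigidPose(rng.uniform(-2, 2), *rng.uniform(-200, 200, 2))
        m, q, r = _exact_problem(30, true, seed=seed + 100, n_outliers=15)
        r = r + rng.normal(0, 0.5, r.shape)
        pose, inl = estimate_rigid(m, q, r, tol_px=3.0, max_iters=2000,
                                   seed=seed)
        th, t = procrustes_oracle(q[inl], r[inl])
        assert abs(pose.theta - th) < 1e-6
        assert np.allclose([pose.tx, pose.ty], t, atol=1e-6)

    def test_deterministic(self):
        m, q, r = _exact_problem(12, RigidPose(1.0, 5.0, 5.0), seed=9,
                                 n_outliers=12)
        a = estimate_rigid(m, q, r, tol_px=3.0, max_iters=500, seed=7)
        b = estimate_rigid(m, q, r, tol_px=3.0, max_iters=500, seed=7)
        assert a[0] == b[0]
        assert np.array_equal(a[1], b[1])


class TestGate:
    @pytest.mark.parametrize("count,expected", [(0, False), (5, False),
                                                (6, False), (7, True),
                                                (20, True)])
    def test_flip_at_printed_threshold(self, count, expected, cfg):
        assert gate_reliability(count, cfg) is expected

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(count=st.integers(0, 20), thr=st.integers(1, 15))
    def test_strictly_greater_semantics(self, count, thr):
        c = PipelineConfig(inlier_accept_threshold=thr)
        assert gate_reliability(count, c) == (count > thr)


class TestColocalize:
    def test_zero_noise_frame(self, sweep, sweep_registrations):
        reg, true = sweep_registrations[0], sweep.poses[0]
        assert reg.accepted and reg.source == "global"
        assert np.hypot(reg.pose.tx - true.tx, reg.pose.ty - true.ty) < 0.5
        assert angle_diff_deg(reg.pose.theta, true.theta) < 0.2

    def test_blank_frame_rejected_not_raised(self, ref_features, cfg, calibs,
                                             phantom):
        blank = np.zeros((400, 400, 3), np.uint8)
        reg = colocalize(blank, ref_features, calibs["surface"],
                         phantom.calibration, cfg)
        assert not reg.accepted and reg.source == "global"
        assert reg.failure is not None

    def test_unrelated_texture_rejected(self, ref_features, cfg, calibs,
                                        phantom):
        rng = np.random.default_rng(11)
        noise = (rng.random((400, 400, 3)) * 255).astype(np.uint8)
        reg = colocalize(noise, ref_features, calibs["surface"],
                         phantom.calibration, cfg)
        assert not reg.accepted

    def test_bit_identical_reruns(self, sweep, ref_features, cfg, calibs,
                                  phantom, sweep_registrations):
        again = colocalize(sweep.frames[0], ref_features, calibs["surface"],
                           phantom.calibration, cfg)
        first = sweep_registrations[0]
        assert again.pose == first.pose
        assert again.inlier_count == first.inlier_count
        assert np.array_equal(again.inlier_indices, first.inlier_indices)


def test_procrustes_direct_properties():
    rng = np.random.default_rng(5)
    src = rng.uniform(-50, 50, (20, 2))
    true = RigidPose(0.7, 3.0, -8.0)
    fit = procrustes_rigid(src, transform_points(true, src))
    assert fit.almost_equal(true, tol=1e-9)
    # reflections are projected onto proper rotations
    mirrored = transform_points(true, src * [-1, 1])
    fit2 = procrustes_rigid(src, mirrored)
    assert np.linalg.det(fit2.rotation()) > 0
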