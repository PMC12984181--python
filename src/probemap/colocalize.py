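"""Locate a surface frame within the wide-field reference image.

Pipeline: keypoint extraction on the scale-normalized frame -> one-way
nearest-descriptor matching -> RANSAC estimation of a rotation+translation
-> closed-form least-squares (Procrustes) refinement over the inliers ->
reliability gate on the inlier count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .errors import DegenerateGeometry, EmptyFrame, EmptyReference
from .features import KeypointSet, MatchSet, extract_surface_features, match_nearest
from .geometry import IDENTITY, RigidPose, transform_points

__all__ = [
    "RegistrationResult",
    "procrustes_rigid",
    "estimate_rigid",
    "gate_reliability",
    "colocalize",
]

log = logging.getLogger(__name__)


@dataclass
class RegistrationResult:
    """Outcome of registering one surface frame to the reference.

    pose maps scale-normalized surface coordinates into reference pixels.
    ``accepted`` is True only when the inlier count clears the reliability
    gate; a rejected pose is retained for diagnostics but must not be used
    for navigation. ``source`` distinguishes fresh global registrations from
    tracker-extrapolated poses.
    """

    pose: RigidPose
    inlier_count: int
    inlier_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    accepted: bool = False
    source: str = "global"
    n_matches: int = 0
    failure: str | None = None

    def to_dict(self) -> dict:
        return {
            "pose": self.pose.to_dict(),
            "inlier_count": int(self.inlier_count),
            "accepted": bool(self.accepted),
            "source": self.source,
            "n_matches": int(self.n_matches),
            "failure": self.failure,
        }


def procrustes_rigid(src: np.ndarray, dst: np.ndarray) -> RigidPose:
    """Closed-form least-squares rotation+translation mapping src -> dst.

    2-D orthogonal Procrustes restricted to proper rotations (det +1): the
    probe cannot mirror the skin, so reflections are excluded. Requires at
    least one point; with all points coincident the rotation is the
    identity.
    """
    P = np.asarray(src, dtype=float)
    Q = np.asarray(dst, dtype=float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    theta = float(np.arctan2(R[1, 0], R[0, 0]))
    t = cq - R @ cp
    return RigidPose(theta=theta, tx=float(t[0]), ty=float(t[1]))


def estimate_rigid(matches: MatchSet, query_pos: np.ndarray, ref_pos: np.ndarray,
                   tol_px: float, max_iters: int, seed: int) -> tuple:
    """RANSAC estimation of the rigid transform best aligning matched pairs.

    Two-point minimal samples give rotation+translation hypotheses; the
    hypothesis with the most inliers (residual < ``tol_px``) wins, ties going
    to the earliest sample. The winning inlier set is refined twice by
    closed-form Procrustes, re-selecting inliers after each refinement, so
    the returned pose is exactly the Procrustes solution on the returned
    inlier set.

    Returns ``(pose, inlier_indices)`` where indices select rows of
    ``matches.pairs``.

    Raises
    ------
    DegenerateGeometry
        With fewer than 2 pairs or when every sampled pair is coincident.
    """
    pairs = matches.pairs
    if len(pairs) < 2:
        raise DegenerateGeometry("need at least 2 correspondences")
    q = np.asarray(query_pos, dtype=float)[pairs[:, 0]]
    r = np.asarray(ref_pos, dtype=float)[pairs[:, 1]]
    n = len(pairs)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(max_iters, 2))
    valid = idx[:, 0] != idx[:, 1]
    i0, i1 = idx[valid, 0], idx[valid, 1]
    dq = q[i1] - q[i0]
    dr = r[i1] - r[i0]
    sep = np.hypot(dq[:, 0], dq[:, 1]) > 1e-9
    i0, i1, dq, dr = i0[sep], i1[sep], dq[sep], dr[sep]
    if len(i0) == 0:
        # all sampled pairs coincident: no rotation is observable
        if np.allclose(q, q[0], atol=1e-9) and n >= 2:
            raise DegenerateGeometry("all correspondence points coincident")
        raise DegenerateGeometry("no valid minimal sample found")

    thetas = np.arctan2(dr[:, 1], dr[:, 0]) - np.arctan2(dq[:, 1], dq[:, 0])
    cos, sin = np.cos(thetas), np.sin(thetas)
    # t = r0 - R q0 per hypothesis
    tx = r[i0, 0] - (cos * q[i0, 0] - sin * q[i0, 1])
    ty = r[i0, 1] - (sin * q[i0, 0] + cos * q[i0, 1])

    best_count, best_mask = -1, None
    # evaluate hypotheses in blocks: residual matrix (block, n)
    block = max(1, int(5e6) // max(1, n))
    tol2 = tol_px * tol_px
    for s in range(0, len(thetas), block):
        sl = slice(s, s + block)
        px = np.outer(cos[sl], q[:, 0]) - np.outer(sin[sl], q[:, 1]) + tx[sl, None]
        py = np.outer(sin[sl], q[:, 0]) + np.outer(cos[sl], q[:, 1]) + ty[sl, None]
        res2 = (px - r[None, :, 0]) ** 2 + (py - r[None, :, 1]) ** 2
        counts = (res2 < tol2).sum(axis=1)
        k = int(counts.argmax())
        if counts[k] > best_count:
            best_count = int(counts[k])
            best_mask = res2[k] < tol2

    if best_count < 2:
        raise DegenerateGeometry("no hypothesis with >= 2 inliers")

    mask = best_mask
    pose = None
    for _ in range(2):  # fixed refinement rounds, deterministic
        pose = procrustes_rigid(q[mask], r[mask])
        res = np.linalg.norm(transform_points(pose, q) - r, axis=1)
        new_mask = res < tol_px
        if new_mask.sum() < 2 or np.array_equal(new_mask, mask):
            mask = new_mask if new_mask.sum() >= 2 else mask
            break
        mask = new_mask
    pose = procrustes_rigid(q[mask], r[mask])
    return pose, np.flatnonzero(mask)


def gate_reliability(inlier_count: int, cfg: PipelineConfig) -> bool:
    """Reliability gate: accepted iff the inlier count is STRICTLY above the
    configured threshold (default 6 -> acceptance requires >= 7 inliers)."""
    return inlier_count > cfg.inlier_accept_threshold


def colocalize(surface_frame: np.ndarray, reference_features: KeypointSet,
               surface_calib, reference_calib, cfg: PipelineConfig) -> RegistrationResult:
    """Register one surface frame against the initialized reference.

    Never raises on bad frames: empty/degenerate frames come back as a
    rejected result so a live stream stays alive.
    """
    rejected = RegistrationResult(pose=IDENTITY, inlier_count=0, accepted=False)
    try:
        kps = extract_surface_features(surface_frame, surface_calib,
                                       reference_calib, cfg)
    except (EmptyFrame, EmptyReference, ValueError) as exc:
        rejected.failure = str(exc)
        return rejected
    matches = match_nearest(kps, reference_features,
                            cross_check=cfg.match_cross_check)
    try:
        pose, inliers = estimate_rigid(
            matches, kps.positions, reference_features.positions,
            tol_px=cfg.ransac_inlier_tol_px, max_iters=cfg.ransac_max_iters,
            seed=cfg.ransac_seed)
    except DegenerateGeometry as exc:
        rejected.failure = str(exc)
        rejected.n_matches = len(matches)
        return rejected
    count = int(len(inliers))
    return RegistrationResult(
        pose=pose,
        inlier_count=count,
        inlier_indices=inliers,
        accepted=gate_reliability(count, cfg),
        source="global",
        n_matches=len(matches),
    )
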