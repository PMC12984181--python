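"""Inter-frame motion estimation and the LOCKED / COASTING / LOST tracker.

While global registration is reliable the tracker simply relays it
(LOCKED). When the global gate drops out, accumulated inter-frame motion
extrapolates the position (COASTING) until either registration recovers —
snapping back to the fresh pose with no blending — or the motion confidence
collapses / the coasting cap is hit, which resets tracking (LOST).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .colocalize import RegistrationResult, estimate_rigid, match_nearest
from .config import PipelineConfig
from .errors import DegenerateGeometry, EmptyFrame
from .features import detect_keypoints, to_gray
from .geometry import IDENTITY, RigidPose, compose, invert

__all__ = ["MotionEstimate", "TrackerState", "interframe_motion", "step_tracker"]

log = logging.getLogger(__name__)

LOCKED = "LOCKED"
COASTING = "COASTING"
LOST = "LOST"


@dataclass(frozen=True)
class MotionEstimate:
    """Inter-frame motion: ``delta`` maps previous-frame pixel coordinates to
    current-frame pixel coordinates (surface scale); ``confidence`` is the
    inlier count of the fit (0 on textureless frames)."""

    delta: RigidPose
    confidence: int


@dataclass(frozen=True)
class TrackerState:
    """State of the dead-reckoning tracker.

    cumulative_delta accumulates inter-frame motion since the last reliable
    registration, newest motion composed on the left (right-to-left, oldest
    first); it is the identity whenever LOCKED.
    """

    status: str = LOST
    last_reliable_pose: RigidPose | None = None
    cumulative_delta: RigidPose = IDENTITY
    frames_coasted: int = 0


def _mask_circle(gray: np.ndarray) -> np.ndarray:
    h, w = gray.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = min(h, w) / 2.0
    m = (xx - (w - 1) / 2.0) ** 2 + (yy - (h - 1) / 2.0) ** 2 <= r * r
    return np.where(m, gray, 0)


def interframe_motion(prev_frame: np.ndarray, cur_frame: np.ndarray,
                      cfg: PipelineConfig,
                      downscale: float = 1.0) -> MotionEstimate:
    """Estimate rigid motion between successive surface frames.

    Both frames are masked to the circular FOV and matched with the same
    keypoint/descriptor machinery as global registration. ``downscale``
    optionally runs detection on resampled frames for speed; the returned
    translation is always expressed in original surface pixels.
    """
    if prev_frame.shape != cur_frame.shape:
        raise ValueError("frames must have the same shape")
    imgs = []
    for f in (prev_frame, cur_frame):
        g = to_gray(f)
        if downscale != 1.0:
            from skimage.transform import rescale
            g = np.rint(np.clip(
                rescale(g.astype(float) / 255.0, downscale, order=3,
                        anti_aliasing=downscale < 1.0), 0, 1) * 255).astype(np.uint8)
        imgs.append(_mask_circle(g))
    kp_prev = detect_keypoints(imgs[0], cfg)
    kp_cur = detect_keypoints(imgs[1], cfg)
    if len(kp_prev) == 0 or len(kp_cur) == 0:
        return MotionEstimate(delta=IDENTITY, confidence=0)
    matches = match_nearest(kp_prev, kp_cur, cross_check=cfg.match_cross_check)
    try:
        delta, inliers = estimate_rigid(
            matches, kp_prev.positions, kp_cur.positions,
            tol_px=cfg.ransac_inlier_tol_px, max_iters=cfg.ransac_max_iters,
            seed=cfg.ransac_seed)
    except DegenerateGeometry:
        return MotionEstimate(delta=IDENTITY, confidence=0)
    if downscale != 1.0:
        delta = RigidPose(theta=delta.theta, tx=delta.tx / downscale,
                          ty=delta.ty / downscale)
    return MotionEstimate(delta=delta, confidence=int(len(inliers)))


def _scale_pose(p: RigidPose, s: float) -> RigidPose:
    """Express a motion given in surface pixels at the reference pitch."""
    return RigidPose(theta=p.theta, tx=p.tx * s, ty=p.ty * s)


def step_tracker(state: TrackerState, reg: RegistrationResult | None,
                 motion: MotionEstimate | None, cfg: PipelineConfig,
                 scale: float = 1.0) -> tuple:
    """Advance the tracker by one frame.

    Parameters
    ----------
    reg : global registration result for this frame (None if not attempted).
    motion : inter-frame motion from the previous frame (None for the first
        frame of a stream).
    scale : surface -> reference scale factor used to express accumulated
        surface-pixel motion at the reference pitch.

    Returns
    -------
    (TrackerState, RigidPose or None)
        The effective pose in reference coordinates, or None when LOST.

    Notes
    -----
    A skin-fixed point moves by the INVERSE of the frame motion in frame
    coordinates, so the extrapolated pose is
    ``compose(last_reliable_pose, invert(scaled cumulative delta))``. On re-lock the
    output snaps to the fresh registration pose exactly (no blending) and
    accumulated drift is discarded.
    """
    if reg is not None and reg.accepted:
        new = TrackerState(status=LOCKED, last_reliable_pose=reg.pose,
                           cumulative_delta=IDENTITY, frames_coasted=0)
        return new, reg.pose

    confident = (motion is not None
                 and motion.confidence > cfg.tracking_confidence_threshold)
    if (state.last_reliable_pose is not None and confident
            and state.frames_coasted < cfg.coast_max_frames):
        cum = compose(motion.delta, state.cumulative_delta)
        effective = compose(state.last_reliable_pose,
                            invert(_scale_pose(cum, scale)))
        new = TrackerState(status=COASTING,
                           last_reliable_pose=state.last_reliable_pose,
                           cumulative_delta=cum,
                           frames_coasted=state.frames_coasted + 1)
        return new, effective

    if state.status != LOST:
        log.info("temporal tracking reset (confidence=%s, coasted=%d)",
                 None if motion is None else motion.confidence,
                 state.frames_coasted)
    return TrackerState(status=LOST), None
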