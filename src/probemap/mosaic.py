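"""Incremental wide-field dermoscopic mosaicking.

Each newly captured frame is registered against the *current composite*
(not pairwise against the previous frame) with the same rigid
keypoint/RANSAC pipeline used for probe co-localization, then blended in
with linear edge feathering. Poses are kept in first-frame coordinates; a
live-position helper registers a frame without inserting it, for the
real-time FOV marker and overlap guidance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .colocalize import estimate_rigid, gate_reliability
from .config import PipelineConfig
from .errors import DegenerateGeometry, InsufficientOverlap, MosaicFull
from .features import KeypointSet, detect_keypoints, match_nearest
from .geometry import IDENTITY, RigidPose, compose, invert, transform_points

__all__ = ["Mosaic", "LivePosition", "start", "add_frame", "live_position", "render"]


def _frame_corners(shape) -> np.ndarray:
    """Pixel-area corners of a (h, w[, c]) frame, CCW."""
    h, w = shape[:2]
    return np.array([[-0.5, -0.5], [w - 0.5, -0.5],
                     [w - 0.5, h - 0.5], [-0.5, h - 0.5]])


def _edge_weight(shape) -> np.ndarray:
    """Feathering weight: 1 + distance to the nearest frame edge."""
    h, w = shape[:2]
    xx = np.minimum(np.arange(w), np.arange(w)[::-1]).astype(float)
    yy = np.minimum(np.arange(h), np.arange(h)[::-1]).astype(float)
    return 1.0 + np.minimum.outer(yy, xx)


@dataclass
class LivePosition:
    """Live FOV rectangle in first-frame coordinates plus overlap guidance."""

    pose: RigidPose
    corners: np.ndarray
    overlap: float
    inlier_count: int


@dataclass
class Mosaic:
    """Incrementally stitched composite.

    frames : list of (image, pose) with pose mapping frame pixels into
        first-frame coordinates; the first pose is the identity.
    origin : first-frame coordinates of canvas pixel (0, 0).
    canvas : current composite (re-blended after every insertion).
    composite_features : keypoints of the current composite, recomputed
        after every insertion.
    """

    cfg: PipelineConfig
    frames: list = field(default_factory=list)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))
    canvas: np.ndarray | None = None
    composite_features: KeypointSet | None = None

    @property
    def count(self) -> int:
        return len(self.frames)

    def frame_polygons(self) -> list:
        return [Polygon(transform_points(pose, _frame_corners(img.shape)))
                for img, pose in self.frames]


def start(first_frame: np.ndarray, cfg: PipelineConfig) -> Mosaic:
    """Open a mosaic session with its anchor frame (identity pose)."""
    m = Mosaic(cfg=cfg)
    m.frames.append((np.asarray(first_frame).copy(), IDENTITY))
    m.origin = np.zeros(2)
    m.canvas = np.asarray(first_frame).copy()
    m.composite_features = detect_keypoints(m.canvas, cfg)
    return m


def _register_to_composite(m: Mosaic, frame: np.ndarray):
    """Rigid registration of a frame against the current composite.

    Returns (pose in first-frame coords, inlier count) or (None, count)
    when the reliability gate rejects.
    """
    kps = detect_keypoints(frame, m.cfg)
    if len(kps) == 0 or m.composite_features is None or len(m.composite_features) == 0:
        return None, 0
    matches = match_nearest(kps, m.composite_features,
                            cross_check=m.cfg.match_cross_check)
    try:
        pose_canvas, inliers = estimate_rigid(
            matches, kps.positions, m.composite_features.positions,
            tol_px=m.cfg.ransac_inlier_tol_px, max_iters=m.cfg.ransac_max_iters,
            seed=m.cfg.ransac_seed)
    except DegenerateGeometry:
        return None, 0
    count = int(len(inliers))
    if not gate_reliability(count, m.cfg):
        return None, count
    # canvas pixel p sits at first-frame coordinates p + origin
    shift = RigidPose(0.0, float(m.origin[0]), float(m.origin[1]))
    return compose(shift, pose_canvas), count


def add_frame(m: Mosaic, frame: np.ndarray) -> Mosaic:
    """Stitch one more frame into the mosaic (in place; returns ``m``).

    Raises
    ------
    MosaicFull
        When the mosaic already holds ``cfg.mosaic_max_frames`` frames.
    InsufficientOverlap
        When registration against the composite fails the reliability gate.
    """
    if m.count >= m.cfg.mosaic_max_frames:
        raise MosaicFull(f"mosaic already holds {m.count} frames "
                         f"(cap {m.cfg.mosaic_max_frames})")
    pose, count = _register_to_composite(m, np.asarray(frame))
    if pose is None:
        raise InsufficientOverlap(
            f"frame rejected by the reliability gate ({count} inliers)")
    m.frames.append((np.asarray(frame).copy(), pose))
    m.canvas, m.origin = render(m, with_origin=True)
    m.composite_features = detect_keypoints(m.canvas, m.cfg)
    return m


def live_position(m: Mosaic, live_frame: np.ndarray) -> LivePosition | None:
    """Locate a live frame relative to the first frame without stitching it.

    Returns None when the gate rejects (no reliable position). The overlap
    fraction of the live FOV with the already-covered area is surfaced as
    coverage guidance for the operator.
    """
    pose, count = _register_to_composite(m, np.asarray(live_frame))
    if pose is None:
        return None
    corners = transform_points(pose, _frame_corners(np.asarray(live_frame).shape))
    live_poly = Polygon(corners)
    covered = unary_union(m.frame_polygons())
    overlap = float(live_poly.intersection(covered).area / live_poly.area)
    return LivePosition(pose=pose, corners=corners, overlap=overlap,
                        inlier_count=count)


def render(m: Mosaic, with_origin: bool = False):
    """Blend all frames into a composite with linear edge feathering.

    Deterministic; pixels covered by a single frame reproduce that frame
    (exactly at integer poses, up to interpolation otherwise).
    """
    corners = np.concatenate([transform_points(pose, _frame_corners(img.shape))
                              for img, pose in m.frames])
    lo = np.floor(corners.min(axis=0) + 0.5)
    hi = np.ceil(corners.max(axis=0) - 0.5)
    origin = lo
    width = int(hi[0] - lo[0]) + 1
    height = int(hi[1] - lo[1]) + 1

    sample = m.frames[0][0]
    channels = 1 if sample.ndim == 2 else sample.shape[2]
    num = np.zeros((height, width, channels), dtype=float)
    den = np.zeros((height, width), dtype=float)

    for img, pose in m.frames:
        arr = np.asarray(img, dtype=float)
        if arr.ndim == 2:
            arr = arr[..., None]
        inv = invert(pose)
        # bounding box of this frame on the canvas grid
        c = transform_points(pose, _frame_corners(img.shape)) - origin
        x0 = max(0, int(np.floor(c[:, 0].min())))
        y0 = max(0, int(np.floor(c[:, 1].min())))
        x1 = min(width - 1, int(np.ceil(c[:, 0].max())))
        y1 = min(height - 1, int(np.ceil(c[:, 1].max())))
        if x1 < x0 or y1 < y0:
            continue
        gx, gy = np.meshgrid(np.arange(x0, x1 + 1, dtype=float),
                             np.arange(y0, y1 + 1, dtype=float))
        pts = np.column_stack([gx.ravel() + origin[0], gy.ravel() + origin[1]])
        src = transform_points(inv, pts)
        coords = [src[:, 1].reshape(gy.shape), src[:, 0].reshape(gx.shape)]
        w = ndi.map_coordinates(_edge_weight(img.shape), coords, order=1,
                                mode="constant", cval=0.0)
        if not np.any(w > 0):
            continue
        for ch in range(channels):
            v = ndi.map_coordinates(arr[..., ch], coords, order=1,
                                    mode="constant", cval=0.0)
            num[y0:y1 + 1, x0:x1 + 1, ch] += w * v
        den[y0:y1 + 1, x0:x1 + 1] += w

    out = np.zeros_like(num)
    mask = den > 0
    out[mask] = num[mask] / den[mask][:, None]
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if channels == 1:
        out = out[..., 0]
    return (out, origin) if with_origin else out
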