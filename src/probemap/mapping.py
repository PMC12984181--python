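"""Scored probe trajectory on the dermoscopy image and quadrant coverage.

Every effective (non-LOST) tracker pose contributes one scored sample:
its acquisition marker — a line segment for vertical sections, a rectangle
for horizontal sections or 3-D stacks — drawn at the registered position
and stroked in the blue-to-yellow color of its probability score.
Consecutive samples closer than two FOV radii are connected with a
color-interpolated segment so sweeps read as a continuous path; larger
jumps stay unconnected rather than inventing coverage. Extrapolated
(coasting) samples are drawn dashed.

Quadrant convention: clock angles from the lesion center, 12 o'clock along
-y, clockwise positive; quadrants 12-3, 3-6, 6-9, 9-12 o'clock.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import circle_perimeter, line as draw_line

from .errors import OpenPath
from .geometry import (CalibrationProfile, RigidPose, px_to_mm, scale_factor,
                       transform_points)
from .scoring import score_to_color

__all__ = [
    "Marker",
    "line_marker",
    "rect_marker",
    "ScoredSample",
    "Trajectory",
    "record",
    "render_overlay",
    "CoverageReport",
    "coverage_report",
]

log = logging.getLogger(__name__)

QUADRANT_NAMES = ("12-3", "3-6", "6-9", "9-12")


@dataclass(frozen=True)
class Marker:
    """Acquisition footprint in normalized surface coordinates.

    kind: ``line`` (vertical section) or ``rect`` (horizontal / 3-D).
    points: (2, 2) endpoints for a line, (4, 2) corners for a rectangle.
    """

    kind: str
    points: np.ndarray

    def centroid(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float).mean(axis=0)

    def segments(self) -> np.ndarray:
        pts = np.asarray(self.points, dtype=float)
        if self.kind == "line":
            return pts[None, :, :]
        nxt = np.roll(pts, -1, axis=0)
        return np.stack([pts, nxt], axis=1)


def _frame_center_norm(surface_calib: CalibrationProfile, s: float) -> np.ndarray:
    w, h = surface_calib.image_shape
    return np.array([s * ((w - 1) / 2.0 + 0.5) - 0.5,
                     s * ((h - 1) / 2.0 + 0.5) - 0.5])


def line_marker(surface_calib: CalibrationProfile,
                reference_calib: CalibrationProfile,
                section_calib: CalibrationProfile) -> Marker:
    """Centered horizontal line spanning the section's lateral extent."""
    s = scale_factor(surface_calib, reference_calib)
    c = _frame_center_norm(surface_calib, s)
    half = 0.5 * section_calib.fov_mm[0] * 1000.0 / reference_calib.mean_pitch_um
    return Marker("line", np.array([[c[0] - half, c[1]], [c[0] + half, c[1]]]))


def rect_marker(surface_calib: CalibrationProfile,
                reference_calib: CalibrationProfile,
                section_calib: CalibrationProfile) -> Marker:
    """Centered rectangle with the horizontal section's footprint."""
    s = scale_factor(surface_calib, reference_calib)
    c = _frame_center_norm(surface_calib, s)
    hw = 0.5 * section_calib.fov_mm[0] * 1000.0 / reference_calib.mean_pitch_um
    hh = 0.5 * section_calib.fov_mm[1] * 1000.0 / reference_calib.mean_pitch_um
    pts = np.array([[c[0] - hw, c[1] - hh], [c[0] + hw, c[1] - hh],
                    [c[0] + hw, c[1] + hh], [c[0] - hw, c[1] + hh]])
    return Marker("rect", pts)


@dataclass(frozen=True)
class ScoredSample:
    """One recorded acquisition: pose, marker footprint and score."""

    index: int
    pose: RigidPose
    marker: Marker
    score: float
    source: str = "global"   # "global" or "extrapolated"

    def marker_points_ref(self) -> np.ndarray:
        return transform_points(self.pose, self.marker.points)

    def center_ref(self) -> np.ndarray:
        return transform_points(self.pose, self.marker.centroid())


@dataclass
class Trajectory:
    """Ordered scored samples forming the acquisition path."""

    lesion_center_px: np.ndarray
    fov_radius_px: float
    samples: list = field(default_factory=list)
    quadrant_colors: dict = field(default_factory=lambda: {
        "12-3": (20, 20, 20), "3-6": (200, 30, 30),
        "6-9": (30, 160, 50), "9-12": (130, 40, 160)})

    @classmethod
    def for_setup(cls, lesion_center_px, surface_calib: CalibrationProfile,
                  reference_calib: CalibrationProfile) -> "Trajectory":
        s = scale_factor(surface_calib, reference_calib)
        radius = s * min(surface_calib.image_shape) / 2.0
        return cls(lesion_center_px=np.asarray(lesion_center_px, dtype=float),
                   fov_radius_px=radius)

    def __len__(self) -> int:
        return len(self.samples)


def record(traj: Trajectory, effective_pose: RigidPose | None, marker: Marker,
           score: float, source: str = "global",
           index: int | None = None) -> Trajectory:
    """Append one scored sample; LOST frames (pose None) are skipped with a
    warning and leave the trajectory unchanged."""
    if effective_pose is None:
        log.warning("skipping LOST frame (no effective pose)")
        return traj
    if not (0.0 <= score <= 100.0):
        raise ValueError("score must be in [0, 100]")
    idx = index if index is not None else (
        traj.samples[-1].index + 1 if traj.samples else 0)
    traj.samples.append(ScoredSample(index=idx, pose=effective_pose,
                                     marker=marker, score=float(score),
                                     source=source))
    return traj


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _put(img, x, y, color):
    h, w = img.shape[:2]
    if 0 <= x < w and 0 <= y < h:
        img[y, x] = color


def _stroke(img, p0, p1, color, dashed=False, thick=True):
    """Integer Bresenham stroke with optional dashing and cross-thickening."""
    r0, c0 = int(round(p0[1])), int(round(p0[0]))
    r1, c1 = int(round(p1[1])), int(round(p1[0]))
    rr, cc = draw_line(r0, c0, r1, c1)
    for k, (r, c) in enumerate(zip(rr, cc)):
        if dashed and (k // 4) % 2 == 1:
            continue
        _put(img, c, r, color)
        if thick:
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                _put(img, c + dx, r + dy, color)


def _stroke_gradient(img, p0, p1, c0, c1):
    """Segment whose color interpolates linearly between two endpoint
    colors (used for the connecting path between nearby samples)."""
    r0, cc0 = int(round(p0[1])), int(round(p0[0]))
    r1, cc1 = int(round(p1[1])), int(round(p1[0]))
    rr, cc = draw_line(r0, cc0, r1, cc1)
    n = max(1, len(rr) - 1)
    for k, (r, c) in enumerate(zip(rr, cc)):
        f = k / n
        col = tuple(int(round((1 - f) * a + f * b)) for a, b in zip(c0, c1))
        _put(img, c, r, col)


def render_overlay(dermoscopy_image: np.ndarray, traj: Trajectory) -> np.ndarray:
    """Draw the scored acquisition path on (a copy of) the reference image.

    Deterministic. Marker stroke color equals ``score_to_color(score)``
    exactly; the latest sample additionally carries the FOV circle and an
    orientation arrow.
    """
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    img = np.asarray(dermoscopy_image)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    img = img.copy()

    # connecting path first so markers draw on top
    for prev, cur in zip(traj.samples, traj.samples[1:]):
        a, b = prev.center_ref(), cur.center_ref()
        if np.linalg.norm(b - a) < 2.0 * traj.fov_radius_px:
            _stroke_gradient(img, a, b, score_to_color(prev.score),
                             score_to_color(cur.score))

    # FOV circle + orientation arrow of the latest sample, under the markers
    # so marker centroids keep their exact score color
    last = traj.samples[-1]
    center = last.center_ref()
    rr, cc = circle_perimeter(int(round(center[1])), int(round(center[0])),
                              int(round(traj.fov_radius_px)),
                              shape=img.shape[:2])
    img[rr, cc] = (255, 255, 255)
    heading = np.array([math.cos(last.pose.theta), math.sin(last.pose.theta)])
    tip = center + 0.8 * traj.fov_radius_px * heading
    _stroke(img, center, tip, (255, 255, 255), thick=False)
    for wing in (math.radians(150), math.radians(-150)):
        a = last.pose.theta + wing
        w = tip + 0.25 * traj.fov_radius_px * np.array([math.cos(a), math.sin(a)])
        _stroke(img, tip, w, (255, 255, 255), thick=False)

    for sample in traj.samples:
        pts = sample.marker_points_ref()
        color = score_to_color(sample.score)
        dashed = sample.source == "extrapolated"
        for seg in (np.stack([pts, np.roll(pts, -1, axis=0)], axis=1)
                    if sample.marker.kind == "rect" else pts[None]):
            _stroke(img, seg[0], seg[1], color, dashed=dashed)
    return img


# --------------------------------------------------------------------------
# Coverage
# --------------------------------------------------------------------------

@dataclass
class CoverageReport:
    """Per-quadrant margin coverage and uncovered arc segments.

    fractions: quadrant name -> fraction of that quadrant's margin arc lying
    within the gap tolerance of any recorded marker. gaps: list of
    (start_mm, end_mm) arc-length intervals (along the polyline) without
    coverage.
    """

    fractions: dict
    gaps: list
    gap_tol_mm: float
    arc_length_mm: float


def _resample_closed(path: np.ndarray, step: float):
    """Uniform arc-length resampling of a closed polyline. Returns points
    and their arc-length positions."""
    seg = np.diff(path, axis=0)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    total = cum[-1]
    n = max(8, int(math.ceil(total / step)))
    s = np.arange(n) * total / n
    x = np.interp(s, cum, path[:, 0])
    y = np.interp(s, cum, path[:, 1])
    return np.column_stack([x, y]), s, total


def _point_segment_dist(points: np.ndarray, segs: np.ndarray) -> np.ndarray:
    """Min distance from each point to any segment. points (n,2),
    segs (m,2,2) -> (n,)."""
    a, b = segs[:, 0], segs[:, 1]
    ab = b - a
    denom = np.maximum((ab * ab).sum(axis=1), 1e-12)
    ap = points[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None]).sum(axis=2) / denom[None, :], 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)


def quadrant_of(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Quadrant index (0: 12-3, 1: 3-6, 2: 6-9, 3: 9-12) per point."""
    d = np.atleast_2d(points) - np.asarray(center)
    ang = np.degrees(np.arctan2(d[:, 0], -d[:, 1])) % 360.0
    return (ang // 90.0).astype(int)


def coverage_report(traj: Trajectory, margin_path: np.ndarray,
                    gap_tol_mm: float,
                    calib: CalibrationProfile) -> CoverageReport:
    """Fraction of each quadrant's margin arc within ``gap_tol_mm`` of any
    recorded marker, plus the list of uncovered arc segments.

    ``margin_path`` is a closed (first point == last point) simple polyline
    in reference pixels.

    Raises
    ------
    OpenPath
        If the polyline is not closed.
    """
    path = np.asarray(margin_path, dtype=float)
    if path.ndim != 2 or len(path) < 4:
        raise OpenPath("margin path needs at least 3 distinct vertices")
    if not np.allclose(path[0], path[-1], atol=1e-6):
        raise OpenPath("margin path is not closed (first point != last)")

    pitch_mm = calib.mean_pitch_um / 1000.0
    tol_px = gap_tol_mm / pitch_mm
    pts, s_px, total_px = _resample_closed(path, step=max(1.0, tol_px / 5.0))

    quad = quadrant_of(pts, traj.lesion_center_px)
    if len(traj) == 0:
        covered = np.zeros(len(pts), dtype=bool)
    else:
        segs = np.concatenate([
            transform_points(smp.pose, smp.marker.points)[
                _seg_index(smp.marker)] for smp in traj.samples])
        covered = _point_segment_dist(pts, segs) <= tol_px

    fractions = {}
    for k, name in enumerate(QUADRANT_NAMES):
        in_q = quad == k
        fractions[name] = float(covered[in_q].mean()) if in_q.any() else 0.0

    gaps = []
    if not covered.all():
        uncov = np.flatnonzero(~covered)
        breaks = np.flatnonzero(np.diff(uncov) > 1)
        runs = np.split(uncov, breaks + 1)
        if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == len(pts) - 1:
            runs[0] = np.concatenate([runs[-1], runs[0]])
            runs = runs[:-1]
        step_px = total_px / len(pts)
        for run in runs:
            s0 = s_px[run[0]] * pitch_mm
            s1 = (s_px[run[-1]] + step_px) * pitch_mm
            gaps.append((float(s0), float(s1)))
    return CoverageReport(fractions=fractions, gaps=gaps,
                          gap_tol_mm=gap_tol_mm,
                          arc_length_mm=float(total_px * pitch_mm))


def _seg_index(marker: Marker):
    """Row pairs turning marker points into segment arrays."""
    if marker.kind == "line":
        return np.array([[0, 1]])
    return np.array([[0, 1], [1, 2], [2, 3], [3, 0]])
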