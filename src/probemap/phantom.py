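"""Synthetic phantoms with known ground truth.

Three generators, all pure functions of (spec, seed):

* dermoscopy-like reference phantoms: multi-octave band-pass noise plus
  scattered elliptical blobs (a pigment-network proxy chosen for stable
  keypoints, not for photorealism), four colored quadrant ink arcs, and a
  radially sigmoid lesion-probability field with optional angular lobes;
* simulated probe streams: the phantom resampled through known rigid poses
  at the surface-image pitch, circularly masked, with optional noise,
  illumination gain and defocus blur;
* vertical-section-like frames whose bright-pixel density in a sub-surface
  band is calibrated to the probability field at the probe position, so the
  reference density scorer recovers the field value.

Clock convention (used for quadrants, paths and lobes): angles in degrees
from the lesion center, 12 o'clock along -y, increasing clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .errors import PathOutOfBounds
from .geometry import (CalibrationProfile, RigidPose, default_calibrations,
                       mm_to_px, scale_factor, transform_points)

__all__ = [
    "PhantomSpec",
    "Phantom",
    "NoiseConfig",
    "ProbePath",
    "BscanConfig",
    "QUADRANT_COLORS",
    "generate_phantom",
    "make_margin_path",
    "simulate_surface_stream",
    "simulate_bscan",
    "clock_to_xy",
]

# ink scheme of the quadrant protocol: 12-3 black, 3-6 red, 6-9 green,
# 9-12 purple
QUADRANT_COLORS = {
    "12-3": (20, 20, 20),
    "3-6": (200, 30, 30),
    "6-9": (30, 160, 50),
    "9-12": (130, 40, 160),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a dermoscopy-like phantom.

    The default canvas covers the full 13.3 x 8.9 mm dermoscope field at
    12.5 um/px (1064 x 712 px): coarser than the device sensor, but with the
    true physical extent, so registration runs at realistic keypoint
    densities on one CPU.

    The probability field is ``p(r, phi) = plateau / (1 + exp((r -
    edge(phi)) / slope))`` with ``edge(phi) = edge_mm`` plus the extent of
    any angular lobe covering clock angle ``phi`` (raised-cosine tapered
    over ``lobe_taper_deg``). At ``r = edge(phi)`` the field is exactly half
    the plateau.
    """

    image_shape: tuple = (1064, 712)          # (width, height) px
    fov_mm: tuple = (13.3, 8.9)
    lesion_center_mm: tuple | None = None     # default: canvas center
    lesion_radius_mm: float = 1.2
    margin_offset_mm: float = 1.8             # ink ring at lesion radius + offset
    plateau: float = 100.0
    edge_mm: float | None = None              # default: lesion radius
    slope_mm: float = 0.15
    angular_lobes: tuple = ()                 # (start_deg, end_deg, extent_mm)
    lobe_taper_deg: float = 15.0
    texture_octaves: tuple = ((0.8, 1.0), (1.6, 0.9), (3.2, 0.7),
                              (6.4, 0.5), (12.8, 0.4))   # (sigma_px, weight)
    n_blobs: int = 300
    blob_darkening: float = 0.25
    ink_thickness_mm: float = 0.06
    seed: int = 0

    @property
    def calibration(self) -> CalibrationProfile:
        return CalibrationProfile("dermoscope", self.fov_mm, self.image_shape)

    @property
    def center_mm(self) -> tuple:
        if self.lesion_center_mm is not None:
            return self.lesion_center_mm
        return (self.fov_mm[0] / 2.0, self.fov_mm[1] / 2.0)

    @property
    def margin_radius_mm(self) -> float:
        return self.lesion_radius_mm + self.margin_offset_mm


@dataclass
class Phantom:
    """Generated phantom: image, probability field and ground truth."""

    image: np.ndarray          # (H, W, 3) uint8
    field: np.ndarray          # (H, W) float, percent
    spec: PhantomSpec

    @property
    def calibration(self) -> CalibrationProfile:
        return self.spec.calibration

    @property
    def center_px(self) -> np.ndarray:
        return mm_to_px(self.calibration, self.spec.center_mm)

    def field_at(self, pts_px) -> np.ndarray:
        """Bilinear probe of the probability field at (x, y) pixel points."""
        pts = np.atleast_2d(np.asarray(pts_px, dtype=float))
        return ndi.map_coordinates(self.field, [pts[:, 1], pts[:, 0]],
                                   order=1, mode="nearest")


def clock_to_xy(deg) -> np.ndarray:
    """Unit vector for a clock angle (0 deg = 12 o'clock = -y, clockwise)."""
    a = np.deg2rad(np.asarray(deg, dtype=float))
    return np.stack([np.sin(a), -np.cos(a)], axis=-1)


def _clock_angle_deg(dx, dy) -> np.ndarray:
    """Inverse of :func:`clock_to_xy`, in [0, 360)."""
    return np.rad2deg(np.arctan2(dx, -dy)) % 360.0


def _lobe_window(phi_deg: np.ndarray, start: float, end: float,
                 taper: float) -> np.ndarray:
    """Raised-cosine angular window on the clock circle, 1 inside
    [start, end], tapering to 0 over ``taper`` degrees outside."""
    span = (end - start) % 360.0
    rel = (phi_deg - start) % 360.0
    w = np.zeros_like(rel)
    inside = rel <= span
    w[inside] = 1.0
    lead = (~inside) & ((rel - span) <= taper)
    w[lead] = 0.5 * (1 + np.cos(np.pi * (rel[lead] - span) / taper))
    trail = (~inside) & ((360.0 - rel) <= taper)
    w[trail] = 0.5 * (1 + np.cos(np.pi * (360.0 - rel[trail]) / taper))
    return w


def _probability_field(spec: PhantomSpec) -> np.ndarray:
    w, h = spec.image_shape
    calib = spec.calibration
    pitch = np.array(calib.pixel_pitch_um) / 1000.0
    xx, yy = np.meshgrid(np.arange(w) * pitch[0], np.arange(h) * pitch[1])
    cx, cy = spec.center_mm
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    edge = np.full_like(r, spec.edge_mm if spec.edge_mm is not None
                        else spec.lesion_radius_mm)
    if spec.angular_lobes:
        phi = _clock_angle_deg(dx, dy)
        for (a0, a1, extent) in spec.angular_lobes:
            edge = edge + extent * _lobe_window(phi, a0, a1, spec.lobe_taper_deg)
    p = spec.plateau / (1.0 + np.exp((r - edge) / spec.slope_mm))
    return np.clip(p, 0.0, 100.0)


def _draw_ink_arcs(img: np.ndarray, spec: PhantomSpec) -> None:
    """Four colored quadrant arcs on the margin ring, 2-degree gaps at the
    quadrant boundaries (in place)."""
    h, w = img.shape[:2]
    calib = spec.calibration
    pitch = np.array(calib.pixel_pitch_um) / 1000.0
    xx, yy = np.meshgrid(np.arange(w) * pitch[0], np.arange(h) * pitch[1])
    cx, cy = spec.center_mm
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    phi = _clock_angle_deg(dx, dy)
    ring = np.abs(r - spec.margin_radius_mm) <= spec.ink_thickness_mm / 2.0
    for k, (name, color) in enumerate(QUADRANT_COLORS.items()):
        a0, a1 = 90.0 * k + 2.0, 90.0 * (k + 1) - 2.0
        sector = (phi >= a0) & (phi < a1)
        img[ring & sector] = color


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministic phantom synthesis: identical spec + seed give a
    bit-identical image and field."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.image_shape
    acc = np.zeros((h, w))
    for sigma, weight in spec.texture_octaves:
        n = ndi.gaussian_filter(rng.standard_normal((h, w)), sigma)
        acc += weight * n / n.std()
    acc = (acc - acc.mean()) / acc.std()
    lum = 0.52 + 0.22 * acc

    # pigment-network proxy: scattered dark ellipses
    for _ in range(spec.n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a, b = rng.uniform(2, 6), rng.uniform(2, 6)
        th = rng.uniform(0, math.pi)
        y0, y1 = max(0, int(cy - 8)), min(h, int(cy + 8))
        x0, x1 = max(0, int(cx - 8)), min(w, int(cx + 8))
        if y1 <= y0 or x1 <= x0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dyy, dxx = yy - cy, xx - cx
        u = dxx * math.cos(th) + dyy * math.sin(th)
        v = -dxx * math.sin(th) + dyy * math.cos(th)
        m = (u / a) ** 2 + (v / b) ** 2 < 1
        lum[y0:y1, x0:x1][m] -= spec.blob_darkening
    lum = np.clip(lum, 0.0, 1.0)

    base = np.array([225.0, 172.0, 148.0])  # skin tone
    img = np.clip(np.rint(lum[..., None] * base), 0, 255).astype(np.uint8)
    _draw_ink_arcs(img, spec)
    return Phantom(image=img, field=_probability_field(spec), spec=spec)


# --------------------------------------------------------------------------
# Probe streams
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    """Per-frame degradations of the simulated surface stream.

    gaussian_sigma is on the 0..1 intensity scale (e.g. 5/255);
    illumination_jitter is the std of a multiplicative gain around 1;
    defocus_sigma_px blurs the sampled frame.
    """

    gaussian_sigma: float = 0.0
    illumination_jitter: float = 0.0
    defocus_sigma_px: float = 0.0


@dataclass(frozen=True)
class ProbePath:
    """Ordered true poses of a simulated acquisition.

    Each pose maps scale-normalized surface coordinates (surface frame
    resampled to the reference pitch) into reference pixels — the same
    convention the registration pipeline estimates.
    """

    poses: tuple
    seed: int = 0


@dataclass(frozen=True)
class StreamResult:
    frames: tuple
    poses: tuple        # true poses, normalized-surface -> reference px
    centers_px: tuple   # true frame-center positions in reference px


def _norm_offset(s: float) -> float:
    # raw surface pixel u sits at normalized coordinate s*(u+0.5)-0.5,
    # matching the pixel-center convention of the resampling step
    return 0.5 * s - 0.5


def _pose_from_center(center_px, theta: float, surface_shape, s: float) -> RigidPose:
    w, h = surface_shape
    # center of the raw frame, ((w-1)/2, (h-1)/2), in normalized coordinates
    cn = np.array([s * ((w - 1) / 2.0 + 0.5) - 0.5,
                   s * ((h - 1) / 2.0 + 0.5) - 0.5])
    c, si = math.cos(theta), math.sin(theta)
    R = np.array([[c, -si], [si, c]])
    t = np.asarray(center_px, dtype=float) - R @ cn
    return RigidPose(theta=theta, tx=float(t[0]), ty=float(t[1]))


def make_margin_path(phantom: Phantom, n_frames: int,
                     start_clock_deg: float = 0.0, sweep_deg: float = 360.0,
                     radius_mm: float | None = None,
                     jitter_mm: float = 0.0, jitter_deg: float = 0.0,
                     heading_offset_deg: float = 90.0,
                     seed: int = 0,
                     surface_calib: CalibrationProfile | None = None) -> ProbePath:
    """True poses sweeping the margin ring.

    The probe heading rotates with the sweep; the default heading offset of
    90 degrees keeps the vertical-section line perpendicular to the margin
    (imaging ACROSS the margin, as in margin assessment), so successive
    section markers do not overlap along the path.

    Raises
    ------
    PathOutOfBounds
        If any frame's circular FOV would leave the phantom canvas.
    """
    spec = phantom.spec
    calib_ref = phantom.calibration
    surf = surface_calib or default_calibrations()["surface"]
    s = scale_factor(surf, calib_ref)
    rng = np.random.default_rng(seed)
    radius = spec.margin_radius_mm if radius_mm is None else radius_mm
    center = np.asarray(spec.center_mm)
    poses = []
    angles = start_clock_deg + sweep_deg * np.arange(n_frames) / max(1, n_frames - 1) \
        if n_frames > 1 else np.array([start_clock_deg])
    for a in angles:
        pos_mm = center + radius * clock_to_xy(a)
        if jitter_mm:
            pos_mm = pos_mm + rng.normal(0.0, jitter_mm, size=2)
        theta = math.radians(a + heading_offset_deg + rng.normal(0.0, jitter_deg))
        cpx = mm_to_px(calib_ref, pos_mm)
        poses.append(_pose_from_center(cpx, theta, surf.image_shape, s))
    path = ProbePath(poses=tuple(poses), seed=seed)
    _check_path_bounds(phantom, path, surf, s)
    return path


def _check_path_bounds(phantom: Phantom, path: ProbePath,
                       surf: CalibrationProfile, s: float) -> None:
    h, w = phantom.image.shape[:2]
    fw, fh = surf.image_shape
    cn = np.array([s * ((fw - 1) / 2.0 + 0.5) - 0.5,
                   s * ((fh - 1) / 2.0 + 0.5) - 0.5])
    r_ref = s * min(fw, fh) / 2.0
    for k, pose in enumerate(path.poses):
        c = transform_points(pose, cn)
        if not (r_ref - 0.5 <= c[0] <= w - 0.5 - r_ref
                and r_ref - 0.5 <= c[1] <= h - 0.5 - r_ref):
            raise PathOutOfBounds(f"frame {k}: FOV circle leaves the canvas")


def simulate_surface_stream(phantom: Phantom, path: ProbePath,
                            noise: NoiseConfig = NoiseConfig(),
                            seed: int = 0,
                            surface_calib: CalibrationProfile | None = None) -> StreamResult:
    """Render the surface-image stream a probe following ``path`` would see.

    Each frame samples the phantom through the true pose at the surface
    pitch (bicubic), applies the configured degradations, and masks the
    circular FOV. Deterministic per (phantom, path, noise, seed).
    """
    surf = surface_calib or default_calibrations()["surface"]
    s = scale_factor(surf, phantom.calibration)
    _check_path_bounds(phantom, path, surf, s)
    fw, fh = surf.image_shape
    uu, vv = np.meshgrid(np.arange(fw, dtype=float), np.arange(fh, dtype=float))
    off = _norm_offset(s)
    norm = np.stack([s * uu + off, s * vv + off], axis=-1).reshape(-1, 2)
    yy, xx = np.mgrid[0:fh, 0:fw]
    mask = ((xx - (fw - 1) / 2.0) ** 2 + (yy - (fh - 1) / 2.0) ** 2
            <= (min(fw, fh) / 2.0) ** 2)
    rng = np.random.default_rng(seed)
    img = phantom.image.astype(float) / 255.0
    cn = np.array([s * ((fw - 1) / 2.0 + 0.5) - 0.5,
                   s * ((fh - 1) / 2.0 + 0.5) - 0.5])

    frames, centers = [], []
    for pose in path.poses:
        ref = transform_points(pose, norm)
        coords = [ref[:, 1].reshape(fh, fw), ref[:, 0].reshape(fh, fw)]
        chans = [ndi.map_coordinates(img[..., c], coords, order=3,
                                     mode="nearest") for c in range(3)]
        frame = np.stack(chans, axis=-1)
        gain = 1.0 + (rng.normal(0.0, noise.illumination_jitter)
                      if noise.illumination_jitter else 0.0)
        frame = frame * gain
        if noise.defocus_sigma_px:
            frame = ndi.gaussian_filter(frame, (noise.defocus_sigma_px,
                                                noise.defocus_sigma_px, 0))
        if noise.gaussian_sigma:
            frame = frame + rng.normal(0.0, noise.gaussian_sigma, frame.shape)
        frame = np.where(mask[..., None], np.clip(frame, 0, 1), 0.0)
        frames.append(np.rint(frame * 255).astype(np.uint8))
        centers.append(transform_points(pose, cn))
    return StreamResult(frames=tuple(frames), poses=tuple(path.poses),
                        centers_px=tuple(centers))


# --------------------------------------------------------------------------
# Vertical-section frames
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BscanConfig:
    """Geometry and intensity layout of synthetic vertical-section frames.

    The scoring band spans ``band`` (fractions of the frame height); within
    it, a smooth random field is thresholded so that EXACTLY the calibrated
    fraction of band pixels is at or above ``cutoff`` — bright lobule-like
    blobs on a darker dermis, under a brighter epidermis strip.
    """

    image_shape: tuple = (2048, 680)   # (width, height) px
    band: tuple = (0.25, 1.0)          # fraction of height
    cutoff: int = 128
    blob_sigma_px: float = 9.0

    @property
    def band_rows(self) -> tuple:
        h = self.image_shape[1]
        return (int(round(self.band[0] * h)), int(round(self.band[1] * h)))

    def make_scorer(self):
        from .scoring import ReferenceDensityScorer
        return ReferenceDensityScorer(intensity_cutoff=self.cutoff,
                                      band=self.band_rows)


def simulate_bscan(phantom: Phantom, pose: RigidPose,
                   cfg: BscanConfig = BscanConfig(), seed: int = 0,
                   surface_calib: CalibrationProfile | None = None) -> np.ndarray:
    """Synthesize the vertical-section frame acquired at ``pose``.

    The in-band bright-pixel fraction equals the probability field at the
    frame-center position (to one pixel of rounding), so the reference
    density scorer recovers the field value.
    """
    surf = surface_calib or default_calibrations()["surface"]
    s = scale_factor(surf, phantom.calibration)
    fw, fh = surf.image_shape
    cn = np.array([s * ((fw - 1) / 2.0 + 0.5) - 0.5,
                   s * ((fh - 1) / 2.0 + 0.5) - 0.5])
    center = transform_points(pose, cn)
    p = float(phantom.field_at(center)[0])

    rng = np.random.default_rng(seed)
    w, h = cfg.image_shape
    frame = 40.0 + 60.0 * rng.random((h, w))            # dermis background < cutoff
    r0, r1 = cfg.band_rows
    frame[:r0] = 140.0 + 40.0 * rng.random((r0, w))     # epidermis strip
    band = frame[r0:r1]
    n_band = band.size
    k = int(round(p / 100.0 * n_band))
    if k > 0:
        g = ndi.gaussian_filter(rng.standard_normal(band.shape), cfg.blob_sigma_px)
        order = np.argsort(g, axis=None)[::-1][:k]      # brightest blobs first
        bright = np.zeros(band.shape, dtype=bool)
        bright.ravel()[order] = True
        vals = band.copy()
        vals[bright] = 200.0 + 40.0 * rng.random(int(k))
        vals[~bright] = np.minimum(vals[~bright], float(cfg.cutoff) - 1.0)
        frame[r0:r1] = vals
    else:
        frame[r0:r1] = np.minimum(band, float(cfg.cutoff) - 1.0)
    return np.clip(np.rint(frame), 0, 255).astype(np.uint8)
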