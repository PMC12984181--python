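"""Coordinate conventions, calibration profiles and rigid-transform algebra.

Conventions used throughout the package
---------------------------------------
* Pixel coordinates are 0-based ``(x, y)``: x rightward, y downward, origin at
  the top-left pixel center. Angles are measured counter-clockwise (CCW) in
  this frame, in radians.
* Physical coordinates are in millimetres with the origin coinciding with the
  center of pixel ``(0, 0)``, so ``px = mm / pitch`` exactly.
* A :class:`RigidPose` maps *source* pixel coordinates into *destination*
  pixel coordinates: ``dst = R(theta) @ src + t``. There is no scale term;
  images of different pixel pitch must be resampled to a common scale first
  (see :func:`scale_factor`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidPose",
    "IDENTITY",
    "compose",
    "invert",
    "transform_points",
    "CalibrationProfile",
    "default_calibrations",
    "scale_factor",
    "mm_to_px",
    "px_to_mm",
]


def _wrap_angle(theta: float) -> float:
    """Wrap an angle to the interval (-pi, pi]."""
    w = math.remainder(theta, 2.0 * math.pi)
    if w <= -math.pi:
        w += 2.0 * math.pi
    return w


@dataclass(frozen=True)
class RigidPose:
    """2-D rotation + translation, ``dst = R(theta) @ src + (tx, ty)``.

    The linear part is a pure rotation (determinant +1): reflections and
    scale are excluded by construction.
    """

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    @property
    def t(self) -> np.ndarray:
        return np.array([self.tx, self.ty], dtype=float)

    def rotation(self) -> np.ndarray:
        c, s = math.cos(self.theta), math.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def matrix(self) -> np.ndarray:
        """2x3 homogeneous matrix ``[R | t]``."""
        return np.column_stack([self.rotation(), self.t])

    def apply(self, pts) -> np.ndarray:
        return transform_points(self, pts)

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Pose applying ``other`` first, then ``self``."""
        return compose(self, other)

    def __matmul__(self, other: "RigidPose") -> "RigidPose":
        return compose(self, other)

    def invert(self) -> "RigidPose":
        return invert(self)

    def almost_equal(self, other: "RigidPose", tol: float = 1e-9) -> bool:
        dth = abs(_wrap_angle(self.theta - other.theta))
        return dth <= tol and abs(self.tx - other.tx) <= tol and abs(self.ty - other.ty) <= tol

    def to_dict(self) -> dict:
        return {"theta": self.theta, "tx": self.tx, "ty": self.ty}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidPose":
        return cls(theta=float(d["theta"]), tx=float(d["tx"]), ty=float(d["ty"]))


IDENTITY = RigidPose()


def compose(a: RigidPose, b: RigidPose) -> RigidPose:
    """Pose applying ``b`` first, then ``a`` (associative)."""
    ta = a.rotation() @ b.t + a.t
    return RigidPose(theta=_wrap_angle(a.theta + b.theta), tx=float(ta[0]), ty=float(ta[1]))


def invert(p: RigidPose) -> RigidPose:
    """Inverse pose: ``compose(invert(p), p)`` is the identity."""
    ti = -(p.rotation().T @ p.t)
    return RigidPose(theta=_wrap_angle(-p.theta), tx=float(ti[0]), ty=float(ti[1]))


def transform_points(p: RigidPose, pts) -> np.ndarray:
    """Apply a pose to an ``(N, 2)`` array (or single pair) of (x, y) points."""
    arr = np.asarray(pts, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    out = arr @ p.rotation().T + p.t
    return out[0] if single else out


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationProfile:
    """Physical <-> pixel mapping for one imaging modality.

    Parameters
    ----------
    modality : str
        One of ``dermoscope``, ``surface``, ``lcoct_vertical``,
        ``lcoct_horizontal``, ``lcoct_3d``.
    fov_mm : tuple of float
        Physical extent (width, height) in mm. For a circular field of view
        both entries equal the diameter.
    image_shape : tuple of int
        Pixel dimensions (width, height).
    circular : bool
        True only for the probe's color surface image, whose FOV is the
        inscribed circle of the square sensor.
    """

    modality: str
    fov_mm: tuple
    image_shape: tuple
    circular: bool = False

    def __post_init__(self):
        if len(self.fov_mm) != 2 or len(self.image_shape) != 2:
            raise ValueError("fov_mm and image_shape must be (width, height)")
        if self.circular and self.fov_mm[0] != self.fov_mm[1]:
            raise ValueError("circular profiles take a single diameter")
        px, py = self.pixel_pitch_um
        if not (px > 0 and py > 0):
            raise ValueError("pixel pitch must be positive on both axes")

    @property
    def pixel_pitch_um(self) -> tuple:
        """Micrometres per pixel along (x, y)."""
        return (
            1000.0 * self.fov_mm[0] / self.image_shape[0],
            1000.0 * self.fov_mm[1] / self.image_shape[1],
        )

    @property
    def mean_pitch_um(self) -> float:
        px, py = self.pixel_pitch_um
        return 0.5 * (px + py)

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "fov_mm": list(self.fov_mm),
            "image_shape": list(self.image_shape),
            "circular": self.circular,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationProfile":
        return cls(
            modality=str(d["modality"]),
            fov_mm=tuple(float(v) for v in d["fov_mm"]),
            image_shape=tuple(int(v) for v in d["image_shape"]),
            circular=bool(d.get("circular", False)),
        )


def default_calibrations() -> dict:
    """Built-in device calibrations (field of view and sensor dimensions).

    dermoscope: 13.3 x 8.9 mm at 5536 x 3692 px; surface: 2.6 mm circular
    at 400 x 400 px; LC-OCT vertical section: 1.2 x 0.4 mm at 2048 x 680 px;
    horizontal section: 1.2 x 0.5 mm at 2048 x 850 px.
    """
    return {
        "dermoscope": CalibrationProfile("dermoscope", (13.3, 8.9), (5536, 3692)),
        "surface": CalibrationProfile("surface", (2.6, 2.6), (400, 400), circular=True),
        "lcoct_vertical": CalibrationProfile("lcoct_vertical", (1.2, 0.4), (2048, 680)),
        "lcoct_horizontal": CalibrationProfile("lcoct_horizontal", (1.2, 0.5), (2048, 850)),
    }


def scale_factor(src: CalibrationProfile, dst: CalibrationProfile,
                 anisotropy_tol: float = 0.01) -> float:
    """Resampling ratio bringing ``src`` pixels to the ``dst`` pixel pitch.

    Because the registration model carries no scale term, the known pitch
    ratio is applied up front: resampling the source image by the returned
    factor puts both images on a common um/px grid.

    Raises
    ------
    ValueError
        If the per-axis ratios disagree by more than ``anisotropy_tol``
        (relative): an anisotropic pitch mismatch cannot be absorbed by an
        isotropic resample.
    """
    sx = src.pixel_pitch_um[0] / dst.pixel_pitch_um[0]
    sy = src.pixel_pitch_um[1] / dst.pixel_pitch_um[1]
    mean = 0.5 * (sx + sy)
    if abs(sx - sy) / mean > anisotropy_tol:
        raise ValueError(
            f"anisotropic pitch mismatch between {src.modality} and "
            f"{dst.modality}: per-axis ratios {sx:.4f} vs {sy:.4f}"
        )
    return mean


def mm_to_px(calib: CalibrationProfile, pt_mm):
    """Convert physical (x, y) mm to pixel coordinates. Origin at pixel (0,0).

    Points outside the FOV are converted as-is (callers may range-check);
    the mapping is affine, not clipped.
    """
    pitch = np.array(calib.pixel_pitch_um) / 1000.0  # mm per px
    return np.asarray(pt_mm, dtype=float) / pitch


def px_to_mm(calib: CalibrationProfile, pt_px):
    """Inverse of :func:`mm_to_px`."""
    pitch = np.array(calib.pixel_pitch_um) / 1000.0
    return np.asarray(pt_px, dtype=float) * pitch
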