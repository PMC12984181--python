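"""Keypoint detection and nearest-descriptor matching.

Detection runs on luminance (ITU-R BT.601 weights for RGB input) with a
difference-of-Gaussians SIFT detector; descriptors are 128-dimensional.
Surface frames are first resampled to the reference pixel pitch and masked
to their inscribed circular field of view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import SIFT
from skimage.transform import rescale

from .config import PipelineConfig
from .errors import EmptyFrame, EmptyReference
from .geometry import CalibrationProfile, scale_factor

__all__ = [
    "KeypointSet",
    "MatchSet",
    "to_gray",
    "detect_keypoints",
    "init_reference",
    "extract_surface_features",
    "match_nearest",
]


@dataclass
class KeypointSet:
    """Detected keypoints with descriptors.

    positions : (N, 2) float array of (x, y) pixel coordinates.
    scales, orientations : per-keypoint detector outputs.
    descriptors : (N, D) array, D = 128 by default.
    """

    positions: np.ndarray
    scales: np.ndarray
    orientations: np.ndarray
    descriptors: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)

    def subset(self, mask) -> "KeypointSet":
        return KeypointSet(
            positions=self.positions[mask],
            scales=self.scales[mask],
            orientations=self.orientations[mask],
            descriptors=self.descriptors[mask],
        )


@dataclass
class MatchSet:
    """One-way nearest-neighbor correspondences.

    pairs : (M, 2) int array of (query index, reference index); every query
        index appears at most once.
    distances : (M,) Euclidean descriptor distances, all >= 0.
    """

    pairs: np.ndarray
    distances: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)


def to_gray(image: np.ndarray) -> np.ndarray:
    """Luminance as uint8. RGB is converted with BT.601 weights."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    if img.dtype != np.uint8:
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img


def detect_keypoints(image: np.ndarray, cfg: PipelineConfig) -> KeypointSet:
    """Run the detector on a grayscale/RGB image. Deterministic.

    Returns an empty :class:`KeypointSet` when nothing is found; callers
    decide whether that is an error.
    """
    gray = to_gray(image)
    det = SIFT(c_dog=cfg.sift_c_dog)
    try:
        det.detect_and_extract(gray)
    except RuntimeError:  # detector found no features at all
        z = np.zeros
        return KeypointSet(z((0, 2)), z(0), z(0), z((0, 128)))
    # the detector's initial x`upsampling` resample shifts reported positions
    # by a constant (1 - 1/u)/2 px (measured via 180-degree-rotation
    # self-consistency); undo it so poses are unbiased
    bias = 0.5 * (1.0 - 1.0 / det.upsampling)
    return KeypointSet(
        positions=det.positions[:, ::-1].astype(float) - bias,  # (row, col) -> (x, y)
        scales=det.scales.copy(),
        orientations=det.orientations.copy(),
        descriptors=det.descriptors.astype(np.float32),
    )


def init_reference(reference_image: np.ndarray, cfg: PipelineConfig,
                   mask: np.ndarray | None = None) -> KeypointSet:
    """Process the wide-field reference once; its keypoints are reused for
    every streamed frame.

    Raises
    ------
    EmptyReference
        If no keypoints are found (flat image).
    """
    kps = detect_keypoints(reference_image, cfg)
    if mask is not None and len(kps):
        xi = np.clip(np.rint(kps.positions[:, 0]).astype(int), 0, mask.shape[1] - 1)
        yi = np.clip(np.rint(kps.positions[:, 1]).astype(int), 0, mask.shape[0] - 1)
        kps = kps.subset(mask[yi, xi])
    if len(kps) == 0:
        raise EmptyReference("no keypoints in reference image")
    return kps


def normalize_surface_frame(frame: np.ndarray, surface_calib: CalibrationProfile,
                            reference_calib: CalibrationProfile) -> tuple:
    """Resample a surface frame to the reference pitch and mask the inscribed
    circle. Returns ``(gray uint8 image, scale factor)``."""
    s = scale_factor(surface_calib, reference_calib)
    gray = to_gray(frame).astype(float) / 255.0
    resampled = rescale(gray, s, order=3, anti_aliasing=s < 1.0)
    h, w = resampled.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = min(h, w) / 2.0
    mask = (xx - (w - 1) / 2.0) ** 2 + (yy - (h - 1) / 2.0) ** 2 <= r * r
    out = np.where(mask, np.clip(resampled, 0, 1), 0.0)
    return (np.rint(out * 255).astype(np.uint8), s)


def extract_surface_features(frame: np.ndarray, surface_calib: CalibrationProfile,
                             reference_calib: CalibrationProfile,
                             cfg: PipelineConfig) -> KeypointSet:
    """Detect keypoints on a scale-normalized, circularly masked surface frame.

    Positions are reported at the reference scale (pixels of the resampled
    frame). Keypoints within ``cfg.mask_edge_margin_px`` of the mask boundary
    are discarded.

    Raises
    ------
    EmptyFrame
        If nothing survives detection + boundary filtering.
    """
    if tuple(frame.shape[:2][::-1]) != tuple(surface_calib.image_shape):
        raise ValueError(
            f"frame shape {frame.shape[:2][::-1]} does not match surface "
            f"calibration {surface_calib.image_shape}"
        )
    norm, _s = normalize_surface_frame(frame, surface_calib, reference_calib)
    kps = detect_keypoints(norm, cfg)
    if len(kps):
        h, w = norm.shape
        c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        radius = min(h, w) / 2.0
        dist = np.linalg.norm(kps.positions - c, axis=1)
        kps = kps.subset(dist < radius - cfg.mask_edge_margin_px)
    if len(kps) == 0:
        raise EmptyFrame("no keypoints in surface frame")
    return kps


def match_nearest(query: KeypointSet, reference: KeypointSet,
                  cross_check: bool = False) -> MatchSet:
    """Match every query descriptor to its minimum-Euclidean-distance
    reference descriptor.

    Exactly one pair per query descriptor; ties broken toward the lowest
    reference index. With ``cross_check=True``, pairs are kept only when the
    query is also the reference descriptor's nearest query (optional
    symmetric filter, off by default).
    """
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("match_nearest requires nonempty keypoint sets")
    qd = query.descriptors.astype(np.float32)
    rd = reference.descriptors.astype(np.float32)
    # chunk the query side to bound the distance-matrix memory
    nn = np.empty(len(qd), dtype=np.int64)
    dist = np.empty(len(qd), dtype=np.float64)
    step = max(1, int(2e7) // max(1, len(rd)))
    for i in range(0, len(qd), step):
        d = cdist(qd[i:i + step], rd)
        nn[i:i + step] = d.argmin(axis=1)  # argmin -> lowest index on ties
        dist[i:i + step] = d[np.arange(d.shape[0]), nn[i:i + step]]
    pairs = np.column_stack([np.arange(len(qd)), nn])
    if cross_check:
        keep = np.zeros(len(qd), dtype=bool)
        rev = np.empty(len(rd), dtype=np.int64)
        for j in range(0, len(rd), step):
            d = cdist(rd[j:j + step], qd)
            rev[j:j + step] = d.argmin(axis=1)
        keep = rev[nn] == np.arange(len(qd))
        pairs, dist = pairs[keep], dist[keep]
    return MatchSet(pairs=pairs, distances=dist)
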