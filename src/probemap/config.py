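"""Pipeline configuration: tunable thresholds with device defaults.

The defaults are also shipped as a documented YAML file
(``probemap/data/defaults.yaml``) so external tooling can read them without
importing the package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .geometry import CalibrationProfile, default_calibrations

__all__ = ["PipelineConfig", "load_config", "save_config", "default_config_path"]


@dataclass
class PipelineConfig:
    """Thresholds and detector settings for the co-localization pipeline.

    Attributes
    ----------
    inlier_accept_threshold : int
        A registration is accepted only when its RANSAC inlier count is
        STRICTLY greater than this value (device default 6: at 6 or fewer
        inliers the result is rejected as unreliable).
    mosaic_max_frames : int
        Maximum number of dermoscopic frames in one mosaic (device cap 40).
    ransac_inlier_tol_px : float
        Residual tolerance (pixels, at the reference scale) for a
        correspondence to count as an inlier.
    ransac_max_iters : int
        Number of RANSAC hypotheses sampled.
    ransac_seed : int
        Seed of the RANSAC PRNG; fixed seed -> bit-identical results.
    tracking_confidence_threshold : int
        Inter-frame motion inlier count required (strictly greater) to keep
        extrapolating position while global registration is unreliable.
    coast_max_frames : int
        Forced reset after this many consecutively extrapolated frames.
    patch_size_px, patch_stride_px : int
        Heatmap patch grid geometry.
    patch_score_threshold : float
        Patches scoring below this percentage are suppressed in the heatmap.
    sift_c_dog : float
        Difference-of-Gaussians contrast threshold of the keypoint detector.
    match_cross_check : bool
        Optional symmetric nearest-neighbor filter (OFF by default: plain
        one-way nearest-descriptor matching).
    mask_edge_margin_px : float
        Keypoints closer than this to the circular mask boundary are
        discarded.
    """

    inlier_accept_threshold: int = 6
    mosaic_max_frames: int = 40
    ransac_inlier_tol_px: float = 3.0
    ransac_max_iters: int = 2000
    ransac_seed: int = 0
    tracking_confidence_threshold: int = 6
    coast_max_frames: int = 25
    patch_size_px: int = 128
    patch_stride_px: int = 64
    patch_score_threshold: float = 50.0
    sift_c_dog: float = 0.04
    match_cross_check: bool = False
    mask_edge_margin_px: float = 6.0

    def __post_init__(self):
        for name in ("inlier_accept_threshold", "mosaic_max_frames",
                     "ransac_max_iters", "tracking_confidence_threshold",
                     "coast_max_frames", "patch_size_px", "patch_stride_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ransac_inlier_tol_px <= 0:
            raise ValueError("ransac_inlier_tol_px must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def default_config_path() -> Path:
    """Path of the packaged, documented defaults file."""
    return Path(resources.files("probemap").joinpath("data/defaults.yaml"))


def load_config(path=None) -> tuple:
    """Load ``(PipelineConfig, {modality: CalibrationProfile})`` from YAML.

    Missing keys fall back to the built-in defaults; ``path=None`` loads the
    packaged defaults file.
    """
    p = default_config_path() if path is None else Path(path)
    with open(p) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig.from_dict(raw.get("pipeline", {}))
    calibs = default_calibrations()
    for name, d in (raw.get("calibrations") or {}).items():
        d = dict(d)
        d.setdefault("modality", name)
        calibs[name] = CalibrationProfile.from_dict(d)
    return cfg, calibs


def save_config(path, cfg: PipelineConfig, calibs=None) -> None:
    doc = {"pipeline": cfg.to_dict()}
    if calibs:
        doc["calibrations"] = {k: v.to_dict() for k, v in calibs.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
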