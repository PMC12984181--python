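"""Examination sessions: per-frame pipeline orchestration and JSON I/O.

One session file records one examination: configuration snapshot,
calibrations, the reference image (by path + content hash, never embedded),
every frame's registration result, tracker status and score, and the scored
trajectory. Serialization is canonical (sorted keys, fixed indentation) so
identical runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import __version__
from .colocalize import colocalize
from .config import PipelineConfig
from .errors import EmptyReference, SchemaError
from .features import init_reference, to_gray
from .geometry import RigidPose, default_calibrations, scale_factor
from .mapping import Marker, Trajectory, line_marker, record
from .scoring import ReferenceDensityScorer, global_score
from .tracking import TrackerState, interframe_motion, step_tracker

__all__ = ["Session", "save_session", "load_session", "run_colocalize_stream",
           "resolve_scorer"]

log = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class Session:
    """Serializable record of one co-localization run."""

    version: str
    seeds: dict
    config: dict
    calibrations: dict
    reference: dict                 # {"path": ..., "sha256": ...}
    frames: list = field(default_factory=list)
    trajectory: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def save_session(session: Session, path) -> None:
    text = json.dumps(session.to_dict(), sort_keys=True, indent=2) + "\n"
    Path(path).write_text(text)


_FRAME_KEYS = {"index", "path", "sha256", "registration", "tracker_status",
               "score"}
_TOP_KEYS = {"version", "seeds", "config", "calibrations", "reference",
             "frames", "trajectory"}


def _require(d: dict, key: str, typ, pointer: str):
    if key not in d:
        raise SchemaError(f"{pointer}/{key}", "missing required field")
    v = d[key]
    if typ is float:
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise SchemaError(f"{pointer}/{key}", f"expected number, got {type(v).__name__}")
    elif not isinstance(v, typ):
        raise SchemaError(f"{pointer}/{key}",
                          f"expected {typ.__name__}, got {type(v).__name__}")
    return v


def _validate_pose(d, pointer):
    for k in ("theta", "tx", "ty"):
        _require(d, k, float, pointer)


def load_session(path) -> Session:
    """Parse and schema-validate a session file.

    Unknown extra fields (e.g. from a newer minor version) load with a
    warning; structural problems raise :class:`SchemaError` carrying a
    JSON-pointer to the offending field.
    """
    try:
        raw = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise SchemaError("/", f"not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError("/", "session document must be a JSON object")

    extra = set(raw) - _TOP_KEYS
    if extra:
        warnings.warn(f"session has unknown fields {sorted(extra)}; "
                      "loading anyway (forward compatibility)")
    _require(raw, "version", str, "")
    _require(raw, "seeds", dict, "")
    _require(raw, "config", dict, "")
    _require(raw, "calibrations", dict, "")
    ref = _require(raw, "reference", dict, "")
    _require(ref, "path", str, "/reference")
    frames = _require(raw, "frames", list, "")
    for i, fr in enumerate(frames):
        ptr = f"/frames/{i}"
        if not isinstance(fr, dict):
            raise SchemaError(ptr, "frame record must be an object")
        _require(fr, "index", int, ptr)
        _require(fr, "path", str, ptr)
        reg = _require(fr, "registration", dict, ptr)
        _validate_pose(_require(reg, "pose", dict, f"{ptr}/registration"),
                       f"{ptr}/registration/pose")
        _require(reg, "inlier_count", int, f"{ptr}/registration")
        _require(reg, "accepted", bool, f"{ptr}/registration")
        _require(fr, "tracker_status", str, ptr)
    traj = _require(raw, "trajectory", dict, "")
    for i, smp in enumerate(traj.get("samples", [])):
        ptr = f"/trajectory/samples/{i}"
        _validate_pose(_require(smp, "pose", dict, ptr), f"{ptr}/pose")
        _require(smp, "score", float, ptr)
    return Session(**{k: raw[k] for k in _TOP_KEYS if k in raw})


def trajectory_from_session(session: Session) -> Trajectory:
    t = session.trajectory
    traj = Trajectory(
        lesion_center_px=np.asarray(t.get("lesion_center_px", [0.0, 0.0])),
        fov_radius_px=float(t.get("fov_radius_px", 1.0)))
    for smp in t.get("samples", []):
        marker = Marker(kind=smp["marker"]["kind"],
                        points=np.asarray(smp["marker"]["points"], dtype=float))
        record(traj, RigidPose.from_dict(smp["pose"]), marker,
               float(smp["score"]), source=smp.get("source", "global"),
               index=int(smp["index"]))
    return traj


def resolve_scorer(name: str):
    """Scorer plug-in lookup by name: ``none`` or ``density``."""
    if name in (None, "none"):
        return None
    if name == "density":
        return ReferenceDensityScorer()
    raise ValueError(f"unknown scorer {name!r}")


def list_frame_files(frames_dir) -> list:
    d = Path(frames_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"frames directory not found: {d}")
    files = sorted(p for p in d.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not files:
        raise FileNotFoundError(f"no image frames (PNG/TIFF) in directory: {d}")
    return files


def run_colocalize_stream(reference_path, frames_dir, cfg: PipelineConfig | None = None,
                          calibs: dict | None = None, scorer_name: str = "none",
                          lesion_center_px=None, seed: int = 0) -> Session:
    """Run the full per-frame pipeline over a directory of surface frames.

    Frames are processed in sorted filename order: global registration,
    inter-frame motion, tracker update, optional scoring, trajectory
    recording. Rejected frames are data, not errors.
    """
    cfg = cfg or PipelineConfig()
    calibs = calibs or default_calibrations()
    surf, ref_cal = calibs["surface"], calibs["dermoscope"]

    reference = iio.imread(reference_path)
    ref_feats = init_reference(reference, cfg)
    s = scale_factor(surf, ref_cal)
    files = list_frame_files(frames_dir)

    if lesion_center_px is None:
        lesion_center_px = (reference.shape[1] / 2.0, reference.shape[0] / 2.0)
    traj = Trajectory.for_setup(lesion_center_px, surf, ref_cal)
    marker = line_marker(surf, ref_cal, calibs["lcoct_vertical"])
    scorer = resolve_scorer(scorer_name)

    state = TrackerState()
    prev = None
    frames = []
    for i, f in enumerate(files):
        frame = iio.imread(f)
        reg = colocalize(frame, ref_feats, surf, ref_cal, cfg)
        motion = (interframe_motion(prev, frame, cfg, downscale=s)
                  if prev is not None else None)
        state, effective = step_tracker(state, reg, motion, cfg, scale=s)
        score = (global_score(scorer, to_gray(frame))
                 if scorer is not None else None)
        if effective is not None:
            src = "global" if state.status == "LOCKED" else "extrapolated"
            record(traj, effective, marker,
                   score if score is not None else 0.0, source=src, index=i)
        log.info("frame %d: status=%s inliers=%d score=%s",
                 i, state.status, reg.inlier_count, score)
        frames.append({
            "index": i,
            "path": str(f),
            "sha256": _sha256(f),
            "registration": reg.to_dict(),
            "tracker_status": state.status,
            "score": score,
        })
        prev = frame

    return Session(
        version=__version__,
        seeds={"seed": int(seed), "ransac_seed": int(cfg.ransac_seed)},
        config=cfg.to_dict(),
        calibrations={k: v.to_dict() for k, v in calibs.items()},
        reference={"path": str(reference_path), "sha256": _sha256(reference_path)},
        frames=frames,
        trajectory={
            "lesion_center_px": list(map(float, np.asarray(lesion_center_px))),
            "fov_radius_px": float(traj.fov_radius_px),
            "samples": [{
                "index": smp.index,
                "pose": smp.pose.to_dict(),
                "marker": {"kind": smp.marker.kind,
                           "points": np.asarray(smp.marker.points).tolist()},
                "score": float(smp.score),
                "source": smp.source,
            } for smp in traj.samples],
        },
    )
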