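"""Lesion-probability scoring of vertical-section frames and patch heatmaps.

A *scorer* is any pure callable mapping a grayscale image region to a
probability score in percent, 0..100. The trained diagnostic model behind
the device is proprietary; :class:`ReferenceDensityScorer` is this package's
deterministic scorer: the fraction of in-band pixels at or above an
intensity cutoff. Heatmaps apply a scorer to an overlapping patch grid,
suppress patches below a retention threshold, and color the retained
patches by the frame's *global* score on a blue (0%) to yellow (100%)
linear RGB ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .errors import PatchTooLarge

__all__ = [
    "ReferenceDensityScorer",
    "score_to_color",
    "global_score",
    "patch_scores",
    "Heatmap",
    "build_heatmap",
]


@dataclass(frozen=True)
class ReferenceDensityScorer:
    """Bright-pixel density scorer.

    score = 100 * (fraction of in-band pixels >= intensity_cutoff).

    ``band`` restricts scoring to a sub-surface row range ``(r0, r1)`` of the
    input region (clipped to its height); None scores all rows. Pure and
    deterministic by construction.
    """

    intensity_cutoff: int = 128
    band: tuple | None = None

    def __call__(self, region: np.ndarray) -> float:
        img = np.asarray(region)
        if img.ndim != 2:
            raise ValueError("scorer expects a grayscale region")
        if self.band is not None:
            r0 = int(np.clip(self.band[0], 0, img.shape[0]))
            r1 = int(np.clip(self.band[1], 0, img.shape[0]))
            img = img[r0:r1]
        if img.size == 0:
            return 0.0
        frac = float(np.count_nonzero(img >= self.intensity_cutoff)) / img.size
        return float(np.clip(100.0 * frac, 0.0, 100.0))


_BLUE = np.array([0.0, 0.0, 255.0])
_YELLOW = np.array([255.0, 255.0, 0.0])


def score_to_color(score: float) -> tuple:
    """Linear RGB ramp from pure blue at 0% to pure yellow at 100%.

    Endpoints are exact; out-of-range scores are clipped. Returns an
    ``(r, g, b)`` tuple of ints in 0..255.
    """
    s = float(np.clip(score, 0.0, 100.0)) / 100.0
    rgb = np.rint((1.0 - s) * _BLUE + s * _YELLOW).astype(int)
    return (int(rgb[0]), int(rgb[1]), int(rgb[2]))


def global_score(scorer, frame: np.ndarray) -> float:
    """Apply a scorer to the whole frame; result bounded to [0, 100]."""
    return float(np.clip(scorer(frame), 0.0, 100.0))


def _grid_starts(dim: int, patch: int, stride: int) -> np.ndarray:
    """Patch start offsets covering [0, dim): regular stride plus a final
    flush patch when the stride does not tile the dimension exactly."""
    starts = list(range(0, dim - patch + 1, stride))
    if starts[-1] != dim - patch:
        starts.append(dim - patch)
    return np.asarray(starts, dtype=int)


def patch_scores(scorer, frame: np.ndarray, patch_size: int, stride: int) -> tuple:
    """Score every patch of an overlapping grid covering the frame.

    Returns ``(scores, xs, ys)``: a (len(ys), len(xs)) array of per-patch
    scores and the patch start offsets along each axis.

    Raises
    ------
    PatchTooLarge
        When the patch exceeds either frame dimension.
    """
    h, w = frame.shape[:2]
    if patch_size > h or patch_size > w:
        raise PatchTooLarge(f"patch {patch_size} px exceeds frame {w}x{h}")
    xs = _grid_starts(w, patch_size, stride)
    ys = _grid_starts(h, patch_size, stride)
    scores = np.empty((len(ys), len(xs)), dtype=float)
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            scores[i, j] = float(np.clip(
                scorer(frame[y:y + patch_size, x:x + patch_size]), 0.0, 100.0))
    return scores, xs, ys


@dataclass
class Heatmap:
    """Thresholded patch-score overlay for one frame.

    Retained patches (score >= threshold) are all drawn in the color of the
    frame's global score — a frame-level suspicion cue, not a per-patch one —
    unless ``per_patch_color`` diagnostics mode is on.
    """

    patch_size: int
    stride: int
    xs: np.ndarray
    ys: np.ndarray
    scores: np.ndarray
    retained: np.ndarray
    global_score: float
    threshold: float
    per_patch_color: bool = False

    @property
    def color(self) -> tuple:
        return score_to_color(self.global_score)

    def patch_color(self, i: int, j: int) -> tuple:
        if self.per_patch_color:
            return score_to_color(self.scores[i, j])
        return self.color

    def render_overlay(self, frame: np.ndarray, alpha: float = 0.45) -> np.ndarray:
        """Blend retained patches over the grayscale frame; suppressed
        patches leave the frame untouched."""
        base = np.repeat(np.asarray(frame, dtype=float)[..., None], 3, axis=2)
        tint = np.zeros_like(base)
        wsum = np.zeros(frame.shape[:2], dtype=float)
        for i, y in enumerate(self.ys):
            for j, x in enumerate(self.xs):
                if self.retained[i, j]:
                    tint[y:y + self.patch_size, x:x + self.patch_size] += \
                        np.array(self.patch_color(i, j), dtype=float)
                    wsum[y:y + self.patch_size, x:x + self.patch_size] += 1.0
        m = wsum > 0
        tint[m] /= wsum[m][:, None]
        out = base.copy()
        out[m] = (1 - alpha) * base[m] + alpha * tint[m]
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)

    def to_dict(self) -> dict:
        return {
            "patch_size": int(self.patch_size),
            "stride": int(self.stride),
            "xs": self.xs.tolist(),
            "ys": self.ys.tolist(),
            "scores": self.scores.tolist(),
            "retained": self.retained.tolist(),
            "global_score": float(self.global_score),
            "threshold": float(self.threshold),
        }


def build_heatmap(scorer, frame: np.ndarray, cfg: PipelineConfig,
                  per_patch_color: bool = False) -> Heatmap:
    """Score a patch grid and keep only patches at or above the retention
    threshold (``cfg.patch_score_threshold``, percent)."""
    scores, xs, ys = patch_scores(scorer, frame, cfg.patch_size_px,
                                  cfg.patch_stride_px)
    g = global_score(scorer, frame)
    return Heatmap(
        patch_size=cfg.patch_size_px,
        stride=cfg.patch_stride_px,
        xs=xs, ys=ys,
        scores=scores,
        retained=scores >= cfg.patch_score_threshold,
        global_score=g,
        threshold=cfg.patch_score_threshold,
        per_patch_color=per_patch_color,
    )
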