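# Methods

`probemap` implements the computational core of a co-localized dermoscopy /
LC-OCT margin-mapping workstation: locating the narrow-field probe surface
image inside a wide-field dermoscopy image in real time, bridging
registration dropouts with dead-reckoning, stitching dermoscopic mosaics,
scoring vertical sections with a pluggable probability scorer, and
rendering the scored acquisition path for per-quadrant margin review.
This note records the models, conventions, numerical choices and known
limitations.

## Coordinate conventions

Pixel coordinates are 0-based `(x, y)`, x rightward, y downward, origin at
the top-left pixel center; angles are CCW radians in that frame. Physical
coordinates are millimetres with the origin at the center of pixel (0, 0),
so `px = mm / pitch` exactly. A `RigidPose` is `dst = R(theta) @ src + t` —
rotation plus translation only. Proper rotations are enforced everywhere
(determinant +1): a handheld probe cannot mirror the skin.

Because the rigid model carries no scale term, images of different pixel
pitch are brought to a common grid first: a surface frame is resampled by
`scale_factor(surface, reference)` (ratio of mean pixel pitches, bicubic,
anti-aliased) before feature extraction. The resampler maps raw pixel `u`
to normalized coordinate `s*(u + 0.5) - 0.5` (pixel-center convention);
the same convention is used by the phantom simulator so ground-truth poses
are directly comparable to estimates. Per-axis pitch ratios that disagree
by more than 1% are rejected as an anisotropic mismatch.

## Calibration

Built-in profiles carry the device constants: video-dermoscope
13.3 × 8.9 mm at 5536 × 3692 px; circular color surface image, 2.6 mm
diameter at 400 × 400 px (the FOV is the inscribed circle of the square
sensor); vertical section 1.2 × 0.4 mm at 2048 × 680 px; horizontal
section 1.2 × 0.5 mm at 2048 × 850 px. All profiles are overridable from
the YAML config; the packaged `data/defaults.yaml` documents every
tunable.

## Registration (co-localization)

1. **Initialization**: SIFT keypoints + 128-D descriptors of the
   wide-field reference, computed once per examination.
   Detection runs on BT.601 luminance; the detector is scikit-image's SIFT
   with contrast threshold `c_dog = 0.04` (exposed in config). The
   detector's internal 2× upsampling shifts reported positions by a
   constant +0.25 px; this is subtracted so estimated poses are unbiased
   (without the correction, rotated frames acquire up to ~0.7 px of
   systematic translation error through the `(I − R)·δ` term).
2. **Per frame**: the surface frame is scale-normalized, masked to its
   inscribed circle (keypoints within 6 px of the mask boundary are
   discarded — the mask edge itself generates spurious responses), and
   matched one-way to the reference: each frame descriptor pairs with its
   minimum-Euclidean-distance reference descriptor, ties to the lowest
   index. No ratio test is applied; an optional symmetric cross-check
   filter exists behind a config flag, default off.
3. **RANSAC**: two-point minimal samples give rotation+translation
   hypotheses (2000 iterations, seeded PRNG, inlier tolerance 3 px at
   reference scale); the best consensus set is refined by closed-form 2-D
   Procrustes (SVD, reflection-projected), re-selecting inliers, twice.
   The returned pose is therefore exactly the least-squares rigid fit on
   the returned inlier set — a property the tests check against an
   independent implementation.
4. **Gate**: the result is reliable only when the inlier count is
   *strictly greater than* 6. The two device statements ("above 6 …
   reliable", "threshold of 6 … below which … rejected") leave exactly 6
   ambiguous; this implementation rejects at 6, requiring ≥ 7 to accept.
   Rejected and failed frames return a rejected result rather than an
   exception, so a live stream never dies.

## Tracking fallback

Inter-frame motion between successive surface frames is estimated with the
same detector/matcher/RANSAC machinery; its inlier count is the motion
confidence. The tracker is a three-state machine:

* **LOCKED** — global registration accepted; its pose is emitted and
  accumulated drift is discarded.
* **COASTING** — registration rejected but motion confidence is strictly
  above the tracking threshold (default 6, the same semantics as the
  global gate): inter-frame deltas accumulate (newest composed on the
  left) and the emitted pose is
  `last_reliable ∘ invert(scale(cumulative_delta))`. The inversion matters:
  a skin-fixed point moves by the inverse of the frame motion in frame
  coordinates. Scale conversion multiplies the translation by the pitch
  ratio; the half-pixel rotation-center offset this ignores contributes
  < 0.01 px for the rotations seen between frames.
* **LOST** — no reliable pose and no confident motion (or the 25-frame
  coasting cap is hit): tracking resets, nothing is emitted, and only a
  fresh accepted registration can re-lock. Re-locking snaps to the
  registered pose exactly; extrapolated and registered poses are never
  blended.

## Mosaicking

Each new dermoscopic frame registers against the *current composite* (not
the previous frame), so error does not chain pairwise; there is no global
bundle adjustment. Insertion is refused when the reliability gate rejects
(`InsufficientOverlap`) and beyond the 40-frame capacity (`MosaicFull`).
Blending is linear edge feathering: each frame contributes with weight
1 + distance-to-its-nearest-edge, warped bilinearly; pixels covered by one
frame reproduce it exactly at integer poses. Composite keypoints are
recomputed after every insertion (simplicity over incremental updates).
The live-position helper registers a frame without inserting it and
reports its rectangle in first-frame coordinates plus the overlap fraction
with the covered area (computed with shapely polygon unions) as operator
guidance.

## Scoring and heatmaps

A scorer is any pure callable mapping a grayscale region to a percentage.
The trained diagnostic network is proprietary and out of scope; the
package's deterministic scorer is `ReferenceDensityScorer`:
`100 × fraction of in-band pixels ≥ cutoff` (default cutoff 128). Patch
heatmaps score an overlapping grid (default 128 px patches, 64 px stride —
chosen to tile the 2048-px-wide vertical section with 50% overlap; a flush
final row/column is added when the stride does not tile the frame),
suppress patches below the retention threshold (default 50%, the device
value is unpublished), and color every retained patch by the *global*
frame score — the device colors patches by the frame-level score, not
per patch; a per-patch coloring mode exists behind a diagnostics flag.
The colormap interpolates linearly in RGB from pure blue (0, 0, 255) at 0%
to pure yellow (255, 255, 0) at 100% (only the endpoints are specified by
the device; linear RGB is the simplest map through them), with exact
endpoints and channel-monotone interior.

## Margin map and coverage

Every non-LOST frame contributes a scored sample: pose, marker footprint
(line segment spanning the 1.2 mm section width for vertical scans,
rectangle for horizontal/3-D), score, and whether the pose was registered
or extrapolated. Rendering strokes each marker in its exact score color;
consecutive samples closer than two FOV radii are joined by a
color-interpolated segment (larger jumps are left unconnected rather than
inventing coverage); extrapolated samples are dashed; the newest sample
carries the FOV circle and an orientation arrow, drawn beneath the markers
so centroid pixels keep their exact score color. Samples are rendered in
acquisition order (later over earlier); revisited positions are not
aggregated.

Quadrants follow the clock convention: angle measured from the lesion
center, 12 o'clock along −y, clockwise positive; quadrant ink colors
follow the marking scheme (black 12–3, red 3–6, green 6–9, purple 9–12).
Coverage of a closed margin polyline is the fraction of its arc (uniformly
resampled at one fifth of the gap tolerance) lying within `gap_tol_mm` of
any marker segment (vectorized point-to-segment distances); uncovered runs
are reported as arc-length intervals, merged across the seam.

## Phantoms (synthetic study conditions)

The generators are pure functions of (spec, seed) and emulate only what
the pipeline consumes:

* **Reference phantom** — multi-octave band-pass noise (σ = 0.8…12.8 px)
  plus ~300 dark elliptical blobs as a pigment-network proxy, a skin-tone
  RGB ramp, and four colored quadrant ink arcs on the margin ring. The
  default canvas covers the full 13.3 × 8.9 mm dermoscope field at
  12.5 µm/px (1064 × 712 px): the physical extent is the device's, the
  pitch is coarser than the 3.5 µm sensor so that a full sweep registers
  at realistic keypoint counts (~7000 on the default texture) on one CPU.
  Texture parameters were chosen once for stable keypoints, not for
  photorealism.
* **Probability field** — radial sigmoid
  `p(r, φ) = plateau / (1 + exp((r − edge(φ))/slope))` with plateau 100%,
  edge at the lesion radius (1.2 mm), slope 0.15 mm, and optional angular
  lobes that push the edge outward over a clock-angle window (raised-cosine
  taper, 15°) to create positive-quadrant scenarios. At `r = edge` the
  field is exactly half the plateau.
* **Surface streams** — the phantom resampled through true poses at the
  surface pitch (bicubic), circularly masked, with optional Gaussian pixel
  noise, illumination gain jitter and defocus blur. True poses use the
  registration pipeline's own normalized-coordinate convention, so
  recovery error is directly measurable. The default margin path sweeps
  the ink ring with the section line held perpendicular to the margin
  (imaging across the margin), 2° heading jitter.
* **Vertical sections** — a brighter epidermis strip over a darker dermis;
  within the scoring band, a smoothed random field is thresholded so that
  *exactly* the field-value fraction of band pixels is at or above the
  scorer cutoff, giving lobule-like bright blobs whose density the
  reference scorer recovers to well under a point.

What the phantoms do **not** model: real dermoscopic pigment structure,
specular highlights, ink smudging, probe pressure deformation, motion
blur, speckle, or any histological appearance. Passing tests therefore
demonstrate the geometric and bookkeeping correctness of the pipeline
under controlled texture — not clinical diagnostic performance, which
depends on the proprietary scorer and real tissue appearance.

## Problem sizes and numerical choices

The test suite and the acceptance script use 50-frame sweeps for pose
recovery (noise-free and σ = 5/255), 40-frame sweeps for the end-to-end
margin map, 512 × 340 px synthetic sections for scoring, and 96 px tiles
for the 40-frame capacity probe; these sizes keep a full run to a few
minutes on a single CPU while leaving every code path exercised at the
device's true physical geometry. RANSAC uses 2000 seeded iterations and a
3 px tolerance; all randomness flows from explicit seeds and every
documented artifact (sessions, mosaics, overlays) is byte-reproducible.
Degenerate inputs are first-class: textureless frames, coincident
correspondence geometry, open margin polylines, oversize patches and
truncated session files each raise a dedicated error (or return a rejected
result where a live stream must survive).

## Known limitations

* No lens-distortion or nonrigid deformation model; skin stretch between
  dermoscopy capture and probing is unmodeled.
* Nearest-neighbor matching without a ratio test follows the device
  description but is less robust on repetitive texture than ratio-filtered
  matching; the cross-check flag mitigates this at some recall cost.
* The mosaic has no loop closure; long chains of insertions can
  accumulate drift the composite-registration strategy only partially
  suppresses.
* Coasting drift is unbounded in principle; the 25-frame cap bounds the
  time spent trusting dead reckoning, not the spatial error.
* The reference density scorer is a calibration stand-in with the same
  interface and value range as the clinical model, not a diagnostic.
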