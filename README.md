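# probemap

Co-localized dermoscopy / LC-OCT probe mapping for skin-cancer margin
assessment.

When a clinician sweeps a line-field confocal OCT (LC-OCT) probe along the
marked margins of a basal cell carcinoma, each acquisition sees only a
2.6 mm circle of skin. `probemap` answers the navigation question that
makes that sweep useful: **where inside the wide-field dermoscopy image is
the probe right now?** It registers every probe surface frame into the
dermoscopic reference, bridges registration dropouts with inter-frame
dead-reckoning, stitches dermoscopic mosaics for lesions larger than one
field of view, attaches a lesion-probability score to each position, and
renders the scored acquisition path so margin segments with suspected
tumor are visible at a glance — blue where the score is 0%, yellow at
100%, with per-quadrant (12–3, 3–6, 6–9, 9–12 o'clock) coverage reporting.

It is written for researchers building or evaluating image-guided margin
workflows who need a testable, deterministic reference implementation:
everything runs on synthetic phantoms with known ground truth, no clinical
data or trained model required.

## The algorithm

Registration of a surface frame to the reference is rigid
(`dst = R(θ)·src + t`, no scale — the known pixel-pitch ratio
pre-normalizes the frame):

1. SIFT keypoints and 128-D descriptors on the reference (once) and on
   each scale-normalized, circularly masked frame;
2. one-way nearest-descriptor matching (minimum Euclidean distance, ties
   to the lowest index);
3. RANSAC over two-point rotation+translation hypotheses, followed by
   closed-form 2-D Procrustes refinement over the consensus set;
4. a reliability gate on the inlier count: **more than 6 inliers** is
   reliable, 6 or fewer is rejected.

When the gate rejects, a LOCKED/COASTING/LOST tracker extrapolates the
pose from accumulated inter-frame motion (same SIFT machinery, its own
confidence gate) until registration recovers or confidence collapses.
Mosaics register each new dermoscopic frame against the current composite
with the same pipeline, up to the 40-frame capacity, with feathered
blending. Scoring is a pluggable pure function (grayscale region →
percent); patch heatmaps keep patches at or above the retention threshold
and color them by the frame's global score on the blue→yellow ramp.
See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Register five simulated probe frames into a synthetic dermoscopy phantom
with known ground-truth poses:

```python
import numpy as np
from probemap import (PipelineConfig, PhantomSpec, default_calibrations,
                      generate_phantom, init_reference, colocalize,
                      simulate_surface_stream)
from probemap.phantom import make_margin_path

cfg = PipelineConfig()
calibs = default_calibrations()

phantom = generate_phantom(PhantomSpec(seed=7))
reference = init_reference(phantom.image, cfg)
print(f"reference keypoints: {len(reference)}")

path = make_margin_path(phantom, 5, seed=3, jitter_deg=2.0)
stream = simulate_surface_stream(phantom, path, seed=3)
for k, (frame, true) in enumerate(zip(stream.frames, stream.poses)):
    reg = colocalize(frame, reference, calibs["surface"],
                     phantom.calibration, cfg)
    err = np.hypot(reg.pose.tx - true.tx, reg.pose.ty - true.ty)
    print(f"frame {k}: accepted={reg.accepted} inliers={reg.inlier_count} "
          f"pose=(theta={np.degrees(reg.pose.theta):.2f} deg, "
          f"t=({reg.pose.tx:.1f}, {reg.pose.ty:.1f}) px) "
          f"error={err:.3f} px")
```

Output:

```
reference keypoints: 7118
frame 0: accepted=True inliers=211 pose=(theta=94.08 deg, t=(642.6, 20.1) px) error=0.019 px
frame 1: accepted=True inliers=235 pose=(theta=174.89 deg, t=(884.3, 449.9) px) error=0.004 px
frame 2: accepted=True inliers=247 pose=(theta=-89.17 deg, t=(427.0, 698.0) px) error=0.007 px
frame 3: accepted=True inliers=236 pose=(theta=-1.14 deg, t=(186.5, 254.6) px) error=0.011 px
frame 4: accepted=True inliers=216 pose=(theta=89.09 deg, t=(633.8, 10.9) px) error=0.008 px
```

Every frame clears the 6-inlier gate by a wide margin (200+ inliers on
this texture) and the recovered position is accurate to hundredths of a
reference pixel (12.5 µm/px here), i.e. well under a micron of physical
error on a noise-free phantom. The same pipeline is available from the
shell:

```sh
probemap phantom --seed 7 --n-frames 40 --out scratch/demo
probemap colocalize --reference scratch/demo/phantom.png \
    --frames scratch/demo/frames --scorer density --out scratch/session.json
probemap map render --session scratch/session.json --out scratch/overlay.png
probemap map report --session scratch/session.json \
    --margin scratch/margin.json --gap-tol-mm 0.5
```

(`colocalize` on phantom imagery needs a config whose `dermoscope`
calibration matches the phantom canvas — see `probemap.config.save_config`;
the defaults describe the physical device sensor.)

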