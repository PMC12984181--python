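# probemap default configuration.
#
# pipeline: thresholds of the co-localization / tracking / heatmap pipeline.
#   inlier_accept_threshold: registration accepted only when the RANSAC
#     inlier count is STRICTLY greater than this value (6 or fewer -> rejected).
#   mosaic_max_frames: maximum number of dermoscopic frames per mosaic.
#   ransac_inlier_tol_px: inlier residual tolerance in reference-scale pixels.
#   ransac_max_iters / ransac_seed: RANSAC sampling budget and PRNG seed.
#   tracking_confidence_threshold: inter-frame inlier count required (strictly
#     greater) to extrapolate position while global registration is down.
#   coast_max_frames: forced tracking reset after this many extrapolated frames.
#   patch_size_px / patch_stride_px: heatmap patch grid.
#   patch_score_threshold: patches scoring below this percent are suppressed.
#   sift_c_dog: keypoint detector contrast threshold.
#   match_cross_check: optional symmetric match filter (default off).
#   mask_edge_margin_px: keypoints this close to the circular FOV edge dropped.
pipeline:
  inlier_accept_threshold: 6
  mosaic_max_frames: 40
  ransac_inlier_tol_px: 3.0
  ransac_max_iters: 2000
  ransac_seed: 0
  tracking_confidence_threshold: 6
  coast_max_frames: 25
  patch_size_px: 128
  patch_stride_px: 64
  patch_score_threshold: 50.0
  sift_c_dog: 0.04
  match_cross_check: false
  mask_edge_margin_px: 6.0

# calibrations: physical field of view (mm) and sensor dimensions (px) per
# modality. circular=true marks the probe surface image, whose FOV is the
# inscribed circle (fov_mm entries are then the diameter, twice).
calibrations:
  dermoscope:
    fov_mm: [13.3, 8.9]
    image_shape: [5536, 3692]
    circular: false
  surface:
    fov_mm: [2.6, 2.6]
    image_shape: [400, 400]
    circular: true
  lcoct_vertical:
    fov_mm: [1.2, 0.4]
    image_shape: [2048, 680]
    circular: false
  lcoct_horizontal:
    fov_mm: [1.2, 0.5]
    image_shape: [2048, 850]
    circular: false
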