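# Methods

## Problem and approach

Estimating body condition and weight of group-housed pigs calls for metric
3D data, but direct 3D annotation and 3D deep learning are expensive.
`pigcloud` implements the alternative: run mature 2D detection and
segmentation on the RGB channel of a fixed overhead RGB-D camera, then lift
each 2D instance mask through the registered depth channel into a metric
per-animal point cloud. No 3D training is involved; the 3D step is pure
geometry.

The lifting procedure is:

1. read the registered RGB frame, the 16-bit depth frame (millimetre
   counts) and a flat-colour instance mask image with its ordered colour
   list (one colour per animal, black background);
2. back-project every pixel `(u, v)` with a nonzero depth count `d`
   through the pinhole model

       z = d · s,  x = (u − c_x) · z / f_x,  y = (v − c_y) · z / f_y

   where `s` is the depth scale in metres per count (0.001 for millimetre
   PNGs) and `(f_x, f_y, c_x, c_y)` are the camera intrinsics in pixels;
3. split the cloud by exact mask colour, in colour-list order, colouring
   points from the RGB frame.

Instance masks can also be constructed from scored detection boxes
intersected with a binary semantic foreground mask: a foreground pixel
inside several boxes is assigned to the highest-scoring box, with exact
score ties broken toward the lower instance index. The tie-break mirrors
the preference order of non-maximum suppression and makes the construction
deterministic.

### Conventions

Pixels are 0-based with pixel-centre semantics; boxes are half-open
`(x_min, y_min, x_max, y_max)`. The camera frame is right-handed with `+z`
along the optical axis away from the camera, so the floor of a pen 3 m
below the sensor sits at `z = 3.0`. Depth count 0 means "no sensor return"
and never produces a point — lifted point counts therefore equal the
number of valid-depth mask pixels exactly, and are independent of RGB
content. Mask colours are compared exactly, which is why masks must be
stored losslessly (PNG); a mask colour missing from the colour list is an
annotation inconsistency and raises, never silently drops.

## Registration and the similarity score

Lifted clouds are validated against reference clouds (e.g. manually
annotated ones) with point-to-point ICP: alternate nearest-neighbour
correspondence (k-d tree, pairs beyond `max_corr_dist` rejected) with a
closed-form Kabsch/SVD rigid fit, until the correspondence RMSD improves
by less than `tol` (default 1e-6 m) or 50 iterations. The Kabsch step
cannot worsen the objective over fixed pairs, and the per-iteration RMSD
history is kept so monotonicity can be asserted.

Agreement between aligned clouds is summarised as an **inlier fraction**:
the fraction of source points whose nearest neighbour in the target lies
within `tau` (default 1 cm), reported both directed and as the symmetric
mean of the two directions. This definition is this package's own
documented stand-in for a cloud-similarity score — the quantity is not
standardised — and `tau` is exposed everywhere it is used.

Parameter guidance: `max_corr_dist` must exceed the largest initial point
displacement or ICP discards the very correspondences it needs. The 5 cm
default suits clouds that already share a camera frame; the pose-recovery
studies in the acceptance suite perturb a ~0.7 m-radius cloud by up to 10°
about its centroid (≈ 0.12 m of rim motion) and therefore use a 0.15 m
gate. Rotations are perturbed about the cloud centroid because rotating
about the camera origin moves a cloud 2.7 m away by ~0.45 m at 10° — not a
pose perturbation any local method should be expected to undo.

## Detection and segmentation metrics

Single-class protocol. Precision is `TP/(TP+FP)`. AP at one IoU threshold
comes from greedy score-ordered matching (each ground truth claimed at
most once, best IoU above threshold wins) and the area under the
interpolated precision–recall curve; `mAP@0.5:0.95` is the unweighted mean
over thresholds 0.50:0.05:0.95. All-point (continuous) interpolation is
the default; COCO-style 101-point sampling is available via
`interpolation="coco101"` since published mAP values vary in this detail.
Global pixel accuracy is `trace/total` of the pixel confusion matrix.

Metrics sweep all detection scores. A fixed operating confidence (the
pipeline convention keeps detections with score > 0.9) is a separate
filter applied to the confusion counts only — applying it before AP would
truncate the PR curve and change the metric's meaning.

Box AP and mask AP are computed by the same matcher on rectangle IoU and
pixel-set IoU respectively and reported separately.

## Preprocessing

Near-duplicate frames from long recordings are removed by double
perceptual hashing: 64-bit aHash (thumbnail pixel vs thumbnail mean) and
64-bit dHash (horizontal gradient sign on a 9×8 thumbnail, invariant to
uniform brightness scaling), both on the LANCZOS-resized grayscale
thumbnail. A frame is dropped only when **both** Hamming distances to some
already-kept frame are ≤ 5 bits (conjunctive rule: two independent
signatures must agree before discarding data). The first frame is always
kept; output order is preserved. A constant image has the documented
all-zero hashes.

Mosaic augmentation stitches same-corner crops of four images around a
centre drawn uniformly from the central 50 % of the canvas. Annotation
boxes are translated into canvas coordinates, clipped to their quadrant,
and dropped when the surviving area falls below 1 % of the original; kept
plus dropped always equals the input count, and the whole operation is
deterministic under a fixed seed.

## Res2Net bottleneck forward pass

The detector enhancement studied alongside the lifting method replaces a
standard residual bottleneck with a Res2Net bottleneck: after a 1×1
projection the channels split into four equal groups and cascade,

    Y1 = X1,  Y2 = K2(X2),  Y3 = K3(X3 + Y2),  Y4 = K4(X4 + Y3),

followed by concatenation, a 1×1 projection and the residual addition.
`res2net_forward` is a pure-numpy reference of exactly this structure so
the cascade is inspectable and testable without any training stack.
Normalisation and activation layers are omitted by default (the forward
map is then linear in the input, a tested property); an elementwise
activation hook can be supplied. Scale is fixed at four groups. Whether
X1 gets its own 3×3 convolution differs between published variants;
pass-through is the default and an optional `k1` kernel enables the
convolved form.

## Synthetic scenes

The generator emulates the target acquisition geometry: a fixed overhead
pinhole camera (848×480, f = 425 px, a D455-like ~87° horizontal field of
view) 3.0 m above a flat floor. Animals are half-ellipsoids resting on the
floor: footprint ellipses with semi-axes 60–110 px by 25–50 px (roughly
0.85–1.55 m × 0.35–0.7 m on the floor at that range — pig-scale) and back
heights 0.4–0.7 m, placed uniformly, fully in frame, non-overlapping by
default (an `allow_overlap` mode creates the adhesion regime that defeats
2D detectors, for stress tests). Depth is exact floor/surface geometry in
millimetres; optional Gaussian depth noise (σ in mm) is added before
rounding, and values clipped at 0 become non-returning pixels, exercising
the invalid-depth path. The RGB channel gets a shaded body colour over a
speckled floor; the illumination factor scales RGB only, so depth — and
every lifted coordinate — is bit-identical across lighting, mirroring
day/night robustness at the level where it is literally true.

Ground truth is exact by construction: the per-instance clouds are the
back-projection of each instance's valid-depth mask pixels, and boxes are
tight mask bounding boxes. `perturb_detections` converts ground truth into
detection sets of known composition (drop rate, box jitter, disjoint
false positives at `round(fp_rate × kept)`, false positives scored below
all true detections) so expected precision and AP follow analytically.

What passing on these scenes does **not** show: robustness to real pig
shapes and poses, depth-sensor artefacts (multipath, edge bleed), RGB-depth
misregistration, or 2D detector errors — the masks here are exact. The
synthetic results validate the geometry, the metrics and the bookkeeping,
not a detector.

## Numerical choices and degenerate inputs

* Kabsch refuses < 3 pairs and collinear configurations (second singular
  value ≤ 1e-9 of the first): the rotation is unobservable there.
* ICP with no correspondences inside the gate reports `converged=False`
  and similarity 0 rather than raising; empty clouds raise.
* AP with empty ground truth or empty detections is 0; precision with no
  positive predictions raises (undefined), it is never reported as 0.
* IoU of two empty geometries raises; disjoint geometries give 0.
* Polygon rasterisation uses the pixel-centre rule (a pixel is inside iff
  its centre is strictly inside the polygon), so the axis-aligned square
  (0,0)–(10,10) covers exactly 100 pixels. Annotation pixel counts depend
  on the fill rule, so it is fixed and tested.
* PLY is written as ASCII at 1e-6 m precision (diff-able fixtures);
  readers ignore unknown vertex properties and refuse non-finite
  coordinates with a count.

## Problem sizes used by the acceptance script

`scripts/acceptance.py` regenerates everything it measures: 25 noise-free
scenes (1–8 instances each, full 848×480 resolution) plus 5 noisy ones for
the lifting checks; 100 rigid perturbations of a 2 000-point instance
cloud for ICP recovery; 200 random toy detection sets × 10 IoU thresholds
against the exhaustive PR oracle; 3 random Res2Net specs against the
nested-loop convolution oracle; a 20-frame 4-run duplicate stream and a
24-annotation mosaic for preprocessing. The whole script runs in well
under a minute on one CPU.

## Known limitations

* The similarity score is a declared stand-in; reported values are not
  comparable to similarity figures computed under other (unpublished)
  definitions.
* The half-ellipsoid animal model has no legs, heads or contact
  deformation; occlusion is modelled only as mask overwriting, not as
  nearer-surface selection.
* No multi-camera fusion, no temporal tracking, no neural inference:
  masks come from files or the generator.
* Rigid registration only — both clouds are metric from the same sensor,
  so no scale estimation is performed.
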