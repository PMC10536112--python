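# Methods

`capivid` processes grayscale videocapillaroscopy recordings of the oral
mucosa in three stages — rigid stabilization, temporal enhancement, and
capillary segmentation — and ships a synthetic phantom generator so every
stage can be tested quantitatively without clinical data.  This note records
the models, the parameters that matter, and the design choices made where
the design was genuinely open.

## Stabilization

### Model

Consecutive frames k and k+1 are related by an image-plane rigid transform
(rotation θ + translation (dx, dy)).  This is adequate for a contact probe:
the probe touches the mucosa, so scale and perspective changes between
consecutive frames at 120 fps are negligible compared with tremor-induced
translation and roll.  Non-rigid tissue deformation is out of scope.

### Pairwise estimation cascade

1. **Keypoint detection.** Blob keypoints are local maxima (over space and a
   five-scale ladder σ ∈ {1.6, 2.4, 3.6, 5.4, 8.0}) of the scale-normalized
   determinant of Hessian, σ⁴·det∇²I, computed with true Gaussian
   derivatives on the 0–255 intensity scale and mapped by a fixed gain so
   that clearly trackable features score in the conventional thousands
   range (an ideal blob of amplitude A scores ≈ 21·A²/16; A ≈ 28 ↦ ≈ 1000).
   Gaussian (rather than box-approximated) derivatives keep sensor noise
   well below structural responses and give elongated ridges near-zero
   determinant, so keypoints concentrate on blob-like anchors.  Positions
   are refined to sub-pixel accuracy by quadratic interpolation of the
   response surface — necessary for the half-pixel motion accuracy target.
   Detection starts at threshold 1000 and relaxes in decrements of 20 until
   both frames yield ≥ 10 keypoints (or the threshold is exhausted, for
   featureless frames).  The bound is a floor, not a target: at the final
   threshold all qualifying keypoints are kept (capped at 500 per frame),
   because the downstream match statistics need an abundant pool.
2. **Descriptors and matching.** Each keypoint carries a 10×10 grid of
   intensities sampled over a fixed 14-px-radius window on a lightly
   smoothed copy of the frame (σ = 1.5), Gaussian-weighted toward the
   centre, zero-meaned and normalized to unit length.  The window is fixed
   rather than scale-proportional: the motion is rigid (no scale change),
   and tying the window to the discrete detection scale would make correct
   correspondences dissimilar whenever the ladder assigns neighbouring
   scales to the same blob in the two frames.  Matching is one-directional
   exact nearest-neighbour search under Euclidean distance, restricted to
   keypoints whose Laplacian sign agrees (bright never matches dark).  No
   ratio test is applied.  Fewer than 5 matches aborts the pair.
3. **Good-match cascade.** Keep matches with distance < max(2·min_dist,
   0.02); if fewer than 5 survive, retry with max(3·min_dist, 0.03); if
   still fewer than 5, keep the best 4 outright.  The 0.02/0.03 floors
   guard the degenerate case of a near-zero minimum distance.
4. **Displacement outlier rejection.** Matches whose image-plane
   displacement deviates from the mean by more than 2 population standard
   deviations are dropped.  This removes matches that travel with the blood
   flow (unchained red cells) rather than with the frame.  The population
   form of the standard deviation is used; on the bundled test cases both
   std conventions give identical outcomes.
5. **Rigid fit.** Closed-form least squares: centroid alignment plus 2-D
   orthogonal Procrustes (SVD of the 2×2 cross-covariance,
   determinant-corrected against reflections).  A single surviving match
   degrades gracefully to pure translation.
6. **Residual consistency check.** The magnitude-based test in step 4 is
   blind to a mismatch whose displacement happens to fall inside the inlier
   range — with rotation present, inlier magnitudes spread widely across
   the frame.  After the first fit, correspondences whose residual exceeds
   max(2·median residual, 1 px) are trimmed and the motion refit once.
   Without this check a single such mismatch occasionally breaks the
   half-pixel accuracy target on phantom sweeps.

Frames are warped into the reference frame of frame 0 by composing the
pairwise estimates (bilinear interpolation, fill value 0); a boolean
validity stack records which output pixels carry real content.  Keypoint
detection suppresses candidates within a descriptor radius of invalid
pixels, so re-stabilizing an already-stabilized sequence yields near-identity
motions instead of locking onto the fill rim.

Sequences are split into segments wherever the inter-frame displacement
exceeds a probe-speed threshold (default 10 % of the frame width per frame
pair): the operator deliberately sweeps between regions of interest, and
frames inside a sweep are not analysable.  Stitching composites the aligned
frames on the union bounding box, averaging overlaps and copying
non-overlapping pixels verbatim.

## Temporal enhancement

Per pixel (i, j) and frame k, over a symmetric window of 2n+1 frames
(default n = 5, i.e. 11 frames ≈ 0.09 s at 120 fps — on the order of the
perfusion recovery time of the vessel regions):

    B(i,j,k) = mean of I(i,j,k') over k' = k−n .. k+n
    σ(i,j,k) = population std of the same window
    H(i,j,k) = I(i,j,k) − σ(i,j,k)

Perfused pixels fluctuate (red cells pass intermittently), so σ is large on
capillaries and near zero on tissue; subtracting σ darkens the whole vessel
track, including stretches invisible in the current frame — this is what
reconstructs the broken, stroke-like vessel appearance.  H is shifted by its
minimum, scaled so its maximum maps to 255 (a flat frame maps to 0), and
median-filtered with a 3×3 kernel (replicate padding) to give the 8-bit
output HF.

Numerical choices: the window is clamped to existing frames at the sequence
ends, with the divisor equal to the actual frame count; all arithmetic is
floating point, with quantization only at HF; the shift/normalization scope
is per frame by default (a per-sequence option exists); pixels invalid in
more than half of their window are marked invalid in the output and excluded
from the statistics.

## Segmentation

### Data preparation

Full images are cut into 160×160 tiles on a regular grid (default stride =
tile size) with the final row/column anchored flush with the image border:
full coverage with overlap, never discarded borders.  For a 620×476 image
this gives column offsets {0, 160, 320, 460} and row offsets {0, 160, 316} —
12 tiles.  Images are augmented by rotations about the centre (angles
equally spaced in the open interval (0°, 360°); image bilinear, mask
nearest-neighbour and re-binarized, uncovered corners background).  Tiles
whose mask holds fewer than 200 white pixels are discarded after
augmentation and tiling.

### Network and training

The segmentation network is a U-Net-style encoder–decoder: four contracting
blocks (two 3×3 convolutions + ReLU each; 32, 64, 128, 256 filters by
default) with 2×2 max pooling between levels (160 → 80 → 40 → 20 at the
bottleneck), a mirrored expanding path of 2×2 stride-2 up-convolutions with
skip concatenations at matching resolution, and a 1×1 convolution to
two per-pixel class scores at input resolution.  Inputs are grayscale tiles
scaled to [0, 1].

The network and its training loop are implemented as a compact CPU CNN in
numpy (`capivid.nn`): im2col convolutions via stride-tricks windows,
hand-derived backward passes (verified against central finite differences in
the test suite), Adam, and class-weighted categorical cross-entropy.  Class
weights are inverse-frequency, w_c = total_pixels / (2·count_c), computed
from the training tiles: capillary pixels are a small minority and would
otherwise be ignored by the loss.

Evaluation is leave-one-out cross-validation over source images: one
training per image, with every tile derived from the held-out image —
augmentations included — excluded from that fold's training set.  The
default schedule is 20 epochs with checkpoint selection at minimum
validation loss; training still runs the full schedule.  Prediction tiles
the input with the same flush-anchor grid, averages foreground probabilities
where tiles overlap, and binarizes at 0.5.  Per-fold metrics are reported
together with two cross-fold summaries: the unweighted mean of per-fold
metrics (headline) and a pooled-pixels variant; the two differ when folds
have unequal sizes, and both are always emitted.

A single master seed derives network initialization, shuffling and
augmentation order; training is bit-reproducible on a fixed platform.

## Metrics

Jaccard (intersection over union), sensitivity, specificity and accuracy
from the per-pixel confusion table, with white = capillary = positive.
Degenerate conventions: Jaccard is 1 when both masks are empty and 0 when
exactly one is; sensitivity (specificity) is 1 when the truth has no
positives (negatives).

## Phantom generator

The generator emulates the statistical structure of oral videocapillaroscopy
that the pipeline relies on — not the biophysics:

* dark tortuous vessels: random-heading smooth centerlines dilated to a
  3–7 px width, darkened by ~60 gray levels on the background;
* a brighter textured background (mean ≈ 155, smooth mottle ≈ 5 gray
  levels) with bright anisotropic Gaussian blobs (30 per frame by default)
  standing in for stationary tissue texture; anisotropy keeps different
  blobs distinguishable to an appearance descriptor, as real texture is;
* intermittent perfusion: each vessel centerline is split into ~40 px arcs,
  and each arc is independently visible per frame with probability
  `flow_visibility` (default 0.6);
* rigid probe jitter: per-frame poses sampled independently and uniformly
  within ±3 px and ±0.8° by default (a smooth-drift mode exists for
  split-point testing), rendered by resampling a padded static scene so no
  empty border is dragged into view;
* additive Gaussian sensor noise (σ = 4) and 8-bit quantization, applied
  last.

The exact pose of every frame is logged, so the returned motion track is the
transform the stabilizer is asked to recover, to machine precision.  All
randomness flows from one seed; identical specs give bit-identical output.

What the phantom does **not** model: optics (PSF, vignetting, specular
highlights), flow dynamics (red-cell velocity, pulsatility), illumination
drift, rolling shutter, or non-rigid tissue deformation.  Passing phantom
tests therefore demonstrates the pipeline's mechanics — motion recovery,
variance-based reconstruction, learning and evaluation plumbing — not
clinical-grade performance on real recordings.

## Preprocessing ablation readout

To credit each preprocessing stage, one fixed deterministic readout
segments (a) the raw reference frame, (b) the enhanced frame of the
unstabilized sequence, and (c) the enhanced frame of the stabilized
sequence, against the same ground-truth mask.  The readout scores pixels by
their dark residual against the local illumination field (difference of
Gaussians, σ 25 vs 1.5) and thresholds at the known true vessel-pixel
fraction ("oracle-fraction" thresholding): the resulting Jaccard measures
how well each processed image *ranks* vessel pixels ahead of background,
independent of any threshold-picking heuristic.  A bimodal threshold such as
Otsu's is deliberately not used here: reconstructed vessel stretches are
darkened at a lower contrast than directly visible ones, and a single
bimodal cut misses exactly the reconstruction effect being measured.  A
20 px interior margin is excluded so warp fill-in at the borders cannot
contaminate the comparison.  Training one network per arm would measure the
same ordering through a noisier, far more expensive instrument; the fixed
readout isolates the preprocessing itself.

## Problem sizes used in bundled checks

The bundled end-to-end checks run on 620×476 phantoms (16–20 frames) for
stabilization and ablation, and a two-image phantom database (~60 retained
tiles after one-level augmentation) trained for 10 epochs with a reduced
encoder (8, 16, 32, 64) for the leave-one-out smoke run.  These sizes
exercise every code path — including the non-divisible tiling geometry —
at desk scale; they are structural replicas, not reproductions, of a
22-image clinical study.

## Known limitations

* The stabilizer assumes some blob-like stationary texture; a frame whose
  only structure is flickering fine capillaries can mis-anchor.
* Magnitude-based outlier rejection plus a single residual-trim pass is not
  a full robust estimator (no RANSAC); gross contamination above ~40 % of
  matches will defeat it.
* The numpy network trains small configurations in minutes but is not meant
  for large-scale training.
* Video-container ingestion depends on the imageio plugins available;
  image-sequence directories are the canonical format.
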