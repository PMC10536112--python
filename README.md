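# capivid

Stabilization, temporal enhancement and automatic capillary segmentation for
oral videocapillaroscopy.

Videocapillaroscopy records the microcirculation of the oral mucosa in vivo
with a contact video probe (8-bit grayscale, 120 fps).  Two acquisition
artifacts make the raw footage hard to analyse: the hand-held probe jitters
(rigid inter-frame translation and rotation), and red blood cells flow
through fine capillaries intermittently, so any single frame shows only
broken, stroke-like fragments of the vessel network.  `capivid` implements a
processing pipeline for clinicians and image-analysis researchers working
with such recordings:

1. **Stabilization** — feature-based rigid registration of consecutive
   frames: iterative Hessian-blob keypoint detection (threshold relaxed from
   1000 in steps of 20 until ≥ 10 keypoints per frame), nearest-neighbour
   descriptor matching, a good-match cascade (distance < max(2·min_dist,
   0.02), then max(3·min_dist, 0.03), then best-4), 2σ displacement outlier
   rejection, and a closed-form least-squares rigid fit (2-D orthogonal
   Procrustes).  Sequences are split wherever probe speed exceeds a
   threshold; aligned frames can be stitched into a mosaic.
2. **Enhancement** — per pixel, over a sliding window of 2n+1 frames
   (default n = 5):

       B(i,j,k) = mean I(i,j,k'),   σ(i,j,k) = std I(i,j,k'),
       H(i,j,k) = I(i,j,k) − σ(i,j,k)

   Perfused pixels fluctuate, so σ highlights capillaries; subtracting σ
   darkens the full vessel track — including stretches invisible in the
   current frame — then H is shifted/normalized to [0, 255] and 3×3
   median-filtered (output HF).
3. **Segmentation** — a U-Net-style encoder–decoder (blocks of 32, 64, 128,
   256 filters) over 160×160 tiles, trained with Adam and class-weighted
   categorical cross-entropy under leave-one-out cross-validation, producing
   binary capillary masks scored by Jaccard index (IoU), sensitivity,
   specificity and accuracy.

Because clinical capillaroscopy databases with expert masks are rarely
public, the package bundles a **phantom generator**: synthetic videos of
dark tortuous vessels on textured backgrounds with intermittent per-arc
perfusion, rigid jitter with an exact motion log, and sensor noise — enough
ground truth to test every stage quantitatively.  See `docs/methods.md` for
the full model description and design rationale.

## Worked example

```python
import numpy as np
from capivid.phantom import PhantomSpec, generate_phantom
from capivid.stabilization import stabilize_sequence
from capivid.enhancement import enhance_sequence
from capivid.pipeline import oracle_fraction_jaccard

# a 620x476, 16-frame phantom: jitter up to ±3 px / ±0.8° per frame,
# each vessel arc visible with probability 0.6 per frame
out = generate_phantom(PhantomSpec(width=620, height=476, n_frames=16, seed=1))

stabilized, motions = stabilize_sequence(out.frames)
err = max(np.hypot(m.dx - t.dx, m.dy - t.dy)
          for m, t in zip(motions, out.true_motions))
print(f"worst motion error: {err:.3f} px")

enhanced = enhance_sequence(stabilized)
for name, frame in [("raw", out.frames.frame(0)),
                    ("enhanced", enhanced.frame(0))]:
    j = oracle_fraction_jaccard(frame, out.truth_mask)
    print(f"{name:9s} readout Jaccard: {j:.3f}")
```

Output:

```
worst motion error: 0.093 px
raw       readout Jaccard: 0.428
enhanced  readout Jaccard: 0.706
```

The stabilizer recovers the logged probe jitter to better than a tenth of a
pixel, and the stabilize-then-enhance pipeline raises the fixed readout's
Jaccard against the true vessel mask from 0.43 (raw frame, broken vessels)
to 0.71 (fluctuation-reconstructed vessels).

## Command line

```sh
capivid simulate  --config phantom.yaml --out phantom/      # synthetic video + ground truth
capivid stabilize --in phantom/frames --out stab/           # frames, validity masks, track.csv
capivid enhance   --in stab/ --out enh/ --n 5
capivid train     --data dataset/ --config train.yaml       # LOOCV; writes fold metrics JSON
capivid evaluate  --pred preds/ --truth masks/ --out metrics.json
```

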