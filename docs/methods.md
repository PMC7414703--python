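# Methods

## Model and assumptions

The detector treats an en-face OCTA angiogram as a two-phase texture: in
perfused retina, capillary flow signal and inter-capillary tissue alternate
at a scale of a few pixels, so any small window contains a *mixture* of
vessel and tissue pixels; in a nonperfused region the capillary signal is
absent and windows are *uniform*. After binarising the image into a vessel
mask, the windowed binary entropy H(p) of the local vessel fraction p
separates the two regimes: H is near 1 bit where p ≈ 0.5 and collapses to 0
where a window is pure tissue (or pure vessel). Ischemia is then "low
entropy, not vessel", grouped into connected clusters and filtered by a
minimum physical area.

Two structural assumptions follow:

* **Shading is slow.** Illumination/contrast differences across a widefield
  scan vary over several millimetres, much slower than capillary texture, so
  a Gaussian low-pass with σ = 5 mm estimates the shading field and
  subtracting it makes one global threshold meaningful. Implicitly this
  assumes any single ischemic region is smaller than the σ scale (~5 × 5 mm);
  a dropout region wider than σ would be partially absorbed into the
  background estimate.
* **Large vessels are not ischemia.** A vessel wider than the entropy
  window is internally uniform and hence low-entropy. Large vessels are
  isolated by a morphological opening of the vessel mask and excluded from
  the candidate set, along with all individual vessel pixels (a pixel with
  flow signal cannot itself be nonperfused tissue).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `sigma_mm` | 5.0 | mm | background (shading) scale; ≈ 333 px at 0.015 mm/px |
| `sigma_px` | unset | px | optional override of the σ conversion (e.g. 350 px to mimic a specific device implementation) |
| `norm_percentile` | 95 | — | upper anchor of intensity normalisation; robust to the brightest 5% of pixels |
| `vessel_threshold` | 0.5 | — | vessel cutoff on the normalised intensity |
| `entropy_window_px` | 5 | px | texture window; 5 px ≈ 0.075 mm, the capillary-mixture scale |
| `entropy_threshold_bits` | 0.3 | bits | candidate cutoff; in a 5 × 5 window, 1/25 vessel pixels (H ≈ 0.242) is a candidate, 2/25 (H ≈ 0.402) is not |
| `min_cluster_area_mm2` | 0.09 | mm² | strict minimum cluster area (20 × 20 px at 0.015 mm/px) |
| `large_vessel_opening_radius_px` | 3 | px | opening disk radius; removes vessel structures narrower than ~6 px |
| `connectivity` | 8 | — | neighbourhood for cluster labelling |

σ is specified in millimetres and converted through the pixel size so the
pipeline is resolution-independent; the `sigma_px` override exists because
pixel-denominated conventions (350 px for this scan geometry) round the
conversion differently (5 mm / 0.015 mm ≈ 333.3 px).

## Numerical choices

* **Percentile convention**: linear interpolation between order statistics
  (numpy's default).
* **Border handling**: reflect padding for the Gaussian filter and the
  entropy window; for the opening, out-of-image pixels count as vessel
  during erosion and as background during dilation (scikit-image's
  convention), so a solid mask is unchanged. All choices are fixed so
  results are bit-reproducible.
* **Entropy is exact**: window vessel counts are accumulated as integers,
  so H equals the closed form for every possible count; H uses
  `xlogy`, giving 0·log 0 ≡ 0 without special-casing.
* **Strict area filter with a tie guard**: a cluster is kept iff
  `count × s² > min_area` *and* the two are not equal to within a 1e-9
  relative tolerance; this keeps float roundoff in `400 × 0.015²` from
  flipping the strict ">" decision at the exact boundary.
* **Labelling order**: clusters are relabelled 1..K by decreasing pixel
  count; equal counts are broken by the topmost-leftmost member pixel in
  row-major order.
* **Degenerate inputs**: a flat image (95th percentile = minimum) raises a
  degenerate-input error at the binarisation step; a σ below 1 px raises a
  parameter error. The ICC raises a degenerate-input error only when the
  whole ratings table is constant (zero denominator); perfectly
  anti-correlated raters yield a negative — possibly < −1 — sample ICC,
  which is reported as computed.
* **Affine invariance**: steps 1–2 are linear and step 3 normalises
  between two order statistics, so the end-to-end result is invariant to
  `v → a·v + b` (a > 0) up to floating-point ties at the threshold.

## Grader review

Edits operate on the candidate (pre-size-filter) mask: add-masks are OR-ed
in and remove-masks AND-NOT-ed out, in order, after which labelling and the
minimum-area filter re-run. This keeps the algorithm, not the grader, as
the final arbiter of cluster validity — an added region below the minimum
area simply vanishes again. Repeated identical edits are idempotent, and a
remove followed by an identical add restores the pre-edit result. The audit
log records, per edit, the grader, role, pixel count, a content digest of
the mask and the running totals; replaying the edits against the log
verifies the digests and reproduces the final label raster bit-for-bit.

## Metric definitions

Vessel density is the percentage of pixels classified as vessel by *this
pipeline's* binarised vessel image over the full scan — a self-contained,
deterministic definition (device softwares use their own, generally
different, binarisation). Ischemic percent is 100 × area / (field height ×
width). Longitudinal tables report per-visit rows plus group mean ± sample
SD per (plexus, timepoint) and mean paired changes vs the previous
timepoint. Inter-grader agreement uses ICC(2,1) (two-way random effects,
absolute agreement, single measures) — the standard choice for two fixed
graders producing continuous measurements — with optional per-metric
z-scoring across patients before pooling several metrics into one
coefficient. Repeated-measures ANOVA and correlation analyses are out of
scope; the tidy table output is designed to feed any stats tool.

## Synthetic phantoms

The generator emulates the four features of real widefield angiograms the
pipeline must cope with: capillary-scale speckle texture (Gaussian-correlated
noise re-thresholded to a target vessel fraction, correlation ≈ 2 px), a few
large vessels (> 5 px wide smooth random-walk tubes), a slowly varying
multiplicative illumination field (planar gradient plus large smooth blobs),
and contiguous dropout patches (unions of overlapping disks, rescaled via a
signed-distance offset to a sampled target area, placed disjointly and away
from large vessels) where capillaries are deleted. Intensities are two-level
(vessel high, tissue low) times illumination times gamma-distributed
multiplicative speckle. All randomness flows from the single integer seed
through one `numpy.random.Generator`.

Defaults represent the study conditions of the reference acquisition: a
600 × 1000 px raster at 0.015 mm/px (the 9 × 15 mm field), capillary density
0.45 (a realistic superficial-plexus vessel fraction), three patches of
0.2–1.0 mm² (comfortably above the 0.09 mm² floor), a 30% planar gradient
plus 15% blob shading, and speckle SNR 5. Ground-truth ischemia is defined
as the planted patch regions, not "pixels without vessels", so scoring is
well-posed — sparse capillary gaps in the perfused texture are not ischemia.

What the phantoms do **not** emulate: decorrelation-signal physics,
projection artifacts from the superficial onto the deep plexus, motion/tilt
artifacts, vessel-calibre distributions, or the anatomy of the foveal
avascular zone. Passing the recovery suite therefore shows the pipeline
correctly implements its model and is robust to shading and speckle of the
stated magnitudes; it does not certify performance on artifact-laden
clinical scans, which is precisely why the grader-review stage exists.

## Problem sizes used in validation

Stage oracles (direct kernel convolution, window counting, flood fill,
erosion/dilation over explicit offsets) run on rasters ≤ 64 × 64, where
brute force is exact and fast. The recovery suite uses 20 full-scale
(600 × 1000 px) phantoms, seeds 0–19, and achieves mean Dice ≥ 0.6 with
patch-level recall ≥ 0.9; an 8-phantom ablation with a strong (50%)
illumination gradient shows the pipeline with the shading correction
bypassed is strictly worse on mean Dice. The acceptance script uses 12
phantoms for recovery and 8 for the simulated two-grader ICC.

## Known limitations

* The global percentile normalisation can misclassify vessels in regions
  whose *contrast* (not just brightness) is strongly depressed, because the
  subtraction corrects additive shading exactly but multiplicative shading
  only approximately.
* Dropout regions touching large vessels are partially eaten by the
  vessel-exclusion rule; areas are slightly underestimated along vessel
  margins and near patch borders (the entropy window shaves ~2 px).
* No inter-visit registration: longitudinal comparisons assume the device's
  own tracking aligned the scans.
* SCP/DCP slab segmentation, signal-strength screening and artifact
  rejection are upstream of this package.
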