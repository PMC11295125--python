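# Methods

`flowim` re-creates, at desk scale, the computational stack of a
stop-flow imaging microscope used for phytoplankton monitoring:
frames of settled particles are captured in paired brightfield and
darkfield illumination, particles are detected and cropped into
regions of interest (ROIs), each ROI is measured and classified, and
classified counts are converted into cell densities with detection
limits.  Because no physical instrument is attached, a seeded
synthetic scene generator takes the place of the camera and provides
exact ground truth for every stage.

## Optical calibration

Resolution is assessed with a USAF-1951 bar target.  An element at
group *g*, element *e* has spatial frequency
`f = 2^(g + (e-1)/6)` line pairs/mm; the resolution implied by the
smallest resolvable element is taken as the line-pair period divided
by √2 (`(1000/f)/√2` µm), the convention used for reverse-lens flow
microscopes.  Numerical aperture comes from the exact marginal-ray
relation `NA = sin(arctan(1/(2N)))` for f-number *N* rather than the
paraxial `1/(2N)`: at f/2 the exact form gives 0.2425 (≈0.24) where
the paraxial form gives 0.25.

The default `OpticalConfig` describes a 1.12 µm-pitch 3280×2464
sensor behind a 5× objective (sample-side pixel 0.224 µm), a 200 µm
deep × 1000 µm wide flow channel, and a calibrated per-frame imaged
volume of 0.062 µL.  The configured volume is deliberately a
constant, not derived from FOV × depth: the geometric product of the
stated field of view and channel depth (~0.08 µL) does not equal the
calibrated value, because the usable imaged area of a real instrument
is smaller than the nominal sensor footprint (vignetting, edge
exclusion).  `imaged_volume` reports both numbers and flags the
disagreement; quantitation always uses the configured constant.
Desk-scale simulations use `scaled_config(w, h)`, which rescales the
volume geometrically so that synthetic densities stay physically
consistent with the reduced frame.

## Preprocessing

Raw images (TIFF/PNG, 8/16-bit, grayscale or RGB→Rec.601 luminance)
are converted to float in [0, 1] at the I/O boundary.  Luminance is
normalized per pixel between a *negative blank* (obstructed view) and
a *positive blank* (open view): `(raw − neg)/(pos − neg)`, clipped to
[0, 1].  Blanks are Gaussian-smoothed (σ = 5 px) first so their shot
noise is not amplified by the division; pixels where the blanks still
coincide are repaired with the median blank separation.  Denoising is
a median filter of configurable radius (default 1 px; radius 0 is the
identity).

## Detection

Two detectors with complementary trade-offs:

* **Fast Detector** — local maxima of the Gaussian-smoothed darkfield
  frame (σ = expected particle radius / 2, default 4 px).  The
  threshold is a fraction (default 0.5) of the frame's robust
  maximum, defined as the maximum of the *smoothed* frame: smoothing
  has already suppressed isolated hot pixels, and unlike a fixed high
  percentile this statistic does not collapse to the noise floor on
  sparse frames (important near the limit of detection, where a frame
  may hold zero or one particle).  An absolute background floor
  (0.08) keeps blank frames silent.  Maxima closer than
  `min_separation` (default 15 px ≈ 3.4 µm) are suppressed, brightest
  wins; fixed-size crops (default 48 px) are cut around survivors.
* **Segmenter** — darkfield foreground segmentation.  The default
  threshold is robust background statistics (median + 8·σ, σ from the
  MAD): sparse darkfield frames are mostly background, so Otsu's
  bimodal-histogram assumption fails and faint debris or defocused
  cells drop below the Otsu threshold, producing false negatives;
  the robust threshold keeps them while the minimum component area
  (30 px) and the background floor reject noise.  Otsu and an
  adaptive local-mean threshold remain selectable.  8-connected
  components become bounding boxes, each expanded by an 8 µm
  sample-side margin (36 px at 0.224 µm/px) for visual context and
  clipped to the frame.

Coordinates are 0-based and half-open; ROI lists are sorted by
(y0, x0) and crops copy pixels.  Merged (multi-particle) crops are
not resolved at detection time — they are handled downstream by
classification and quantitation.

## Detection scoring

Scoring mimics hemocytometer practice: frames are tiled into complete
800×800 px counting squares (a 3280×2464 frame gives 12), and every
ROI is classified by how much of each annotated object's mask its box
encapsulates.  With primary = the object with the highest
encapsulated fraction (ties to the lower id): no object pixels →
**false positive**; primary < 0.9 → **split**; primary ≥ 0.9 with a
second object ≥ 0.5 → **merge**; otherwise **correct**.  Objects
intersected by no ROI are **false negatives**.  An ROI that is both
split-like and merge-like counts as a split — the costlier error.
All counts are normalized by the number of valid objects.  The
implementation is cross-checked in the tests against a brute-force
matcher that enumerates every ROI × object pixel intersection.

## Features

Thirteen named features per ROI, measured on the darkfield crop over
the largest Otsu-thresholded foreground component: area (µm²), minor
and major axis lengths, eccentricity, circularity (4πA/P²),
perimeter, equivalent diameter (lengths in sample-side µm),
foreground intensity sum/mean/std (normalized units), solidity,
extent, and the *edge noise gradient* — the mean Sobel gradient
magnitude over the mask's one-pixel boundary band, normalized by mean
object intensity.  The edge noise gradient is defined operationally;
its focus sensitivity (sharp > defocused) is verified on synthetic
pairs rather than assumed.

## Classification

* **Split** — stratified 85:15 train/test, per class
  `round(0.15·n)` test items, seeded.
* **Augmentation** — the 8-element dihedral orbit (4 rotations ×
  mirror) of each square crop, identity included.
* **Random forest** — scikit-learn forest with a randomized search
  (default 50 combinations, macro-F1, 3-fold CV) over a space
  bracketing a known-good configuration
  (`n_estimators 250, min_samples_split 5, min_samples_leaf 2,
  max_features sqrt, max_depth 30, bootstrap False`); a budget of 0
  fits that configuration directly.  Feature importances are MDI,
  normalized to sum to 1.
* **Small CNN** — `INPUT-32CONV(5×5)-MP(2×2)-16CONV(5×5)-MP(2×2)-
  8CONV(3×3)-MP(2×2)-16FC-NFC(softmax)`, Adam at learning rate 0.01,
  categorical cross-entropy, trained 12–24 epochs in three
  cross-validation segments that resample the train/validation split.
  The network is implemented directly on NumPy (im2col convolutions,
  float32), which is ample at this size and bit-reproducible under a
  seed.  A global gradient-norm clip of 5 keeps Adam stable at the
  relatively hot 0.01 learning rate.  The trainable-parameter count
  depends on the input crop size and channel count
  (`micro_cnn_param_count` exposes the closed form; e.g. 20,266 for
  48 px × 2 channels × 2 classes).  Default input is a 48 px
  two-channel (darkfield + brightfield) crop; both are configurable.
* **Model selection** — among candidate initializations, maximize
  `overall_accuracy − λ·stdev(per-class accuracy)` with λ = 1 (the
  two objectives are stated; their combination is this package's
  choice), ties to the lower index.
* **Mixture bias** — constructed mixtures of known composition are
  pushed through a trained classifier; predicted vs true proportions
  give the bias curve.  With confusion rates `C[i,j] = P(pred j |
  true i)` the observed proportions obey `q = Cᵀp`; `correct_bias`
  inverts this by nonnegative least squares and renormalizes.

## Quantitation

`density = (in_focus + merges·occupancy) / (frames · V_frame µL) ·
1000 · dilution`, with debris and out-of-focus ROIs excluded.  Merge
occupancy is `max(2, round(area / median single-cell area))` per
multi-object ROI — the floor of 2 encodes that a merge holds at least
two objects.  The pipeline's model-free ROI classifier uses
transparent feature rules: debris below 3 µm² foreground area;
out-of-focus below an edge-noise-gradient of 0.05; multi-object when
foreground area exceeds 1.8× the single-cell median, or 1.25× when
the primary component carries ≥ 2 intensity peaks (overlapping
doublets segment to one component with two maxima — area alone cannot
separate them from large singles).

Detection limits follow the standard blank-based scheme with
z = 1.645 (one-sided 95th normal quantile): LoB = mean + z·sd of
blank false-positive densities; LoD = LoB + z·sd of low-concentration
replicates; LoQ = the lowest dilution level whose replicate CV is
≤ 20% (a common convention, configurable, and flagged as an
assumption) with mean ≥ LoD.  The parabolic dilution ladder
12×, 10×, 8×, 6×, 4×, 2× gives cumulative levels 12–46080×.

## Synthetic scenes

The generator is phenomenological, not wave-optical: microspheres
render as bright darkfield annuli at 0.8 of their radius (rings of
their inner refractive diameter) with a dim center; cells as filled
soft-edged ellipses with mild internal texture; flocs as unions of
4–12 random lobes with strong texture; debris as faint ragged spots.
Brightfield is the complement (dark objects, bright background).
Defocus adds `0.12 µm of PSF σ per µm of focus offset` on top of a
0.3 µm base PSF, which both enlarges the apparent thresholded extent
and lowers the edge noise gradient — the two focus signatures the
features rely on.  Sensor noise is additive Gaussian (sd 0.01).
Truth masks record the ideal pre-blur geometry.  Particle counts are
Poisson(density × frame volume), positions uniform with an edge
margin, sizes lognormal (σ_log 0.12) around per-morphotype medians;
microsphere mode draws exact diameters from {1, 2, 4.5, 6, 10, 15} µm
(the 1 and 2 µm values complete the documented 1–15 µm range and are
generator assumptions).  Classification libraries render one particle
per crop with random size/orientation/jitter for five stylized
classes: circular cells, 1.7–2.5:1 ellipsoidal cells, ≥4:1 elongated
cells, flocs, and a defocused "unknown" null class.

What passing tests show — and do not.  The generator reproduces the
*contrasts* that drive each algorithm (annulus vs filled profile,
focus blur, crowding, morphotype shape statistics), so recovery
results demonstrate that the algorithms implement their contracts.
It does not reproduce halo artifacts, chromatic effects, fouling,
motion blur, or the true intra-class morphological diversity of field
samples, so accuracy numbers on synthetic libraries do not predict
accuracy on real imagery.

## Problem sizes and numerical choices

Test and acceptance runs use 1024×1024 px frames (volume rescaled
geometrically to ~0.0105 µL) — large enough for realistic crowding at
5×10⁵–7×10⁶ /mL while keeping the whole suite desk-scale.  Density
recovery is judged against the *realized* simulated count (the truth
the renderer actually drew), not the Poisson target, so small frame
counts do not inject sampling noise into the comparison.  The CNN
acceptance task trains at 32 px input on unaugmented crops: the
generator already randomizes orientation, which is the variation the
dihedral augmentation exists to supply for small curated libraries.
Ties in peak suppression break toward the smaller (row, col); ties in
primary-object assignment toward the lower object id; empty masks,
blank frames, and empty mixtures raise typed errors or return empty
results as documented per function.

## Known limitations

Rendering is 2-D and additive; overlapping particles sum intensities
rather than occlude.  The model-free ROI rule classifier is tuned for
monodisperse-ish cultures and will misjudge merges in strongly
polydisperse samples — a trained classifier should replace it there.
The Fast Detector's fixed crop size under-encapsulates objects larger
than the crop; that regime belongs to the Segmenter.  LoB/LoD/LoQ
computed on synthetic calibration data characterize the procedure,
not any physical instrument.
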