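# Methods

This note documents the models, parameters and design choices behind
`finprint`, and what the synthetic experiments do and do not show.

## The biometric and its assumptions

The identifying signal is the 2-D arrangement of melanophore dots on the
upper flank between the eye and the dorsal fin.  The matcher uses dot
*positions only* — no dot shape, size or intensity descriptors — on the
assumption that positions are the stable part of the pattern while dot
appearance changes with growth and lighting.  Identification is
closed-set: every query is assumed to be enrolled, and the gallery fish
with the minimal distance wins.  There is no rejection threshold for
unknown fish; open-set operation is out of scope.

The trimmed nearest-neighbour distance is asymmetric (query dots are
matched into the template).  The trim keeps the ⌈¾·n⌉ smallest of the n
per-dot nearest-neighbour distances; the ceiling guarantees at least one
distance for tiny patterns.  Discarding the largest quarter makes the
distance robust to spuriously detected or missed dots, which are the
dominant error mode of any detector.  The shift grid (±30 px step 5
short-term, ±50 px long-term) absorbs ROI-localization error between two
photographs of the same fish; on synthetic renders that error is a
near-pure translation of up to a few tens of pixels, consistent with the
grid sizes.  An optional uniform-scale grid (0.9–1.1, step 0.05, about
the template centroid) exists behind `MatchConfig.scale_grid` but is off
by default: shift-only matching is the canonical formulation, and the
width normalization of the ROI already absorbs most growth.

Tie-breaks are deterministic everywhere: the lexicographically smallest
(dx, dy) wins among equal shifts, and the smallest fish id wins among
equal gallery distances.

### Representative patterns

For long-term matching each fish/session is enrolled as a subset of one
*reference* pattern (the pattern with minimal mean distance to the
fish's other patterns).  After aligning every other pattern to the
reference by its best shift, a reference dot is kept if at least
max(3, ⌊N/3⌋ + 1) of the N patterns have a point within 20 px of it;
with fewer than three patterns everything is kept.  The two acceptance
criteria ("more than a third of the images" and "at least three images
for low image counts") are combined with max(); their precedence is
genuinely ambiguous in prose, so the rule is explicit configuration
here.  Kept dots retain the reference's coordinates — the representative
is a subset of detected dots, not an average — and if no dot reaches the
threshold (wildly inconsistent detections) the best-supported dots are
kept rather than returning an empty signature.

### Count heuristic

Patterns whose dot counts differ by more than a factor of two
(inclusive bound) are skipped during gallery search.  The heuristic only
prunes comparisons whose distance would be large; if it prunes the
whole gallery, the search falls back to comparing against every fish.

## ROI extraction choices

* Coordinates are 0-based, x = column (rightward), y = row (downward),
  pixel centers at integers.  All landmark arithmetic, including the ROI
  formula `y ∈ [UP.y + (BP.y − UP.y)/20, BP.y/2]`, is evaluated in the
  de-skewed fish-object frame with origin at the bounding-box top-left;
  "BP.y/2" is read in that frame (the plausible alternative — the
  UP–BP midpoint — is not used, and the bound is configurable in code).
  Rectangle bounds are floored on the top/left and ceiled on the
  bottom/right.
* Green segmentation thresholds: hue ∈ [90°, 150°], HSL saturation
  ≥ 0.3.  No reference values exist for the original backdrop, so the
  defaults match the synthetic scenes; real deployments recalibrate.
* Head-left standardization: the side containing sub-20-gray (eye)
  pixels is taken as the head; if none are found, the half with more
  mask area wins.  Rotated-in content outside the source frame is filled
  with a bright constant (210) so it can never masquerade as eye pixels.
* The narrowest-column search runs over the posterior half of the
  object but excludes the trailing 5% of columns: the tail fin's own
  trailing edge always tapers to narrow corner columns that would
  otherwise win over the true pre-tail waist.  Ties break rightmost.
* The upper-fin fit takes the topmost mask pixel per column in the
  3/8–5/8 window, splits at the window center, fits ordinary least
  squares lines to each half and intersects them; near-parallel fits
  fall back to the highest border point.
* ROI resampling is bilinear to width 1000, height preserving the
  aspect ratio.  Degenerate rectangles (BP.y/2 at or above the top
  bound) raise rather than returning an empty crop.

## Dot detection choices

* The patch classifier is a numpy CNN: 1×25×25 input, three 3×3
  convolutions (8/16/32 channels) with ReLU and 2×2 max-pooling after
  the first two, a 64-unit hidden layer and a softmax pair — five
  trained layers.  Training uses Adam (lr 10⁻³, batch 32), cross-entropy
  loss, a stratified 10% validation slice for early stopping (patience
  6, up to 40 epochs) and fixed-seed initialization.  At least 12 epochs
  are always run: on easy data validation accuracy saturates within one
  epoch while the decision boundary is still soft, which matters
  downstream because the sliding-window scan thresholds raw softmax
  probabilities at 0.30.
* Candidate points are window *centers* on the stride-5 grid; only
  windows fully inside the ROI are scanned, and only those whose center
  lies in the posterior ⅔ (x ≥ 1000/3).  The probability threshold is
  strict (> 0.30) on the raw softmax output.
* Clustering is single-linkage with a strict (< 15 px) distance cutoff;
  cluster centroids are the final dots.  Single linkage chains: three
  collinear candidates 10 px apart form one cluster.  This is a
  documented approximation of the original (undocumented) clustering
  routine.
* The blob alternative runs Laplacian-of-Gaussian detection (σ ∈
  [2.5, 5.5], 3 scales, threshold 0.12) on the ROI contrast-normalized
  by its median gray level — making it invariant to the session's
  illumination gain — and refines each blob to the intensity-weighted
  centroid of the local darkness.  It needs no training and is fully
  deterministic, which makes it the default for large simulation runs.

## HOG matcher choices

Only the normalized patch size (64), border offset (10) and cell size
(2) are fixed by the protocol; block geometry is the reference HOG
formulation: 2×2-cell blocks, unit-cell stride, 9 unsigned orientation
bins, L2-Hys block normalization (computed by scikit-image).  Distance
is the Euclidean norm.  The scan stride defaults to 4 px.  Two
implementation details depart from a literal per-window computation:

* the anti-aliasing prefilter for the downscale to 64×64 is applied to
  the whole ROI once per window size instead of per window (identical
  at aligned placements, negligible boundary differences elsewhere);
* the subregion's crop height is rounded down to a multiple of 8 so
  that every template shares one scan-descriptor bank per query ROI
  (ROI heights vary by a few pixels between images).

The "right ¾ of the ROI" subregion is shipped as a preset
(`PRESET_DISTANT`) for the most distant session pair; the right ⅔ is
the default.

## Pattern-stability analysis

`align_similarity` is the closed-form (Umeyama) least-squares similarity
fit; `displacement_analysis` aligns each later session's labeled dots to
the first session per fish and reports the mean per-axis absolute
residual, averaged over dots, sessions and fish.  Alignment first,
displacement second — the statistic quantifies pattern change after
removing pose and growth, not raw pixel motion.

## The synthetic generator

The generator emulates the acquisition conditions, not salmon
photorealism.  The fish silhouette is a parametric profile guaranteeing
exactly the features the landmark chain relies on: a rounded head with
a dark eye disk (gray < 20) in the head third, a straight back whose
dorsal-fin leading edge begins at half the head-to-waist length (so the
two-line fit intersects at the fin base), a belly below the fin base, a
unique narrowest pre-tail column at 84% of the body extent, and an
opaque tail fin.  The implied normalized-ROI height is ≈ 271 px for a
1000-px width.

* Identities carry 4–40 dots (default range 8–30) in unit flank
  coordinates, dart-thrown with a minimum spacing of 32 normalized-ROI
  px — comfortably above the 15-px clustering cutoff plus candidate
  spread, so clustering can never merge two true dots.  Dot radii are
  4.5–6.5 ROI px with intensity drops of 0.5–0.75.
* Scenes apply rotation within ±45°, translation, a multiplicative
  illumination gain, optional Gaussian blur, and anisotropic growth
  factors (length up to ×1.6, height up to ×1.9, interpolated
  geometrically across the four-session series).  Pattern drift between
  sessions is Gaussian with sd 4.5 normalized-ROI px per axis by
  default; an optional per-image jitter emulates residual pose and
  detection noise within a session.
* Training patches for the classifier are cropped from actual rendered
  images after the full ROI chain, dot patches centered on a
  ground-truth dot within ±3 px and background patches at least 20 px
  from every dot — the same procedure as manual patch selection from
  real ROIs, and the reason the classifier transfers to scanning
  without domain mismatch.
* Every render returns the applied affine, landmark positions and true
  dot centroids, so each pipeline stage is validated against exact
  ground truth rather than against another estimator.

What the generator does **not** emulate: skin texture is band-limited
noise, not scale rows; the tail fin is opaque (real ones are
semi-transparent and segment unreliably — NP detection is validated on
waist geometry only); underwater (aquarium) optics are reduced to blur
plus gain with no scattering model; there is no fish bending, occlusion
or background clutter; and dot appearance does not change with age.
Passing the synthetic suites therefore demonstrates the correctness and
internal consistency of the pipeline under the stated geometric and
photometric variation — it does not certify performance on real
underwater imagery, where the original study itself saw accuracy drop
for the longest between-session gaps.

## Problem sizes and determinism

The study-scale checks use 328 identities × 3 images (short-term), 30
identities × 4 sessions × 6 images (long-term) and 535 + 535 patches
(classifier), matching the original experimental design; smaller cohorts
are used in unit tests where the property under test does not depend on
scale.  All randomness flows from explicit integer seeds through
`numpy.random.Generator`; renders, cohorts, training and matching are
bit-reproducible for a fixed seed, and the matcher itself is fully
deterministic including tie-breaks.

## Known limitations

* Closed-set only; no score calibration or rejection.
* The count heuristic assumes detectors with roughly consistent dot
  counts across images of one fish; detectors with wildly varying
  counts would need the heuristic relaxed.
* Landmark extraction presumes exactly one fish per frame, left-side
  view, on a chroma-separable backdrop.
* The CNN is intentionally small and trained on synthetic crops; real
  deployments should retrain it on patches from their own imagery
  (`finprint train-detector` with a replacement patch source).
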