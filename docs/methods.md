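# Methods

## Problem and data model

A catheter tip pressed onto tissue at contact angle θ (0° = shaft parallel
to the surface, 90° = perpendicular) and contact force F (gram-force)
leaves an ink print whose area A (mm²) and shape characterise the
electrode–tissue interface. The package models three layers:

1. a per-(tip, angle) **logarithmic force–area law** `A = a·ln(F) + b`;
2. a **four-class footprint morphology** determined by tip shape and angle
   (T1 rectangular: flat tip at 0°; T2 semi-ellipsoidal: round tip at 0°;
   T3 circular: either tip at 90°; T4 ellipsoidal: intermediate angles);
3. an **image pipeline** that recovers areas and classes from print
   photographs.

Percentage contact area normalises A by the total electrode surface,
`PCA = 100·A / S_tip`, with S_tip = 37.26 mm² (flat) and 25.67 mm²
(round). These constants are carried as presets on the bundled tip
specifications; the geometric formulas (cylinder π·d·L plus a flat cap
π·d²/4 or hemispherical cap π·d²/2 on a cylinder shortened by d/2)
reproduce them to within 0.06 mm² with d = 2.33 mm and L = 4.5 / 3.5 mm.
Forces convert as 1 gf = 0.00981 N.

## Image pipeline

- **Binarisation.** Otsu's threshold (256-bin between-class-variance
  maximisation, via scikit-image) by default, with a fixed-threshold
  override. The print is a single region, so only the largest connected
  component is retained; this replaces manual segmentation of raw
  photographs and is exact for single-print images. A constant image
  yields an empty mask with a warning.
- **Area.** Foreground pixel count × (mm/px)². For rasterised analytic
  shapes spanning ≥ 50 px along the shortest axis the error is below 2%
  (measured: ≤ 0.5% on the default grid).
- **Principal axis.** Orientation (degrees from the image vertical,
  counterclockwise positive, in (−90, 90]) and eccentricity come from the
  second central moments of the mask. Below eccentricity 0.1 a shape is
  treated as rotationally ambiguous: its orientation is reported as 0 and
  alignment skips rotation, so near-circular prints are not rotated by
  noise-driven arbitrary angles.
- **Alignment.** The centroid is translated to the canvas centre
  (whole-pixel shift), the mask rotated by −orientation about the centre
  with nearest-neighbour resampling (keeps the mask binary and conserves
  area; rotations under 0.5° are skipped, which makes alignment
  idempotent), then re-centred. The 180° axis ambiguity is resolved by
  flipping the heavier half toward the canvas bottom — applied only when
  the imbalance exceeds 2% of the mass, so symmetric shapes keep a stable
  pose; the rule only matters for the asymmetric T2 prints.
- **Averaging.** Aligned replicates are stacked on a common canvas (the
  largest input padded by 25% unless specified); the occupancy map is
  their per-pixel mean, and the consensus mask keeps pixels covered by at
  least half of the replicates (ties included). Both the grayscale
  occupancy and the thresholded consensus are exported, since either can
  serve as the "average morphology" image.

## Shape descriptors and classification

Classification uses three pose-invariant descriptors, evaluated after
rotating the mask to its principal frame:

- **eccentricity** of the moment ellipse;
- **rectangularity** = area / axis-aligned bounding-box area (1 for an
  upright rectangle, π/4 ≈ 0.785 for an ellipse);
- **axial asymmetry** = normalised symmetric difference between the mask
  and its mirror image across a principal-axis line through the centroid,
  maximised over the two axes. This is 0 for doubly symmetric shapes and
  ≈ 0.185 for a half-ellipse (analytically: the overlap of a half-disk
  with its reflection about the centroid line along the flat edge is
  4∫√(1−y²)dy over [4/(3π), 2·4/(3π)+…], giving symmetric difference
  0.58 of 2× the area). A plain area difference of the two halves would
  not work: the centroid nearly balances the half-areas of any shape
  (≈ 0.05 for a half-disk), so reflection overlap is used instead.

The decision rule, with configurable thresholds:
eccentricity < 0.3 → T3; else rectangularity > 0.9 → T1; else
axial asymmetry > 0.15 → T2; else T4. Exactly one class is always
returned. The margins on the default grid are comfortable: T2 prints sit
at asymmetry ≈ 0.185 vs ellipses ≤ 0.03, rectangles at rectangularity
≥ 0.97 vs T2 at ≈ 0.78.

## Synthetic generator

The generator defines the study conditions: 2 tips × angles
{0, 30, 45, 60, 90}° × forces {2, 4, 6, 10, 15, 20, 30, 40} gf ×
6 replicates (480 images), pixel scale 0.02 mm/px on a 512×512 canvas
(≥ 50 px across the smallest footprint at 2 gf), foreground 0.9,
background 0.1, additive pixel noise SD 0.05 clipped to [0, 1] (an
8σ-separated bimodal histogram, so Otsu is well-posed).

Replicate areas are `A = (a·ln F + b)·(1 + ε)`, ε ~ N(0, cv) with
cv = 0.08 by default — matching the SD/mean ratios of the bundled summary
tables (0.06–0.18) — plus per-replicate pose jitter (rotation ≤ 5°,
centroid offset ≤ 5 px) so the alignment stage is genuinely exercised.
Each image draws from its own generator seeded from the dataset seed and
the image index, making datasets byte-reproducible.

Footprint geometry is solved from the target area with one free
dimension:

- **T1** rectangle of width = tip diameter (2.33 mm), length = A/width;
  below A = d² it degrades to a square of side √A.
- **T3** disk of radius √(A/π).
- **T4** ellipse with aspect ratio major/minor = 1/sin θ — the projection
  of the circular tip cross-section tilted by the contact angle — with the
  minor axis clamped at the tip diameter when the area allows. The
  angle-driven aspect keeps intermediate-angle prints measurably elongated
  at every grid area (a diameter-fixed minor axis would collapse to a
  circle at the smallest areas, e.g. the round tip at 45° and 2 gf).
- **T2** half-ellipse: flat edge of width = tip diameter, elliptical dome
  of height 4A/(π·w), rendered flat edge down. A pure half-ellipse rather
  than a half-ellipse-plus-rectangle "stadium" is used because a stadium
  with the body lengths the grid areas imply fills > 90% of its bounding
  box and is indistinguishable from a rectangle under the classification
  rule above; the half-ellipse keeps rectangularity at π/4 while retaining
  the flat-edge asymmetry that defines the class.

Shapes are rasterised by evaluating the exact implicit membership test at
pixel centres in the jittered frame — no resampling — so the pixel area is
an unbiased estimate of the analytic `truth_area` recorded in the
manifest.

What the generator does **not** emulate: tissue deformation (no contact
mechanics — areas are imposed by the law, not derived from pressure),
ink bleed and transfer unevenness, illumination gradients, multi-print
scenes, and non-flat tissue. Passing tests therefore demonstrate that the
pipeline correctly recovers areas, laws and classes from prints with the
assumed statistical structure, not that it is robust to real photographic
artefacts.

## Fitting and aggregation conventions

- Fits are OLS of area on ln(force) (scipy.stats.linregress); natural
  logarithm throughout.
- Per-(tip, angle) fits default to the 8 per-force **mean** areas rather
  than all 48 replicates: refitting the bundled mean tables reproduces the
  bundled printed coefficients to ±0.001 for the self-consistent rows,
  which identifies means as the convention behind them (a
  `fit_on="replicates"` flag fits all points instead).
- SD uses the sample (n−1) convention; single-replicate conditions report
  SD 0 with a flag. Raw replicates behind the bundled tables are
  unpublished, so no test asserts SD reproduction.
- Groups with fewer than 3 distinct forces are reported without a fit and
  flagged, never silently dropped.
- Display rounding mirrors the reference tables: coefficients and areas to
  3 decimals, PCA to integer, Newtons to 3 significant figures.

## Known limitations and honest discrepancies

- Two cells of the bundled summary tables are internally inconsistent as
  published (one mean contradicts its own printed percentage; verbatim
  transcription is kept), so 2 of 10 coefficient-table refits and 1 of 80
  PCA round-trip cells disagree beyond tolerance; the corresponding
  acceptance tests fail by design rather than patching published data.
- The published Newton conversions were evidently computed with
  0.0098 N/gf although 0.00981 is stated; this package uses 0.00981, so
  the 6 gf conversion differs from the printed value in the last digit.
- The round-tip 45° law has b = 0.012 mm²; rasterisation noise makes a 1%
  relative recovery of that intercept impossible from images (absolute
  error ≈ 0.002–0.006 mm² on the default grid).
- Coefficient recovery under replicate noise (cv = 0.08, 6 replicates,
  8 forces) lands both a and b within 10% in ≈ 88–90% of repetitions
  (slope SE is ≈ 6% of a at these settings), which the acceptance suite
  reports as measured.
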