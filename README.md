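# contactprint

Morphometry of catheter contact prints on heart-muscle tissue.

During radiofrequency catheter ablation, the lesion a catheter creates
depends on how much of its tip electrode actually touches the myocardium.
Bench experiments measure this by coating the tip with ink, pressing it onto
flattened tissue at a controlled contact angle and contact force, and
photographing the resulting print. `contactprint` implements the complete
analysis of such experiments for researchers studying ablation contact
mechanics:

- **Image pipeline** — grayscale conversion, Otsu (or fixed-threshold)
  binarisation with largest-component retention, contact-area measurement by
  calibrated pixel counting, principal-axis estimation from second central
  moments, centroid alignment with rotation of the longest axis to vertical,
  and replicate averaging into an occupancy map with a majority consensus
  mask.
- **Morphology classification** — each footprint is assigned one of four
  classes: T1 rectangular (flat tip lying parallel to tissue), T2
  semi-ellipsoidal (round tip lying parallel), T3 circular (either tip
  perpendicular), T4 ellipsoidal (intermediate angles).
- **Force–area model** — per-condition aggregation (mean, sample SD,
  percentage contact area `PCA = 100 · area / tip surface area`, with
  electrode surfaces 37.26 mm² flat and 25.67 mm² round), gram-force to
  Newton conversion (1 gf = 0.00981 N), and ordinary least-squares fitting
  of the logarithmic law

  ```
  area = a · ln(force) + b,    R² = 1 − SS_res / SS_tot
  ```

- **Synthetic generator** — renders contact prints with the statistical
  structure of the bench data (one connected footprint per image, bimodal
  intensities, shape class keyed to tip and angle, areas following
  `a·ln(F)+b` with multiplicative replicate noise, small pose jitter), so
  the entire pipeline is testable without photographs. The default study
  grid is 2 tips × 5 angles (0°, 30°, 45°, 60°, 90°) × 8 forces (2–40 gf)
  × 6 replicates = 480 images.

The package also bundles the reference per-condition summary tables
(mean contact area, SD, integer PCA for both tips over the full grid) as
CSV fixtures, plus the per-(tip, angle) logarithmic coefficients, for
refitting and round-trip checks.

## Worked example

Refit the bundled summary tables (`python examples/fit_reference_tables.py`):

```
tip    angle       a       b     R2
flat       0   2.685   7.782  0.837
flat      30   3.036   3.465  0.845
...
round     90   2.341   2.709  0.953
```

For the flat tip at 0°, contact area grows by a = 2.685 mm² per e-fold
increase in force from b = 7.782 mm² at 1 gf; the logarithmic law explains
R² = 83.7% of the between-force variance. Shallower contact angles give
systematically larger areas at every force.

Simulate and analyse a small study (`python examples/simulate_and_analyze.py`):

```
rendered 48 prints (2 angles x 8 forces x 3 replicates)

angle  a_true   a_fit  b_true   b_fit       R2
    0   2.685   2.686   7.782   7.781  1.00000
   90   2.693   2.694   0.892   0.891  1.00000

morphology classes seen: ['T1', 'T3'] (T1 rectangle at 0 deg, T3 circle at 90 deg)
```

The image stage recovers the generating coefficients to within 0.1% on
noiseless prints — the residual is pure rasterisation error — and every
condition's averaged morphology is classified into the class the generator
drew. `examples/morphology_profile.py` shows the replicate-averaging step
on its own.

## Command line

```bash
contactprint simulate --out prints/ --seed 1            # synthetic dataset + manifest
contactprint analyze  --manifest prints/manifest.csv --images prints/ --out report/
contactprint fit      --records records.csv --out fits.csv
contactprint report   --records records.csv --out report/
```

`analyze` writes `summary.csv` (per-condition mean/SD/PCA), `fits.csv`
(per-(tip, angle) a, b, R²), `descriptors.csv` (per-image shape
descriptors and class), per-condition occupancy/consensus PNGs, and a run
log with config hash and seed; identical inputs reproduce identical bytes.

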