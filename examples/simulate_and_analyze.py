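"""Simulate a small study and recover the force--area laws from the images.

Generates a noiseless synthetic dataset for the flat tip at two contact
angles (0 and 90 degrees) across the full 8-force grid with 3 replicates,
runs the complete image pipeline (binarise, measure, align, average, fit),
and compares the recovered logarithmic laws with the generating ones.
"""

from contactprint import FLAT_TIP, GroundTruthLaw, generate_dataset, run_study

laws = {
    ("flat", 0.0): GroundTruthLaw(a=2.685, b=7.782, noise_cv=0),
    ("flat", 90.0): GroundTruthLaw(a=2.693, b=0.892, noise_cv=0),
}
prints, manifest = generate_dataset(
    laws, replicates=3, seed=42, tips=[FLAT_TIP], angles=[0, 90]
)
print(f"rendered {len(prints)} prints "
      f"({manifest['angle_deg'].nunique()} angles x "
      f"{manifest['force_gf'].nunique()} forces x 3 replicates)")

report = run_study(prints, manifest=manifest, seed=42)
print(f"\n{'angle':>5s} {'a_true':>7s} {'a_fit':>7s} {'b_true':>7s} "
      f"{'b_fit':>7s} {'R2':>8s}")
for _, row in report.fits.iterrows():
    law = laws[(row["tip"], row["angle_deg"])]
    print(f"{row['angle_deg']:5.0f} {law.a:7.3f} {row['a']:7.3f} "
          f"{law.b:7.3f} {row['b']:7.3f} {row['r2']:8.5f}")

classes = {prof.morphology_class for prof in report.profiles.values()}
print(f"\nmorphology classes seen: {sorted(classes)} "
      "(T1 rectangle at 0 deg, T3 circle at 90 deg)")
print("Recovered coefficients should sit within 1% of the generating laws:"
      "\nthe image stage adds only rasterisation error, no area noise.")
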