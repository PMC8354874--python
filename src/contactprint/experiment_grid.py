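"""Full-study orchestration.

Runs the image pipeline over a manifest-driven dataset (synthetic or
user-supplied), aggregates per condition, fits one log law per
(tip, angle), builds per-condition averaged-morphology profiles, and
exports a report shaped like the study's summary, fit and average-image
outputs.  All stages reuse the public functions of
:mod:`contactprint.image_morphology` and
:mod:`contactprint.force_area_model`; there is no hidden recomputation
path, so the report's numbers are bitwise those of the underlying modules.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .force_area_model import TIP_SURFACE_AREA_MM2, aggregate, fit_by_condition
from .image_morphology import (
    BinaryMask,
    ClassThresholds,
    MorphologyProfile,
    average_morphology,
    binarize,
    compute_descriptors,
    classify_morphology,
    descriptors_frame,
    measure_area,
    read_image,
    to_grayscale,
    write_mask_png,
    write_occupancy_png,
)
from .synthetic_data import ContactPrint

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "run_study", "run_study_from_records", "export_report"]


@dataclass(frozen=True)
class StudyConfig:
    """Tunable knobs of a study run (thresholds, fitting, canvas)."""

    binarize_method: str = "otsu"
    threshold: float | None = None
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    fit_on: str = "means"  # or "replicates"
    min_forces_for_fit: int = 3
    canvas_pad: float = 1.25
    tip_areas: dict[str, float] = field(
        default_factory=lambda: dict(TIP_SURFACE_AREA_MM2)
    )

    def hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StudyReport:
    """Everything a full run produces."""

    summaries: pd.DataFrame  # one row per (tip, angle, force)
    fits: pd.DataFrame  # one row per (tip, angle)
    profiles: dict[tuple[str, float, float], MorphologyProfile]
    descriptors: pd.DataFrame
    records: pd.DataFrame  # per-image measured areas
    provenance: dict


def _masks_from_prints(
    prints: Sequence[ContactPrint], manifest: pd.DataFrame, config: StudyConfig
) -> tuple[pd.DataFrame, dict, list]:
    records = []
    masks_by_condition: dict[tuple[str, float, float], list[BinaryMask]] = {}
    named = []
    for cp, (_, row) in zip(prints, manifest.iterrows()):
        gray = to_grayscale(cp.pixels)
        mask = binarize(
            gray,
            method=config.binarize_method,
            threshold=config.threshold,
            pixel_scale=cp.pixel_scale,
        )
        area = measure_area(mask)
        key = (str(row["tip"]), float(row["angle_deg"]), float(row["force_gf"]))
        masks_by_condition.setdefault(key, []).append(mask)
        records.append(
            {
                "tip": key[0],
                "angle_deg": key[1],
                "force_gf": key[2],
                "replicate": int(row["replicate"]),
                "area_mm2": area,
            }
        )
        if mask.pixels.any():
            desc = compute_descriptors(mask)
            named.append(
                (str(row["file"]), desc, classify_morphology(desc, config.thresholds))
            )
    return pd.DataFrame(records), masks_by_condition, named


def run_study(
    source,
    manifest: pd.DataFrame | str | Path | None = None,
    images_dir: str | Path | None = None,
    config: StudyConfig | None = None,
    seed: int | None = None,
) -> StudyReport:
    """Run the full analysis.

    ``source`` may be a list of in-memory :class:`ContactPrint` objects
    (with ``manifest`` the matching manifest table), or ``None`` with
    ``manifest`` pointing at a manifest CSV and ``images_dir`` at the PNG
    directory.  For records-only input (no images) use
    :func:`run_study_from_records`.
    """
    config = config or StudyConfig()
    if isinstance(manifest, (str, Path)):
        manifest = pd.read_csv(manifest)
    if source is None:
        if manifest is None or images_dir is None:
            raise ValueError("need a manifest and images_dir when no prints are given")
        if len(manifest) == 0:
            raise ValueError("empty manifest")
        images_dir = Path(images_dir)
        prints = []
        for _, row in manifest.iterrows():
            path = images_dir / str(row["file"])
            if not path.exists():
                raise FileNotFoundError(f"manifest names a missing image: {path}")
            pixels = read_image(path)
            prints.append(
                ContactPrint(
                    pixels=pixels,
                    pixel_scale=float(row["pixel_scale_mm_per_px"]),
                    condition=None,  # type: ignore[arg-type]
                    truth_area=float(row.get("truth_area_mm2", float("nan"))),
                )
            )
    else:
        prints = list(source)
        if manifest is None:
            raise ValueError("a manifest table must accompany in-memory prints")
        if len(manifest) == 0:
            raise ValueError("empty manifest")
        if len(prints) != len(manifest):
            raise ValueError("manifest/image count mismatch")

    records, masks_by_condition, named = _masks_from_prints(prints, manifest, config)
    logger.info("measured %d prints over %d conditions", len(records), len(masks_by_condition))

    profiles = {}
    for key, masks in sorted(masks_by_condition.items()):
        nonempty = [m for m in masks if m.pixels.any()]
        if not nonempty:
            logger.warning("condition %s has no nonempty masks; skipped", key)
            continue
        profiles[key] = average_morphology(nonempty, thresholds=config.thresholds)

    report = _finish_report(records, config, seed)
    report.profiles = profiles
    report.descriptors = descriptors_frame(named)
    return report


def run_study_from_records(
    records: pd.DataFrame | str | Path,
    config: StudyConfig | None = None,
    seed: int | None = None,
) -> StudyReport:
    """Aggregate and fit a long records table (no image stage).

    ``records`` has columns ``tip, angle_deg, force_gf, replicate,
    area_mm2`` (a ``mean_area_mm2`` column is accepted as pre-averaged
    areas with one implicit replicate per force).
    """
    config = config or StudyConfig()
    if isinstance(records, (str, Path)):
        records = pd.read_csv(records)
    records = records.copy()
    if "area_mm2" not in records.columns and "mean_area_mm2" in records.columns:
        records = records.rename(columns={"mean_area_mm2": "area_mm2"})
        if "replicate" not in records.columns:
            records["replicate"] = 1
    if len(records) == 0:
        raise ValueError("no records supplied")
    return _finish_report(records, config, seed)


def _finish_report(records: pd.DataFrame, config: StudyConfig, seed) -> StudyReport:
    summaries = aggregate(records, tip_areas=config.tip_areas)
    fits = fit_by_condition(
        records, on=config.fit_on, min_forces=config.min_forces_for_fit
    )
    for _, row in fits[~fits["fitted"]].iterrows():
        logger.warning(
            "tip=%s angle=%s has fewer than %d distinct forces; no fit",
            row["tip"],
            row["angle_deg"],
            config.min_forces_for_fit,
        )
    under = summaries[summaries["n"] < 6]
    if len(under):
        logger.warning("%d conditions have fewer than 6 replicates", len(under))
    provenance = {
        "config_hash": config.hash(),
        "seed": seed,
        "version": __version__,
    }
    return StudyReport(
        summaries=summaries,
        fits=fits,
        profiles={},
        descriptors=pd.DataFrame(),
        records=records,
        provenance=provenance,
    )


def export_report(report: StudyReport, out_dir: str | Path) -> Path:
    """Write summary.csv, fits.csv, descriptors.csv, profile PNGs and a log.

    Floats are written at fixed precision so re-running with identical
    inputs overwrites every file byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.summaries.to_csv(out / "summary.csv", index=False, float_format="%.6f")
    report.fits.to_csv(out / "fits.csv", index=False, float_format="%.6f")
    if len(report.descriptors):
        report.descriptors.to_csv(
            out / "descriptors.csv", index=False, float_format="%.6f"
        )
    profile_dir = out / "profiles"
    if report.profiles:
        profile_dir.mkdir(exist_ok=True)
    for (tip, angle, force), prof in sorted(report.profiles.items()):
        stem = f"{tip}_a{int(angle):02d}_f{force:g}gf"
        write_occupancy_png(prof.occupancy, profile_dir / f"{stem}_occupancy.png")
        write_mask_png(prof.consensus_mask, profile_dir / f"{stem}_consensus.png")
    log = dict(report.provenance)
    log["n_conditions"] = int(len(report.summaries))
    log["n_fits"] = int(report.fits["fitted"].sum()) if len(report.fits) else 0
    log["profile_classes"] = {
        f"{tip}_a{int(angle):02d}_f{force:g}gf": prof.morphology_class
        for (tip, angle, force), prof in sorted(report.profiles.items())
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return out
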