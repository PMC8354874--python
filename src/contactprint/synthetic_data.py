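"""Synthetic contact-print generator.

Emulates the ink-print photographs of an ablation-catheter tip pressed onto
a flattened tissue surface.  Each print is a single bright footprint on a
darker background whose analytic area follows a logarithmic force--area law
``area = a*ln(force) + b`` with multiplicative replicate noise, and whose
shape class is determined by the tip geometry and contact angle:

* T1 rectangular      -- flat tip lying parallel to the surface (0 deg)
* T2 semi-ellipsoidal -- round tip lying parallel to the surface (0 deg)
* T3 circular         -- either tip perpendicular to the surface (90 deg)
* T4 ellipsoidal      -- either tip at an intermediate angle

The generator is phenomenological: it reproduces the statistical and
geometric structure the downstream image analysis assumes (one connected
footprint, bimodal intensities, replicate-to-replicate jitter), not the
contact mechanics of deforming tissue.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "TipSpec",
    "GroundTruthLaw",
    "ContactCondition",
    "ContactPrint",
    "FLAT_TIP",
    "ROUND_TIP",
    "ANGLES_DEG",
    "FORCES_GF",
    "MORPHOLOGY_CLASSES",
    "target_area",
    "footprint_class",
    "render_footprint",
    "generate_dataset",
    "write_dataset",
    "default_laws",
    "load_laws",
]

#: Contact angles of the study grid, degrees between catheter shaft and tissue.
ANGLES_DEG: tuple[int, ...] = (0, 30, 45, 60, 90)

#: Contact forces of the study grid, gram-force.
FORCES_GF: tuple[int, ...] = (2, 4, 6, 10, 15, 20, 30, 40)

#: Footprint class labels and their descriptive names.
MORPHOLOGY_CLASSES: dict[str, str] = {
    "T1": "rectangular",
    "T2": "semi-ellipsoidal",
    "T3": "circular",
    "T4": "ellipsoidal",
}


@dataclass(frozen=True)
class TipSpec:
    """Geometry of an ablation-catheter tip electrode.

    Parameters
    ----------
    shape:
        ``"flat"`` (cylindrical electrode with a flat end cap) or
        ``"round"`` (cylindrical electrode with a hemispherical end cap).
    diameter:
        Electrode diameter, mm.
    electrode_length:
        Electrode length along the catheter axis, mm.
    surface_area:
        Total electrode surface area, mm^2.  When set, it takes precedence
        over the value implied by the cylinder formulas (the bundled tips
        carry the constants used to normalise percentage contact area:
        37.26 mm^2 flat, 25.67 mm^2 round).
    """

    shape: str
    diameter: float = 2.33
    electrode_length: float = 4.5
    surface_area: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("flat", "round"):
            raise ValueError(f"unknown tip shape {self.shape!r}")
        if self.diameter <= 0 or self.electrode_length <= 0:
            raise ValueError("tip dimensions must be positive")
        if self.surface_area is not None and self.surface_area <= 0:
            raise ValueError("surface_area must be positive")
        if self.diameter > 2 * self.electrode_length:
            raise ValueError("diameter exceeds twice the electrode length")


FLAT_TIP = TipSpec("flat", diameter=2.33, electrode_length=4.5, surface_area=37.26)
ROUND_TIP = TipSpec("round", diameter=2.33, electrode_length=3.5, surface_area=25.67)

_TIPS = {"flat": FLAT_TIP, "round": ROUND_TIP}


@dataclass(frozen=True)
class GroundTruthLaw:
    """Logarithmic force--area law ``area = a*ln(force) + b``.

    ``a`` is in mm^2 per ln(gf), ``b`` in mm^2; ``noise_cv`` is the
    coefficient of variation of the multiplicative replicate noise on area.
    """

    a: float
    b: float
    noise_cv: float = 0.08

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass(frozen=True)
class ContactCondition:
    """One experimental condition: tip, contact angle, force, replicate."""

    tip: TipSpec
    angle: float  # degrees in [0, 90]
    force: float  # gram-force, > 0
    replicate: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.angle <= 90:
            raise ValueError("contact angle must lie in [0, 90] degrees")
        if self.force <= 0:
            raise ValueError("contact force must be positive")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")


@dataclass
class ContactPrint:
    """A rendered contact print: intensity image plus calibration and truth."""

    pixels: np.ndarray  # float64 in [0, 1]
    pixel_scale: float  # mm per pixel
    condition: ContactCondition
    truth_area: float  # analytic footprint area, mm^2


def target_area(law: GroundTruthLaw, force: float) -> float:
    """Noise-free footprint area at ``force`` under ``law``, mm^2."""
    if force <= 0:
        raise ValueError("force must be positive")
    area = law.a * math.log(force) + law.b
    if area <= 0:
        raise ValueError(
            f"law predicts nonpositive area {area:.4f} mm^2 at {force} gf"
        )
    return area


def footprint_class(tip_shape: str, angle: float) -> str:
    """Footprint shape class for a tip shape and contact angle.

    Parallel contact (0 deg) prints the side of the electrode: a rectangle
    for a flat tip, a semi-ellipse for a round tip.  Perpendicular contact
    (90 deg) prints the circular cross-section for either tip.  Intermediate
    angles print an ellipse.
    """
    if tip_shape not in ("flat", "round"):
        raise ValueError(f"unknown tip shape {tip_shape!r}")
    if not 0 <= angle <= 90:
        raise ValueError("contact angle must lie in [0, 90] degrees")
    if angle == 90:
        return "T3"
    if angle == 0:
        return "T1" if tip_shape == "flat" else "T2"
    return "T4"


# -- geometry ---------------------------------------------------------------


def _solve_geometry(klass: str, area: float, diameter: float, angle: float):
    """Solve the free footprint dimension(s) from the target area (mm).

    One dimension is fixed at the tip diameter whenever the solved free
    dimension would exceed it; otherwise the shape shrinks with a fixed
    aspect ratio so the class-defining elongation survives at small areas.
    Returns ``(kind, params...)`` in mm.
    """
    d = diameter
    if klass == "T1":
        length = area / d
        if length >= d:
            return ("rect", d, length)
        side = math.sqrt(area)
        return ("rect", side, side)
    if klass == "T3":
        return ("circle", math.sqrt(area / math.pi))
    if klass == "T4":
        # Projection of the circular tip cross-section tilted by the contact
        # angle: major/minor = 1/sin(angle).
        aspect = 1.0 / math.sin(math.radians(angle))
        minor = math.sqrt(4.0 * area / (math.pi * aspect))
        if minor > d:
            minor = d
            major = 4.0 * area / (math.pi * d)
        else:
            major = aspect * minor
        return ("ellipse", minor, major)
    if klass == "T2":
        # Half-ellipse: flat edge of width w, elliptical dome of height h.
        w = d
        h = 4.0 * area / (math.pi * w)
        if h < 1.2 * w:  # keep the dome the long axis at small areas
            w = math.sqrt(4.0 * area / (1.5 * math.pi))
            h = 1.5 * w
        return ("halfellipse", w, h)
    raise ValueError(f"unknown footprint class {klass!r}")


def _min_extent_mm(geom) -> float:
    kind = geom[0]
    if kind == "rect":
        return min(geom[1], geom[2])
    if kind == "circle":
        return 2 * geom[1]
    if kind in ("ellipse", "halfellipse"):
        return min(geom[1], geom[2])
    raise ValueError(kind)


def _membership(geom, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Footprint membership test in the footprint frame (u across, v along)."""
    kind = geom[0]
    if kind == "rect":
        w, length = geom[1], geom[2]
        return (np.abs(u) <= w / 2) & (np.abs(v) <= length / 2)
    if kind == "circle":
        r = geom[1]
        return u * u + v * v <= r * r
    if kind == "ellipse":
        minor, major = geom[1], geom[2]
        return (u / (minor / 2)) ** 2 + (v / (major / 2)) ** 2 <= 1.0
    if kind == "halfellipse":
        w, h = geom[1], geom[2]
        # Centroid of a half-ellipse sits 4h/(3*pi) from the flat edge;
        # place the centroid at the origin with the flat edge toward +v
        # (image bottom) so the rendered pose is already canonical.
        yc = 4.0 * h / (3.0 * math.pi)
        inside = (u / (w / 2)) ** 2 + ((v - yc) / h) ** 2 <= 1.0
        return inside & (v <= yc)
    raise ValueError(kind)


def render_footprint(
    condition: ContactCondition,
    law: GroundTruthLaw,
    pixel_scale: float = 0.02,
    seed: int = 0,
    *,
    canvas: tuple[int, int] = (512, 512),
    jitter_deg: float = 5.0,
    jitter_px: float = 5.0,
    foreground: float = 0.9,
    background: float = 0.1,
    pixel_noise_sd: float = 0.05,
) -> ContactPrint:
    """Render one synthetic contact print.

    The analytic footprint area is ``target_area(law, force) * (1 + eps)``
    with ``eps ~ Normal(0, law.noise_cv)`` drawn deterministically from
    ``seed``; the footprint is rotated by a small random angle and offset by
    a small random translation so that the alignment stage downstream is
    genuinely exercised.  The rasterised pixel area tracks the analytic
    ``truth_area`` to well within 2% at the default scale.
    """
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    rng = np.random.default_rng(seed)
    base = target_area(law, condition.force)
    eps = rng.normal(0.0, law.noise_cv) if law.noise_cv > 0 else 0.0
    area = base * (1.0 + eps)
    if area <= 0:
        raise ValueError(
            f"replicate noise drew a nonpositive area ({area:.4f} mm^2)"
        )
    klass = footprint_class(condition.tip.shape, condition.angle)
    geom = _solve_geometry(klass, area, condition.tip.diameter, condition.angle)

    if _min_extent_mm(geom) / pixel_scale < 50:
        warnings.warn(
            "footprint spans fewer than 50 pixels along its shortest axis; "
            "area fidelity may degrade",
            UserWarning,
            stacklevel=2,
        )

    theta = math.radians(rng.uniform(-jitter_deg, jitter_deg)) if jitter_deg > 0 else 0.0
    if jitter_px > 0:
        off_r, off_c = rng.uniform(-jitter_px, jitter_px, size=2)
    else:
        off_r = off_c = 0.0

    rows, cols = canvas
    cy = (rows - 1) / 2.0 + off_r
    cx = (cols - 1) / 2.0 + off_c
    yy = (np.arange(rows) - cy)[:, None] * pixel_scale
    xx = (np.arange(cols) - cx)[None, :] * pixel_scale
    # rotate image coordinates into the footprint frame
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    u = xx * cos_t + yy * sin_t
    v = -xx * sin_t + yy * cos_t
    mask = _membership(geom, u, v)

    if (
        mask[0, :].any()
        or mask[-1, :].any()
        or mask[:, 0].any()
        or mask[:, -1].any()
        or not mask.any()
    ):
        raise ValueError("footprint does not fit on the canvas")

    image = np.where(mask, foreground, background).astype(np.float64)
    if pixel_noise_sd > 0:
        image = image + rng.normal(0.0, pixel_noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return ContactPrint(
        pixels=image,
        pixel_scale=pixel_scale,
        condition=condition,
        truth_area=area,
    )


# -- dataset generation -------------------------------------------------------

MANIFEST_COLUMNS = [
    "file",
    "tip",
    "angle_deg",
    "force_gf",
    "replicate",
    "truth_area_mm2",
    "pixel_scale_mm_per_px",
    "seed",
]


def _normalise_laws(laws: Mapping) -> dict[tuple[str, float], GroundTruthLaw]:
    """Accept ``{tip: {angle: law}}`` or ``{(tip, angle): law}`` mappings."""
    flat: dict[tuple[str, float], GroundTruthLaw] = {}
    for key, value in laws.items():
        if isinstance(key, tuple):
            flat[(key[0], float(key[1]))] = _as_law(value)
        else:
            for angle, law in value.items():
                flat[(str(key), float(angle))] = _as_law(law)
    return flat


def _as_law(value) -> GroundTruthLaw:
    if isinstance(value, GroundTruthLaw):
        return value
    return GroundTruthLaw(
        a=float(value["a"]),
        b=float(value["b"]),
        noise_cv=float(value.get("noise_cv", 0.08)),
    )


def generate_dataset(
    laws: Mapping,
    replicates: int = 6,
    pixel_scale: float = 0.02,
    seed: int = 0,
    *,
    tips: Sequence[TipSpec] | None = None,
    angles: Iterable[float] = ANGLES_DEG,
    forces: Iterable[float] = FORCES_GF,
    **render_kwargs,
) -> tuple[list[ContactPrint], pd.DataFrame]:
    """Generate the full (tips x angles x forces x replicates) print grid.

    ``laws`` maps ``(tip shape, angle)`` to a :class:`GroundTruthLaw`, either
    as a flat mapping or nested ``{tip: {angle: law}}``.  Returns the prints
    and a manifest with one row per image.  Identical arguments yield a
    byte-identical dataset: every image draws from its own generator seeded
    from ``seed`` and the image index.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    law_map = _normalise_laws(laws)
    if tips is None:
        tips = [FLAT_TIP, ROUND_TIP]
    angles = list(angles)
    forces = list(forces)

    prints: list[ContactPrint] = []
    rows = []
    index = 0
    for tip in tips:
        for angle in angles:
            try:
                law = law_map[(tip.shape, float(angle))]
            except KeyError:
                raise KeyError(
                    f"no force-area law supplied for tip {tip.shape!r} "
                    f"at angle {angle} deg"
                ) from None
            for force in forces:
                for rep in range(1, replicates + 1):
                    image_seed = int(
                        np.random.SeedSequence([int(seed), index]).generate_state(1)[0]
                        % (2**31)
                    )
                    cond = ContactCondition(tip=tip, angle=angle, force=force, replicate=rep)
                    cp = render_footprint(
                        cond, law, pixel_scale=pixel_scale, seed=image_seed, **render_kwargs
                    )
                    fname = (
                        f"{tip.shape}_a{int(angle):02d}_f{force:g}gf_r{rep}.png"
                    )
                    prints.append(cp)
                    rows.append(
                        {
                            "file": fname,
                            "tip": tip.shape,
                            "angle_deg": angle,
                            "force_gf": force,
                            "replicate": rep,
                            "truth_area_mm2": cp.truth_area,
                            "pixel_scale_mm_per_px": pixel_scale,
                            "seed": image_seed,
                        }
                    )
                    index += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return prints, manifest


def to_uint8(image: np.ndarray) -> np.ndarray:
    """Quantise a [0, 1] float image to 8-bit grayscale."""
    return np.rint(np.clip(image, 0.0, 1.0) * 255).astype(np.uint8)


def write_dataset(
    prints: Sequence[ContactPrint], manifest: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write prints as 8-bit grayscale PNGs plus ``manifest.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cp, fname in zip(prints, manifest["file"]):
        Image.fromarray(to_uint8(cp.pixels), mode="L").save(out / fname)
    manifest.to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv"


def default_laws(noise_cv: float = 0.08) -> dict[str, dict[float, GroundTruthLaw]]:
    """The bundled per-(tip, angle) logarithmic laws of the reference study."""
    text = resources.files("contactprint.data").joinpath("table3_laws.json").read_text()
    raw = json.loads(text)
    return {
        tip: {
            float(angle): GroundTruthLaw(
                a=entry["a"], b=entry["b"], noise_cv=noise_cv
            )
            for angle, entry in per_angle.items()
        }
        for tip, per_angle in raw.items()
    }


def load_laws(path: str | Path, noise_cv: float = 0.08) -> dict:
    """Load laws from a JSON or YAML file shaped ``{tip: {angle: {a, b[, noise_cv]}}}``."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return {
        tip: {
            float(angle): GroundTruthLaw(
                a=float(entry["a"]),
                b=float(entry["b"]),
                noise_cv=float(entry.get("noise_cv", noise_cv)),
            )
            for angle, entry in per_angle.items()
        }
        for tip, per_angle in raw.items()
    }


def tip_by_name(name: str) -> TipSpec:
    """Return the bundled flat or round tip by name."""
    try:
        return _TIPS[name]
    except KeyError:
        raise ValueError(f"unknown tip {name!r}; expected 'flat' or 'round'") from None
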