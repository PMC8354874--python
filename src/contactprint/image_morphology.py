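"""Contact-print image analysis.

Implements the morphometric pipeline applied to each print photograph:
grayscale conversion, binarisation (Otsu by default), contact-area
measurement by calibrated pixel counting, principal-axis estimation from
second central moments, centroid alignment with rotation of the longest
axis to vertical, replicate averaging into an occupancy map with a majority
consensus mask, and classification of the footprint into the four observed
morphologies (rectangular, semi-ellipsoidal, circular, ellipsoidal).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "BinaryMask",
    "ShapeDescriptors",
    "MorphologyProfile",
    "ClassThresholds",
    "to_grayscale",
    "binarize",
    "measure_area",
    "principal_orientation",
    "compute_descriptors",
    "classify_morphology",
    "align_mask",
    "average_morphology",
    "read_image",
    "write_occupancy_png",
    "write_mask_png",
]

#: Below this eccentricity a footprint is treated as rotationally ambiguous
#: (no meaningful longest axis) and alignment skips the rotation step.
ECCENTRICITY_AMBIGUOUS = 0.1

#: Rotations smaller than this (degrees) are skipped: nearest-neighbour
#: resampling at sub-half-degree angles only degrades the boundary, and
#: skipping them makes alignment idempotent.
ROTATION_TOL_DEG = 0.5

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class BinaryMask:
    """A boolean footprint mask with its mm-per-pixel calibration."""

    pixels: np.ndarray
    pixel_scale: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("mask must be a non-empty 2-D grid")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")


@dataclass(frozen=True)
class ShapeDescriptors:
    """Scalar shape descriptors of one binary footprint.

    ``orientation_deg`` is the major-axis angle from the image vertical in
    (-90, 90], counterclockwise positive.  ``rectangularity`` is the ratio
    of footprint area to the area of its axis-aligned bounding box after
    rotation to the principal frame (1 for an upright rectangle, pi/4 for
    an ellipse).  ``axial_asymmetry`` is the normalised symmetric
    difference between the aligned footprint and its mirror image across a
    principal-axis line through the centroid, maximised over the two axes;
    it is 0 for doubly symmetric shapes and about 0.19 for a half-ellipse,
    which is what separates the semi-ellipsoidal prints from ellipses.
    """

    area_mm2: float
    centroid: tuple[float, float]  # (row, col), pixels
    orientation_deg: float
    eccentricity: float
    rectangularity: float
    axial_asymmetry: float


@dataclass(frozen=True)
class ClassThresholds:
    """Decision thresholds of the four-way morphology classifier."""

    circular_eccentricity: float = 0.3
    rectangularity_min: float = 0.9
    asymmetry_min: float = 0.15


@dataclass
class MorphologyProfile:
    """Averaged morphology of one condition's replicate prints."""

    occupancy: np.ndarray  # per-pixel fraction of aligned replicates covering it
    consensus_mask: BinaryMask  # occupancy >= 0.5, ties included
    n_replicates: int
    morphology_class: str | None


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a raster image to a single-channel [0, 1] float image.

    Single-channel input is returned unchanged (as float); 3-channel input
    is combined with the Rec. 601 luminance weights 0.299/0.587/0.114.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] == 1:
        return arr[..., 0]
    if arr.ndim == 3 and arr.shape[-1] == 3:
        return arr @ _LUMA
    raise ValueError(f"unsupported image shape {arr.shape}; expected 1 or 3 channels")


def binarize(
    gray: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    pixel_scale: float = 1.0,
) -> BinaryMask:
    """Threshold a grayscale image and keep the largest connected component.

    ``method="otsu"`` picks the threshold maximising the between-class
    variance over a 256-bin histogram; ``method="fixed"`` requires
    ``threshold``.  The print is a single region, so all smaller components
    (stray noise) are discarded.  A constant image yields an empty mask with
    a warning rather than an error.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("binarize expects a single-channel image")
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(gray) == 0:
            warnings.warn(
                "constant image: Otsu threshold undefined, returning empty mask",
                UserWarning,
                stacklevel=2,
            )
            return BinaryMask(np.zeros(gray.shape, dtype=bool), pixel_scale)
        thr = float(threshold_otsu(gray, nbins=256))
    else:
        raise ValueError(f"unknown binarisation method {method!r}")

    fg = gray > thr
    if not fg.any():
        return BinaryMask(fg, pixel_scale)
    labels, n = label(fg, return_num=True)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == counts.argmax()
    return BinaryMask(fg, pixel_scale)


def measure_area(mask: BinaryMask) -> float:
    """Contact area in mm^2: foreground pixel count times pixel_scale^2."""
    return float(mask.pixels.sum()) * mask.pixel_scale**2


def _region(mask: BinaryMask):
    return regionprops(mask.pixels.astype(np.uint8))[0]


def principal_orientation(mask: BinaryMask) -> tuple[float, float]:
    """Major-axis orientation (degrees from vertical, ccw) and eccentricity.

    Both come from the second central moments of the foreground.  Nearly
    isotropic footprints (eccentricity below 0.1) have no meaningful longest
    axis; their orientation is reported as 0.
    """
    if mask.pixels.sum() < 2:
        raise ValueError("orientation needs at least 2 foreground pixels")
    props = _region(mask)
    ecc = float(props.eccentricity)
    if ecc < ECCENTRICITY_AMBIGUOUS:
        return 0.0, ecc
    return float(np.degrees(props.orientation)), ecc


def _integer_shift(pixels: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift a boolean grid by whole pixels with zero fill."""
    out = np.zeros_like(pixels)
    rows, cols = pixels.shape
    src_r = slice(max(0, -dr), min(rows, rows - dr))
    src_c = slice(max(0, -dc), min(cols, cols - dc))
    dst_r = slice(max(0, dr), min(rows, rows + dr))
    dst_c = slice(max(0, dc), min(cols, cols + dc))
    out[dst_r, dst_c] = pixels[src_r, src_c]
    return out


def _reflection_asymmetry(pixels: np.ndarray, axis: int) -> float:
    """Normalised symmetric difference of a mask and its mirror about the
    centroid line perpendicular to ``axis`` (0 = rows, 1 = cols)."""
    n = pixels.sum()
    if n == 0:
        return 0.0
    c = ndimage.center_of_mass(pixels)[axis]
    flipped = np.flip(pixels, axis=axis)
    size = pixels.shape[axis]
    # centroid of the flipped mask sits at (size-1) - c; shift it back onto c
    shift = int(round(2 * c - (size - 1)))
    if axis == 0:
        flipped = _integer_shift(flipped, shift, 0)
    else:
        flipped = _integer_shift(flipped, 0, shift)
    return float((pixels ^ flipped).sum()) / (2.0 * n)


def compute_descriptors(mask: BinaryMask) -> ShapeDescriptors:
    """Compute all scalar descriptors of a footprint mask.

    Rectangularity and axial asymmetry are evaluated in the principal frame
    (the mask rotated so its longest axis is vertical) so they describe the
    shape itself, not its pose on the canvas.
    """
    if not mask.pixels.any():
        raise ValueError("descriptors are undefined for an empty mask")
    area = measure_area(mask)
    centroid = tuple(float(x) for x in ndimage.center_of_mass(mask.pixels))
    orientation, ecc = principal_orientation(mask)

    aligned = mask.pixels
    if ecc >= ECCENTRICITY_AMBIGUOUS and abs(orientation) > 0.5:
        aligned = ndimage.rotate(mask.pixels, -orientation, reshape=True, order=0)
    rows = np.flatnonzero(aligned.any(axis=1))
    cols = np.flatnonzero(aligned.any(axis=0))
    bbox_area = (rows[-1] - rows[0] + 1) * (cols[-1] - cols[0] + 1)
    rectangularity = float(aligned.sum()) / float(bbox_area)
    asymmetry = max(
        _reflection_asymmetry(aligned, 0), _reflection_asymmetry(aligned, 1)
    )
    return ShapeDescriptors(
        area_mm2=area,
        centroid=centroid,
        orientation_deg=orientation,
        eccentricity=ecc,
        rectangularity=min(rectangularity, 1.0),
        axial_asymmetry=asymmetry,
    )


def classify_morphology(
    descriptors: ShapeDescriptors, thresholds: ClassThresholds = ClassThresholds()
) -> str:
    """Assign one of the four footprint classes from shape descriptors.

    Nearly isotropic footprints are circular (T3); elongated ones are
    rectangular (T1) when they fill their bounding box, semi-ellipsoidal
    (T2) when markedly asymmetric along one principal axis, and ellipsoidal
    (T4) otherwise.  Exactly one class is always returned.
    """
    if descriptors.eccentricity < thresholds.circular_eccentricity:
        return "T3"
    if descriptors.rectangularity > thresholds.rectangularity_min:
        return "T1"
    if descriptors.axial_asymmetry > thresholds.asymmetry_min:
        return "T2"
    return "T4"


def _default_canvas(shape: tuple[int, int]) -> tuple[int, int]:
    return (math.ceil(shape[0] * 1.25), math.ceil(shape[1] * 1.25))


def align_mask(
    mask: BinaryMask, canvas: tuple[int, int] | None = None
) -> BinaryMask:
    """Centre a footprint on a canvas and rotate its longest axis vertical.

    The centroid is translated to the canvas centre (whole-pixel shift),
    then the mask is rotated by minus its principal orientation about the
    centre with nearest-neighbour resampling, which keeps the mask binary
    and conserves area to well within 2%.  Rotation is skipped for nearly
    isotropic footprints.  The 180-degree ambiguity of the axis is resolved
    by flipping the heavier half toward the canvas bottom, giving every
    replicate a canonical pose.
    """
    if canvas is None:
        canvas = _default_canvas(mask.pixels.shape)
    rows, cols = canvas
    out = np.zeros((rows, cols), dtype=bool)

    fg_r, fg_c = np.nonzero(mask.pixels)
    if fg_r.size == 0:
        return BinaryMask(out, mask.pixel_scale)
    cr, cc = ndimage.center_of_mass(mask.pixels)
    dr = int(round((rows - 1) / 2.0 - cr))
    dc = int(round((cols - 1) / 2.0 - cc))
    new_r = fg_r + dr
    new_c = fg_c + dc
    if (
        new_r.min() < 0
        or new_c.min() < 0
        or new_r.max() >= rows
        or new_c.max() >= cols
    ):
        raise ValueError("canvas too small for the centred footprint")
    out[new_r, new_c] = True

    centred = BinaryMask(out, mask.pixel_scale)
    if out.sum() < 2:
        return centred
    orientation, ecc = principal_orientation(centred)
    if ecc >= ECCENTRICITY_AMBIGUOUS and abs(orientation) > ROTATION_TOL_DEG:
        rotated = ndimage.rotate(out, -orientation, reshape=False, order=0)
        if rotated.any():
            out = rotated
            # rotation moves the centroid by a fraction of a pixel; re-centre
            cr, cc = ndimage.center_of_mass(out)
            dr = int(round((rows - 1) / 2.0 - cr))
            dc = int(round((cols - 1) / 2.0 - cc))
            if dr or dc:
                out = _integer_shift(out, dr, dc)

    # Canonical 180-degree pose: flip the heavier half toward the bottom,
    # but only on a material imbalance -- symmetric shapes would otherwise
    # flip on single-pixel noise and alignment would not be idempotent.
    mid = rows // 2
    top, bottom = out[:mid].sum(), out[mid:].sum()
    if top - bottom > 0.02 * (top + bottom):
        out = out[::-1, ::-1]
    return BinaryMask(out, mask.pixel_scale)


def average_morphology(
    masks: Sequence[BinaryMask],
    canvas: tuple[int, int] | None = None,
    thresholds: ClassThresholds = ClassThresholds(),
    classify: bool = True,
) -> MorphologyProfile:
    """Average replicate footprints into an occupancy map and consensus mask.

    Every replicate is aligned (centred, rotated to vertical, canonical
    pose) onto a shared canvas; the occupancy map is the per-pixel mean of
    the aligned masks and the consensus keeps pixels covered by at least
    half of them (ties included).  The consensus shape is classified into
    T1-T4 unless ``classify`` is disabled.
    """
    if len(masks) == 0:
        raise ValueError("average_morphology needs at least one mask")
    scale = masks[0].pixel_scale
    for m in masks[1:]:
        if not math.isclose(m.pixel_scale, scale, rel_tol=1e-9):
            raise ValueError("all masks must share one pixel scale")
    if canvas is None:
        rows = max(m.pixels.shape[0] for m in masks)
        cols = max(m.pixels.shape[1] for m in masks)
        canvas = _default_canvas((rows, cols))

    aligned = [align_mask(m, canvas) for m in masks]
    stack = np.stack([a.pixels for a in aligned])
    occupancy = stack.mean(axis=0)
    consensus = BinaryMask(occupancy >= 0.5 - 1e-12, scale)
    klass: str | None = None
    if classify and consensus.pixels.any():
        klass = classify_morphology(compute_descriptors(consensus), thresholds)
    return MorphologyProfile(
        occupancy=occupancy,
        consensus_mask=consensus,
        n_replicates=len(masks),
        morphology_class=klass,
    )


# -- raster IO ----------------------------------------------------------------


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale or RGB PNG/TIFF as a [0, 1] float array."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float64)
    if arr.dtype == bool:
        return arr.astype(np.float64)
    raise ValueError(f"unsupported image dtype {arr.dtype}")


def write_occupancy_png(occupancy: np.ndarray, path: str | Path) -> None:
    """Write an occupancy map as an 8-bit grayscale PNG (0-255 = 0-1)."""
    data = np.rint(np.clip(occupancy, 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def write_mask_png(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as a 1-bit PNG."""
    Image.fromarray(mask.pixels).convert("1").save(path)


def descriptors_frame(
    named_descriptors: Sequence[tuple[str, ShapeDescriptors, str]]
) -> pd.DataFrame:
    """Tabulate (file, descriptors, class) triples in the export layout."""
    rows = [
        {
            "file": name,
            "area_mm2": d.area_mm2,
            "centroid_row": d.centroid[0],
            "centroid_col": d.centroid[1],
            "orientation_deg": d.orientation_deg,
            "eccentricity": d.eccentricity,
            "rectangularity": d.rectangularity,
            "axial_asymmetry": d.axial_asymmetry,
            "class": klass,
        }
        for name, d, klass in named_descriptors
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "file",
            "area_mm2",
            "centroid_row",
            "centroid_col",
            "orientation_deg",
            "eccentricity",
            "rectangularity",
            "axial_asymmetry",
            "class",
        ],
    )
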