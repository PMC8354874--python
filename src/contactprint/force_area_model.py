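"""Quantitative force--area layer.

Per-condition aggregation of replicate contact areas, percentage contact
area relative to the tip electrode surface, gram-force to Newton
conversion, tip surface-area geometry, and the ordinary least-squares fit
of contact area on the natural logarithm of contact force,

    area = a * ln(force) + b,

with the coefficient of determination R^2 = 1 - SS_res/SS_tot.  The
package also bundles the reference study's printed per-condition summary
tables (flat-tip and round-tip catheters over the 5-angle x 8-force grid)
as CSV fixtures for refitting and round-trip checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import TipSpec

__all__ = [
    "GF_PER_NEWTON",
    "TIP_SURFACE_AREA_MM2",
    "AreaRecord",
    "ConditionSummary",
    "LogFit",
    "gf_to_newton",
    "tip_surface_area",
    "percentage_contact_area",
    "aggregate",
    "fit_log_model",
    "fit_by_condition",
    "predict_area",
    "load_printed_tables",
]

#: Conversion constant: 1 gf = 0.00981 N (g = 9.81 m/s^2).
GF_PER_NEWTON = 0.00981

#: Electrode surface areas used to normalise percentage contact area, mm^2.
TIP_SURFACE_AREA_MM2 = {"flat": 37.26, "round": 25.67}


@dataclass(frozen=True)
class AreaRecord:
    """One replicate measurement: condition plus measured contact area."""

    tip: str
    angle_deg: float
    force_gf: float
    replicate: int
    area_mm2: float

    @property
    def pca(self) -> float:
        return percentage_contact_area(self.area_mm2, TIP_SURFACE_AREA_MM2[self.tip])


@dataclass(frozen=True)
class ConditionSummary:
    """Replicate mean and spread for one (tip, angle, force) condition."""

    tip: str
    angle_deg: float
    force_gf: float
    mean_area: float
    sd_area: float
    mean_pca: float
    n: int
    single_replicate: bool = False


@dataclass(frozen=True)
class LogFit:
    """OLS fit of ``area = a*ln(force) + b`` with its R^2."""

    a: float
    b: float
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")
        if self.n_points < 3:
            raise ValueError("a log fit needs at least 3 points")


def gf_to_newton(force_gf: float) -> float:
    """Convert gram-force to Newtons (1 gf = 0.00981 N)."""
    if force_gf < 0:
        raise ValueError("force must be non-negative")
    return force_gf * GF_PER_NEWTON


def round_sig(value: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display convention for Newtons)."""
    if value == 0:
        return 0.0
    return round(value, -int(math.floor(math.log10(abs(value)))) + sig - 1)


def tip_surface_area(tip: TipSpec, use_preset: bool = True) -> float:
    """Electrode surface area in mm^2.

    A flat tip is a cylinder plus a flat end cap, ``pi*d*L + pi*d^2/4``; a
    round tip is a cylinder of length ``L - d/2`` plus a hemispherical cap,
    ``pi*d*(L - d/2) + pi*d^2/2``.  A preset ``surface_area`` on the tip
    (the study's normalisation constants) takes precedence unless
    ``use_preset`` is disabled.
    """
    if use_preset and tip.surface_area is not None:
        return tip.surface_area
    d, length = tip.diameter, tip.electrode_length
    if d <= 0 or length <= 0:
        raise ValueError("tip dimensions must be positive")
    if tip.shape == "flat":
        return math.pi * d * length + math.pi * d**2 / 4.0
    return math.pi * d * (length - d / 2.0) + math.pi * d**2 / 2.0


def percentage_contact_area(area_mm2: float, tip_area_mm2: float) -> float:
    """Contact area as a percentage of the tip electrode surface area."""
    if tip_area_mm2 <= 0:
        raise ValueError("tip surface area must be positive")
    if area_mm2 < 0:
        raise ValueError("contact area must be non-negative")
    return 100.0 * area_mm2 / tip_area_mm2


def aggregate(records: pd.DataFrame, tip_areas: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-(tip, angle, force) mean, sample SD and mean percentage area.

    ``records`` is a long table with columns
    ``tip, angle_deg, force_gf, replicate, area_mm2``.  The SD uses the
    sample (n-1) convention; single-replicate conditions report SD 0 and
    are flagged in ``single_replicate``.  Mean PCA is computed from the
    mean area.
    """
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    tip_areas = tip_areas or TIP_SURFACE_AREA_MM2
    rows = []
    for (tip, angle, force), grp in records.groupby(
        ["tip", "angle_deg", "force_gf"], sort=True
    ):
        areas = grp["area_mm2"].to_numpy(dtype=float)
        n = len(areas)
        mean = float(areas.mean())
        sd = float(areas.std(ddof=1)) if n > 1 else 0.0
        rows.append(
            {
                "tip": tip,
                "angle_deg": angle,
                "force_gf": force,
                "mean_area_mm2": mean,
                "sd_mm2": sd,
                "mean_pca_pct": percentage_contact_area(mean, tip_areas[tip]),
                "n": n,
                "single_replicate": n == 1,
            }
        )
    return pd.DataFrame(rows)


def fit_log_model(forces_gf, areas_mm2) -> LogFit:
    """OLS fit of contact area on the natural log of contact force.

    Requires at least 3 points with distinct, strictly positive forces.
    R^2 is 1 - SS_res/SS_tot about the mean (and exactly 1 for collinear
    data, where SS_tot may be matched by SS_res = 0).
    """
    forces = np.asarray(forces_gf, dtype=float)
    areas = np.asarray(areas_mm2, dtype=float)
    if forces.shape != areas.shape or forces.ndim != 1:
        raise ValueError("forces and areas must be 1-D and equally long")
    if forces.size < 3:
        raise ValueError("a log fit needs at least 3 points")
    if (forces <= 0).any():
        raise ValueError("all forces must be positive")
    if np.unique(forces).size < 2:
        raise ValueError("forces must not all be identical")
    x = np.log(forces)
    res = stats.linregress(x, areas)
    resid = areas - (res.slope * x + res.intercept)
    ss_tot = float(((areas - areas.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    return LogFit(a=float(res.slope), b=float(res.intercept), r2=r2, n_points=forces.size)


def fit_by_condition(
    records: pd.DataFrame, on: str = "means", min_forces: int = 3
) -> pd.DataFrame:
    """Fit one log law per (tip, angle).

    ``on="means"`` fits the per-force mean areas (8 points on the full
    grid, the convention behind the study's printed coefficient table);
    ``on="replicates"`` fits every replicate point instead.  Groups with
    fewer than ``min_forces`` distinct forces get no fit and are flagged.
    """
    if on not in ("means", "replicates"):
        raise ValueError("on must be 'means' or 'replicates'")
    if "mean_area_mm2" in records.columns and "area_mm2" not in records.columns:
        records = records.rename(columns={"mean_area_mm2": "area_mm2"})
    rows = []
    for (tip, angle), grp in records.groupby(["tip", "angle_deg"], sort=True):
        if on == "means":
            pts = grp.groupby("force_gf")["area_mm2"].mean().reset_index()
            forces = pts["force_gf"].to_numpy(dtype=float)
            areas = pts["area_mm2"].to_numpy(dtype=float)
        else:
            forces = grp["force_gf"].to_numpy(dtype=float)
            areas = grp["area_mm2"].to_numpy(dtype=float)
        if np.unique(forces).size < min_forces:
            rows.append(
                {
                    "tip": tip,
                    "angle_deg": angle,
                    "a": np.nan,
                    "b": np.nan,
                    "r2": np.nan,
                    "n_points": len(forces),
                    "fitted": False,
                }
            )
            continue
        fit = fit_log_model(forces, areas)
        rows.append(
            {
                "tip": tip,
                "angle_deg": angle,
                "a": fit.a,
                "b": fit.b,
                "r2": fit.r2,
                "n_points": fit.n_points,
                "fitted": True,
            }
        )
    return pd.DataFrame(rows)


def predict_area(fit: LogFit, force_gf: float) -> float:
    """Predicted contact area ``a*ln(force) + b`` in mm^2."""
    if force_gf <= 0:
        raise ValueError("force must be positive")
    return fit.a * math.log(force_gf) + fit.b


def load_printed_tables() -> pd.DataFrame:
    """The bundled reference summary tables (both tips), long format.

    Columns: ``tip, angle_deg, force_gf, mean_area_mm2, sd_mm2,
    pca_printed_pct`` -- the published per-condition mean contact area,
    its SD over 6 replicates, and the integer percentage contact area.
    """
    frames = []
    for name in ("table1_flat.csv", "table2_round.csv"):
        with resources.files("contactprint.data").joinpath(name).open("rb") as fh:
            frames.append(pd.read_csv(fh))
    return pd.concat(frames, ignore_index=True)
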