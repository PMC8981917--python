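"""Collagen quantification from dye-binding absorbance via a standard curve.

The Sircol-style assay reads absorbance at 525 nm against a standard series
of known pepsin-acid-soluble collagen masses.  An ordinary least-squares
line of absorbance on mass inverts unknown absorbances to microgram
equivalents; per-cell content divides by the seeded cell number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "CollagenResult",
    "AssayError",
    "fit_standard_curve",
    "quantify_collagen",
    "per_cell",
    "quantify_samples",
]


class AssayError(ValueError):
    """The standard series cannot yield a usable curve."""


@dataclass(frozen=True)
class StandardCurve:
    """Linear absorbance-vs-mass calibration.

    slope in absorbance units per ug, intercept in absorbance units;
    ``valid_range`` is the (min, max) standard mass in ug — inversions
    outside it are flagged as extrapolations.
    """

    slope: float
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]

    def predict(self, mass_ug: float) -> float:
        return self.intercept + self.slope * mass_ug


@dataclass(frozen=True)
class CollagenResult:
    mass_ug: float
    extrapolated: bool
    clamped: bool  # negative inversion clamped to zero


def fit_standard_curve(concentrations, absorbances) -> StandardCurve:
    """OLS line of absorbance on standard mass (ug).

    Requires >= 3 standards with strictly increasing concentrations and a
    positive slope (absorbance must rise with collagen mass).
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size < 3:
        raise AssayError(f"need >= 3 standards, got {c.size}")
    if np.any(np.diff(c) <= 0):
        raise AssayError("standard concentrations must be strictly increasing")
    fit = stats.linregress(c, a)
    if fit.slope <= 0:
        raise AssayError(
            f"standard-curve slope {fit.slope:.4g} is not positive; assay failure"
        )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        valid_range=(float(c.min()), float(c.max())),
    )


def quantify_collagen(
    absorbance: float, curve: StandardCurve, dilution_factor: float = 1.0
) -> CollagenResult:
    """Invert the standard curve: ((A - intercept)/slope) * dilution, in ug.

    Negative inversions (absorbance below the blank) clamp to 0 with a flag;
    masses outside the standards' range carry an extrapolation flag.
    """
    mass = (absorbance - curve.intercept) / curve.slope * dilution_factor
    clamped = mass < 0
    if clamped:
        mass = 0.0
    lo, hi = curve.valid_range
    raw = mass / dilution_factor if dilution_factor != 0 else mass
    extrapolated = not (lo <= raw <= hi)
    return CollagenResult(mass_ug=float(mass), extrapolated=extrapolated, clamped=clamped)


def per_cell(mass_ug: float, seeded_cells: int) -> float:
    """Collagen per cell in pg/cell: ug * 1e6 / cells."""
    if seeded_cells <= 0:
        raise ValueError(f"seeded_cells must be positive, got {seeded_cells}")
    if mass_ug < 0:
        raise ValueError("mass must be non-negative")
    return mass_ug * 1.0e6 / seeded_cells


def quantify_samples(
    samples: pd.DataFrame, curve: StandardCurve, seeded_cells: int | None = None
) -> pd.DataFrame:
    """Quantify a table of samples with columns specimen_id, absorbance[, dilution].

    Returns one row per sample with collagen_ug, flags, and collagen_pg_per_cell
    when ``seeded_cells`` is given.
    """
    rows = []
    for _, rec in samples.iterrows():
        dilution = float(rec.get("dilution", 1.0)) if "dilution" in samples else 1.0
        res = quantify_collagen(float(rec["absorbance"]), curve, dilution)
        row = {
            "specimen_id": rec["specimen_id"],
            "collagen_ug": res.mass_ug,
            "extrapolated": res.extrapolated,
            "clamped": res.clamped,
        }
        if seeded_cells is not None:
            row["collagen_pg_per_cell"] = per_cell(res.mass_ug, seeded_cells)
        rows.append(row)
    return pd.DataFrame(rows)
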