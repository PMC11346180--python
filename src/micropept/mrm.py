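"""Absolute quantitation from MRM transition peak areas.

Synthetic peptide standards measured at a ladder of known
concentrations define, per peptide, a detection threshold (LOD: the
lowest level with signal in every replicate), a quantification
threshold (LOQ: the lowest level at or above the LOD whose replicate
coefficient of variation stays within ``cv_limit``, default 20%), and
an ordinary-least-squares calibration curve of mean area on
concentration fitted in the region above the LOQ.  Sample areas are
converted to mol/L through the curve and flagged when they fall below
the thresholds; molar concentrations convert to the mass scale via
ug/ml = mol/L x MW(g/mol) x 1000.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "NotQuantifiable",
    "determine_lod_loq",
    "fit_calibration",
    "calibrate",
    "quantify",
    "convert_units",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """Replicate areas measured for one peptide at one known level."""

    peptide_id: str
    concentration: float  # mol/L
    areas: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("calibration concentration must be > 0")
        if not self.areas:
            raise ValueError("at least one replicate area required")


@dataclass(frozen=True)
class CalibrationCurve:
    peptide_id: str
    slope: float
    intercept: float
    r_squared: float
    lod: float  # mol/L
    loq: float  # mol/L


class NotQuantifiable(ValueError):
    """Raised when a peptide is never detected or has no usable
    calibration region."""


def _detected(point: CalibrationPoint, min_area: float) -> bool:
    return all(area > min_area for area in point.areas)


def determine_lod_loq(
    points: Sequence[CalibrationPoint],
    cv_limit: float = 0.20,
    min_area: float = 0.0,
) -> tuple[float, float]:
    """LOD = lowest level detected (area > ``min_area``) in all
    replicates; LOQ = lowest level >= LOD with replicate CV <= cv_limit."""
    ordered = sorted(points, key=lambda p: p.concentration)
    lod = None
    for p in ordered:
        if _detected(p, min_area):
            lod = p.concentration
            break
    if lod is None:
        raise NotQuantifiable(
            f"peptide {ordered[0].peptide_id!r} never detected at any level"
        )
    for p in ordered:
        if p.concentration < lod or not _detected(p, min_area):
            continue
        mean = float(np.mean(p.areas))
        cv = float(np.std(p.areas, ddof=1)) / mean if len(p.areas) > 1 else 0.0
        if cv <= cv_limit:
            return lod, p.concentration
    raise NotQuantifiable(
        f"peptide {ordered[0].peptide_id!r} detected but no level meets the "
        f"CV <= {cv_limit:.0%} quantification rule"
    )


def fit_calibration(
    points: Sequence[CalibrationPoint], lod: float, loq: float
) -> CalibrationCurve:
    """OLS of mean area on concentration over the levels at or above
    the LOQ; needs >= 3 such levels."""
    usable = sorted(
        (p for p in points if p.concentration >= loq), key=lambda p: p.concentration
    )
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 calibration levels above the LOQ, got {len(usable)}"
        )
    x = np.array([p.concentration for p in usable])
    y = np.array([np.mean(p.areas) for p in usable])
    res = stats.linregress(x, y)
    return CalibrationCurve(
        peptide_id=usable[0].peptide_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        lod=lod,
        loq=loq,
    )


def calibrate(
    points: Sequence[CalibrationPoint],
    cv_limit: float = 0.20,
    min_area: float = 0.0,
) -> CalibrationCurve:
    """Convenience: thresholds plus curve in one call."""
    lod, loq = determine_lod_loq(points, cv_limit=cv_limit, min_area=min_area)
    return fit_calibration(points, lod, loq)


def quantify(area: float, curve: CalibrationCurve) -> tuple[float, str]:
    """Concentration (mol/L) for a measured area, flagged "<LOD" below
    the detection threshold and "<LOQ" between the thresholds."""
    if curve.slope <= 0:
        raise ValueError("calibration slope must be > 0")
    concentration = (area - curve.intercept) / curve.slope
    if concentration < curve.lod:
        flag = "<LOD"
    elif concentration < curve.loq:
        flag = "<LOQ"
    else:
        flag = ""
    return concentration, flag


def convert_units(concentration: float, molecular_weight: float) -> float:
    """mol/L -> ug/ml: mol/L x g/mol gives g/L = mg/ml, x 1000 -> ug/ml."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be > 0")
    return concentration * molecular_weight * 1000.0
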