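"""Targeted MRM quantitation: linear external calibration, concentration
read-back with linear-range flags, identity confirmation criteria, and
conversion to tissue concentrations.

Identity of an analyte measured by two MRM transitions is confirmed when
(i) both transitions co-occur in time, (ii) the confirmation/quantification
abundance ratio lies within +/-25% of that of a comparable standard, and
(iii) both transitions have signal-to-noise ratios strictly above 9.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import stats

from .errors import ValidationError

#: default RT co-occurrence tolerance in minutes (tabulated RT SDs <= 0.02)
RT_TOLERANCE_MIN = 0.05
#: homogenate density used for extract -> tissue conversion, mg tissue / mL
TISSUE_DENSITY_MG_PER_ML = 33.3


@dataclass
class CalibrationCurve:
    """Unweighted OLS calibration line of peak area on concentration (nM)."""

    analyte: str
    concentrations: list[float]
    areas: list[float]
    slope: float
    intercept: float
    r_squared: float
    linear_range: tuple  # (min, max) of the standard series, nM

    def predict_area(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def to_dict(self) -> dict:
        d = asdict(self)
        d["linear_range"] = list(self.linear_range)
        return d


def fit_calibration(analyte: str, points) -> CalibrationCurve:
    """Fit a calibration line from ``(concentration_nM, area)`` pairs.

    Requires at least three points over more than one distinct
    concentration. ``r_squared`` is the squared Pearson correlation (0 for
    a flat response).
    """
    pts = [(float(c), float(a)) for c, a in points]
    if len(pts) < 3:
        raise ValidationError("calibration needs at least 3 points")
    conc = np.array([p[0] for p in pts])
    area = np.array([p[1] for p in pts])
    if np.unique(conc).size < 2:
        raise ValidationError("calibration needs more than one concentration")
    if np.std(area) == 0:
        # flat response: OLS slope 0, no explained variance
        slope, intercept, r2 = 0.0, float(area[0]), 0.0
    else:
        res = stats.linregress(conc, area)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    return CalibrationCurve(
        analyte=analyte,
        concentrations=conc.tolist(),
        areas=area.tolist(),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        linear_range=(float(conc.min()), float(conc.max())),
    )


def quantify(curve: CalibrationCurve, area: float, dilution: float = 1.0):
    """Invert the calibration line: ``(concentration_nM, in_range)``.

    ``in_range`` is True when the computed concentration falls within the
    standard-series range (boundaries inclusive).
    """
    if curve.slope == 0:
        raise ValidationError("zero calibration slope")
    conc = dilution * (area - curve.intercept) / curve.slope
    lo, hi = curve.linear_range
    return float(conc), bool(lo <= conc <= hi)


@dataclass
class MRMMeasurement:
    """One analyte's MRM observation in a sample."""

    analyte: str
    quant_area: float
    quant_rt: float
    quant_snr: float
    confirm_area: Optional[float] = None
    confirm_rt: Optional[float] = None
    confirm_snr: Optional[float] = None
    #: confirm/quant relative abundance in a comparable standard
    standard_ratio: Optional[float] = None

    def __post_init__(self):
        for v in (self.quant_area, self.confirm_area):
            if v is not None and v < 0:
                raise ValidationError("negative peak area")


@dataclass
class ConfirmationResult:
    analyte: str
    co_occurrence: bool
    ratio_within_25pct: bool
    snr_above_9: bool
    confirmed: bool
    reason: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


def confirm_identity(
    m: MRMMeasurement, rt_tolerance: float = RT_TOLERANCE_MIN
) -> ConfirmationResult:
    """Apply the three confirmation criteria to an MRM measurement.

    Criterion (ii) passes when the observed confirm/quant ratio lies within
    [0.75, 1.25] times the standard's ratio; criterion (iii) is strict
    (SNR > 9 for both transitions; exactly 9 fails). A missing standard
    ratio leaves (ii) indeterminate and the identity unconfirmed, with the
    reason recorded.
    """
    if m.confirm_area is None or m.confirm_rt is None or m.confirm_snr is None:
        raise ValidationError(
            f"{m.analyte}: confirmation transition missing; RT-only analytes "
            "(e.g. choline) are not subject to MRM confirmation"
        )
    co = abs(m.quant_rt - m.confirm_rt) <= rt_tolerance
    snr_ok = (m.quant_snr > 9.0) and (m.confirm_snr > 9.0)
    reason = None
    if m.standard_ratio is None:
        ratio_ok = False
        reason = "standard ratio unavailable: criterion ii indeterminate"
    elif m.quant_area == 0:
        ratio_ok = False
        reason = "zero quantification area"
    else:
        observed = m.confirm_area / m.quant_area
        ratio_ok = (
            0.75 * m.standard_ratio <= observed <= 1.25 * m.standard_ratio
        )
    return ConfirmationResult(
        analyte=m.analyte,
        co_occurrence=bool(co),
        ratio_within_25pct=bool(ratio_ok),
        snr_above_9=bool(snr_ok),
        confirmed=bool(co and ratio_ok and snr_ok),
        reason=reason,
    )


def tissue_concentration(
    conc_extract_nmol_per_ml: float,
    tissue_density: float = TISSUE_DENSITY_MG_PER_ML,
) -> float:
    """Convert an extract concentration (nmol/mL) to nmol per mg of tissue.

    With homogenates prepared at ``tissue_density`` mg of frozen tissue per
    mL of buffer, nmol/mg = (nmol/mL) / density; a 33.3 nmol/mL extract at
    the default density is 1.0 nmol/mg.
    """
    if tissue_density <= 0:
        raise ValidationError("tissue density must be positive")
    if conc_extract_nmol_per_ml < 0:
        raise ValidationError("concentration must be non-negative")
    return conc_extract_nmol_per_ml / tissue_density
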