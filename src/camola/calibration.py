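"""External-standard linear calibration and inverse prediction.

Amino acids are quantified against a line fitted to standards of known
concentration: response = slope·conc + intercept. Unknowns are read back by
inverse prediction, and concentrations in the extract are converted to content
per gram of tea through the extraction ratio (mg tea powder per mL solvent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError


@dataclass
class CalibrationCurve:
    """Fitted external-standard line for one analyte.

    ``conc_range`` is the (min, max) concentration spanned by the standards;
    predictions outside it are flagged as extrapolation.
    """

    analyte: str
    slope: float
    intercept: float
    r2: float = 1.0
    conc_range: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self):
        if self.slope == 0:
            raise ValidationError(f"{self.analyte}: zero slope is not invertible")
        if self.r2 > 1 + 1e-12:
            raise ValidationError(f"{self.analyte}: r2={self.r2} > 1")

    def response(self, conc) -> np.ndarray | float:
        """Forward-evaluate the line at the given concentration(s)."""
        out = self.slope * np.asarray(conc, dtype=float) + self.intercept
        return float(out) if out.ndim == 0 else out


def fit_calibration(standards: Sequence[tuple[float, float]], analyte: str = "") -> CalibrationCurve:
    """OLS of response on concentration over ≥ 3 standards."""
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError(f"{analyte}: need at least 3 (conc, response) standards")
    conc, resp = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise DegenerateInputError(f"{analyte}: all standard concentrations equal; design is singular")
    res = stats.linregress(conc, resp)
    yhat = res.intercept + res.slope * conc
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((resp - yhat) ** 2)) / ss_tot
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        conc_range=(float(conc.min()), float(conc.max())),
    )


def inverse_predict(curve: CalibrationCurve, response: float) -> float:
    """Concentration (response − intercept)/slope; warns on extrapolation or negative result."""
    conc = (response - curve.intercept) / curve.slope
    lo, hi = curve.conc_range
    if not (lo <= conc <= hi):
        warnings.warn(
            f"{curve.analyte}: predicted concentration {conc:.4g} outside the standard "
            f"range [{lo:g}, {hi:g}] (extrapolation)",
            stacklevel=2,
        )
    if conc < 0:
        warnings.warn(
            f"{curve.analyte}: negative predicted concentration {conc:.4g}", stacklevel=2
        )
    return float(conc)


def sample_concentration(conc_in_extract: float, extract_ratio: float) -> float:
    """Convert extract concentration (mg/mL) to content per tea mass (mg/g).

    ``extract_ratio`` is mg tea powder per mL of extraction solvent (e.g. 0.4 g
    in 20 mL → 20 mg/mL); mg/g = conc / ratio × 1000.
    """
    if extract_ratio <= 0:
        raise ValidationError(f"extract_ratio must be > 0, got {extract_ratio}")
    return conc_in_extract / extract_ratio * 1000.0
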