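"""Rate-law fitting and model selection for roasting time courses.

Aroma-compound formation during isothermal roasting is described by the rate
law dA/dt = K·Aⁿ. Its two integrated special cases, plus the empirical
exponential form with a baseline offset that the accelerating time courses
follow, are fitted here:

* zero order      A(t) = A0 + K·t                 (OLS of A on t)
* first order     ln A(t) = ln A0 + K·t           (OLS of ln A on t)
* exp. offset     A(t) = a·e^{b·t} + c            (nonlinear least squares)

Model selection is by coefficient of determination R² = 1 − SSres/SStot (ties
go to the form with fewer parameters). Fits are per compound × temperature;
time is hours, temperature °C, and concentration units are carried verbatim.

Negative fitted intercepts (and hence negative predicted concentrations at
early times) are legitimate extrapolation artifacts of lag-phase compounds and
are kept, not clipped; :func:`below_detection_mask` offers the alternative of
dropping leading below-detection points before fitting.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateInputError, FitFailureError, ValidationError
from .records import TimeCourse

logger = logging.getLogger(__name__)


class KineticModelForm(str, enum.Enum):
    ZERO_ORDER = "zero_order"
    FIRST_ORDER = "first_order"
    EXP_OFFSET = "exp_offset"

    @property
    def arity(self) -> int:
        return 3 if self is KineticModelForm.EXP_OFFSET else 2


@dataclass
class KineticFit:
    """One fitted rate model for a compound at one temperature."""

    form: KineticModelForm
    params: dict[str, float]
    r2: float
    n_points: int
    compound: str = ""
    temperature: Optional[float] = None
    notes: str = ""

    def __post_init__(self):
        if self.r2 > 1 + 1e-12:
            raise ValidationError(f"r2={self.r2} > 1")
        if self.n_points < self.form.arity + 1:
            raise ValidationError(
                f"{self.form.value}: {self.n_points} points cannot constrain "
                f"{self.form.arity} parameters"
            )

    def equation_string(self, places: int = 5) -> str:
        """Report-style equation, e.g. "y = 2.83929x - 2.86429" or "y = 0.41551e^0.01314x + 0.31244"."""
        def signed(v: float) -> str:
            return f"- {abs(v):.{places}f}" if v < 0 else f"+ {v:.{places}f}"

        if self.form is KineticModelForm.ZERO_ORDER:
            return f"y = {self.params['K']:.{places}f}x {signed(self.params['A0'])}"
        if self.form is KineticModelForm.FIRST_ORDER:
            return f"ln y = {self.params['K']:.{places}f}x {signed(np.log(self.params['A0']))}"
        return (
            f"y = {self.params['a']:.{places}f}e^{self.params['b']:.{places}f}x "
            f"{signed(self.params['c'])}"
        )


def _r_squared(y: np.ndarray, yhat: np.ndarray, context: str = "") -> tuple[float, str]:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        msg = f"{context}: constant signal (SStot = 0); R² reported as 1 by convention"
        logger.warning(msg)
        return 1.0, msg
    return 1.0 - ss_res / ss_tot, ""


def fit_zero_order(tc: TimeCourse) -> KineticFit:
    """OLS of A on t: A = A0 + K·t."""
    t, a = tc.times, tc.concentrations
    if np.ptp(t) == 0:
        raise DegenerateInputError(f"{tc.compound}: all time points equal; design is singular")
    res = stats.linregress(t, a)
    yhat = res.intercept + res.slope * t
    r2, note = _r_squared(a, yhat, tc.compound)
    return KineticFit(
        KineticModelForm.ZERO_ORDER,
        {"K": float(res.slope), "A0": float(res.intercept)},
        r2,
        len(tc),
        compound=tc.compound,
        temperature=tc.temperature,
        notes=note,
    )


def fit_first_order(tc: TimeCourse) -> KineticFit:
    """OLS of ln A on t: ln A = ln A0 + K·t; R² on the log scale."""
    t, a = tc.times, tc.concentrations
    bad = np.where(a <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"{tc.compound}: non-positive concentration at t={t[bad[0]]:g} h; "
            "first-order fit needs A > 0 everywhere"
        )
    res = stats.linregress(t, np.log(a))
    yhat = res.intercept + res.slope * t
    r2, note = _r_squared(np.log(a), yhat, tc.compound)
    return KineticFit(
        KineticModelForm.FIRST_ORDER,
        {"K": float(res.slope), "A0": float(np.exp(res.intercept))},
        r2,
        len(tc),
        compound=tc.compound,
        temperature=tc.temperature,
        notes=note,
    )


def _exp_model(t, a, b, c):
    return a * np.exp(b * t) + c


def fit_exp_offset(
    tc: TimeCourse,
    init: Optional[Sequence[float]] = None,
    seed: int = 0,
    n_restarts: int = 5,
) -> KineticFit:
    """Nonlinear least squares for A = a·e^{b·t} + c.

    Default initialization: c₀ = min(A) − 0.1·range(A), then a log-linear fit
    of A − c₀ supplies a₀ and b₀. On top of the default start, ``n_restarts``
    jittered starts (c₀ shifted uniformly within ±range(A)/2, seeded) are
    tried; the converged solution with the lowest residual sum of squares
    wins. Convergence tolerance is 1e−10 on the parameters; R² is computed on
    the natural concentration scale.
    """
    t, a_obs = tc.times, tc.concentrations
    if len(tc) < 4:
        raise ValidationError(f"{tc.compound}: exp-offset fit needs at least 4 points")
    rng = np.random.default_rng(seed)
    span = float(np.ptp(a_obs)) or 1.0
    c_base = float(np.min(a_obs)) - 0.1 * span

    starts: list[tuple[float, float, float]] = []
    if init is not None:
        starts.append(tuple(float(v) for v in init))
    for i in range(1 + n_restarts):
        c0 = c_base if i == 0 else c_base + rng.uniform(-0.5, 0.5) * span
        y = a_obs - c0
        if np.any(y <= 0):
            continue
        b0, ln_a0 = np.polyfit(t, np.log(y), 1)
        starts.append((float(np.exp(ln_a0)), float(b0), c0))

    best = None
    last_residuals = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _exp_model, t, a_obs, p0=p0, maxfev=20000, xtol=1e-10, ftol=1e-12
                )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        resid = a_obs - _exp_model(t, *popt)
        last_residuals = resid
        sse = float(np.sum(resid**2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitFailureError(
            f"{tc.compound}: exp-offset fit failed to converge after {n_restarts} restarts",
            last_residuals=last_residuals,
        )
    popt = best[1]
    yhat = _exp_model(t, *popt)
    r2, note = _r_squared(a_obs, yhat, tc.compound)
    return KineticFit(
        KineticModelForm.EXP_OFFSET,
        {"a": float(popt[0]), "b": float(popt[1]), "c": float(popt[2])},
        r2,
        len(tc),
        compound=tc.compound,
        temperature=tc.temperature,
        notes=note,
    )


def select_model(fits: Sequence[KineticFit]) -> KineticFit:
    """Fit with maximal R²; ties (within 1e−9) go to the form with fewer parameters."""
    fits = list(fits)
    if not fits:
        raise FitFailureError("no successful fits to select from")
    best_r2 = max(f.r2 for f in fits)
    contenders = [f for f in fits if f.r2 >= best_r2 - 1e-9]
    return min(contenders, key=lambda f: f.form.arity)


def predict(fit: KineticFit, t) -> np.ndarray | float:
    """Evaluate the fitted model at time(s) t (hours)."""
    t = np.asarray(t, dtype=float)
    p = fit.params
    if fit.form is KineticModelForm.ZERO_ORDER:
        out = p["A0"] + p["K"] * t
    elif fit.form is KineticModelForm.FIRST_ORDER:
        out = p["A0"] * np.exp(p["K"] * t)
    else:
        out = _exp_model(t, p["a"], p["b"], p["c"])
    return float(out) if out.ndim == 0 else out


def below_detection_mask(tc: TimeCourse, limit: float) -> TimeCourse:
    """Drop leading points with A < limit (lag phase below the detection limit)."""
    if limit < 0:
        raise ValidationError("detection limit must be >= 0")
    keep = 0
    while keep < len(tc) and tc.concentrations[keep] < limit:
        keep += 1
    if len(tc) - keep < 3:
        raise DegenerateInputError(
            f"{tc.compound}: fewer than 3 points remain above the detection limit {limit}"
        )
    if keep:
        logger.info("%s: dropped %d leading point(s) below detection limit %g", tc.compound, keep, limit)
    return TimeCourse(
        tc.compound, tc.temperature, tc.times[keep:], tc.concentrations[keep:], units=tc.units
    )


def fit_all_forms(tc: TimeCourse, seed: int = 0) -> list[KineticFit]:
    """Fit every applicable model form, skipping forms whose preconditions fail."""
    fits = [fit_zero_order(tc)]
    try:
        fits.append(fit_first_order(tc))
    except ValidationError:
        pass
    try:
        fits.append(fit_exp_offset(tc, seed=seed))
    except (ValidationError, FitFailureError):
        pass
    return fits
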