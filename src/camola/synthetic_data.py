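"""Synthetic-data generation for every pipeline input.

The study's raw GC×GC–MS data are not deposited, so each consuming stage is
exercised on data generated from the published ground truth instead:

* :func:`gen_envelope` forward-simulates the instrument distortions that
  :mod:`camola.isotopologue_correction` inverts — natural heavy-isotope
  convolution, molecular-ion hydrogen loss, and multiplicative (lognormal)
  peak-area noise;
* :func:`gen_timecourse` evaluates a kinetic model and adds additive Gaussian
  concentration noise;
* :func:`gen_calibration` evaluates a standard line with Gaussian response noise;
* :func:`build_reference_fixtures` writes the transcribed study tables (labeling
  distributions, kinetic models, calibration curves) as CSV fixtures in the
  schemas :mod:`camola.tables_io` reads.

Noise models: peak areas are positive and instrument variability scales with
signal, so areas get lognormal noise parameterized by a coefficient of
variation (default 5%); concentrations and detector responses get additive
Gaussian noise. Identical seeds produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import presets
from .errors import ValidationError
from .isotopologue_correction import CorrectionParams, _composition
from .kinetics import KineticFit, KineticModelForm, predict
from .records import CompoundRecord, CorrectedDistribution, IsotopologueEnvelope, TimeCourse
from .calibration import CalibrationCurve


@dataclass
class ScenarioPreset:
    """A named generating scenario (ground truth + recipe metadata)."""

    name: str
    description: str
    payload: dict = field(default_factory=dict)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_envelope(
    true_dist: CorrectedDistribution,
    formula,
    params: CorrectionParams,
    noise_cv: float = 0.0,
    total_area: float = 1e6,
    seed=None,
) -> IsotopologueEnvelope:
    """Forward-simulate a raw envelope from a true label-count distribution.

    Order of distortions mirrors (in reverse) the correction pipeline:
    distribute ``total_area`` by ``true_dist``; add first-order natural-abundance
    leakage (+1 from ¹³C/³³S, +2 from ³⁴S); split each channel 1/(1+r) : r/(1+r)
    between itself and the channel below (hydrogen loss); multiply by lognormal
    noise with the given CV.
    """
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    n_c, n_s = _composition(formula)
    a1 = n_c * params.c13 + n_s * params.s33
    a2 = n_s * params.s34

    lo = min(true_dist.fractions)
    hi = max(true_dist.fractions) + 2  # room for +1/+2 leakage
    offsets = np.arange(lo, hi + 1)
    species = np.array([true_dist.fractions.get(int(k), 0.0) for k in offsets])
    species = species / species.sum() * total_area

    observed = species.copy()
    for i in range(len(offsets)):
        if species[i] == 0:
            continue
        if i + 1 < len(offsets):
            observed[i + 1] += a1 * species[i]
        if i + 2 < len(offsets):
            observed[i + 2] += a2 * species[i]

    if params.r > 0:
        shifted = np.zeros(len(offsets) + 1)  # index 0 is channel lo-1
        shifted[1:] += observed / (1 + params.r)
        shifted[:-1] += observed * params.r / (1 + params.r)
        offsets = np.arange(lo - 1, hi + 1)
        observed = shifted

    if noise_cv > 0:
        rng = _rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        observed = observed * rng.lognormal(-sigma**2 / 2, sigma, size=observed.shape)

    areas = {int(k): float(v) for k, v in zip(offsets, observed) if k >= -1 and v > 0}
    compound = true_dist.compound or (
        formula if isinstance(formula, CompoundRecord) else CompoundRecord("synthetic", formula if isinstance(formula, str) else "C1")
    )
    return IsotopologueEnvelope(compound, true_dist.system or "synthetic", areas)


def gen_timecourse(
    form: KineticModelForm,
    params: dict[str, float],
    times: Sequence[float] = presets.DEFAULT_TIME_GRID_H,
    noise_sd: float = 0.0,
    seed=None,
    floor: bool = False,
    compound: str = "synthetic",
    temperature: Optional[float] = None,
) -> TimeCourse:
    """Evaluate a kinetic model on a time grid and add Gaussian noise (sd in concentration units)."""
    times = np.asarray(times, dtype=float)
    fit = KineticFit(form, dict(params), r2=1.0, n_points=max(len(times), form.arity + 1))
    conc = np.asarray(predict(fit, times), dtype=float)
    if noise_sd > 0:
        conc = conc + _rng(seed).normal(0.0, noise_sd, size=conc.shape)
    if floor:
        conc = np.clip(conc, 0.0, None)
    return TimeCourse(compound, temperature if temperature is not None else float("nan"), times, conc)


def gen_calibration(
    curve: CalibrationCurve,
    concs: Sequence[float],
    noise_sd: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Standards table (analyte, conc, response) from a line plus Gaussian response noise."""
    concs = np.asarray(concs, dtype=float)
    if concs.size == 0:
        raise ValidationError("need at least one standard concentration")
    resp = curve.slope * concs + curve.intercept
    if noise_sd > 0:
        resp = resp + _rng(seed).normal(0.0, noise_sd, size=resp.shape)
    return pd.DataFrame({"analyte": curve.analyte, "conc": concs, "response": resp})


def scenario_presets() -> dict[str, ScenarioPreset]:
    """Named generating scenarios: model-system recipes plus ground-truth tables."""
    out = {
        name: ScenarioPreset(f"system_{name}", meta["description"], dict(meta))
        for name, meta in presets.MODEL_SYSTEMS.items()
    }
    out["c13_labeling"] = ScenarioPreset(
        "c13_labeling",
        "corrected isotopologue distributions from the 13C6-glucose labeling runs",
        {"distributions": presets.C13_DISTRIBUTIONS, "design": presets.GLUCOSE_DESIGN},
    )
    out["d5_labeling"] = ScenarioPreset(
        "d5_labeling",
        "corrected isotopologue distributions from the D5-theanine labeling runs",
        {"distributions": presets.D5_DISTRIBUTIONS, "design": presets.THEANINE_D5_DESIGN},
    )
    out["kinetics"] = ScenarioPreset(
        "kinetics", "published per-temperature kinetic models", {"models": presets.KINETIC_MODELS}
    )
    out["calibration"] = ScenarioPreset(
        "calibration", "published amino-acid standard curves", {"curves": presets.CALIBRATION_CURVES}
    )
    return out


def _distribution_frame(table: dict, provenance: str) -> pd.DataFrame:
    max_ch = max(max(d) for _, _, d_all, d_half in table.values() for d in (d_all, d_half))
    rows = []
    for name, (mz, formula, d_all, d_half) in table.items():
        for system, dist in (("all", d_all), ("half", d_half)):
            row = {"compound": name, "nominal_mass": mz, "formula": formula, "system": system,
                   "provenance": provenance}
            for k in range(0, max_ch + 1):
                row["M" if k == 0 else f"M+{k}"] = dist.get(k, "")
            rows.append(row)
    return pd.DataFrame(rows)


def build_reference_fixtures(outdir=None) -> dict[str, pd.DataFrame]:
    """Assemble the transcribed study tables as DataFrames; optionally write CSVs.

    Keys: ``distributions_c13``, ``distributions_d5``, ``kinetic_models``,
    ``calibration_curves``. Each row carries a ``provenance`` tag naming the
    experiment it was transcribed from.
    """
    frames = {
        "distributions_c13": _distribution_frame(
            presets.C13_DISTRIBUTIONS, "reference_c13_glucose_labeling"
        ),
        "distributions_d5": _distribution_frame(
            presets.D5_DISTRIBUTIONS, "reference_d5_theanine_labeling"
        ),
        "kinetic_models": pd.DataFrame(
            [
                {
                    "compound": name,
                    "cas": presets.KINETIC_CAS.get(name, ""),
                    "temperature_C": temp,
                    "form": form.value,
                    **{f"param_{k}": v for k, v in params.items()},
                    "r2_reported": r2,
                    "provenance": "reference_kinetic_fits",
                }
                for (name, temp), (form, params, r2) in presets.KINETIC_MODELS.items()
            ]
        ),
        "calibration_curves": pd.DataFrame(
            [
                {
                    "analyte": analyte,
                    "slope": slope,
                    "intercept": intercept,
                    "r2_reported": r2,
                    "provenance": "reference_amino_acid_calibration",
                }
                for analyte, (slope, intercept, r2) in presets.CALIBRATION_CURVES.items()
            ]
        ),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in frames.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
    return frames
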