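"""Reference constants of the glucose–theanine roasting study.

These are the published measured/fitted values the synthetic-data generator
uses as ground truth: corrected isotopologue distributions from the ¹³C₆-glucose
and D₅-theanine labeling experiments, per-temperature fitted kinetic models for
the four tracked aroma compounds, external-standard calibration lines for the
17 free amino acids, and the model-reaction recipes.

Distribution values are transcribed as printed (whole percents). A few rows of
the ¹³C source table are internally inconsistent as printed (half-labeled mass
shifts exceeding the fully-labeled state, one row summing to 130, C6 compounds
listed with M+7 intensity); they are kept verbatim — the inference engine
flags such patterns — and excluded from round-trip fixtures via
:data:`C13_CONSISTENT`.
"""

from __future__ import annotations

from .camola_inference import LabelingDesign
from .kinetics import KineticModelForm
from .records import CompoundRecord

# ¹³C₆-glucose labeling experiment (glucose–theanine system, 110 °C / 5 h).
# name -> (m/z, formula, all-system distribution, half-system distribution);
# distributions map channel offset -> percent.
C13_DISTRIBUTIONS: dict[str, tuple[int, str, dict[int, float], dict[int, float]]] = {
    "3-Methylbutyraldehyde": (86, "C5H10O", {0: 100}, {0: 100}),
    "Furfuryl alcohol": (98, "C5H6O2", {4: 40, 5: 60}, {0: 40, 4: 20, 5: 40}),
    "Hexanal": (100, "C6H12O", {3: 41, 5: 59}, {0: 40, 3: 30, 5: 30}),
    "Furfural": (96, "C5H4O2", {5: 100}, {0: 32, 4: 32, 5: 36}),
    "Benzaldehyde": (106, "C7H6O", {0: 100}, {0: 100}),
    "5-Methylfurfural": (110, "C6H6O2", {4: 50, 5: 50}, {0: 100}),
    "2,3-Butanedione": (86, "C4H6O2", {4: 100}, {0: 33, 1: 10, 2: 10, 3: 10, 4: 37}),
    "Pyrazine": (80, "C4H4N2", {4: 100}, {0: 30, 2: 50, 4: 20}),
    "2-Methylpyrazine": (94, "C5H6N2", {5: 100}, {0: 25, 2: 25, 3: 25, 5: 25}),
    "2,5-Dimethylpyrazine": (108, "C6H8N2", {3: 100}, {0: 23, 3: 50, 6: 27}),
    "2,3-Dimethylpyrazine": (108, "C6H8N2", {3: 100}, {0: 33, 3: 46, 6: 21}),
    "2-Vinylpyrazine": (106, "C6H6N2", {5: 40, 6: 30, 7: 30}, {5: 40, 6: 30, 7: 30}),
    "2-Pyrrolecarboxaldehyde": (95, "C5H5NO", {4: 46, 5: 54}, {0: 20, 1: 26, 2: 10, 3: 30, 4: 14}),
    "2-Acetylpyrrole": (109, "C6H7NO", {7: 100}, {0: 30, 2: 70}),
    "2-Acetylfuran": (110, "C6H6O2", {3: 70, 7: 30}, {0: 50, 5: 50, 7: 30}),
    "2,5-Dimethyl-1-propyl-1H-pyrrole": (
        137, "C9H15N", {3: 30, 4: 70}, {0: 25, 2: 10, 3: 40, 4: 7, 5: 8, 6: 10},
    ),
    "N-Ethylacetamide": (87, "C4H9NO", {0: 29, 2: 71}, {0: 100}),
    "Nonanoic acid": (158, "C9H18O2", {0: 100}, {0: 100}),
}

# Rows whose printed all/half patterns are mutually consistent and sum to 100;
# safe as ground truth for forward-simulation round trips.
C13_CONSISTENT: tuple[str, ...] = (
    "3-Methylbutyraldehyde",
    "Furfuryl alcohol",
    "Hexanal",
    "Furfural",
    "Benzaldehyde",
    "5-Methylfurfural",
    "2,3-Butanedione",
    "Pyrazine",
    "2-Methylpyrazine",
    "2-Pyrrolecarboxaldehyde",
    "N-Ethylacetamide",
    "Nonanoic acid",
)

# D₅-theanine labeling experiment (deuterated theanine + unlabeled glucose).
D5_DISTRIBUTIONS: dict[str, tuple[int, str, dict[int, float], dict[int, float]]] = {
    "Furfuryl alcohol": (98, "C5H6O2", {0: 100}, {0: 100}),
    "Hexanal": (100, "C6H12O", {0: 100}, {0: 100}),
    "Furfural": (96, "C5H4O2", {0: 100}, {0: 100}),
    "2-Methylfuran": (82, "C5H6O", {0: 80, 5: 20}, {0: 90, 5: 10}),
    "1-Ethyl-1H-pyrrole": (95, "C6H9N", {5: 100}, {5: 100}),
}

GLUCOSE_DESIGN = LabelingDesign(p=0.5, label_shift_per_carbon=1, precursor_carbon_count=6)
THEANINE_D5_DESIGN = LabelingDesign(p=0.5, label_shift_per_carbon=1, precursor_carbon_count=5)

# Published kinetic models per compound x roasting temperature (°C).
# (form, params, reported R²); time in hours, concentration in the study's
# (unstated) units.
KINETIC_MODELS: dict[tuple[str, int], tuple[KineticModelForm, dict[str, float], float]] = {
    ("Benzaldehyde", 100): (KineticModelForm.ZERO_ORDER, {"K": 0.2379, "A0": -0.00247}, 0.9149),
    ("Benzaldehyde", 110): (
        KineticModelForm.EXP_OFFSET, {"a": 0.41551, "b": 0.01314, "c": 0.03794}, 0.9148,
    ),
    ("Benzaldehyde", 120): (
        KineticModelForm.EXP_OFFSET, {"a": 0.13824, "b": 0.01326, "c": 0.31244}, 0.9384,
    ),
    ("2-Methylpyrazine", 100): (KineticModelForm.ZERO_ORDER, {"K": 0.06502, "A0": -4.52855}, 0.8195),
    ("2-Methylpyrazine", 110): (KineticModelForm.ZERO_ORDER, {"K": 0.08362, "A0": -4.14681}, 0.9526),
    ("2-Methylpyrazine", 120): (KineticModelForm.ZERO_ORDER, {"K": 0.13029, "A0": -0.59493}, 0.8984),
    ("2,6-Dimethylpyrazine", 100): (KineticModelForm.ZERO_ORDER, {"K": 0.41071, "A0": -0.25}, 0.995),
    ("2,6-Dimethylpyrazine", 110): (KineticModelForm.ZERO_ORDER, {"K": 0.49107, "A0": 0.41071}, 0.9938),
    ("2,6-Dimethylpyrazine", 120): (KineticModelForm.ZERO_ORDER, {"K": 2.83929, "A0": -2.86429}, 0.9984),
    ("2-Methylfuran", 100): (KineticModelForm.ZERO_ORDER, {"K": 0.00616, "A0": -0.31015}, 0.915),
    ("2-Methylfuran", 110): (
        KineticModelForm.EXP_OFFSET, {"a": 0.12865, "b": 0.01288, "c": -0.14638}, 0.9018,
    ),
    ("2-Methylfuran", 120): (
        KineticModelForm.EXP_OFFSET, {"a": 0.61399, "b": 0.0133, "c": -0.20183}, 0.9584,
    ),
}

KINETIC_CAS: dict[str, str] = {
    "Benzaldehyde": "100-52-7",
    "2-Methylpyrazine": "109-08-0",
    "2,6-Dimethylpyrazine": "108-50-9",
    "2-Methylfuran": "534-22-5",
}

# Compounds whose formation shows a lag phase (below detection at t = 0):
# simulated/refit time courses for these start at 2 h.
LAG_COMPOUNDS: frozenset[str] = frozenset({"2-Methylpyrazine", "2,6-Dimethylpyrazine", "2-Methylfuran"})

# External-standard amino-acid calibration lines: analyte -> (slope, intercept, reported R²).
CALIBRATION_CURVES: dict[str, tuple[float, float, float]] = {
    "Asp": (106.13, 2.263, 0.9926),
    "Glu": (186.24, -1.652, 0.9947),
    "Ser": (129.82, -4.001, 0.9736),
    "His": (244.16, 2.171, 0.9947),
    "Gly": (173.12, 0.806, 0.9867),
    "Thr": (118.05, -0.813, 0.9946),
    "Arg": (272.84, -3.179, 0.9892),
    "Ala": (150.76, 3.308, 0.9878),
    "Tyr": (269.11, -1.592, 0.9831),
    "Cys": (193.99, 0.254, 0.9885),
    "Val": (111.16, -1.667, 0.9972),
    "Met": (198.02, -0.456, 0.9906),
    "Phe": (168.98, 4.169, 0.9953),
    "Ile": (196.92, -1.296, 0.9882),
    "Leu": (189.35, 1.067, 0.9743),
    "Lys": (153.69, -0.885, 0.9877),
    "Theanine": (120.98, -17.923, 0.9913),
}

# Model-reaction recipes (metadata recorded on generated datasets).
MODEL_SYSTEMS: dict[str, dict] = {
    "A": {
        "description": "glucose-theanine Maillard model system",
        "theanine_umol": 500,
        "glucose_umol": 500,
        "volume_mL": 10,
        "pH": 5.5,
        "temperature_C": 110,
        "duration_h": 5,
    },
    "B": {"description": "theanine-only control", "theanine_umol": 500, "glucose_umol": 0,
          "volume_mL": 10, "pH": 5.5, "temperature_C": 110, "duration_h": 5},
    "C": {"description": "glucose-only control", "theanine_umol": 0, "glucose_umol": 500,
          "volume_mL": 10, "pH": 5.5, "temperature_C": 110, "duration_h": 5},
}

# Internal standard for semi-quantification of volatiles.
INTERNAL_STANDARD = {"name": "2-methyl-3-heptanone", "amount_ug": 0.816, "solvent": "n-hexane"}

# Sampling grid of the roasting experiments: 0-12 h at 2 h intervals.
DEFAULT_TIME_GRID_H: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)


def compound_record(name: str) -> CompoundRecord:
    """CompoundRecord for any compound in the labeling tables."""
    for table in (C13_DISTRIBUTIONS, D5_DISTRIBUTIONS):
        if name in table:
            mz, formula, _, _ = table[name]
            return CompoundRecord(name=name, formula=formula, nominal_mass=mz)
    raise KeyError(name)
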