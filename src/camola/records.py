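"""Core domain records shared by every stage of the pipeline.

The pipeline moves data through three containers:

* :class:`IsotopologueEnvelope` — raw selected-ion peak areas for one compound in
  one labeling system, keyed by channel offset relative to the molecular ion
  (−1 is the hydrogen-loss artifact channel, 0 is M⁺, k is M⁺+k).
* :class:`CorrectedDistribution` — percentage distribution over label counts after
  hydrogen-loss and natural-abundance correction and normalization.
* :class:`TimeCourse` — a (time, concentration) series for one compound at one
  roasting temperature, the input to the kinetic fits.

:class:`RunConfig` holds the global knobs (natural-abundance constants, rounding,
hypothesis-search bounds, seed) and can be loaded from YAML.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import ValidationError

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation elemental formula ("C5H6O2") into element counts.

    Raises :class:`ValidationError` if any character is left over after
    tokenizing, so typos like "C5H6O2x" fail loudly.
    """
    if not formula or not isinstance(formula, str):
        raise ValidationError(f"empty or non-string formula: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            break
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula):
        raise ValidationError(f"formula {formula!r} does not parse at position {pos}")
    return counts


@dataclass(frozen=True)
class CompoundRecord:
    """Identity and composition of one volatile compound.

    ``nominal_mass`` is the integer m/z of the molecular ion M⁺ monitored in the
    selected-ion traces.
    """

    name: str
    formula: str
    nominal_mass: Optional[int] = None
    cas: Optional[str] = None

    def __post_init__(self):
        comp = parse_formula(self.formula)
        if comp.get("C", 0) < 1:
            raise ValidationError(
                f"{self.name}: formula {self.formula!r} has no carbon; need at least one"
            )
        if self.nominal_mass is not None and self.nominal_mass <= 0:
            raise ValidationError(f"{self.name}: nominal_mass must be > 0")
        object.__setattr__(self, "_composition", comp)

    @property
    def composition(self) -> dict[str, int]:
        return dict(self._composition)

    @property
    def n_carbon(self) -> int:
        return self._composition.get("C", 0)

    @property
    def n_sulfur(self) -> int:
        return self._composition.get("S", 0)


@dataclass
class IsotopologueEnvelope:
    """Raw per-channel peak areas for one compound in one labeling system.

    ``system`` tags the labeling design: ``"all"`` (fully labeled precursor
    pool), ``"half"`` (1:1 labeled/unlabeled), or ``"control"`` (unlabeled).
    ``areas`` maps channel offset → peak area; a channel that was not monitored
    is simply absent (absent ≠ zero).
    """

    compound: CompoundRecord
    system: str
    areas: dict[int, float]

    def __post_init__(self):
        if not self.areas:
            raise ValidationError(f"{self.compound.name}/{self.system}: empty envelope")
        clean: dict[int, float] = {}
        for k, v in self.areas.items():
            k = int(k)
            v = float(v)
            if k < -1:
                raise ValidationError(
                    f"{self.compound.name}/{self.system}: channel {k} below M-1 is not meaningful"
                )
            if v < 0 or not math.isfinite(v):
                raise ValidationError(
                    f"{self.compound.name}/{self.system}: negative or non-finite area {v} at channel {k}"
                )
            clean[k] = v
        self.areas = dict(sorted(clean.items()))

    @property
    def channels(self) -> list[int]:
        return list(self.areas)

    def total(self) -> float:
        return float(sum(self.areas.values()))

    def dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (offsets, areas) over the contiguous span min..max, gaps as 0."""
        lo, hi = min(self.areas), max(self.areas)
        offsets = np.arange(lo, hi + 1)
        vals = np.array([self.areas.get(int(k), 0.0) for k in offsets], dtype=float)
        return offsets, vals


@dataclass
class CorrectedDistribution:
    """Percentage distribution over label counts (channels) for one compound/system.

    Fractions are kept at full precision; rounding happens only at reporting
    time via :meth:`rounded`.
    """

    fractions: dict[int, float]
    compound: Optional[CompoundRecord] = None
    system: Optional[str] = None

    def __post_init__(self):
        clean = {int(k): float(v) for k, v in self.fractions.items()}
        for k, v in clean.items():
            if v < -1e-9:
                raise ValidationError(f"negative fraction {v} at channel {k}")
        total = sum(clean.values())
        if abs(total - 100.0) > 0.5:
            raise ValidationError(f"fractions sum to {total}, expected 100 ± 0.5")
        self.fractions = dict(sorted(clean.items()))

    def rounded(self, places: int = 0) -> dict[int, float]:
        """Fractions rounded for display; whole percents by default."""
        out = {}
        for k, v in self.fractions.items():
            r = round(v, places)
            out[k] = int(r) if places <= 0 else r
        return out

    @property
    def support(self) -> set[int]:
        """Channels with non-negligible weight."""
        return {k for k, v in self.fractions.items() if v > 1e-9}


@dataclass
class TimeCourse:
    """Concentration of one compound over roasting time at one temperature.

    Times are hours, temperature °C; concentration units are caller-supplied
    and carried verbatim.
    """

    compound: str
    temperature: float
    times: np.ndarray
    concentrations: np.ndarray
    units: str = "a.u."

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValidationError(f"{self.compound}: times and concentrations must be 1-D and equal length")
        if t.size < 3:
            raise ValidationError(f"{self.compound}: need at least 3 time points, got {t.size}")
        if np.any(t < 0):
            raise ValidationError(f"{self.compound}: negative time")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"{self.compound}: times must be strictly increasing")
        self.times = t
        self.concentrations = a

    def __len__(self) -> int:
        return int(self.times.size)


_DEFAULT_ABUNDANCE = {"c13": 0.0110, "s33": 0.0076, "s34": 0.0420}


@dataclass
class RunConfig:
    """Global pipeline configuration.

    ``hloss_ratio_source`` is either the string ``"control"`` (estimate the
    (M−1)/M ratio from an unlabeled control envelope) or a fixed float ratio.
    ``distance_threshold`` is the sum-of-squared-percent cutoff above which the
    best fragment hypothesis is rejected and the compound is called
    multi-pathway.
    """

    natural_abundance: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_ABUNDANCE))
    hloss_ratio_source: object = "control"
    rounding: int = 0
    max_fragments: int = 4
    distance_threshold: float = 150.0
    seed: int = 0

    def __post_init__(self):
        for iso, frac in self.natural_abundance.items():
            if not (0 <= frac < 1):
                raise ValidationError(f"natural abundance {iso}={frac} outside [0, 1)")
        if self.max_fragments < 1:
            raise ValidationError("max_fragments must be >= 1")
        if isinstance(self.hloss_ratio_source, str):
            if self.hloss_ratio_source != "control":
                raise ValidationError("hloss_ratio_source must be 'control' or a ratio >= 0")
        elif float(self.hloss_ratio_source) < 0:
            raise ValidationError("fixed hloss ratio must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        merged = dict(natural_abundance=dict(_DEFAULT_ABUNDANCE))
        merged["natural_abundance"].update(data.pop("natural_abundance", {}))
        merged.update(data)
        return cls(**merged)

    def to_dict(self) -> dict:
        return {
            "natural_abundance": dict(self.natural_abundance),
            "hloss_ratio_source": self.hloss_ratio_source,
            "rounding": self.rounding,
            "max_fragments": self.max_fragments,
            "distance_threshold": self.distance_threshold,
            "seed": self.seed,
        }
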