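"""Tabular input/output and internal-standard semi-quantification.

CSV/TSV schemas
---------------
Envelope tables (raw peak areas, one row per compound × labeling system):
``compound, formula[, nominal_mass][, cas], system, M-1, M, M+1, ... M+n``.
Channel cells left empty mean "not monitored" (absent, not zero).

Distribution tables (corrected percentages) use the same layout minus the
``M-1`` column.

Time courses: ``compound, temperature_C, time_h, concentration`` (long form,
one row per sampled point). Calibration standards: ``analyte, conc, response``.

Delimiters are auto-detected between comma and tab only; anything else must be
declared explicitly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .records import (
    CompoundRecord,
    CorrectedDistribution,
    IsotopologueEnvelope,
    RunConfig,
    TimeCourse,
)

logger = logging.getLogger(__name__)

_CHANNEL_PREFIX = "M"


def _detect_sep(path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt in (",", "csv"):
            return ","
        if fmt in ("\t", "tsv", "tab"):
            return "\t"
        raise ValidationError(f"unsupported delimiter {fmt!r}; declare ',' or '\\t'")
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _channel_of(column: str) -> Optional[int]:
    """Map a header like "M-1", "M", "M+0", "M+3" to a channel offset."""
    col = column.strip()
    if not col.startswith(_CHANNEL_PREFIX):
        return None
    rest = col[len(_CHANNEL_PREFIX):].strip()
    if rest == "":
        return 0
    if rest[0] in "+-":
        try:
            return int(rest)
        except ValueError:
            return None
    return None


def read_envelope_table(path, fmt: Optional[str] = None) -> list[IsotopologueEnvelope]:
    """Read raw isotopologue envelopes from a CSV/TSV table, one per row."""
    df = pd.read_csv(path, sep=_detect_sep(path, fmt))
    df.columns = [str(c).strip() for c in df.columns]
    required = {"compound", "formula", "system"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: header must declare {sorted(required)}; got {list(df.columns)}")
    channel_cols = {c: ch for c in df.columns if (ch := _channel_of(c)) is not None}
    if not channel_cols:
        raise ValidationError(f"{path}: no channel columns (M-1, M, M+1, ...) found")

    envelopes = []
    for idx, row in df.iterrows():
        try:
            compound = CompoundRecord(
                name=str(row["compound"]),
                formula=str(row["formula"]),
                nominal_mass=int(row["nominal_mass"]) if "nominal_mass" in df.columns and pd.notna(row.get("nominal_mass")) else None,
                cas=str(row["cas"]) if "cas" in df.columns and pd.notna(row.get("cas")) else None,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {idx + 2}: {exc}") from exc
        areas = {}
        for col, ch in channel_cols.items():
            val = row[col]
            if pd.isna(val) or (isinstance(val, str) and not val.strip()):
                continue  # absent channel, not zero
            areas[ch] = float(val)
        try:
            envelopes.append(IsotopologueEnvelope(compound, str(row["system"]).strip(), areas))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {idx + 2}: {exc}") from exc
    return envelopes


def write_envelope_table(envelopes: Sequence[IsotopologueEnvelope], path, sep: str = ",") -> None:
    """Write envelopes in the schema :func:`read_envelope_table` reads."""
    lo = min(min(e.areas) for e in envelopes)
    hi = max(max(e.areas) for e in envelopes)
    rows = []
    for e in envelopes:
        row = {
            "compound": e.compound.name,
            "formula": e.compound.formula,
            "nominal_mass": e.compound.nominal_mass,
            "system": e.system,
        }
        for k in range(lo, hi + 1):
            col = "M" if k == 0 else f"M{k:+d}"
            row[col] = e.areas.get(k, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, sep=sep)


def read_distribution_table(path, fmt: Optional[str] = None) -> list[CorrectedDistribution]:
    """Read corrected percentage distributions (same layout as envelopes, channels ≥ 0)."""
    dists = []
    for env in read_envelope_table(path, fmt):
        fractions = {k: v for k, v in env.areas.items() if k >= 0}
        dists.append(CorrectedDistribution(fractions, compound=env.compound, system=env.system))
    return dists


def write_distribution_table(
    dists: Sequence[CorrectedDistribution], path, places: int = 0, sep: str = ","
) -> None:
    """Write distributions as a channels-as-columns percentage table."""
    hi = max(max(d.fractions) for d in dists)
    rows = []
    for d in dists:
        rounded = d.rounded(places)
        row = {
            "compound": d.compound.name if d.compound else "",
            "formula": d.compound.formula if d.compound else "",
            "system": d.system or "",
        }
        for k in range(0, hi + 1):
            col = "M" if k == 0 else f"M+{k}"
            row[col] = rounded.get(k, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, sep=sep)


def read_timecourse_table(path, fmt: Optional[str] = None, units: str = "a.u.") -> list[TimeCourse]:
    """Read long-form time courses, grouped by (compound, temperature_C)."""
    df = pd.read_csv(path, sep=_detect_sep(path, fmt))
    required = {"compound", "temperature_C", "time_h", "concentration"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: header must declare {sorted(required)}")
    out = []
    for (compound, temp), grp in df.groupby(["compound", "temperature_C"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            TimeCourse(
                str(compound),
                float(temp),
                grp["time_h"].to_numpy(float),
                grp["concentration"].to_numpy(float),
                units=units,
            )
        )
    return out


def write_timecourse_table(courses: Sequence[TimeCourse], path, sep: str = ",") -> None:
    rows = [
        {"compound": tc.compound, "temperature_C": tc.temperature, "time_h": t, "concentration": c}
        for tc in courses
        for t, c in zip(tc.times, tc.concentrations)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, sep=sep)


def read_calibration_table(path, fmt: Optional[str] = None) -> dict[str, list[tuple[float, float]]]:
    """Read standards as analyte -> [(conc, response), ...]."""
    df = pd.read_csv(path, sep=_detect_sep(path, fmt))
    required = {"analyte", "conc", "response"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: header must declare {sorted(required)}")
    out: dict[str, list[tuple[float, float]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["analyte"]), []).append((float(row["conc"]), float(row["response"])))
    return out


def quantify_by_internal_standard(
    compound_area: float,
    is_area: float,
    is_amount: float,
    compound: str = "",
) -> float:
    """Single-point semi-quantification against a spiked internal standard.

    Returns ``compound_area / is_area × is_amount`` (μg per sample aliquot),
    assuming a relative response factor of 1 — semi-quantitative by design.
    """
    if is_area <= 0:
        raise DegenerateInputError(
            f"internal-standard area must be > 0 to quantify {compound or 'compound'}"
        )
    if compound_area < 0:
        raise ValidationError(f"negative peak area for {compound or 'compound'}")
    return compound_area / is_area * is_amount


def _digest(payload) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def write_report(
    results: Sequence[dict],
    out,
    config: Optional[RunConfig] = None,
    inputs: Optional[Sequence] = None,
) -> Path:
    """Write a machine-readable JSON report plus a human-readable CSV table.

    The JSON holds the config used, a digest of the declared inputs, and the
    per-compound result rows; the CSV mirrors the rows as a flat table. ``out``
    is the JSON path; the CSV lands next to it with the same stem.
    """
    out = Path(out)
    rows = [dict(r) for r in results]
    report = {
        "inputs_digest": _digest(list(inputs) if inputs is not None else rows),
        "config": config.to_dict() if config is not None else None,
        "n_results": len(rows),
        "results": rows,
    }
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    pd.DataFrame(rows).to_csv(out.with_suffix(".csv"), index=False)
    return out
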