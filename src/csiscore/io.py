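"""Cohort readers, scored-table writers and deterministic reports.

Input schema (UTF-8 CSV, header required), one row per patient::

    patient_id, cmi_label,
    ca_reach,  ca_d_sten_mm,  ca_d_norm_mm,  ca_percent,  ca_occluded,  ca_absent,
    sma_reach, sma_d_sten_mm, sma_d_norm_mm, sma_percent, sma_occluded, sma_absent,
    ima_reach, ima_d_sten_mm, ima_d_norm_mm, ima_percent, ima_occluded, ima_absent

Empty cells are allowed where a percent stands in for diameters (or vice
versa); ``cmi_label`` is optional.  Row errors are collected and reported
together with their line numbers.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import ConfigError, MeasurementError, SchemaError
from .lesion import (
    LesionMeasurement,
    VESSEL_ORDER,
    components_from_measurements,
)
from .scoring import (
    DEFAULT_CUTOFF,
    DEFAULT_WEIGHTS,
    ScoredPatient,
    WeightVector,
    score_patient,
)

__all__ = [
    "PatientRecord",
    "read_cohort",
    "score_cohort",
    "scored_to_frame",
    "write_report",
    "REQUIRED_COLUMNS",
]

_VESSEL_FIELDS = ("reach", "d_sten_mm", "d_norm_mm", "percent", "occluded", "absent")

REQUIRED_COLUMNS = ["patient_id"] + [
    f"{v.value.lower()}_{f}" for v in VESSEL_ORDER for f in _VESSEL_FIELDS
]

_TRUE = {"1", "true", "yes", "t", "y"}
_FALSE = {"0", "false", "no", "f", "n", ""}


@dataclass(frozen=True)
class PatientRecord:
    """One validated input row."""

    patient_id: str
    measurements: tuple[LesionMeasurement, LesionMeasurement, LesionMeasurement]
    cmi_label: Optional[bool] = None


def _parse_bool(raw: object, column: str) -> bool:
    text = "" if raw is None else str(raw).strip().lower()
    if text in ("nan", "na"):
        text = ""
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise SchemaError(f"column {column}: cannot parse boolean from {raw!r}")


def _parse_float(raw: object, column: str) -> Optional[float]:
    text = "" if raw is None else str(raw).strip()
    if text.lower() in ("", "nan", "na"):
        return None
    try:
        return float(text)
    except ValueError:
        raise SchemaError(f"column {column}: cannot parse number from {raw!r}") from None


def _row_to_record(row: dict, has_label: bool) -> PatientRecord:
    measurements = []
    for vessel in VESSEL_ORDER:
        key = vessel.value.lower()
        measurements.append(
            LesionMeasurement(
                vessel=vessel,
                reach=str(row.get(f"{key}_reach", "") or "none"),
                d_stenosis=_parse_float(row.get(f"{key}_d_sten_mm"), f"{key}_d_sten_mm"),
                d_normal=_parse_float(row.get(f"{key}_d_norm_mm"), f"{key}_d_norm_mm"),
                percent_override=_parse_float(row.get(f"{key}_percent"), f"{key}_percent"),
                occluded=_parse_bool(row.get(f"{key}_occluded"), f"{key}_occluded"),
                absent=_parse_bool(row.get(f"{key}_absent"), f"{key}_absent"),
            )
        )
    label: Optional[bool] = None
    if has_label:
        raw = row.get("cmi_label")
        text = "" if raw is None else str(raw).strip().lower()
        if text not in ("", "nan", "na"):
            label = _parse_bool(raw, "cmi_label")
    return PatientRecord(
        patient_id=str(row["patient_id"]).strip(),
        measurements=tuple(measurements),
        cmi_label=label,
    )


def read_cohort(path: "str | Path") -> list[PatientRecord]:
    """Read and validate a cohort CSV.

    Every row is validated; if any row fails, a :class:`SchemaError` listing
    each offending line number (header = line 1) is raised.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    has_label = "cmi_label" in frame.columns

    records: list[PatientRecord] = []
    errors: list[str] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(frame.to_dict(orient="records")):
        line = i + 2  # header is line 1
        try:
            rec = _row_to_record(row, has_label)
            # classify now so measurement inconsistencies surface with the line
            components_from_measurements(rec.measurements)
            if rec.patient_id == "":
                raise SchemaError("empty patient_id")
            if rec.patient_id in seen:
                raise SchemaError(
                    f"duplicate patient_id {rec.patient_id!r} (first seen on line "
                    f"{seen[rec.patient_id]})"
                )
            seen[rec.patient_id] = line
            records.append(rec)
        except (SchemaError, MeasurementError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise SchemaError(f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors))
    return records


def score_cohort(
    records: Sequence[PatientRecord],
    weights: WeightVector = DEFAULT_WEIGHTS,
    cutoff: int = DEFAULT_CUTOFF,
    absent_vessel_policy: str = "zero",
) -> list[ScoredPatient]:
    """Classify and score every patient.

    ``absent_vessel_policy="zero"`` lets absent vessels contribute (0, 0);
    ``"missing"`` excludes patients with an absent vessel from the output.
    """
    if absent_vessel_policy not in ("zero", "missing"):
        raise ConfigError(
            f"absent_vessel_policy must be 'zero' or 'missing', got {absent_vessel_policy!r}"
        )
    scored: list[ScoredPatient] = []
    for rec in records:
        components, annotations = components_from_measurements(rec.measurements)
        if absent_vessel_policy == "missing" and any(a.endswith("_absent") for a in annotations):
            continue
        scored.append(
            score_patient(
                rec.patient_id,
                components,
                weights=weights,
                cutoff=cutoff,
                cmi_label=rec.cmi_label,
                annotations=annotations,
            )
        )
    return scored


def scored_to_frame(scored: Sequence[ScoredPatient]) -> pd.DataFrame:
    """Scored patients as the output table schema."""
    rows = []
    for p in scored:
        c = p.components
        rows.append(
            {
                "patient_id": p.patient_id,
                "c_extent": c.c_extent,
                "c_grade": c.c_grade,
                "s_extent": c.s_extent,
                "s_grade": c.s_grade,
                "i_extent": c.i_extent,
                "i_grade": c.i_grade,
                "csi_score": p.csi_score,
                "risk_group": p.risk_group,
                "subgroup": p.subgroup,
                "cmi_label": "" if p.cmi_label is None else bool(p.cmi_label),
                "flags": ";".join(sorted(p.annotations)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "c_extent",
            "c_grade",
            "s_extent",
            "s_grade",
            "i_extent",
            "i_grade",
            "csi_score",
            "risk_group",
            "subgroup",
            "cmi_label",
            "flags",
        ],
    )


def _round_value(key: str, value):
    if isinstance(value, bool) or not isinstance(value, float):
        return value
    if math.isnan(value):
        return None
    decimals = 1 if "percent" in key or "agreement" in key else 3
    return round(value, decimals)


def _rounded(obj, key: str = ""):
    if isinstance(obj, dict):
        return {str(k): _rounded(v, str(k)) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_rounded(v, key) for v in obj]
    return _round_value(key, obj)


def write_report(results: dict, path: "str | Path", format: str = "json") -> None:
    """Serialize a report deterministically.

    Floats are rounded at fixed precision (AUC, kappa and other statistics
    to 3 decimals; percentages to 1), keys are sorted, so identical results
    always produce byte-identical files.  Formats: ``json``, ``csv`` (dotted
    flat keys), ``text``.
    """
    path = Path(path)
    data = _rounded(results)
    if format == "json":
        path.write_text(json.dumps(data, sort_keys=True, indent=2) + "\n", encoding="utf-8")
    elif format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["key", "value"])
            for key, value in sorted(_flatten(data)):
                writer.writerow([key, value])
    elif format == "text":
        lines = [f"{key}: {value}" for key, value in sorted(_flatten(data))]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ConfigError(f"unknown report format {format!r}; expected json, csv or text")


def _flatten(obj, prefix: str = ""):
    if isinstance(obj, dict):
        for k in sorted(obj):
            yield from _flatten(obj[k], f"{prefix}{k}." if prefix == "" else f"{prefix}{k}.")
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            yield from _flatten(v, f"{prefix}{i}.")
    else:
        yield prefix[:-1], obj
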