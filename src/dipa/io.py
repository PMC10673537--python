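"""Cohort CSV reading and writing.

The cohort file emulates a narcotics-registry export joined to clinic
surveys: one row per prescription, with the visit-level keys repeated
(visits without medication carry one row with empty drug fields).

Columns: patient_id, period, ipa, gender, age, procedure, drug,
strength_mg, doses_per_day, usage, is_otc.
"""

from __future__ import annotations

import csv
import hashlib
from pathlib import Path
from typing import Iterable, Sequence

from .errors import SchemaError, ValidationError
from .mme import PrescriptionRecord
from .scoring import PERIODS, PatientVisit

__all__ = ["COHORT_COLUMNS", "write_cohort", "read_cohort", "file_sha256"]

COHORT_COLUMNS = (
    "patient_id", "period", "ipa", "gender", "age", "procedure",
    "drug", "strength_mg", "doses_per_day", "usage", "is_otc",
)


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "true" if x else "false"
    if isinstance(x, float):
        return str(x)  # shortest repr round-trips exactly
    return str(x)


def write_cohort(visits: Sequence[PatientVisit], path: str | Path) -> Path:
    """Write visits as the documented cohort CSV (deterministic bytes)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COHORT_COLUMNS)
        for v in visits:
            base = [v.patient_id, v.period, _fmt(v.ipa), _fmt(v.gender),
                    _fmt(v.age), _fmt(v.procedure)]
            if v.prescriptions:
                for p in v.prescriptions:
                    writer.writerow(
                        base + [p.drug, _fmt(p.strength_mg), _fmt(p.doses_per_day),
                                p.usage, _fmt(p.is_otc)]
                    )
            else:
                writer.writerow(base + ["", "", "", "", ""])
    return path


def _parse_ipa(text: str, line_no: int) -> int | None:
    t = text.strip()
    if t == "":
        return None
    try:
        value = int(t)
    except ValueError:
        raise SchemaError(f"line {line_no}: unparseable IPA value {text!r}") from None
    if value not in (0, 1, 2):
        raise SchemaError(f"line {line_no}: IPA must be 0, 1 or 2, got {value}")
    return value


def read_cohort(path: str | Path) -> list[PatientVisit]:
    """Read a cohort CSV, grouping prescription rows into visits.

    Rows sharing (patient_id, period) merge into one visit; their
    visit-level fields must agree.  Errors name the offending line.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        missing = set(COHORT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s): {', '.join(sorted(missing))}"
            )
        visits: dict[tuple[str, str], PatientVisit] = {}
        for line_no, row in enumerate(reader, start=2):
            pid = (row["patient_id"] or "").strip()
            period = (row["period"] or "").strip()
            if not pid:
                raise SchemaError(f"line {line_no}: missing patient_id")
            if period not in PERIODS:
                raise SchemaError(
                    f"line {line_no}: period must be one of {PERIODS}, got {period!r}"
                )
            ipa = _parse_ipa(row["ipa"] or "", line_no)
            key = (pid, period)
            if key not in visits:
                age_text = (row["age"] or "").strip()
                try:
                    visits[key] = PatientVisit(
                        patient_id=pid,
                        period=period,
                        ipa=ipa,
                        gender=(row["gender"] or "").strip() or None,
                        age=float(age_text) if age_text else None,
                        procedure=(row["procedure"] or "").strip() or None,
                    )
                except ValidationError as exc:
                    raise SchemaError(f"line {line_no}: {exc}") from exc
            elif visits[key].ipa != ipa:
                raise SchemaError(
                    f"line {line_no}: conflicting IPA values for visit {key}"
                )
            drug = (row["drug"] or "").strip()
            if drug:
                try:
                    visits[key].prescriptions.append(
                        PrescriptionRecord(
                            drug=drug,
                            strength_mg=float(row["strength_mg"]),
                            doses_per_day=float(row["doses_per_day"]),
                            usage=(row["usage"] or "consistent").strip() or "consistent",
                            is_otc=(row["is_otc"] or "").strip().lower()
                            in ("true", "1", "yes"),
                        )
                    )
                except (TypeError, ValueError, ValidationError) as exc:
                    raise SchemaError(f"line {line_no}: bad prescription row: {exc}") from exc
    return list(visits.values())


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
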