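"""Morphine-milligram-equivalent (MME) conversion engine.

Daily narcotic usage is standardized to oral morphine equivalents: each
opioid's daily milligrams are multiplied by a drug-specific conversion
factor (morphine itself has factor 1 by definition).  Factors follow the
CDC oral-MME reference set and are packaged as a versioned CSV so every
report can record exactly which table produced its numbers.

Methadone is the one tiered drug: its factor grows with total daily
milligrams (4x up to 20 mg/day, 8x to 40, 10x to 60, 12x above), so its
contribution is computed on the drug's pooled daily total rather than per
prescription row.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .errors import DrugLookupError, TableError, ValidationError

__all__ = [
    "OpioidConversionEntry",
    "ConversionTable",
    "PrescriptionRecord",
    "load_conversion_table",
    "compute_daily_mme",
    "DEFAULT_TABLE_RESOURCE",
]

DEFAULT_TABLE_RESOURCE = "mme_conversion_factors_v1.csv"


@dataclass(frozen=True)
class OpioidConversionEntry:
    """One drug's MME conversion rule.

    ``factor`` is MME per mg of the opioid component.  ``dose_tiers`` is a
    sorted ``(max_daily_mg, factor)`` ladder for tiered drugs (methadone);
    the last tier's bound may be ``inf``.  Non-opioids carry factor 0 and
    never contribute MME.
    """

    drug_name: str
    factor: float
    is_opioid: bool
    synonyms: tuple[str, ...] = ()
    schedule: str | None = None
    dose_tiers: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.is_opioid:
            if self.dose_tiers:
                bounds = [t[0] for t in self.dose_tiers]
                if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
                    raise TableError(
                        f"{self.drug_name}: dose tiers must be strictly "
                        "ascending in max daily mg"
                    )
                if any(t[1] <= 0 for t in self.dose_tiers):
                    raise TableError(f"{self.drug_name}: tier factor must be > 0")
            elif self.factor <= 0:
                raise TableError(
                    f"{self.drug_name}: opioid conversion factor must be > 0"
                )
        elif self.factor != 0:
            raise TableError(f"{self.drug_name}: non-opioid must have factor 0")

    def factor_for_daily_mg(self, daily_mg: float) -> float:
        """Conversion factor applicable at a given total daily mg."""
        if not self.dose_tiers:
            return self.factor
        for max_mg, fac in self.dose_tiers:
            if daily_mg <= max_mg:
                return fac
        return self.dose_tiers[-1][1]


class ConversionTable:
    """Validated drug -> conversion-factor lookup with synonym resolution."""

    def __init__(self, entries: Sequence[OpioidConversionEntry], version: str):
        self.entries = list(entries)
        self.version = version
        self._index: dict[str, OpioidConversionEntry] = {}
        for entry in self.entries:
            for name in (entry.drug_name, *entry.synonyms):
                key = name.strip().lower()
                if key in self._index and self._index[key] is not entry:
                    raise TableError(f"duplicate drug name or synonym: {name!r}")
                self._index[key] = entry

    def resolve(self, name: str) -> OpioidConversionEntry | None:
        return self._index.get(name.strip().lower())

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PrescriptionRecord:
    """One prescribed drug as reported at a clinic visit.

    ``strength_mg`` is the opioid component's mg per unit dose (for
    combination products like Norco, only the opioid mg).  ``doses_per_day``
    is the typical daily count — occasional (as-needed) users report their
    typical as-needed count, so class C still produces a nonzero MME.
    """

    drug: str
    strength_mg: float
    doses_per_day: float
    usage: str = "consistent"  # {occasional, consistent}
    is_otc: bool = False

    def __post_init__(self) -> None:
        if self.usage not in ("occasional", "consistent"):
            raise ValidationError(f"usage must be occasional/consistent, got {self.usage!r}")
        if not math.isfinite(self.strength_mg) or self.strength_mg < 0:
            raise ValidationError(f"strength_mg must be finite and >= 0, got {self.strength_mg}")
        if not math.isfinite(self.doses_per_day) or self.doses_per_day < 0:
            raise ValidationError(f"doses_per_day must be finite and >= 0, got {self.doses_per_day}")


def _parse_bool(text: str, line_no: int) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no", ""):
        return False
    raise TableError(f"line {line_no}: cannot parse boolean {text!r}")


def load_conversion_table(path_or_default: str | None = None) -> ConversionTable:
    """Load and validate a conversion table CSV.

    With no argument, loads the packaged CDC oral-MME table.  The file may
    open with ``# table_version: <tag>`` comment lines; tiered drugs appear
    as multiple rows sharing a name, each carrying ``tier_max_mg`` and
    ``tier_factor``.  Duplicate non-tier rows are rejected.
    """
    if path_or_default is None:
        ref = resources.files("dipa.data").joinpath(DEFAULT_TABLE_RESOURCE)
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path_or_default, encoding="utf-8") as fh:
            text = fh.read()

    version = "unversioned"
    lines = text.splitlines()
    data_lines: list[tuple[int, str]] = []
    for i, line in enumerate(lines, start=1):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.lower().startswith("table_version:"):
                version = stripped.split(":", 1)[1].strip()
            continue
        if line.strip():
            data_lines.append((i, line))
    if not data_lines:
        raise TableError("conversion table is empty")

    header = [h.strip().lower() for h in next(csv.reader([data_lines[0][1]]))]
    required = {"drug", "factor", "is_opioid"}
    missing = required - set(header)
    if missing:
        raise TableError(f"missing required column(s): {', '.join(sorted(missing))}")

    # group rows by drug so tiered drugs (several rows) assemble into one entry
    grouped: dict[str, list[tuple[int, dict[str, str]]]] = {}
    order: list[str] = []
    for line_no, line in data_lines[1:]:
        cells = next(csv.reader([line]))
        if len(cells) < len(header):
            cells += [""] * (len(header) - len(cells))
        row = dict(zip(header, cells))
        drug = row.get("drug", "").strip().lower()
        if not drug:
            raise TableError(f"line {line_no}: missing drug name")
        if drug not in grouped:
            order.append(drug)
        grouped.setdefault(drug, []).append((line_no, row))

    entries = []
    for drug in order:
        rows = grouped[drug]
        tiered = any(r.get("tier_max_mg", "").strip() for _, r in rows)
        if len(rows) > 1 and not tiered:
            raise TableError(
                f"line {rows[1][0]}: duplicate drug {drug!r} (only tiered "
                "drugs may span multiple rows)"
            )
        line_no, first = rows[0]
        try:
            is_opioid = _parse_bool(first.get("is_opioid", ""), line_no)
            synonyms = tuple(
                s.strip().lower()
                for s in first.get("synonyms", "").split("|")
                if s.strip()
            )
            schedule = first.get("schedule", "").strip() or None
            if tiered:
                tiers = []
                for ln, r in rows:
                    if not r.get("tier_max_mg", "").strip():
                        raise TableError(f"line {ln}: tiered drug row missing tier_max_mg")
                    tiers.append((float(r["tier_max_mg"]), float(r["tier_factor"])))
                entry = OpioidConversionEntry(
                    drug_name=drug, factor=tiers[0][1], is_opioid=is_opioid,
                    synonyms=synonyms, schedule=schedule, dose_tiers=tuple(tiers),
                )
            else:
                entry = OpioidConversionEntry(
                    drug_name=drug, factor=float(first["factor"]),
                    is_opioid=is_opioid, synonyms=synonyms, schedule=schedule,
                )
        except TableError:
            raise
        except (ValueError, KeyError) as exc:
            raise TableError(f"line {line_no}: malformed row for {drug!r}: {exc}") from exc
        entries.append(entry)
    return ConversionTable(entries, version=version)


def compute_daily_mme(
    prescriptions: Iterable[PrescriptionRecord], table: ConversionTable
) -> float:
    """Total daily MME for one visit's prescription list.

    Sum over opioid records of ``strength_mg x doses_per_day x factor``;
    tiered drugs use the factor selected by that drug's pooled daily mg.
    OTC and non-opioid records contribute 0.  Every opioid name must
    resolve in the table (directly or via synonym).
    """
    records = list(prescriptions)
    unresolved: list[str] = []
    flat_total = 0.0
    tiered_mg: dict[str, tuple[OpioidConversionEntry, float]] = {}
    for rec in records:
        if rec.is_otc:
            continue
        entry = table.resolve(rec.drug)
        if entry is None:
            unresolved.append(rec.drug)
            continue
        if not entry.is_opioid:
            continue
        if rec.strength_mg <= 0:
            raise ValidationError(
                f"opioid record {rec.drug!r} must have strength_mg > 0"
            )
        daily_mg = rec.strength_mg * rec.doses_per_day
        if entry.dose_tiers:
            prev = tiered_mg.get(entry.drug_name, (entry, 0.0))[1]
            tiered_mg[entry.drug_name] = (entry, prev + daily_mg)
        else:
            flat_total += daily_mg * entry.factor
    if unresolved:
        raise DrugLookupError(unresolved)
    tier_total = sum(
        mg * entry.factor_for_daily_mg(mg) for entry, mg in tiered_mg.values()
    )
    return flat_total + tier_total
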