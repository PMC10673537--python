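"""Provider efficiency scoring and per-period cohort summaries.

The efficiency (pain-management) score at a post-operative period is the
percentage of surveyed patients reporting no pain (IPA 0) or tolerable
pain (IPA 1):

    score = 100 * |{IPA <= 1}| / n

Percent-on-narcotics is the share of visits in classes C, D or E.  Visits
are tracked at four follow-up windows: two weeks, six weeks, three months
and six months after surgery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classification import (
    ClassBoundaries,
    DIPARating,
    MedicationClass,
    OPERATIONAL_BOUNDARIES,
    classify_visit,
    make_dipa_rating,
)
from .errors import ValidationError
from .mme import ConversionTable, PrescriptionRecord, compute_daily_mme

__all__ = [
    "PERIODS",
    "canonicalize_period",
    "PatientVisit",
    "PeriodSummary",
    "efficiency_score",
    "percent_on_narcotics",
    "annotate_visit",
    "annotate_visits",
    "summarize_period",
    "summarize_cohort",
]

#: Post-operative periods in chronological order.
PERIODS: tuple[str, ...] = ("2wk", "6wk", "3mo", "6mo")

# days-since-surgery windows used to canonicalize raw visit dates;
# clinics rarely land exactly on the nominal day
_PERIOD_WINDOWS = {
    "2wk": (10, 21),
    "6wk": (35, 56),
    "3mo": (75, 105),
    "6mo": (160, 200),
}


def canonicalize_period(days_since_surgery: float) -> str:
    """Map days since surgery onto the nominal follow-up period."""
    for period, (lo, hi) in _PERIOD_WINDOWS.items():
        if lo <= days_since_surgery <= hi:
            return period
    raise ValidationError(
        f"{days_since_surgery} days does not fall in any follow-up window "
        f"{_PERIOD_WINDOWS}"
    )


@dataclass
class PatientVisit:
    """One patient's survey at one post-operative period.

    ``daily_mme``, ``med_class`` and ``rating`` are derived fields filled
    by :func:`annotate_visit` from the prescriptions, the conversion table
    and the class boundaries.  ``ipa`` may be ``None`` for patients who
    skipped the survey; such visits are excluded from the efficiency-score
    denominator.
    """

    patient_id: str
    period: str
    ipa: int | None
    prescriptions: list[PrescriptionRecord] = field(default_factory=list)
    gender: str | None = None
    age: float | None = None
    procedure: str | None = None
    daily_mme: float | None = None
    med_class: MedicationClass | None = None
    rating: DIPARating | None = None

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValidationError(
                f"period must be one of {PERIODS}, got {self.period!r}"
            )
        if self.ipa is not None and self.ipa not in (0, 1, 2):
            raise ValidationError(f"IPA must be 0, 1, 2 or missing, got {self.ipa}")

    @property
    def has_any_medication(self) -> bool:
        return len(self.prescriptions) > 0

    @property
    def usage_pattern(self) -> str | None:
        """Predominant reported usage among opioid prescriptions, if any."""
        usages = {p.usage for p in self.prescriptions if not p.is_otc}
        if not usages:
            return None
        return "consistent" if "consistent" in usages else "occasional"


@dataclass(frozen=True)
class PeriodSummary:
    """Aggregate scores for one post-operative period."""

    period: str
    n: int
    efficiency_score: float
    pct_on_narcotics: float
    mean_mme: float
    mean_mme_narcotics_only: float
    class_distribution: Mapping[str, float]
    ipa_by_class: Mapping[str, Mapping[int, int]]

    def as_row(self) -> dict:
        row = {
            "period": self.period,
            "n": self.n,
            "efficiency": round(self.efficiency_score, 2),
            "pct_narcotics": round(self.pct_on_narcotics, 2),
            "mean_mme": round(self.mean_mme, 2),
        }
        row.update({f"p{c}": round(self.class_distribution[c], 4) for c in "ABCDE"})
        return row


def efficiency_score(ipa_values: Sequence[int]) -> float:
    """Percentage of IPA responses reporting no or tolerable pain."""
    values = list(ipa_values)
    if not values:
        raise ValidationError("efficiency score is undefined for an empty list")
    if any(v not in (0, 1, 2) for v in values):
        raise ValidationError("IPA values must all be 0, 1 or 2")
    return 100.0 * sum(1 for v in values if v <= 1) / len(values)


def percent_on_narcotics(classes: Sequence[MedicationClass | str]) -> float:
    """Percentage of visits whose medication class is C, D or E."""
    letters = [c.letter if isinstance(c, MedicationClass) else str(c).upper() for c in classes]
    if not letters:
        raise ValidationError("percent on narcotics is undefined for an empty list")
    if any(l not in "ABCDE" for l in letters):
        raise ValidationError(f"unknown class letter in {letters}")
    return 100.0 * sum(1 for l in letters if l in "CDE") / len(letters)


def annotate_visit(
    visit: PatientVisit,
    table: ConversionTable,
    boundaries: ClassBoundaries = OPERATIONAL_BOUNDARIES,
) -> PatientVisit:
    """Fill a visit's derived daily MME, medication class and DIPA rating."""
    mme = compute_daily_mme(visit.prescriptions, table)
    has_opioid = any(
        not p.is_otc
        and (e := table.resolve(p.drug)) is not None
        and e.is_opioid
        and p.doses_per_day > 0
        for p in visit.prescriptions
    )
    med_class = classify_visit(mme, visit.has_any_medication, has_opioid, boundaries)
    visit.daily_mme = mme
    visit.med_class = med_class
    visit.rating = make_dipa_rating(med_class, visit.ipa) if visit.ipa is not None else None
    return visit


def annotate_visits(
    visits: Iterable[PatientVisit],
    table: ConversionTable,
    boundaries: ClassBoundaries = OPERATIONAL_BOUNDARIES,
) -> list[PatientVisit]:
    return [annotate_visit(v, table, boundaries) for v in visits]


def summarize_period(visits: Sequence[PatientVisit]) -> PeriodSummary:
    """Aggregate one period's visits into a :class:`PeriodSummary`.

    The efficiency denominator counts only visits with an IPA response;
    class shares and MME means cover all visits (zeros from classes A/B
    included in ``mean_mme``; ``mean_mme_narcotics_only`` restricts to
    C/D/E visits).
    """
    visits = list(visits)
    if not visits:
        raise ValidationError("cannot summarize an empty period")
    periods = {v.period for v in visits}
    if len(periods) > 1:
        raise ValidationError(f"mixed periods in one summary: {sorted(periods)}")
    if any(v.med_class is None or v.daily_mme is None for v in visits):
        raise ValidationError("visits must be annotated before summarizing")

    period = visits[0].period
    ipa_values = [v.ipa for v in visits if v.ipa is not None]
    classes = [v.med_class for v in visits]
    mmes = np.array([v.daily_mme for v in visits], dtype=float)
    narc_mmes = np.array(
        [v.daily_mme for v in visits if v.med_class.is_narcotic], dtype=float
    )

    n = len(visits)
    dist = {c: sum(1 for mc in classes if mc.letter == c) / n for c in "ABCDE"}
    ipa_by_class: dict[str, dict[int, int]] = {c: {0: 0, 1: 0, 2: 0} for c in "ABCDE"}
    for v in visits:
        if v.ipa is not None:
            ipa_by_class[v.med_class.letter][v.ipa] += 1

    return PeriodSummary(
        period=period,
        n=n,
        efficiency_score=efficiency_score(ipa_values) if ipa_values else float("nan"),
        pct_on_narcotics=percent_on_narcotics(classes),
        mean_mme=float(mmes.mean()),
        mean_mme_narcotics_only=float(narc_mmes.mean()) if narc_mmes.size else 0.0,
        class_distribution=dist,
        ipa_by_class=ipa_by_class,
    )


def summarize_cohort(visits: Iterable[PatientVisit]) -> list[PeriodSummary]:
    """Summaries for every period present, in chronological order."""
    by_period: dict[str, list[PatientVisit]] = {}
    for v in visits:
        by_period.setdefault(v.period, []).append(v)
    return [summarize_period(by_period[p]) for p in PERIODS if p in by_period]
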