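"""Seeded synthetic cohort generator.

Emulates a post-operative orthopedic cohort followed at four clinic
periods (2 weeks, 6 weeks, 3 months, 6 months): 502 patients, 225 male /
277 female, ages 18-87 (mean 50, SD 16), procedures split 210 fracture
fixation / 138 spinal surgery / 154 total joint replacement.

Per period, each visit's medication class is drawn from a configured
A-E distribution; narcotic visits get a daily MME drawn from that class's
truncated normal (C: mean 16.34 on 2.3-30; D: 45.39 on 33.75-67.5;
E: 94.09 on 80-135, SD set so ~99% of mass lies inside the range), and a
concrete prescription list is back-filled so that re-running the MME
engine on the generated prescriptions reproduces the sampled class
exactly.  The IPA response is drawn from the period's satisfaction
probability (chance of reporting IPA <= 1): 62.5% / 80.5% / 75.65% /
60.9% across the four periods.  Narcotic shares decline from 65.2% at two
weeks to 32.6% at six months (intermediate periods interpolated — an
invented default, the intermediate shares are not published).

Class membership and satisfaction are assigned by stratified sampling:
each period's class counts and satisfied counts are apportioned exactly
to the configured proportions (largest-remainder rounding) and then
randomly permuted across patients, so configured marginals are recovered
to rounding precision rather than fluctuating with binomial noise.

Identical seeds yield identical cohorts; the generator never consults
global random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm

from .classification import MedicationClass, OPERATIONAL_BOUNDARIES, classify_visit
from .errors import ValidationError
from .mme import ConversionTable, PrescriptionRecord, compute_daily_mme, load_conversion_table
from .scoring import PERIODS, PatientVisit

__all__ = ["ClassMMEModel", "CohortConfig", "default_config", "generate"]

# z-score such that ~99% of a normal's mass lies within +-z SD
_Z99 = 2.5758293035489004

# candidate (drug, unit strength mg, usage) pools per narcotic class;
# drugs follow the short-acting C/D vs long-acting E split
_CLASS_DRUGS: dict[str, list[tuple[str, float, str]]] = {
    "C": [
        ("hydrocodone", 5.0, "occasional"),
        ("hydrocodone", 7.5, "occasional"),
        ("oxycodone", 5.0, "occasional"),
        ("tramadol", 50.0, "occasional"),
        ("codeine", 30.0, "occasional"),
    ],
    "D": [
        ("hydrocodone", 10.0, "consistent"),
        ("oxycodone", 5.0, "consistent"),
        ("oxycodone", 10.0, "consistent"),
    ],
    "E": [
        ("morphine", 15.0, "consistent"),
        ("morphine", 30.0, "consistent"),
        ("oxycodone", 10.0, "consistent"),
        ("hydromorphone", 4.0, "consistent"),
    ],
}

_OTC_DRUGS = [("ibuprofen", 400.0), ("acetaminophen", 500.0), ("naproxen", 220.0)]


@dataclass(frozen=True)
class ClassMMEModel:
    """Truncated-normal daily-MME model for one narcotic class."""

    mean: float
    low: float
    high: float
    sd: float | None = None  # None: derived so ~99% of mass is in [low, high]

    def __post_init__(self) -> None:
        if not (0 < self.low < self.mean < self.high):
            raise ValidationError(
                f"need 0 < low < mean < high, got {self.low}/{self.mean}/{self.high}"
            )

    @property
    def effective_sd(self) -> float:
        if self.sd is not None:
            return self.sd
        return min(self.mean - self.low, self.high - self.mean) / _Z99

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        sd = self.effective_sd
        a = (self.low - self.mean) / sd
        b = (self.high - self.mean) / sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=sd, size=size, random_state=rng)


@dataclass(frozen=True)
class CohortConfig:
    """Every knob of the synthetic cohort, with study-matched defaults."""

    n_patients: int = 502
    periods: tuple[str, ...] = PERIODS
    class_distribution: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    satisfaction: Mapping[str, float] = field(default_factory=dict)
    ipa_zero_share: float = 0.5  # P(IPA=0 | satisfied); unpublished, configurable
    mme_by_class: Mapping[str, ClassMMEModel] = field(default_factory=dict)
    male_fraction: float = 225 / 502
    age_mean: float = 50.0
    age_sd: float = 16.0
    age_bounds: tuple[float, float] = (18.0, 87.0)
    procedure_weights: Mapping[str, float] = field(
        default_factory=lambda: {"fracture": 210, "spine": 138, "joint": 154}
    )
    attrition: float = 0.0
    cross_sectional: bool = False
    seed: int = 1976

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        if not (0 <= self.ipa_zero_share <= 1) or not (0 <= self.attrition < 1):
            raise ValidationError("probabilities must lie in [0, 1]")
        if not (0 <= self.male_fraction <= 1):
            raise ValidationError("male_fraction must lie in [0, 1]")
        for period in self.periods:
            if period in self.satisfaction and not (0 <= self.satisfaction[period] <= 1):
                raise ValidationError(f"satisfaction[{period}] outside [0, 1]")
            if period in self.class_distribution:
                dist = self.class_distribution[period]
                total = sum(dist.values())
                if abs(total - 1.0) > 1e-9 or any(p < 0 for p in dist.values()):
                    raise ValidationError(
                        f"class distribution for {period} must be a probability "
                        f"vector, sums to {total}"
                    )

    def to_json(self) -> str:
        payload = asdict(self)
        payload["mme_by_class"] = {
            k: asdict(m) for k, m in self.mme_by_class.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        payload = json.loads(text)
        if "mme_by_class" in payload:
            payload["mme_by_class"] = {
                k: ClassMMEModel(**v) for k, v in payload["mme_by_class"].items()
            }
        for key in ("periods", "age_bounds"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


#: within-narcotic class mix C:D:E — the per-period split is not published;
#: chosen once to reflect predominantly occasional short-acting use
_NARC_MIX = {"C": 0.60, "D": 0.30, "E": 0.10}
#: A:B split of medication-free vs OTC-only visits (unpublished)
_NON_NARC_MIX = {"A": 0.5, "B": 0.5}

#: published narcotic shares at the first and last period
_NARC_SHARE_2WK = 0.652
_NARC_SHARE_6MO = 0.326

#: published per-period satisfaction (probability of IPA <= 1)
_SATISFACTION = {"2wk": 0.625, "6wk": 0.805, "3mo": 0.7565, "6mo": 0.609}


def default_config(seed: int = 1976) -> CohortConfig:
    """The study-default cohort configuration.

    Marginals match the published cohort: n=502, per-period satisfaction
    62.5 / 80.5 / 75.65 / 60.9 (%), narcotic share 65.2% at two weeks
    declining linearly (by period index) to 32.6% at six months, class
    MME models from the published means and ranges.
    """
    class_dist: dict[str, dict[str, float]] = {}
    for i, period in enumerate(PERIODS):
        narc = _NARC_SHARE_2WK + (_NARC_SHARE_6MO - _NARC_SHARE_2WK) * i / (len(PERIODS) - 1)
        dist = {c: narc * _NARC_MIX[c] for c in "CDE"}
        dist.update({c: (1 - narc) * _NON_NARC_MIX[c] for c in "AB"})
        class_dist[period] = dist
    return CohortConfig(
        class_distribution=class_dist,
        satisfaction=dict(_SATISFACTION),
        mme_by_class={
            "C": ClassMMEModel(mean=16.34, low=2.3, high=30.0),
            "D": ClassMMEModel(mean=45.39, low=33.75, high=67.5),
            "E": ClassMMEModel(mean=94.09, low=80.0, high=135.0),
        },
        seed=seed,
    )


def _backfill_prescriptions(
    letter: str, target_mme: float, table: ConversionTable, rng: np.random.Generator
) -> tuple[list[PrescriptionRecord], float]:
    """Construct a prescription list whose recomputed MME hits the target.

    Picks one class-appropriate drug and solves doses_per_day so that
    strength x doses x factor equals the sampled MME; a final classify
    check guards against float round-off crossing a class cutoff.
    """
    pool = _CLASS_DRUGS[letter]
    drug, strength, usage = pool[rng.integers(len(pool))]
    factor = table.resolve(drug).factor
    doses = target_mme / (strength * factor)
    rec = PrescriptionRecord(
        drug=drug, strength_mg=strength, doses_per_day=doses, usage=usage
    )
    mme = compute_daily_mme([rec], table)
    if classify_visit(mme, True, True, OPERATIONAL_BOUNDARIES).letter != letter:
        # float round-off landed exactly on a cutoff: nudge inward
        doses *= 1.0 - 1e-9
        rec = PrescriptionRecord(
            drug=drug, strength_mg=strength, doses_per_day=doses, usage=usage
        )
        mme = compute_daily_mme([rec], table)
    return [rec], mme


def _apportion(categories: Sequence[str], probs: np.ndarray, m: int) -> list[int]:
    """Largest-remainder apportionment of m slots to the given proportions."""
    quotas = probs / probs.sum() * m
    counts = np.floor(quotas).astype(int)
    remainder = m - int(counts.sum())
    if remainder > 0:
        # stable tie-break: larger fractional part first, then category order
        order = sorted(
            range(len(categories)), key=lambda j: (-(quotas[j] - counts[j]), j)
        )
        for j in order[:remainder]:
            counts[j] += 1
    return counts.tolist()


def _stratified_labels(
    categories: Sequence[str], probs: np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    counts = _apportion(categories, probs, m)
    labels = np.repeat(np.array(categories, dtype=object), counts)
    return rng.permutation(labels)


def generate(
    config: CohortConfig | None = None,
    table: ConversionTable | None = None,
) -> list[PatientVisit]:
    """Generate the synthetic cohort described by ``config``.

    One visit per patient per period (unless ``cross_sectional`` assigns
    each patient a single period, or ``attrition`` drops later visits).
    Returned visits carry concrete prescription lists; derived fields are
    left unset so the full scoring pipeline can be exercised on them.
    """
    if config is None:
        config = default_config()
    if table is None:
        table = load_conversion_table()
    rng = np.random.default_rng(config.seed)

    n = config.n_patients
    genders = _stratified_labels(
        ["male", "female"],
        np.array([config.male_fraction, 1 - config.male_fraction]),
        n, rng,
    )
    lo, hi = config.age_bounds
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    ages = truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    proc_names = list(config.procedure_weights)
    proc_w = np.array([config.procedure_weights[p] for p in proc_names], dtype=float)
    procedures = _stratified_labels(proc_names, proc_w, n, rng)

    # attendance: which patients show up at which period
    attend: dict[str, list[int]] = {p: [] for p in config.periods}
    for i in range(n):
        if config.cross_sectional:
            attend[config.periods[rng.integers(len(config.periods))]].append(i)
        else:
            for j, period in enumerate(config.periods):
                if config.attrition and j > 0 and rng.random() < config.attrition:
                    continue
                attend[period].append(i)

    width = len(str(n))
    visits_by_key: dict[tuple[int, int], PatientVisit] = {}
    for pi, period in enumerate(config.periods):
        idxs = attend[period]
        m = len(idxs)
        if m == 0:
            continue
        dist = config.class_distribution.get(period)
        if dist is None:
            raise ValidationError(f"no class distribution configured for {period}")
        p_sat = config.satisfaction.get(period)
        if p_sat is None:
            raise ValidationError(f"no satisfaction probability for {period}")

        letters = sorted(dist)
        class_labels = _stratified_labels(
            letters, np.array([dist[l] for l in letters]), m, rng
        )
        sat_labels = _stratified_labels(
            ["sat", "unsat"], np.array([p_sat, 1 - p_sat]), m, rng
        )

        for i, letter, sat in zip(idxs, class_labels, sat_labels):
            prescriptions: list[PrescriptionRecord] = []
            if letter == "B":
                otc_drug, otc_strength = _OTC_DRUGS[rng.integers(len(_OTC_DRUGS))]
                prescriptions.append(
                    PrescriptionRecord(
                        drug=otc_drug, strength_mg=otc_strength,
                        doses_per_day=float(rng.integers(1, 4)),
                        usage="occasional", is_otc=True,
                    )
                )
            elif letter in "CDE":
                model = config.mme_by_class[letter]
                target = float(model.sample(1, rng)[0])
                prescriptions, _ = _backfill_prescriptions(letter, target, table, rng)

            if sat == "sat":
                ipa = 0 if rng.random() < config.ipa_zero_share else 1
            else:
                ipa = 2

            visits_by_key[(i, pi)] = PatientVisit(
                patient_id=f"P{i + 1:0{width}d}",
                period=period,
                ipa=ipa,
                prescriptions=prescriptions,
                gender=str(genders[i]),
                age=float(np.round(ages[i], 1)),
                procedure=str(procedures[i]),
            )
    return [visits_by_key[k] for k in sorted(visits_by_key)]
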