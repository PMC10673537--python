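"""Nonparametric validation battery for the medication-class scheme.

The class scheme was validated with distribution-free tests: Shapiro-Wilk
to check (and reject) normality of per-class MME samples, Kruskal-Wallis
for separation of the narcotic classes C/D/E, Mann-Whitney U for
between-period comparisons, and Spearman rank correlation between the
ordinal class letter (A=0 .. E=4) and the daily MME.  All p-values are
two-sided.  The numerical engines are scipy.stats; this module fixes the
exact variants and packaging of results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .classification import class_to_ordinal
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "TestResult",
    "shapiro_wilk",
    "kruskal_wallis",
    "mann_whitney",
    "spearman_rho",
    "kendall_tau",
    "ipa_by_gender",
    "run_validation_battery",
]

# exact Mann-Whitney null enumeration is tractable and used below this size
EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()
    n_per_group: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value outside [0, 1]: {self.p_value}")
        if any(n <= 0 for n in self.n_per_group):
            raise ValidationError("group sizes must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _clean(sample, name="sample") -> np.ndarray:
    arr = np.asarray(list(sample), dtype=float)
    if arr.size == 0:
        raise ValidationError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def shapiro_wilk(sample: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (W statistic)."""
    arr = _clean(sample)
    if arr.size < 3:
        raise InsufficientDataError(f"Shapiro-Wilk needs n >= 3, got n={arr.size}")
    if np.ptp(arr) == 0:
        raise InsufficientDataError("Shapiro-Wilk undefined for a constant sample")
    res = sps.shapiro(arr)
    return TestResult(
        test_name="shapiro_wilk",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(int(arr.size),),
    )


def kruskal_wallis(*groups: Sequence[float], labels: Sequence[str] | None = None) -> TestResult:
    """Kruskal-Wallis H test with tie correction, chi-square p-value."""
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    arrays = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        # all observations tied: zero separation by definition
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    names = tuple(labels) if labels is not None else tuple(
        f"group{i}" for i in range(len(arrays))
    )
    return TestResult(
        test_name="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        groups=names,
        n_per_group=tuple(int(a.size) for a in arrays),
    )


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Small untied samples (both n <= 8) use the exact null distribution by
    enumeration; larger or tied samples use the normal approximation with
    tie and continuity corrections.
    """
    x = _clean(a, "a")
    y = _clean(b, "b")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    exact = x.size <= EXACT_MW_MAX_N and y.size <= EXACT_MW_MAX_N and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return TestResult(
        test_name="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        groups=("a", "b"),
        n_per_group=(int(x.size), int(y.size)),
        extra={"method": "exact" if exact else "asymptotic"},
    )


def _ranks_or_ordinal(values) -> np.ndarray:
    vals = list(values)
    if vals and isinstance(vals[0], str):
        return np.array([class_to_ordinal(v) for v in vals], dtype=float)
    return np.asarray(vals, dtype=float)


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    Class letters are accepted directly and mapped to ordinal ranks
    A=0 .. E=4 before ranking.
    """
    xv = _ranks_or_ordinal(x)
    yv = _ranks_or_ordinal(y)
    if xv.size != yv.size:
        raise ValidationError(f"length mismatch: {xv.size} vs {yv.size}")
    if xv.size < 3:
        raise InsufficientDataError("Spearman correlation needs n >= 3")
    rho, p = sps.spearmanr(xv, yv)
    return TestResult(
        test_name="spearman_rho",
        statistic=float(rho),
        p_value=float(p),
        n_per_group=(int(xv.size),),
    )


def kendall_tau(x, y) -> TestResult:
    """Kendall tau-b rank correlation (verbose-mode companion to rho)."""
    xv = _ranks_or_ordinal(x)
    yv = _ranks_or_ordinal(y)
    if xv.size != yv.size:
        raise ValidationError(f"length mismatch: {xv.size} vs {yv.size}")
    if xv.size < 3:
        raise InsufficientDataError("Kendall correlation needs n >= 3")
    tau, p = sps.kendalltau(xv, yv)
    return TestResult(
        test_name="kendall_tau",
        statistic=float(tau),
        p_value=float(p),
        n_per_group=(int(xv.size),),
    )


def ipa_by_gender(
    ipa: Sequence[int], gender: Sequence[str], method: str = "mann-whitney"
) -> TestResult:
    """Compare IPA pain tolerability between genders.

    Default is a Mann-Whitney test on the ordinal IPA values split by
    gender; ``method="chi2"`` instead tests the 2x3 gender-by-IPA
    contingency table.
    """
    ipa_arr = np.asarray(list(ipa))
    gen = np.asarray([str(g).lower() for g in gender])
    if ipa_arr.size != gen.size:
        raise ValidationError("ipa and gender must have equal lengths")
    levels = sorted(set(gen))
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 gender levels, got {levels}")
    a = ipa_arr[gen == levels[0]].astype(float)
    b = ipa_arr[gen == levels[1]].astype(float)
    if method == "mann-whitney":
        res = mann_whitney(a, b)
        return TestResult(
            test_name="ipa_by_gender_mw",
            statistic=res.statistic,
            p_value=res.p_value,
            groups=tuple(levels),
            n_per_group=res.n_per_group,
        )
    if method == "chi2":
        table = np.array(
            [[np.sum(x == lvl) for lvl in (0, 1, 2)] for x in (a, b)], dtype=float
        )
        chi2, p, _, _ = sps.chi2_contingency(table[:, table.sum(axis=0) > 0])
        return TestResult(
            test_name="ipa_by_gender_chi2",
            statistic=float(chi2),
            p_value=float(p),
            groups=tuple(levels),
            n_per_group=(int(a.size), int(b.size)),
        )
    raise ValidationError(f"unknown method {method!r}")


def run_validation_battery(visits, verbose: bool = False) -> list[TestResult]:
    """Run the full statistical battery on an annotated cohort.

    Covers per-class MME normality (Shapiro-Wilk), C/D/E separation
    (Kruskal-Wallis), first-vs-last-period narcotic share (Mann-Whitney on
    the binary on-narcotics indicator), and the class-vs-MME and
    frequency-vs-MME rank correlations.
    """
    from .scoring import PERIODS  # deferred: avoid import cycle

    visits = list(visits)
    if any(v.med_class is None for v in visits):
        raise ValidationError("visits must be annotated before validation")
    results: list[TestResult] = []

    by_class: dict[str, list[float]] = {}
    for v in visits:
        if v.med_class.is_narcotic:
            by_class.setdefault(v.med_class.letter, []).append(v.daily_mme)

    for letter in sorted(by_class):
        sample = by_class[letter]
        if len(sample) >= 3 and np.ptp(sample) > 0:
            res = shapiro_wilk(sample)
            results.append(
                TestResult(
                    test_name=f"shapiro_wilk_class_{letter}",
                    statistic=res.statistic, p_value=res.p_value,
                    groups=(letter,), n_per_group=res.n_per_group,
                )
            )

    if len(by_class) >= 2:
        letters = sorted(by_class)
        results.append(
            kruskal_wallis(*(by_class[l] for l in letters), labels=letters)
        )

    present = [p for p in PERIODS if any(v.period == p for v in visits)]
    if len(present) >= 2:
        first, last = present[0], present[-1]
        ind_first = [float(v.med_class.is_narcotic) for v in visits if v.period == first]
        ind_last = [float(v.med_class.is_narcotic) for v in visits if v.period == last]
        res = mann_whitney(ind_first, ind_last)
        results.append(
            TestResult(
                test_name=f"mann_whitney_narcotics_{first}_vs_{last}",
                statistic=res.statistic, p_value=res.p_value,
                groups=(first, last), n_per_group=res.n_per_group,
                extra=res.extra,
            )
        )

    letters_all = [v.med_class.letter for v in visits]
    mmes_all = [v.daily_mme for v in visits]
    res = spearman_rho(letters_all, mmes_all)
    results.append(
        TestResult(
            test_name="spearman_class_vs_mme",
            statistic=res.statistic, p_value=res.p_value,
            n_per_group=res.n_per_group,
        )
    )
    freqs = [
        sum(p.doses_per_day for p in v.prescriptions if not p.is_otc)
        for v in visits
    ]
    res = spearman_rho(freqs, mmes_all)
    results.append(
        TestResult(
            test_name="spearman_frequency_vs_mme",
            statistic=res.statistic, p_value=res.p_value,
            n_per_group=res.n_per_group,
        )
    )
    if verbose:
        res = kendall_tau(letters_all, mmes_all)
        results.append(
            TestResult(
                test_name="kendall_class_vs_mme",
                statistic=res.statistic, p_value=res.p_value,
                n_per_group=res.n_per_group,
            )
        )
    genders = {v.gender for v in visits if v.gender}
    if len(genders) == 2:
        surveyed = [v for v in visits if v.ipa is not None and v.gender]
        if surveyed:
            results.append(
                ipa_by_gender(
                    [v.ipa for v in surveyed], [v.gender for v in surveyed]
                )
            )
    return results
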