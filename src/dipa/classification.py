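"""A-E medication classes, DIPA ratings, and cluster-derived boundaries.

The five-class scheme summarizes a patient's analgesic regimen at a visit:

* **A** — no pain medication (0 MME)
* **B** — over-the-counter medication only (0 MME)
* **C** — occasional short-acting narcotics, daily MME in (0, 30]
* **D** — consistent short-acting narcotics, daily MME in (30, 80)
* **E** — long-acting or stronger narcotics, daily MME >= 80

C/D/E cutoffs come either from the operational defaults above (continuous
half-open intervals covering all positive reals, consistent with the
integer guide "1-30 / 31-79 / 80+") or from clustering observed narcotic
MME values: a hierarchical (Ward) pass proposes the cluster count, K-means
fixes the centers, and each cluster's observed extreme values become the
cutoff points.

A DIPA rating pairs the class letter with the three-level IPA pain report
(0 no pain, 1 tolerable, 2 intolerable): occasional short-acting narcotics
with tolerable pain is "C1".
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import DegenerateDataError, InconsistentVisitError, ValidationError

__all__ = [
    "MedicationClass",
    "ClassBoundaries",
    "OPERATIONAL_BOUNDARIES",
    "DIPARating",
    "ClusteringResult",
    "classify_visit",
    "make_dipa_rating",
    "parse_dipa_rating",
    "derive_boundaries",
    "class_to_ordinal",
]

DEFAULT_CLUSTER_SEED = 1976


class MedicationClass(enum.IntEnum):
    """Ordered medication classes A < B < C < D < E."""

    A = 0
    B = 1
    C = 2
    D = 3
    E = 4

    @property
    def letter(self) -> str:
        return self.name

    @property
    def description(self) -> str:
        return _DESCRIPTIONS[self]

    @property
    def is_narcotic(self) -> bool:
        return self >= MedicationClass.C


_DESCRIPTIONS = {
    MedicationClass.A: "no pain medication",
    MedicationClass.B: "over-the-counter medication only",
    MedicationClass.C: "occasional use of short-acting narcotics",
    MedicationClass.D: "consistent use of short-acting narcotics",
    MedicationClass.E: "long-acting or stronger narcotics",
}


def class_to_ordinal(letter: str | MedicationClass) -> int:
    """Map a class letter to its ordinal rank A=0 .. E=4."""
    if isinstance(letter, MedicationClass):
        return int(letter)
    return int(MedicationClass[letter.upper()])


@dataclass(frozen=True)
class ClassBoundaries:
    """MME cutoffs for the narcotic classes C/D/E.

    Classification uses ``c_high`` and ``e_min`` only: MME in (0, c_high]
    is C, [e_min, inf) is E, and anything between is D — so cluster-derived
    boundaries with a gap between observed ranges still partition the
    positive reals.  ``c_low``/``d_low``/``d_high`` record the observed (or
    nominal) interval edges for reporting.
    """

    c_low: float = 0.0
    c_high: float = 30.0
    d_low: float = 30.0
    d_high: float = 80.0
    e_min: float = 80.0
    source: str = "operational_default"
    seed: int | None = None
    table_version: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.c_low <= self.c_high <= self.d_low <= self.d_high <= self.e_min):
            raise ValidationError(
                "class boundaries must be ordered 0 <= c_low <= c_high <= "
                f"d_low <= d_high <= e_min, got {self}"
            )
        if self.c_high <= 0:
            raise ValidationError("c_high must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClassBoundaries":
        return cls(**json.loads(text))


OPERATIONAL_BOUNDARIES = ClassBoundaries()


@dataclass(frozen=True)
class DIPARating:
    """Medication class letter paired with the IPA pain digit, e.g. C1."""

    med_class: MedicationClass
    ipa: int

    def __post_init__(self) -> None:
        if self.ipa not in (0, 1, 2):
            raise ValidationError(f"IPA score must be 0, 1 or 2, got {self.ipa}")

    @property
    def code(self) -> str:
        return f"{self.med_class.letter}{self.ipa}"

    def __str__(self) -> str:
        return self.code


def make_dipa_rating(med_class: MedicationClass | str, ipa: int) -> DIPARating:
    """Combine a medication class and an IPA score into a DIPA rating."""
    if isinstance(med_class, str):
        try:
            med_class = MedicationClass[med_class.upper()]
        except KeyError:
            raise ValidationError(f"unknown medication class {med_class!r}") from None
    return DIPARating(med_class=med_class, ipa=int(ipa))


def parse_dipa_rating(code: str) -> DIPARating:
    """Inverse of ``DIPARating.code`` ("C1" -> class C, IPA 1)."""
    code = code.strip().upper()
    if len(code) != 2 or code[0] not in "ABCDE" or code[1] not in "012":
        raise ValidationError(f"malformed DIPA code {code!r}")
    return DIPARating(MedicationClass[code[0]], int(code[1]))


def classify_visit(
    daily_mme: float,
    has_any_medication: bool,
    has_opioid: bool,
    boundaries: ClassBoundaries = OPERATIONAL_BOUNDARIES,
) -> MedicationClass:
    """Assign the A-E class for one visit.

    Zero MME splits on medication presence (A vs B); positive MME falls in
    exactly one narcotic class.  An opioid flag with zero MME (or MME with
    no opioid) is a data inconsistency, not a classifiable state.
    """
    if daily_mme < 0 or not np.isfinite(daily_mme):
        raise ValidationError(f"daily MME must be finite and >= 0, got {daily_mme}")
    if has_opioid and not has_any_medication:
        raise ValidationError("has_opioid implies has_any_medication")
    if daily_mme == 0:
        if has_opioid:
            raise InconsistentVisitError("opioid present but daily MME is 0")
        return MedicationClass.B if has_any_medication else MedicationClass.A
    if not has_opioid:
        raise InconsistentVisitError("daily MME > 0 but no opioid flagged")
    if daily_mme <= boundaries.c_high:
        return MedicationClass.C
    if daily_mme >= boundaries.e_min:
        return MedicationClass.E
    return MedicationClass.D


@dataclass(frozen=True)
class ClusteringResult:
    """K-means outcome on narcotic MME values.

    ``centers`` are sorted ascending; ``extremes`` holds each cluster's
    observed (min, max); ``assignments`` gives the cluster index (in
    center order) of each input value, in input order.
    """

    k: int
    centers: tuple[float, ...]
    extremes: tuple[tuple[float, float], ...]
    assignments: tuple[int, ...]

    def __post_init__(self) -> None:
        if list(self.centers) != sorted(self.centers) or len(set(self.centers)) != len(self.centers):
            raise ValidationError("cluster centers must be strictly increasing")


def _auto_k(values: np.ndarray, k_range=range(2, 7), seed: int = DEFAULT_CLUSTER_SEED) -> int:
    """Propose the cluster count by Ward-linkage cuts scored by silhouette."""
    x = values.reshape(-1, 1)
    z = linkage(x, method="ward")
    best_k, best_score = 2, -np.inf
    n_distinct = len(np.unique(values))
    for k in k_range:
        if k >= len(values) or k > n_distinct:
            break
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(x, labels)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def derive_boundaries(
    narcotic_mmes,
    k: int | str = "auto",
    seed: int = DEFAULT_CLUSTER_SEED,
    n_init: int = 10,
    table_version: str | None = None,
) -> tuple[ClusteringResult, ClassBoundaries | None]:
    """Derive narcotic class cutoffs by clustering observed daily MMEs.

    Hierarchical clustering (Ward linkage, Euclidean distance) proposes the
    cluster count when ``k="auto"`` (searching k in 2..6 by silhouette);
    K-means with ``n_init`` restarts then fixes the centers.  Each
    cluster's observed min/max become the cutoff points.  Values are
    sorted internally, so the result is invariant to input order, and the
    seed makes it reproducible.

    Returns the clustering result and, when exactly three clusters are
    found (the C/D/E scheme), cluster-derived ``ClassBoundaries``;
    otherwise boundaries are ``None``.
    """
    values = np.asarray(list(narcotic_mmes), dtype=float)
    if values.size == 0:
        raise ValidationError("cannot derive boundaries from an empty sample")
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValidationError("narcotic MMEs must be finite and > 0")

    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]

    if k == "auto":
        if len(np.unique(values)) < 2:
            raise DegenerateDataError("auto-k needs at least 2 distinct values")
        k = _auto_k(sorted_vals, seed=seed)
    k = int(k)
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if len(np.unique(values)) < k:
        raise DegenerateDataError(
            f"need at least {k} distinct values for k={k}, "
            f"got {len(np.unique(values))}"
        )

    if k == 1:
        labels_sorted = np.zeros(values.size, dtype=int)
        centers = np.array([sorted_vals.mean()])
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        raw_labels = km.fit_predict(sorted_vals.reshape(-1, 1))
        raw_centers = km.cluster_centers_.ravel()
        rank = np.argsort(raw_centers)          # raw label -> ascending-center index
        relabel = np.empty_like(rank)
        relabel[rank] = np.arange(k)
        labels_sorted = relabel[raw_labels]
        centers = raw_centers[rank]

    assignments = np.empty(values.size, dtype=int)
    assignments[order] = labels_sorted
    extremes = tuple(
        (float(sorted_vals[labels_sorted == j].min()),
         float(sorted_vals[labels_sorted == j].max()))
        for j in range(k)
    )
    result = ClusteringResult(
        k=k,
        centers=tuple(float(c) for c in centers),
        extremes=extremes,
        assignments=tuple(int(a) for a in assignments),
    )

    boundaries = None
    if k == 3:
        boundaries = ClassBoundaries(
            c_low=extremes[0][0],
            c_high=extremes[0][1],
            d_low=extremes[1][0],
            d_high=extremes[1][1],
            e_min=extremes[2][0],
            source="cluster_derived",
            seed=seed,
            table_version=table_version,
        )
    return result, boundaries
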