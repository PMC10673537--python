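"""A-E classification, DIPA ratings, and cluster-derived boundaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dipa.classification import (
    ClassBoundaries,
    MedicationClass,
    OPERATIONAL_BOUNDARIES,
    classify_visit,
    derive_boundaries,
    make_dipa_rating,
    parse_dipa_rating,
)
from dipa.cohort import ClassMMEModel
from dipa.errors import (
    DegenerateDataError,
    InconsistentVisitError,
    ValidationError,
)


class TestClassifyVisit:
    @pytest.mark.parametrize(
        "mme, has_med, has_opioid, expected",
        [
            (0, False, False, "A"),
            (0, True, False, "B"),
            (20, True, True, "C"),
            (45, True, True, "D"),
            (94, True, True, "E"),
            (30, True, True, "C"),   # upper cutoff inclusive for C
            (80, True, True, "E"),   # lower cutoff inclusive for E
            (30.0001, True, True, "D"),
            (79.9999, True, True, "D"),
            (0.5, True, True, "C"),
            (1e6, True, True, "E"),
        ],
    )
    def test_operational_cutoffs(self, mme, has_med, has_opioid, expected):
        assert classify_visit(mme, has_med, has_opioid).letter == expected

    def test_opioid_with_zero_mme_is_inconsistent(self):
        with pytest.raises(InconsistentVisitError):
            classify_visit(0, True, True)

    def test_positive_mme_without_opioid_is_inconsistent(self):
        with pytest.raises(InconsistentVisitError):
            classify_visit(10, True, False)

    def test_negative_mme_rejected(self):
        with pytest.raises(ValidationError):
            classify_visit(-1, False, False)

    def test_opioid_implies_medication(self):
        with pytest.raises(ValidationError):
            classify_visit(10, False, True)

    @given(m1=st.floats(0.01, 500), m2=st.floats(0.01, 500))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_mme_for_narcotic_users(self, m1, m2):
        lo, hi = sorted((m1, m2))
        assert classify_visit(lo, True, True) <= classify_visit(hi, True, True)

    @given(mme=st.floats(0.001, 1000, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_partition_exactly_one_narcotic_class(self, mme):
        cls = classify_visit(mme, True, True)
        b = OPERATIONAL_BOUNDARIES
        in_c = 0 < mme <= b.c_high
        in_d = b.c_high < mme < b.e_min
        in_e = mme >= b.e_min
        assert [in_c, in_d, in_e].count(True) == 1
        assert cls.letter == "CDE"[[in_c, in_d, in_e].index(True)]


class TestDIPARating:
    @pytest.mark.parametrize(
        "letter, ipa, code", [("C", 1, "C1"), ("A", 0, "A0"), ("E", 2, "E2")]
    )
    def test_code_concatenation(self, letter, ipa, code):
        assert make_dipa_rating(letter, ipa).code == code

    def test_round_trips_through_parse(self):
        for letter, ipa in itertools.product("ABCDE", (0, 1, 2)):
            rating = make_dipa_rating(letter, ipa)
            assert parse_dipa_rating(rating.code) == rating

    @pytest.mark.parametrize("bad_ipa", [-1, 3, 5])
    def test_ipa_out_of_range_rejected(self, bad_ipa):
        with pytest.raises(ValidationError):
            make_dipa_rating("C", bad_ipa)

    def test_malformed_code_rejected(self):
        with pytest.raises(ValidationError):
            parse_dipa_rating("F1")
        with pytest.raises(ValidationError):
            parse_dipa_rating("C3")


class TestBoundaries:
    def test_json_round_trip(self):
        b = ClassBoundaries(
            c_low=2.3, c_high=30, d_low=33.75, d_high=67.5, e_min=80,
            source="cluster_derived", seed=1976, table_version="cdc-oral-v1",
        )
        assert ClassBoundaries.from_json(b.to_json()) == b

    def test_misordered_boundaries_rejected(self):
        with pytest.raises(ValidationError):
            ClassBoundaries(c_high=80, d_low=30, d_high=60, e_min=90)

    def test_operational_intervals_are_disjoint_and_ordered(self):
        b = OPERATIONAL_BOUNDARIES
        assert 0 <= b.c_low < b.c_high <= b.d_low <= b.d_high <= b.e_min


def kmeans2_oracle(values):
    """Brute-force optimal 2-partition by enumerating contiguous splits.

    In one dimension the K-means optimum is a contiguous partition of the
    sorted values, so enumerating split points finds the global optimum.
    """
    xs = np.sort(np.asarray(values, dtype=float))
    best = None
    for cut in range(1, len(xs)):
        left, right = xs[:cut], xs[cut:]
        ss = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if best is None or ss < best[0]:
            best = (ss, left.mean(), right.mean())
    return best[1], best[2]


class TestDeriveBoundaries:
    def test_two_point_masses_match_enumeration_oracle(self):
        data = [10, 10, 10, 100, 100, 100]
        result, _ = derive_boundaries(data, k=2)
        assert result.centers == pytest.approx(kmeans2_oracle(data))
        assert result.extremes == ((10.0, 10.0), (100.0, 100.0))

    def test_random_k2_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        data = np.concatenate([rng.normal(5, 1, 30), rng.normal(50, 4, 30)])
        result, _ = derive_boundaries(data, k=2)
        assert result.centers == pytest.approx(kmeans2_oracle(data))

    def test_k1_degenerate_case(self):
        data = [4.0, 5.0, 6.0]
        result, boundaries = derive_boundaries(data, k=1)
        assert result.centers == (pytest.approx(5.0),)
        assert result.extremes == ((4.0, 6.0),)
        assert boundaries is None

    def test_three_cluster_recovery_from_class_models(self):
        rng = np.random.default_rng(5)
        models = {
            "C": ClassMMEModel(16.34, 2.3, 30.0),
            "D": ClassMMEModel(45.39, 33.75, 67.5),
            "E": ClassMMEModel(94.09, 80.0, 135.0),
        }
        n = 200
        samples = {c: m.sample(n, rng) for c, m in models.items()}
        pooled = np.concatenate(list(samples.values()))
        result, boundaries = derive_boundaries(pooled, k=3)
        for center, model in zip(result.centers, models.values()):
            se = model.effective_sd / np.sqrt(n)
            assert abs(center - model.mean) <= 3 * se
        assert boundaries is not None
        assert boundaries.source == "cluster_derived"
        # derived cutoffs classify >= 99% of points back to their source class
        labels = np.repeat([2, 3, 4], n)  # C, D, E ordinals
        relabeled = np.array(
            [int(classify_visit(v, True, True, boundaries)) for v in pooled]
        )
        assert (relabeled == labels).mean() >= 0.99

    def test_auto_k_finds_three_separated_clusters(self):
        rng = np.random.default_rng(2)
        data = np.concatenate(
            [rng.normal(15, 3, 80), rng.normal(45, 5, 80), rng.normal(95, 8, 80)]
        )
        data = np.clip(data, 1, None)
        result, _ = derive_boundaries(data, k="auto")
        assert result.k == 3

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        data = np.concatenate([rng.normal(10, 2, 40), rng.normal(60, 5, 40)])
        r1, _ = derive_boundaries(data, k=2)
        r2, _ = derive_boundaries(rng.permutation(data), k=2)
        assert r1.centers == pytest.approx(r2.centers)
        assert r1.extremes == r2.extremes

    def test_assignments_cover_every_input_once(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(1, 100, 50)
        result, _ = derive_boundaries(data, k=3)
        assert len(result.assignments) == 50
        assert set(result.assignments) == {0, 1, 2}
        for j, (lo, hi) in enumerate(result.extremes):
            members = data[np.array(result.assignments) == j]
            assert members.min() == pytest.approx(lo)
            assert members.max() == pytest.approx(hi)

    def test_errors_on_degenerate_input(self):
        with pytest.raises(ValidationError):
            derive_boundaries([])
        with pytest.raises(DegenerateDataError):
            derive_boundaries([5.0, 5.0, 5.0], k=2)
        with pytest.raises(ValidationError):
            derive_boundaries([-1.0, 2.0], k=2)
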