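"""Cohort table, specimen aggregation, ratios, association, probabilities."""

import numpy as np
import pytest

from fwrnet.cohort import (
    AssociationResult,
    PatientRecord,
    RatioResult,
    SpecimenMetrics,
    aggregate_specimen,
    load_cohort_table,
    sign_test_pvalue,
    subgroup_association,
    survival_range_probability,
    tumor_biopsy_ratios,
)
from fwrnet.errors import (
    CohortValidationError,
    DegenerateRatioError,
    EmptyDenominatorError,
    EmptySpecimenError,
    GroupTooSmallError,
    UndefinedCorrelationError,
    UnpairedPatientError,
)
from fwrnet.metrics import NetworkMetrics


def make_metrics(cc, cp):
    return NetworkMetrics(CC=cc, CP=cp, n_nodes=10)


class TestCohortTable:
    def test_packaged_table_has_25_records(self):
        assert len(load_cohort_table()) == 25

    def test_survival_groups_split_11_14(self):
        records = load_cohort_table()
        shorter = [r for r in records if 15 <= r.survival_months <= 75]
        longer = [r for r in records if 101 <= r.survival_months <= 288]
        assert len(shorter) == 11
        assert len(longer) == 14
        assert all(r.group == "shorter" for r in shorter)
        assert all(r.group == "longer" for r in longer)

    def test_survival_median_and_range(self):
        surv = [r.survival_months for r in load_cohort_table()]
        assert np.median(surv) == 101
        assert (min(surv), max(surv)) == (15, 288)

    def test_loads_from_explicit_path(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "patient_id,disease_free_months,recurrence,survival_months,"
            "ihc_tumor,ihc_biopsy\nA,5,yes,50,2,3\n"
        )
        recs = load_cohort_table(p)
        assert recs[0].patient_id == "A"
        assert recs[0].recurrence is True

    def test_out_of_range_ihc_score_names_row(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "patient_id,disease_free_months,recurrence,survival_months,"
            "ihc_tumor,ihc_biopsy\nA,5,yes,50,4,3\n"
        )
        with pytest.raises(CohortValidationError, match="row 0"):
            load_cohort_table(p)

    def test_negative_months_rejected(self):
        with pytest.raises(CohortValidationError):
            PatientRecord("X", -1, True, 50, 2, 2)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("patient_id,survival_months\nA,50\n")
        with pytest.raises(CohortValidationError, match="missing columns"):
            load_cohort_table(p)

    def test_between_boundary_survival_warns(self):
        rec = PatientRecord("X", 10, True, 90, 2, 2)
        with pytest.warns(UserWarning, match="between the group boundaries"):
            assert rec.group is None


class TestAggregateSpecimen:
    def test_mean_of_two_tiles(self):
        s = aggregate_specimen(
            [make_metrics(0.2, 1.0), make_metrics(0.4, 2.0)], "P1", "biopsy"
        )
        assert s.mean_CC == pytest.approx(0.3)
        assert s.mean_CP == pytest.approx(1.5)
        assert s.n_tiles_used == 2

    def test_single_tile_identity(self):
        s = aggregate_specimen([make_metrics(0.7, 3.0)], "P1", "primary_tumor")
        assert (s.mean_CC, s.mean_CP) == (0.7, 3.0)

    def test_empty_specimen_errors(self):
        with pytest.raises(EmptySpecimenError):
            aggregate_specimen([], "P1", "biopsy")

    def test_mean_of_many_noisy_tiles_near_truth(self, rng):
        ccs = rng.normal(0.5, 0.05, size=100)
        tiles = [make_metrics(c, 1.0) for c in ccs]
        s = aggregate_specimen(tiles, "P1", "biopsy")
        se = 0.05 / np.sqrt(100)
        assert abs(s.mean_CC - 0.5) < 3 * se + abs(ccs.mean() - 0.5)


class TestRatios:
    def pair(self, pid, cc_b, cp_b, cc_t, cp_t):
        return [
            SpecimenMetrics(pid, "biopsy", cc_b, cp_b, 1),
            SpecimenMetrics(pid, "primary_tumor", cc_t, cp_t, 1),
        ]

    def test_equal_metrics_give_unit_ratio(self):
        res = tumor_biopsy_ratios(self.pair("P1", 0.3, 1.0, 0.3, 1.0))
        assert res[0].cc_ratio == pytest.approx(1.0)

    def test_cp_ratio_two(self):
        res = tumor_biopsy_ratios(self.pair("P1", 0.3, 0.6, 0.3, 1.2))
        assert res[0].cp_ratio == pytest.approx(2.0)

    def test_order_invariance(self):
        specs = self.pair("P1", 0.3, 1.0, 0.6, 2.0) + self.pair("P2", 0.5, 1.0, 0.5, 1.0)
        fwd = {r.patient_id: r.cc_ratio for r in tumor_biopsy_ratios(specs)}
        rev = {r.patient_id: r.cc_ratio for r in tumor_biopsy_ratios(specs[::-1])}
        assert fwd == rev

    def test_missing_pair_errors(self):
        with pytest.raises(UnpairedPatientError):
            tumor_biopsy_ratios([SpecimenMetrics("P1", "biopsy", 0.3, 1.0, 1)])

    def test_duplicate_specimen_errors(self):
        specs = self.pair("P1", 0.3, 1.0, 0.3, 1.0)
        specs.append(SpecimenMetrics("P1", "biopsy", 0.4, 1.0, 1))
        with pytest.raises(UnpairedPatientError):
            tumor_biopsy_ratios(specs)

    def test_zero_biopsy_metric_errors(self):
        with pytest.raises(DegenerateRatioError):
            tumor_biopsy_ratios(self.pair("P1", 0.0, 1.0, 0.3, 1.0))


class TestSubgroupAssociation:
    def test_linear_relationship_gives_r_one(self):
        x = np.arange(5, dtype=float)
        res = subgroup_association(x, 10 + 3 * x)
        assert res.R == pytest.approx(1.0)

    @pytest.mark.parametrize("n,expected", [(11, 9.7656e-04), (14, 1.2207e-04)])
    def test_sign_test_closed_forms(self, n, expected):
        assert sign_test_pvalue(n) == pytest.approx(expected, rel=1e-4)
        assert sign_test_pvalue(n) == 2 * 0.5**n

    def test_association_reports_group_size_p(self, rng):
        x = rng.random(11)
        y = rng.random(11)
        res = subgroup_association(x, y)
        assert isinstance(res, AssociationResult)
        assert res.n == 11
        assert res.p == sign_test_pvalue(11)

    def test_mask_selects_subgroup(self, rng):
        x = np.arange(10, dtype=float)
        y = 2 * x
        mask = x < 5
        res = subgroup_association(x, y, mask)
        assert res.n == 5
        assert res.R == pytest.approx(1.0)

    def test_group_too_small(self):
        with pytest.raises(GroupTooSmallError):
            subgroup_association([1.0, 2.0], [3.0, 4.0])

    def test_constant_ratios_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            subgroup_association([1.0, 1.0, 1.0], [3.0, 4.0, 5.0])


class TestSurvivalRangeProbability:
    @staticmethod
    def build(ratio_surv_pairs):
        """ratio_surv_pairs: list of (cc_ratio, survival_months)."""
        ratios, cohort = [], []
        for i, (r, s) in enumerate(ratio_surv_pairs):
            pid = f"P{i}"
            ratios.append(RatioResult(pid, cc_ratio=r, cp_ratio=r))
            cohort.append(PatientRecord(pid, 0, True, s, 2, 2))
        return ratios, cohort

    def test_eleven_of_fifteen(self):
        pairs = [(1.0, 150)] * 11 + [(1.0, 50)] * 4 + [(2.0, 150)] * 3
        ratios, cohort = self.build(pairs)
        k, n, p = survival_range_probability(
            ratios, "cc_ratio", (0.97, 1.05), (101, 288), cohort
        )
        assert (k, n) == (11, 15)
        assert p == pytest.approx(0.7333, abs=5e-5)

    def test_seven_of_nine(self):
        pairs = [(1.0, 200)] * 7 + [(1.0, 50)] * 2 + [(3.0, 200)] * 4
        ratios, cohort = self.build(pairs)
        k, n, p = survival_range_probability(
            ratios, "cp_ratio", (0.99, 1.10), (126, 288), cohort
        )
        assert (k, n) == (7, 9)
        assert p == pytest.approx(0.7778, abs=5e-5)

    def test_all_patients_in_both_ranges(self):
        ratios, cohort = self.build([(1.0, 150)] * 6)
        _, _, p = survival_range_probability(
            ratios, "cc_ratio", (0.0, 2.0), (0, 300), cohort
        )
        assert p == 1.0

    def test_patient_order_invariance(self):
        pairs = [(1.0, 150), (1.02, 50), (1.04, 120), (2.0, 90)]
        ratios, cohort = self.build(pairs)
        a = survival_range_probability(ratios, "cc_ratio", (0.97, 1.05), (101, 288), cohort)
        b = survival_range_probability(
            ratios[::-1], "cc_ratio", (0.97, 1.05), (101, 288), cohort[::-1]
        )
        assert a == b

    def test_monotone_in_survival_upper_bound(self):
        pairs = [(1.0, s) for s in (50, 100, 150, 200, 250)]
        ratios, cohort = self.build(pairs)
        last_k = -1
        for hi in (60, 120, 180, 260):
            k, _, _ = survival_range_probability(
                ratios, "cc_ratio", (0.9, 1.1), (0, hi), cohort
            )
            assert k >= last_k
            last_k = k

    def test_empty_denominator_errors(self):
        ratios, cohort = self.build([(2.0, 150)])
        with pytest.raises(EmptyDenominatorError):
            survival_range_probability(
                ratios, "cc_ratio", (0.97, 1.05), (101, 288), cohort
            )
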