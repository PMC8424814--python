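"""Consolidation scores, provider rates and the per-admission collapse."""

import numpy as np
import pytest

from cpinet import (
    ProviderRates,
    Status,
    compute_provider_rates,
    compute_scores,
    consolidate_admission,
    consolidate_dataset,
    default_config,
    generate,
)

from conftest import make_admission, make_cpi


def rates_for(pharm="CP1", physician="MD1", success=1.0, rejection=0.0):
    return ProviderRates(pharmacist_success={pharm: success},
                         physician_rejection={physician: rejection})


class TestProviderRates:
    def test_study_scale_success_rate(self):
        cpis = [make_cpi(admission=f"A{i}", order=1, accepted=i < 147,
                         pharmacist="CP1") for i in range(256)]
        rates = compute_provider_rates(cpis)
        assert rates.pharmacist_success["CP1"] == pytest.approx(147 / 256)

    def test_perfect_pharmacist(self):
        cpis = [make_cpi(order=i + 1, accepted=True) for i in range(10)]
        assert compute_provider_rates(cpis).pharmacist_success["CP1"] == 1.0

    def test_physician_rejection_rate(self):
        cpis = [make_cpi(order=i + 1, accepted=i != 0) for i in range(4)]
        assert compute_provider_rates(cpis).physician_rejection["MD1"] == 0.25

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            compute_provider_rates([])


class TestScores:
    def test_complexity_mean(self):
        cpis = [make_cpi(order=1, complexity_code=1.0),
                make_cpi(order=2, complexity_code=0.0),
                make_cpi(order=3, complexity_code=0.5)]
        s = compute_scores(cpis, rates_for())
        assert s.problem_complexity == pytest.approx(0.5)

    def test_rejection_fraction(self):
        cpis = [make_cpi(order=i + 1, accepted=i > 0) for i in range(4)]
        s = compute_scores(cpis, rates_for())
        assert s.rejection == pytest.approx(0.25)

    def test_combined_cp_success_is_mean_of_provider_rates(self):
        cpis = [make_cpi(order=1, pharmacist="A"), make_cpi(order=2, pharmacist="B")]
        rates = ProviderRates(pharmacist_success={"A": 0.9, "B": 0.5},
                              physician_rejection={"MD1": 0.0})
        assert compute_scores(cpis, rates).combined_cp_success == pytest.approx(0.7)

    def test_diagnosis_revision_fraction(self):
        s = compute_scores([make_cpi()], rates_for(),
                           diagnoses=(("a", True), ("b", False), ("c", False)))
        assert s.diagnosis_revision == pytest.approx(1 / 3)

    def test_missing_provider_is_an_error(self):
        with pytest.raises(KeyError, match="CP1"):
            compute_scores([make_cpi()], rates_for(pharm="OTHER"))

    def test_mixed_admissions_rejected(self):
        with pytest.raises(ValueError, match="multiple admissions"):
            compute_scores([make_cpi(), make_cpi(admission="A2")], rates_for())

    def test_score_order_invariance(self):
        cpis = [make_cpi(order=i + 1, accepted=i % 2 == 0,
                         complexity_code=[0.0, 0.5, 1.0][i % 3]) for i in range(6)]
        fwd = compute_scores(cpis, rates_for())
        rev = compute_scores(list(reversed(cpis)), rates_for())
        assert fwd == rev


class TestConsolidateAdmission:
    def test_mixed_admission_yields_two_records(self):
        adm = make_admission()
        cpis = [make_cpi(order=i + 1, accepted=i < 3) for i in range(5)]
        recs = consolidate_admission(cpis, adm, rates_for(success=0.6, rejection=0.4))
        assert sorted(r.status.value for r in recs) == ["accepted", "rejected"]
        assert all(r.total_cpi == 5 for r in recs)

    def test_accepted_only_admission(self):
        adm = make_admission()
        cpis = [make_cpi(order=i + 1) for i in range(3)]
        recs = consolidate_admission(cpis, adm, rates_for())
        assert len(recs) == 1
        assert recs[0].status is Status.ACCEPTED
        assert recs[0].scores.rejection == 0.0

    def test_type_flags_aggregate_by_or(self):
        adm = make_admission()
        flags = [dict.fromkeys(make_cpi().type_flags, False) for _ in range(3)]
        flags[0]["change_dose"] = True
        cpis = [make_cpi(order=i + 1, type_flags=f) for i, f in enumerate(flags)]
        recs = consolidate_admission(cpis, adm, rates_for())
        assert recs[0].type_flags["change_dose"] is True
        assert recs[0].type_flags["change_route"] is False

    def test_score_scope_switch(self):
        adm = make_admission()
        cpis = [make_cpi(order=1, accepted=True, complexity_code=0.0),
                make_cpi(order=2, accepted=False, complexity_code=1.0)]
        rates = rates_for(success=0.5, rejection=0.5)
        mixed = consolidate_admission(cpis, adm, rates, score_scope="mixed")
        admission = consolidate_admission(cpis, adm, rates, score_scope="admission")
        acc_mixed = next(r for r in mixed if r.status is Status.ACCEPTED)
        acc_adm = next(r for r in admission if r.status is Status.ACCEPTED)
        assert acc_mixed.scores.problem_complexity == 0.0  # subgroup's own CPI
        assert acc_adm.scores.problem_complexity == 0.5  # whole admission
        assert acc_mixed.scores.rejection == 0.5  # admission-wide either way


class TestConsolidateDataset:
    def test_empty_input(self):
        assert consolidate_dataset([], []) == []

    def test_count_matches_brute_force_subgroup_count(self, small_dataset):
        recs = consolidate_dataset(small_dataset.cpis, small_dataset.admissions)
        expected = 0
        keys = {(c.patient_id, c.admission_id) for c in small_dataset.cpis}
        for key in keys:
            sub = [c for c in small_dataset.cpis
                   if (c.patient_id, c.admission_id) == key]
            expected += int(any(c.accepted for c in sub))
            expected += int(any(not c.accepted for c in sub))
        assert len(recs) == expected

    def test_rejected_record_count_equals_admissions_with_rejection(self, small_dataset):
        recs = consolidate_dataset(small_dataset.cpis, small_dataset.admissions)
        admissions_with_rejection = len(
            {(c.patient_id, c.admission_id) for c in small_dataset.cpis
             if not c.accepted})
        assert sum(r.status is Status.REJECTED for r in recs) == admissions_with_rejection

    def test_all_scores_within_unit_interval(self, small_consolidated):
        for r in small_consolidated:
            for name, v in r.scores.as_dict().items():
                assert 0.0 <= v <= 1.0, (r.key, name, v)

    def test_readmission_treated_as_separate_admission(self):
        adms = [make_admission(), make_admission(admission="P1A2")]
        cpis = [make_cpi(order=1, accepted=True),
                make_cpi(order=2, accepted=False),
                make_cpi(admission="P1A2", order=1, accepted=True),
                make_cpi(admission="P1A2", order=2, accepted=False)]
        recs = consolidate_dataset(cpis, adms)
        assert len(recs) == 4
        assert len({r.key for r in recs}) == 4

    def test_rejection_score_bounds_by_group(self, small_consolidated):
        for r in small_consolidated:
            if r.status is Status.REJECTED:
                assert r.scores.rejection > 0.0
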