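"""Shared fixtures: hand-built micro-datasets and small synthetic draws."""

from __future__ import annotations

import dataclasses

import pytest

from cpinet import (
    AdmissionRecord,
    CPIRecord,
    Phase,
    consolidate_dataset,
    default_config,
    generate,
)
from cpinet.records import Outcomes, RISK_FLAG_NAMES, TYPE_FLAG_NAMES


def make_admission(patient="P1", admission="P1A1", **over) -> AdmissionRecord:
    fields = dict(
        patient_id=patient,
        admission_id=admission,
        age_years=55.0,
        gender="M",
        nationality="Jordan",
        age_group="adult",
        critical=False,
        elderly_gt84=False,
        insured=True,
        los_before_index=1.0,
        los_icu_before_index=0.0,
        risk_flags={f: False for f in RISK_FLAG_NAMES},
        diagnoses=(("dx1", False), ("dx2", True)),
        outcomes=Outcomes(los_total=4.0, los_icu_total=0.0, losta=3.0, losicua=0.0,
                          readmitted_30d=False, died=False, cost=1500.0),
    )
    fields.update(over)
    return AdmissionRecord(**fields)


def make_cpi(patient="P1", admission="P1A1", order=1, accepted=True, pharmacist="CP1",
             physician="MD1", **over) -> CPIRecord:
    fields = dict(
        patient_id=patient,
        admission_id=admission,
        cpi_order=order,
        phase=Phase.I,
        pharmacist_id=pharmacist,
        physician_id=physician,
        accepted=accepted,
        type_flags={f: False for f in TYPE_FLAG_NAMES},
        complexity_code=1.0,
        intention_code=1.0,
        domain_code=1.0,
        consult_initiated=False,
        outcomes_driven=False,
    )
    fields.update(over)
    return CPIRecord(**fields)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact but structurally complete synthetic dataset."""
    cfg = dataclasses.replace(default_config(seed=7), n_patients=60)
    return generate(cfg)


@pytest.fixture(scope="session")
def small_consolidated(small_dataset):
    return consolidate_dataset(small_dataset.cpis, small_dataset.admissions)
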