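"""Collapse per-CPI rows into accepted/rejected records per admission.

An admission with three accepted and two rejected CPI becomes two
consolidated records: one for the accepted subgroup and one for the
rejected subgroup.  Recommendation-type flags aggregate by logical OR
over the subgroup's CPI.  The ten scores summarize either the
recommendation subgroup itself (complexity, intention, domain,
prescribing step, consultancy, outcomes-driven) or the admission as a
whole (rejection, combined CP success, physician rejection, diagnosis
revision) -- the latter are defined "in that admission" / "during the
whole study period" and are shared by both records of an admission.
``score_scope`` switches to a uniform interpretation when needed.

Provider rates are computed in a first pass over the *full* dataset
before any consolidation, so each pharmacist's success rate and each
physician's rejection rate reflect the whole study period.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .records import (
    AdmissionRecord,
    ConsolidatedRecord,
    CPIRecord,
    Phase,
    ScoreSet,
    Status,
    TYPE_FLAG_NAMES,
)

__all__ = [
    "ProviderRates",
    "compute_provider_rates",
    "compute_scores",
    "consolidate_admission",
    "consolidate_dataset",
]

#: Scores computed over the recommendation subgroup's own CPI.
SUBGROUP_SCORES = (
    "problem_complexity",
    "problem_intention",
    "clinical_domain",
    "prescribing_step",
    "consultancy",
    "outcomes_driven",
)
#: Scores defined over the whole admission (and provider history).
ADMISSION_SCORES = ("rejection", "combined_cp_success", "physician_rejection", "diagnosis_revision")


@dataclass(frozen=True)
class ProviderRates:
    """Study-period provider rates.

    ``pharmacist_success[p]`` = accepted CPI / total CPI recommended by
    pharmacist ``p``; ``physician_rejection[d]`` = rejected CPI / total
    CPI addressed to physician ``d``.  Providers with no CPI are absent.
    """

    pharmacist_success: Mapping[str, float]
    physician_rejection: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, rates in (("pharmacist_success", self.pharmacist_success),
                            ("physician_rejection", self.physician_rejection)):
            for k, v in rates.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{k!r}] = {v} outside [0, 1]")


def compute_provider_rates(cpis: Sequence[CPIRecord]) -> ProviderRates:
    """First pass: per-provider acceptance/rejection rates over the dataset."""
    if not cpis:
        raise ValueError("cannot compute provider rates from an empty CPI list")
    ph_total: Counter = Counter()
    ph_acc: Counter = Counter()
    md_total: Counter = Counter()
    md_rej: Counter = Counter()
    for c in cpis:
        ph_total[c.pharmacist_id] += 1
        ph_acc[c.pharmacist_id] += int(c.accepted)
        md_total[c.physician_id] += 1
        md_rej[c.physician_id] += int(not c.accepted)
    return ProviderRates(
        pharmacist_success={p: ph_acc[p] / ph_total[p] for p in ph_total},
        physician_rejection={d: md_rej[d] / md_total[d] for d in md_total},
    )


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)


def compute_scores(
    cpis: Sequence[CPIRecord],
    rates: ProviderRates,
    diagnoses: Sequence[tuple[str, bool]] | None = None,
) -> ScoreSet:
    """Score a CPI list (a whole admission or one status subgroup).

    All scores are averages in [0, 1]: code means for complexity /
    intention / domain, fractions for the flag-based ones, the fraction
    of rejected CPI, and provider-history rates averaged over the CPI.
    ``diagnoses`` is the admission's (label, revised) list; the revision
    score is the fraction revised (0 when no diagnosis is recorded).
    """
    if not cpis:
        raise ValueError("cannot score an empty CPI list")
    admission_ids = {c.admission_id for c in cpis}
    if len(admission_ids) != 1:
        raise ValueError(f"CPI from multiple admissions: {sorted(admission_ids)}")
    for c in cpis:
        if c.pharmacist_id not in rates.pharmacist_success:
            raise KeyError(f"pharmacist {c.pharmacist_id!r} missing from provider rates")
        if c.physician_id not in rates.physician_rejection:
            raise KeyError(f"physician {c.physician_id!r} missing from provider rates")
    diagnoses = diagnoses or ()
    revised = _mean([float(rev) for _, rev in diagnoses]) if diagnoses else 0.0
    return ScoreSet(
        problem_complexity=_mean([c.complexity_code for c in cpis]),
        problem_intention=_mean([c.intention_code for c in cpis]),
        clinical_domain=_mean([c.domain_code for c in cpis]),
        prescribing_step=_mean([float(c.type_flags["drug_prescribing_step"]) for c in cpis]),
        consultancy=_mean([float(c.consult_initiated) for c in cpis]),
        outcomes_driven=_mean([float(c.outcomes_driven) for c in cpis]),
        rejection=_mean([float(not c.accepted) for c in cpis]),
        combined_cp_success=_mean([rates.pharmacist_success[c.pharmacist_id] for c in cpis]),
        physician_rejection=_mean([rates.physician_rejection[c.physician_id] for c in cpis]),
        diagnosis_revision=revised,
    )


def _modal_phase(cpis: Sequence[CPIRecord]) -> Phase:
    counts = Counter(c.phase for c in cpis)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        # tie: phase of the earliest CPI
        return min(cpis, key=lambda c: c.cpi_order).phase
    return top[0][0]


def consolidate_admission(
    cpis: Sequence[CPIRecord],
    admission: AdmissionRecord,
    rates: ProviderRates,
    score_scope: str = "mixed",
) -> list[ConsolidatedRecord]:
    """Build one record per non-empty status subgroup of an admission.

    ``score_scope``:
        ``"mixed"``     -- subgroup-descriptive scores from the subgroup's
                           own CPI, admission-wide scores from all CPI
                           (default),
        ``"admission"`` -- every score over all CPI of the admission,
        ``"subgroup"``  -- every score over the subgroup's CPI only.
    """
    if score_scope not in ("mixed", "admission", "subgroup"):
        raise ValueError(f"unknown score_scope {score_scope!r}")
    if not cpis:
        raise ValueError("admission has no CPI")
    whole = compute_scores(cpis, rates, admission.diagnoses)
    phase = _modal_phase(cpis)
    out: list[ConsolidatedRecord] = []
    for status, subgroup in (
        (Status.ACCEPTED, [c for c in cpis if c.accepted]),
        (Status.REJECTED, [c for c in cpis if not c.accepted]),
    ):
        if not subgroup:
            continue
        sub = compute_scores(subgroup, rates, admission.diagnoses)
        if score_scope == "admission":
            scores = whole
        elif score_scope == "subgroup":
            scores = sub
        else:
            scores = ScoreSet(
                **{name: getattr(sub, name) for name in SUBGROUP_SCORES},
                **{name: getattr(whole, name) for name in ADMISSION_SCORES},
            )
        out.append(ConsolidatedRecord(
            patient_id=admission.patient_id,
            admission_id=admission.admission_id,
            status=status,
            total_cpi=len(cpis),
            phase=phase,
            admission=admission,
            type_flags={f: any(c.type_flags[f] for c in subgroup) for f in TYPE_FLAG_NAMES},
            scores=scores,
        ))
    return out


def consolidate_dataset(
    cpis: Sequence[CPIRecord],
    admissions: Sequence[AdmissionRecord],
    score_scope: str = "mixed",
) -> list[ConsolidatedRecord]:
    """Two-pass consolidation of a whole dataset.

    Pass one computes study-period provider rates from every CPI; pass
    two consolidates each admission.  The output holds one record per
    non-empty (admission, status) subgroup, in admission order.
    """
    if not cpis:
        return []
    rates = compute_provider_rates(cpis)
    by_adm: dict[tuple[str, str], list[CPIRecord]] = {}
    for c in cpis:
        by_adm.setdefault((c.patient_id, c.admission_id), []).append(c)
    adm_index = {(a.patient_id, a.admission_id): a for a in admissions}
    unknown = set(by_adm) - set(adm_index)
    if unknown:
        raise KeyError(f"CPI reference unknown admissions: {sorted(unknown)[:5]}")
    out: list[ConsolidatedRecord] = []
    for key, group in by_adm.items():
        out.extend(consolidate_admission(group, adm_index[key], rates, score_scope))
    return out
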