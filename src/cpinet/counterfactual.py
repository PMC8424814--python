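"""Reassignment (what-if) analysis: 80 % versus 100 % CPI acceptance.

The factual scenario predicts each consolidated record's outcome from
its observed inputs (where about one CPI in five was rejected).  The
counterfactual scenario edits every record as if physicians had
accepted all CPI, predicts again with the same frozen model, and
compares the paired predictions: a Wilcoxon signed-rank test for
continuous outcomes, a continuity-corrected McNemar test for
categorical ones.

Two edit policies are provided.  The *default* policy changes only what
acceptance directly defines: the record's status becomes "accepted" and
its rejection score 0.  The *extended* policy additionally sets the
provider-history scores to the values they would take in a world where
every CPI is authorized -- combined CP success 1 and physician
rejection 0 -- which matters when the model has attributed part of the
rejection signal to those correlated inputs.

This is a predictive what-if on a fitted regression surface, not a
causal-identification procedure: it assumes the model's inputs capture
the outcome-relevant differences between admissions with and without
rejections.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.stats

from .grnn import GRNNModel, predict
from .records import (
    ColumnSpec,
    ConsolidatedRecord,
    FULL_SCHEMA,
    SCORE_NAMES,
    Status,
    encode_features,
)
from .stats import TestResult

__all__ = [
    "ReassignmentPolicy",
    "CounterfactualResult",
    "reassign",
    "run_counterfactual",
    "paired_continuous_test",
    "paired_categorical_test",
    "encode_for_model",
]

_EDITABLE = {"status"} | {f"score_{s}" for s in SCORE_NAMES}


@dataclass(frozen=True)
class ReassignmentPolicy:
    """A set of (field, new value) edits applied to every record.

    Fields are ``"status"`` or ``"score_<name>"``.  Setting fields to
    constants makes any policy idempotent by construction.
    """

    edits: tuple[tuple[str, object], ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        for field_name, _ in self.edits:
            if field_name not in _EDITABLE:
                raise ValueError(f"policy edits unknown field {field_name!r}")

    @classmethod
    def default(cls) -> "ReassignmentPolicy":
        return cls(edits=(("status", Status.ACCEPTED), ("score_rejection", 0.0)),
                   name="default")

    @classmethod
    def extended(cls) -> "ReassignmentPolicy":
        return cls(
            edits=(("status", Status.ACCEPTED), ("score_rejection", 0.0),
                   ("score_combined_cp_success", 1.0), ("score_physician_rejection", 0.0)),
            name="extended",
        )

    @classmethod
    def none(cls) -> "ReassignmentPolicy":
        return cls(edits=(), name="none")


def reassign(
    records: Sequence[ConsolidatedRecord], policy: ReassignmentPolicy
) -> list[ConsolidatedRecord]:
    """Apply the policy to every record; pure (inputs untouched)."""
    out = []
    for r in records:
        score_edits = {f[len("score_"):]: v for f, v in policy.edits if f.startswith("score_")}
        new_scores = replace(r.scores, **score_edits) if score_edits else r.scores
        new_status = dict(policy.edits).get("status", r.status)
        out.append(replace(r, status=Status(new_status), scores=new_scores,
                           type_flags=dict(r.type_flags)))
    return out


def encode_for_model(records: Sequence[ConsolidatedRecord], model: GRNNModel) -> np.ndarray:
    """Encode records under the model's frozen column set and scaling."""
    by_name = {c.name: c for c in FULL_SCHEMA}
    include_status = "status_rejected" in model.column_names
    schema = [by_name[n] for n in model.column_names if n != "status_rejected"]
    fm = encode_features(records, schema=schema, include_status=include_status,
                         scaling=model.scaling)
    if fm.column_names != model.column_names:
        raise ValueError("record encoding does not match the model's column set")
    return fm.matrix


@dataclass
class CounterfactualResult:
    """Paired factual/counterfactual predictions and their comparison.

    ``mean_difference`` averages factual - counterfactual over all
    records; ``mean_difference_affected`` restricts to records from
    admissions that actually contained a rejected CPI (where the
    generator's causal effect, if any, lives).  For the cost outcome the
    mean difference is the estimated saving in JD per consolidated CPI.
    """

    outcome: str
    policy: str
    record_keys: tuple
    factual: np.ndarray
    counterfactual: np.ndarray
    affected: np.ndarray  # bool: admission had >= 1 rejected CPI
    test: TestResult
    factual_summary: dict
    counterfactual_summary: dict

    @property
    def mean_difference(self) -> float:
        return float((self.factual - self.counterfactual).mean())

    @property
    def mean_difference_affected(self) -> float:
        if not self.affected.any():
            return 0.0
        d = self.factual - self.counterfactual
        return float(d[self.affected].mean())

    def scenario_line(self) -> str:
        """The study's display convention: 'mean ± sd, median (range)'."""
        f, c = self.factual_summary, self.counterfactual_summary
        def fmt(s):
            return (f"{s['mean']:.1f} ± {s['sd']:.1f}, "
                    f"{s['median']:g} ({s['min']:g}–{s['max']:g})")
        return (f"{self.outcome}: counterfactual {fmt(c)} versus factual {fmt(f)}, "
                f"P-value = {self.test.p_value:.3f}")


def _summary(v: np.ndarray) -> dict:
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        "median": float(np.median(v)),
        "min": float(v.min()),
        "max": float(v.max()),
    }


def run_counterfactual(
    model: GRNNModel,
    records: Sequence[ConsolidatedRecord],
    policy: ReassignmentPolicy | None = None,
    outcome: str = "losta",
    outcome_kind: str = "continuous",
    out_of_admission: bool = True,
) -> CounterfactualResult:
    """Predict both scenarios and compare them pairwise.

    When the model was trained with admission groups (the pipeline
    default) and ``out_of_admission`` is left on, both scenario
    predictions for a record hide the exemplars of that record's own
    admission.  A record's training exemplar carries its *factual*
    outcome; letting the edited query match itself (or its same-
    admission twin, which shares the outcome) drags every
    counterfactual prediction back toward the factual value and biases
    the scenario contrast toward zero.  The paired test is a Wilcoxon
    signed-rank for ``outcome_kind="continuous"`` and a McNemar test on
    the discordant counts for ``"categorical"``.
    """
    if policy is None:
        policy = ReassignmentPolicy.default()
    if outcome_kind not in ("continuous", "categorical"):
        raise ValueError(f"unknown outcome kind {outcome_kind!r}")
    if outcome_kind != model.task:
        raise ValueError(
            f"model task {model.task!r} does not match outcome kind {outcome_kind!r}")
    records = list(records)
    if not records:
        raise ValueError("no records to reassign")

    X_fact = encode_for_model(records, model)
    X_cf = encode_for_model(reassign(records, policy), model)
    affected = np.array(
        [r.scores.rejection > 0 or r.status == Status.REJECTED for r in records])
    exclude = None
    if out_of_admission and model.exemplar_groups is not None:
        exclude = [f"{r.patient_id}/{r.admission_id}" for r in records]

    if outcome_kind == "continuous":
        fact = np.asarray(predict(model, X_fact, exclude_groups=exclude), dtype=float)
        cf = np.asarray(predict(model, X_cf, exclude_groups=exclude), dtype=float)
        test = paired_continuous_test(fact - cf)
        f_sum, c_sum = _summary(fact), _summary(cf)
    else:
        fact = np.asarray(predict(model, X_fact, exclude_groups=exclude))
        cf = np.asarray(predict(model, X_cf, exclude_groups=exclude))
        classes = list(model.classes)
        pos = classes[-1] if len(classes) == 2 else classes[0]
        b = int(np.sum((fact != pos) & (cf == pos)))
        c = int(np.sum((fact == pos) & (cf != pos)))
        test = paired_categorical_test(b, c)
        count = lambda v: {str(cl): int((v == cl).sum()) for cl in classes}
        f_sum, c_sum = count(fact), count(cf)

    return CounterfactualResult(
        outcome=outcome,
        policy=policy.name,
        record_keys=tuple(r.key for r in records),
        factual=fact,
        counterfactual=cf,
        affected=affected,
        test=test,
        factual_summary=f_sum,
        counterfactual_summary=c_sum,
    )


def paired_continuous_test(differences) -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's rule); if everything is
    zero the result is p = 1 by convention.  The null distribution is
    exact for up to 25 non-zero differences without rank ties, else the
    normal approximation with tie correction.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one difference")
    nz = d[d != 0.0]
    if nz.size == 0:
        return TestResult(method="wilcoxon_signed_rank", statistic=0.0, p_value=1.0, n=0)
    ties = len(np.unique(np.abs(nz))) < nz.size
    method = "exact" if (nz.size <= 25 and not ties) else "approx"
    res = scipy.stats.wilcoxon(nz, zero_method="wilcox", method=method)
    return TestResult(method="wilcoxon_signed_rank", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=int(nz.size))


def paired_categorical_test(b: int, c: int) -> TestResult:
    """Continuity-corrected McNemar test on discordant-pair counts.

    ``b`` and ``c`` count the pairs shifting 0->1 and 1->0.  The
    statistic is ``(max(|b - c| - 1, 0))^2 / (b + c)`` on one degree of
    freedom; with no discordance p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        return TestResult(method="mcnemar_corrected", statistic=0.0, p_value=1.0, n=0)
    stat = max(abs(b - c) - 1.0, 0.0) ** 2 / (b + c)
    p = float(scipy.stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return TestResult(method="mcnemar_corrected", statistic=float(stat), p_value=p, n=b + c)
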