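"""Domain types, delimited-text I/O, validation and feature encoding.

The unit of observation is a clinical pharmacy intervention (CPI): a
pharmacist's recommendation about one patient's drug therapy during one
hospital admission, which the treating physician either accepts or
rejects.  Raw data arrive as a flat table with one row per CPI; the
admission-level fields (demographics, risk flags, outcomes) repeat on
every row of the same admission.  Downstream analysis works on
*consolidated* records: at most one "accepted" and one "rejected"
summary row per patient-admission, carrying ten ordinal scores in
``[0, 1]`` and OR-aggregated recommendation-type flags.

All files are comma-separated UTF-8 with a fixed, versioned header
(``header_version`` column).  Booleans are written as ``Yes``/``No``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np

HEADER_VERSION = "cpinet-1"

__all__ = [
    "HEADER_VERSION",
    "Phase",
    "Status",
    "CPIRecord",
    "AdmissionRecord",
    "ScoreSet",
    "ConsolidatedRecord",
    "ColumnSpec",
    "FeatureMatrix",
    "Issue",
    "SchemaError",
    "RowParseError",
    "EncodingError",
    "TYPE_FLAG_NAMES",
    "RISK_FLAG_NAMES",
    "SCORE_NAMES",
    "FULL_SCHEMA",
    "REDUCED_SCHEMA",
    "read_cpi_log",
    "write_cpi_log",
    "read_consolidated",
    "write_consolidated",
    "validate_dataset",
    "encode_features",
]


class Phase(str, Enum):
    """Study phase of a CPI (I = pilot period, II = main period)."""

    I = "I"
    II = "II"


class Status(str, Enum):
    """Physician decision group of a consolidated record."""

    ACCEPTED = "accepted"
    REJECTED = "rejected"


#: Recommendation-type flags carried by every CPI.
TYPE_FLAG_NAMES: tuple[str, ...] = (
    "non_drug",
    "change_form",
    "change_dose",
    "change_frequency",
    "change_route",
    "change_duration",
    "safety_related",
    "efficacy_related",
    "stop_medication",
    "add_medication",
    "drug_prescribing_step",
    "miscellaneous",
    "not_determined",
)

#: Admission-level hospitalization-risk flags.
RISK_FLAG_NAMES: tuple[str, ...] = (
    "anticholinergic",
    "antiarrhythmic",
    "dementia",
    "anemia",
    "heart_failure",
    "two_antihypertensives",
    "three_antihypertensives",
    "beta_blocker",
    "benzodiazepine",
    "tricyclic",
    "non_green_antibiotic",
    "surgical",
    "polypharmacy_ge8",
    "multi_comorbidity",
    "vascular",
    "acei_arb",
    "diuretic",
    "renal",
    "liver",
    "high_alert_med",
)

#: The ten consolidation scores, each in [0, 1].
SCORE_NAMES: tuple[str, ...] = (
    "problem_complexity",
    "problem_intention",
    "clinical_domain",
    "prescribing_step",
    "consultancy",
    "outcomes_driven",
    "rejection",
    "combined_cp_success",
    "physician_rejection",
    "diagnosis_revision",
)

COMPLEXITY_CODES = {"simple": 0.0, "follow_up": 0.5, "complex": 1.0}
INTENTION_CODES = {"error": 0.0, "problem": 1.0}
DOMAIN_CODES = {"operational": 0.0, "clinical": 1.0}


class SchemaError(ValueError):
    """A file header does not match the documented column schema."""


class RowParseError(ValueError):
    """A data row holds a value that cannot be parsed; carries the row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class EncodingError(ValueError):
    """A record cannot be encoded under a frozen feature schema."""


@dataclass(frozen=True)
class CPIRecord:
    """One clinical pharmacy intervention (one raw table row)."""

    patient_id: str
    admission_id: str
    cpi_order: int
    phase: Phase
    pharmacist_id: str
    physician_id: str
    accepted: bool
    type_flags: dict[str, bool]
    complexity_code: float  # 0 simple, 0.5 follow-up, 1 complex
    intention_code: float  # 0 error, 1 problem
    domain_code: float  # 0 operational, 1 clinical
    consult_initiated: bool  # clinician approached the pharmacist
    outcomes_driven: bool  # outcomes- rather than guideline-based

    def __post_init__(self) -> None:
        if self.cpi_order < 1:
            raise ValueError("cpi_order must be a positive integer")
        if self.complexity_code not in (0.0, 0.5, 1.0):
            raise ValueError(f"complexity_code must be 0, 0.5 or 1, got {self.complexity_code}")
        missing = set(TYPE_FLAG_NAMES) - set(self.type_flags)
        if missing:
            raise ValueError(f"type_flags missing entries: {sorted(missing)}")


@dataclass(frozen=True)
class Outcomes:
    """Admission outcomes; stays are in days, cost in Jordanian dinars."""

    los_total: float
    los_icu_total: float
    losta: float  # hospital stay after the index CPI
    losicua: float  # ICU stay after the index CPI
    readmitted_30d: bool
    died: bool
    cost: float


@dataclass(frozen=True)
class AdmissionRecord:
    """Admission-level demographics, risk flags, diagnoses and outcomes."""

    patient_id: str
    admission_id: str
    age_years: float
    gender: str  # "M" / "F"
    nationality: str  # "Jordan" / "Other"
    age_group: str  # "adult" / "pediatric"
    critical: bool
    elderly_gt84: bool
    insured: bool
    los_before_index: float
    los_icu_before_index: float
    risk_flags: dict[str, bool]
    diagnoses: tuple[tuple[str, bool], ...]  # (label, revised)
    outcomes: Outcomes

    def __post_init__(self) -> None:
        missing = set(RISK_FLAG_NAMES) - set(self.risk_flags)
        if missing:
            raise ValueError(f"risk_flags missing entries: {sorted(missing)}")


@dataclass(frozen=True)
class ScoreSet:
    """The ten consolidation scores of one (admission, status) record."""

    problem_complexity: float
    problem_intention: float
    clinical_domain: float
    prescribing_step: float
    consultancy: float
    outcomes_driven: float
    rejection: float
    combined_cp_success: float
    physician_rejection: float
    diagnosis_revision: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0 or math.isclose(v, 0.0) or math.isclose(v, 1.0)):
                raise ValueError(f"score {f.name}={v} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ConsolidatedRecord:
    """At most one accepted and one rejected summary row per admission."""

    patient_id: str
    admission_id: str
    status: Status
    total_cpi: int
    phase: Phase
    admission: AdmissionRecord
    type_flags: dict[str, bool]  # OR over the subgroup's CPI
    scores: ScoreSet

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.patient_id, self.admission_id, self.status.value)


@dataclass(frozen=True)
class Issue:
    """One validation finding: severity is ``"error"`` or ``"warning"``."""

    severity: str
    key: str
    message: str


# ---------------------------------------------------------------------------
# Feature schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnSpec:
    """One model input.

    kind:
        ``continuous``  -- scaled with training center/spread,
        ``binary``      -- encoded 0/1,
        ``score``       -- already in [0, 1], passed through unscaled,
        ``categorical`` -- one-hot over ``levels``, each indicator scaled
                           by 1/sqrt(2) so a category flip contributes unit
                           squared distance.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None


def _flag_getter(group: str, flag: str) -> Callable[[ConsolidatedRecord], float]:
    if group == "risk":
        return lambda r: float(r.admission.risk_flags[flag])
    return lambda r: float(r.type_flags[flag])


_GETTERS: dict[str, Callable[[ConsolidatedRecord], float]] = {
    "age_years": lambda r: r.admission.age_years,
    "los_before_index": lambda r: r.admission.los_before_index,
    "los_icu_before_index": lambda r: r.admission.los_icu_before_index,
    "total_cpi": lambda r: float(r.total_cpi),
    "gender_male": lambda r: float(r.admission.gender == "M"),
    "nationality_jordan": lambda r: float(r.admission.nationality == "Jordan"),
    "age_group_adult": lambda r: float(r.admission.age_group == "adult"),
    "critical": lambda r: float(r.admission.critical),
    "elderly_gt84": lambda r: float(r.admission.elderly_gt84),
    "insured": lambda r: float(r.admission.insured),
    "phase_ii": lambda r: float(r.phase == Phase.II),
    "status_rejected": lambda r: float(r.status == Status.REJECTED),
}
for _f in RISK_FLAG_NAMES:
    _GETTERS[f"risk_{_f}"] = _flag_getter("risk", _f)
for _f in TYPE_FLAG_NAMES:
    _GETTERS[f"type_{_f}"] = _flag_getter("type", _f)
for _s in SCORE_NAMES:
    _GETTERS[f"score_{_s}"] = (lambda s: (lambda r: getattr(r.scores, s)))(_s)


def _make_schema(names_kinds: Iterable[tuple[str, str]]) -> tuple[ColumnSpec, ...]:
    return tuple(ColumnSpec(n, k) for n, k in names_kinds)


#: The full 54-input schema: 36 variables matched between the accepted and
#: rejected groups plus 18 unmatched ones.  Two-level categoricals enter as
#: single 0/1 columns so the input-layer width stays auditable.
FULL_SCHEMA: tuple[ColumnSpec, ...] = _make_schema(
    [
        ("age_years", "continuous"),
        ("gender_male", "binary"),
        ("nationality_jordan", "binary"),
        ("age_group_adult", "binary"),
        ("critical", "binary"),
        ("elderly_gt84", "binary"),
        ("insured", "binary"),
        ("los_before_index", "continuous"),
        ("los_icu_before_index", "continuous"),
        ("phase_ii", "binary"),
        ("total_cpi", "continuous"),
    ]
    + [(f"risk_{f}", "binary") for f in RISK_FLAG_NAMES]
    + [(f"type_{f}", "binary") for f in TYPE_FLAG_NAMES]
    + [(f"score_{s}", "score") for s in SCORE_NAMES]
)
assert len(FULL_SCHEMA) == 54

#: The reduced 18-input schema: only the variables that differed between
#: the accepted and rejected groups (the "unmatched" set).  With the status
#: indicator appended it is the 19-input model.
REDUCED_SCHEMA: tuple[ColumnSpec, ...] = _make_schema(
    [("phase_ii", "binary"), ("total_cpi", "continuous")]
    + [
        (f"risk_{f}", "binary")
        for f in (
            "polypharmacy_ge8",
            "multi_comorbidity",
            "vascular",
            "acei_arb",
            "diuretic",
            "renal",
            "liver",
            "high_alert_med",
        )
    ]
    + [
        (f"type_{f}", "binary")
        for f in ("drug_prescribing_step", "efficacy_related", "stop_medication", "add_medication")
    ]
    + [
        (f"score_{s}", "score")
        for s in ("consultancy", "rejection", "combined_cp_success", "physician_rejection")
    ]
)
assert len(REDUCED_SCHEMA) == 18


@dataclass
class FeatureMatrix:
    """Numeric design matrix with a frozen, reusable scaling.

    ``scaling`` maps a continuous column name to its training
    ``(center, spread)``; binary and score columns pass through.  The
    scaling must always come from training rows: encode the training set
    first and pass ``fm.scaling`` when encoding any other rows.
    """

    column_names: tuple[str, ...]
    column_kinds: tuple[str, ...]
    matrix: np.ndarray
    row_keys: tuple[tuple[str, str, str], ...]
    scaling: dict[str, tuple[float, float]]
    groups: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.column_names.index(name)]


def encode_features(
    records: Sequence[ConsolidatedRecord],
    schema: Sequence[ColumnSpec] = FULL_SCHEMA,
    include_status: bool = True,
    scaling: dict[str, tuple[float, float]] | None = None,
    method: str = "zscore",
) -> FeatureMatrix:
    """Encode consolidated records into a numeric matrix.

    Continuous columns are z-standardized (or min-max scaled with
    ``method="minmax"``) using center/spread fitted on *these* rows when
    ``scaling`` is None, else the frozen parameters supplied.  Booleans
    become 0/1, scores pass through on their natural [0, 1] scale, and
    multi-level categoricals are one-hot encoded with a 1/sqrt(2) factor
    per indicator.  A zero-variance continuous column keeps spread 1 so
    encoding stays defined.
    """
    if not records:
        raise ValueError("cannot encode an empty record list")
    if method not in ("zscore", "minmax"):
        raise ValueError(f"unknown scaling method {method!r}")
    specs = list(schema)
    if include_status:
        specs.append(ColumnSpec("status_rejected", "binary"))

    fit = scaling is None
    scaling = dict(scaling or {})
    names: list[str] = []
    kinds: list[str] = []
    cols: list[np.ndarray] = []
    groups: dict[str, tuple[int, ...]] = {}

    for spec in specs:
        if spec.kind == "categorical":
            if not spec.levels:
                raise EncodingError(f"categorical column {spec.name!r} has no levels")
            getter = _GETTERS.get(spec.name)
            if getter is None:
                raise EncodingError(f"no getter for column {spec.name!r}")
            raw = [getter(r) for r in records]
            idx0 = len(names)
            for level in spec.levels:
                names.append(f"{spec.name}={level}")
                kinds.append("categorical")
                cols.append(np.array([v == level for v in raw], dtype=float) / math.sqrt(2.0))
            groups[spec.name] = tuple(range(idx0, len(names)))
            unseen = {v for v in raw} - set(spec.levels)
            if unseen:
                raise EncodingError(f"unseen categories for {spec.name!r}: {sorted(unseen)}")
            continue

        getter = _GETTERS.get(spec.name)
        if getter is None:
            raise EncodingError(f"no getter for column {spec.name!r}")
        col = np.array([float(getter(r)) for r in records], dtype=float)
        if np.isnan(col).any():
            raise EncodingError(f"missing values in column {spec.name!r}")
        if spec.kind == "continuous":
            if fit:
                if method == "zscore":
                    center, spread = float(col.mean()), float(col.std())
                else:
                    center = float(col.min())
                    spread = float(col.max() - col.min())
                if spread == 0.0:
                    spread = 1.0
                scaling[spec.name] = (center, spread)
            elif spec.name not in scaling:
                raise EncodingError(f"no frozen scaling for continuous column {spec.name!r}")
            center, spread = scaling[spec.name]
            col = (col - center) / spread
        elif spec.kind == "binary":
            bad = set(np.unique(col)) - {0.0, 1.0}
            if bad:
                raise EncodingError(f"non-binary values in column {spec.name!r}: {sorted(bad)}")
        names.append(spec.name)
        kinds.append(spec.kind)
        cols.append(col)

    return FeatureMatrix(
        column_names=tuple(names),
        column_kinds=tuple(kinds),
        matrix=np.column_stack(cols),
        row_keys=tuple(r.key for r in records),
        scaling=scaling,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_BOOL_IN = {"yes": True, "no": False, "true": True, "false": False, "1": True, "0": False}


def _fmt_bool(v: bool) -> str:
    return "Yes" if v else "No"


def _parse_bool(value: str, column: str, row: int) -> bool:
    try:
        return _BOOL_IN[value.strip().lower()]
    except KeyError:
        raise RowParseError(row, f"column {column!r}: cannot parse boolean {value!r}") from None


def _parse_float(value: str, column: str, row: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise RowParseError(row, f"column {column!r}: cannot parse number {value!r}") from None


def _parse_enum(value: str, mapping: dict[str, float], column: str, row: int) -> float:
    v = value.strip().lower()
    if v in mapping:
        return mapping[v]
    try:  # numeric codes are accepted too
        num = float(value)
    except ValueError:
        num = None
    if num is not None and num in mapping.values():
        return num
    raise RowParseError(row, f"column {column!r}: invalid value {value!r} (expected one of {sorted(mapping)})")


def _fmt_diagnoses(diagnoses: Iterable[tuple[str, bool]]) -> str:
    return ";".join(f"{label}:{int(revised)}" for label, revised in diagnoses)


def _parse_diagnoses(text: str, row: int) -> tuple[tuple[str, bool], ...]:
    text = text.strip()
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        label, sep, rev = part.rpartition(":")
        if not sep or rev not in ("0", "1"):
            raise RowParseError(row, f"cannot parse diagnosis entry {part!r}")
        out.append((label, rev == "1"))
    return tuple(out)


CPI_LOG_COLUMNS: tuple[str, ...] = (
    ("header_version", "patient_id", "admission_id", "cpi_order", "phase",
     "pharmacist_id", "physician_id", "accepted")
    + tuple(f"type_{f}" for f in TYPE_FLAG_NAMES)
    + ("complexity", "intention", "domain", "consult_initiated", "outcomes_driven",
       "age_years", "gender", "nationality", "age_group", "critical", "elderly_gt84",
       "insured", "los_before_index", "los_icu_before_index")
    + tuple(f"risk_{f}" for f in RISK_FLAG_NAMES)
    + ("diagnoses", "los_total", "los_icu_total", "losta", "losicua",
       "readmitted_30d", "died", "cost")
)


def write_cpi_log(
    path,
    cpis: Sequence[CPIRecord],
    admissions: Sequence[AdmissionRecord],
    float_digits: int = 17,
) -> None:
    """Write a raw per-CPI table (one row per CPI, admission fields repeated)."""
    adm = {(a.patient_id, a.admission_id): a for a in admissions}
    fmt = lambda x: f"{x:.{float_digits}g}"
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CPI_LOG_COLUMNS)
        for c in cpis:
            a = adm[(c.patient_id, c.admission_id)]
            inv_cx = {v: k for k, v in COMPLEXITY_CODES.items()}
            row = (
                [HEADER_VERSION, c.patient_id, c.admission_id, c.cpi_order, c.phase.value,
                 c.pharmacist_id, c.physician_id, _fmt_bool(c.accepted)]
                + [_fmt_bool(c.type_flags[f]) for f in TYPE_FLAG_NAMES]
                + [inv_cx[c.complexity_code],
                   "problem" if c.intention_code == 1.0 else "error",
                   "clinical" if c.domain_code == 1.0 else "operational",
                   _fmt_bool(c.consult_initiated), _fmt_bool(c.outcomes_driven),
                   fmt(a.age_years), a.gender, a.nationality, a.age_group,
                   _fmt_bool(a.critical), _fmt_bool(a.elderly_gt84), _fmt_bool(a.insured),
                   fmt(a.los_before_index), fmt(a.los_icu_before_index)]
                + [_fmt_bool(a.risk_flags[f]) for f in RISK_FLAG_NAMES]
                + [_fmt_diagnoses(a.diagnoses), fmt(a.outcomes.los_total),
                   fmt(a.outcomes.los_icu_total), fmt(a.outcomes.losta),
                   fmt(a.outcomes.losicua), _fmt_bool(a.outcomes.readmitted_30d),
                   _fmt_bool(a.outcomes.died), fmt(a.outcomes.cost)]
            )
            w.writerow(row)


def read_cpi_log(
    path,
    dialect: dict | None = None,
    on_error: str = "raise",
    issues: list[Issue] | None = None,
) -> tuple[list[CPIRecord], list[AdmissionRecord]]:
    """Read a raw per-CPI table back into records.

    The header must contain every documented column (a missing one raises
    :class:`SchemaError` naming it).  With ``on_error="raise"`` the first
    bad row raises :class:`RowParseError`; with ``"report"`` bad rows are
    skipped and located messages are appended to ``issues``.  Admission
    fields are taken from the first row of each admission; later rows
    that disagree are reported as warnings.
    """
    if on_error not in ("raise", "report"):
        raise ValueError("on_error must be 'raise' or 'report'")
    if issues is None:
        issues = []
    cpis: list[CPIRecord] = []
    admissions: dict[tuple[str, str], AdmissionRecord] = {}
    first_row: dict[tuple[str, str], dict] = {}

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, **(dialect or {}))
        header = reader.fieldnames or []
        missing = [c for c in CPI_LOG_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        for i, raw in enumerate(reader, start=2):  # header is line 1
            try:
                cpi, adm_fields = _parse_cpi_row(raw, i)
            except RowParseError as exc:
                if on_error == "raise":
                    raise
                issues.append(Issue("error", f"line {i}", str(exc)))
                continue
            key = (cpi.patient_id, cpi.admission_id)
            if key not in admissions:
                admissions[key] = _build_admission(cpi, adm_fields, i)
                first_row[key] = adm_fields
            else:
                for k, v in adm_fields.items():
                    if first_row[key][k] != v:
                        issues.append(Issue(
                            "warning", f"line {i}",
                            f"admission {key[1]}: field {k!r} disagrees with first "
                            f"occurrence ({v!r} vs {first_row[key][k]!r}); first wins",
                        ))
            cpis.append(cpi)
    return cpis, list(admissions.values())


def _parse_cpi_row(raw: dict, i: int) -> tuple[CPIRecord, dict]:
    g = lambda c: (raw.get(c) or "").strip()
    phase_txt = g("phase")
    if phase_txt not in ("I", "II"):
        raise RowParseError(i, f"column 'phase': invalid value {phase_txt!r}")
    try:
        order = int(g("cpi_order"))
    except ValueError:
        raise RowParseError(i, f"column 'cpi_order': not an integer: {g('cpi_order')!r}") from None
    cpi = CPIRecord(
        patient_id=g("patient_id"),
        admission_id=g("admission_id"),
        cpi_order=order,
        phase=Phase(phase_txt),
        pharmacist_id=g("pharmacist_id"),
        physician_id=g("physician_id"),
        accepted=_parse_bool(g("accepted"), "accepted", i),
        type_flags={f: _parse_bool(g(f"type_{f}"), f"type_{f}", i) for f in TYPE_FLAG_NAMES},
        complexity_code=_parse_enum(g("complexity"), COMPLEXITY_CODES, "complexity", i),
        intention_code=_parse_enum(g("intention"), INTENTION_CODES, "intention", i),
        domain_code=_parse_enum(g("domain"), DOMAIN_CODES, "domain", i),
        consult_initiated=_parse_bool(g("consult_initiated"), "consult_initiated", i),
        outcomes_driven=_parse_bool(g("outcomes_driven"), "outcomes_driven", i),
    )
    first_adm_col = CPI_LOG_COLUMNS.index("age_years")
    return cpi, {c: g(c) for c in CPI_LOG_COLUMNS[first_adm_col:]}


def _build_admission(cpi: CPIRecord, f: dict, i: int) -> AdmissionRecord:
    return AdmissionRecord(
        patient_id=cpi.patient_id,
        admission_id=cpi.admission_id,
        age_years=_parse_float(f["age_years"], "age_years", i),
        gender=f["gender"],
        nationality=f["nationality"],
        age_group=f["age_group"],
        critical=_parse_bool(f["critical"], "critical", i),
        elderly_gt84=_parse_bool(f["elderly_gt84"], "elderly_gt84", i),
        insured=_parse_bool(f["insured"], "insured", i),
        los_before_index=_parse_float(f["los_before_index"], "los_before_index", i),
        los_icu_before_index=_parse_float(f["los_icu_before_index"], "los_icu_before_index", i),
        risk_flags={k: _parse_bool(f[f"risk_{k}"], f"risk_{k}", i) for k in RISK_FLAG_NAMES},
        diagnoses=_parse_diagnoses(f["diagnoses"], i),
        outcomes=Outcomes(
            los_total=_parse_float(f["los_total"], "los_total", i),
            los_icu_total=_parse_float(f["los_icu_total"], "los_icu_total", i),
            losta=_parse_float(f["losta"], "losta", i),
            losicua=_parse_float(f["losicua"], "losicua", i),
            readmitted_30d=_parse_bool(f["readmitted_30d"], "readmitted_30d", i),
            died=_parse_bool(f["died"], "died", i),
            cost=_parse_float(f["cost"], "cost", i),
        ),
    )


CONSOLIDATED_COLUMNS: tuple[str, ...] = (
    ("header_version", "patient_id", "admission_id", "status", "total_cpi", "phase",
     "age_years", "gender", "nationality", "age_group", "critical", "elderly_gt84",
     "insured", "los_before_index", "los_icu_before_index")
    + tuple(f"risk_{f}" for f in RISK_FLAG_NAMES)
    + tuple(f"type_{f}" for f in TYPE_FLAG_NAMES)
    + tuple(f"score_{s}" for s in SCORE_NAMES)
    + ("diagnoses", "los_total", "los_icu_total", "losta", "losicua",
       "readmitted_30d", "died", "cost")
)


def write_consolidated(path, records: Sequence[ConsolidatedRecord], float_digits: int = 17) -> None:
    fmt = lambda x: f"{x:.{float_digits}g}"
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CONSOLIDATED_COLUMNS)
        for r in records:
            a = r.admission
            w.writerow(
                [HEADER_VERSION, r.patient_id, r.admission_id, r.status.value,
                 r.total_cpi, r.phase.value, fmt(a.age_years), a.gender, a.nationality,
                 a.age_group, _fmt_bool(a.critical), _fmt_bool(a.elderly_gt84),
                 _fmt_bool(a.insured), fmt(a.los_before_index), fmt(a.los_icu_before_index)]
                + [_fmt_bool(a.risk_flags[f]) for f in RISK_FLAG_NAMES]
                + [_fmt_bool(r.type_flags[f]) for f in TYPE_FLAG_NAMES]
                + [fmt(getattr(r.scores, s)) for s in SCORE_NAMES]
                + [_fmt_diagnoses(a.diagnoses), fmt(a.outcomes.los_total),
                   fmt(a.outcomes.los_icu_total), fmt(a.outcomes.losta),
                   fmt(a.outcomes.losicua), _fmt_bool(a.outcomes.readmitted_30d),
                   _fmt_bool(a.outcomes.died), fmt(a.outcomes.cost)]
            )


def read_consolidated(path) -> list[ConsolidatedRecord]:
    records: list[ConsolidatedRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CONSOLIDATED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        for i, raw in enumerate(reader, start=2):
            g = lambda c: (raw.get(c) or "").strip()
            status_txt = g("status")
            if status_txt not in ("accepted", "rejected"):
                raise RowParseError(i, f"column 'status': invalid value {status_txt!r}")
            adm = AdmissionRecord(
                patient_id=g("patient_id"),
                admission_id=g("admission_id"),
                age_years=_parse_float(g("age_years"), "age_years", i),
                gender=g("gender"),
                nationality=g("nationality"),
                age_group=g("age_group"),
                critical=_parse_bool(g("critical"), "critical", i),
                elderly_gt84=_parse_bool(g("elderly_gt84"), "elderly_gt84", i),
                insured=_parse_bool(g("insured"), "insured", i),
                los_before_index=_parse_float(g("los_before_index"), "los_before_index", i),
                los_icu_before_index=_parse_float(g("los_icu_before_index"), "los_icu_before_index", i),
                risk_flags={k: _parse_bool(g(f"risk_{k}"), f"risk_{k}", i) for k in RISK_FLAG_NAMES},
                diagnoses=_parse_diagnoses(g("diagnoses"), i),
                outcomes=Outcomes(
                    los_total=_parse_float(g("los_total"), "los_total", i),
                    los_icu_total=_parse_float(g("los_icu_total"), "los_icu_total", i),
                    losta=_parse_float(g("losta"), "losta", i),
                    losicua=_parse_float(g("losicua"), "losicua", i),
                    readmitted_30d=_parse_bool(g("readmitted_30d"), "readmitted_30d", i),
                    died=_parse_bool(g("died"), "died", i),
                    cost=_parse_float(g("cost"), "cost", i),
                ),
            )
            records.append(ConsolidatedRecord(
                patient_id=adm.patient_id,
                admission_id=adm.admission_id,
                status=Status(status_txt),
                total_cpi=int(g("total_cpi")),
                phase=Phase(g("phase")),
                admission=adm,
                type_flags={f: _parse_bool(g(f"type_{f}"), f"type_{f}", i) for f in TYPE_FLAG_NAMES},
                scores=ScoreSet(**{s: _parse_float(g(f"score_{s}"), f"score_{s}", i) for s in SCORE_NAMES}),
            ))
    return records


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_dataset(
    cpis: Sequence[CPIRecord],
    admissions: Sequence[AdmissionRecord],
) -> list[Issue]:
    """Cross-check a raw dataset against its invariants.

    Pure reporting: returns a list of located issues and never raises.
    A clean dataset yields an empty list.
    """
    issues: list[Issue] = []
    adm = {(a.patient_id, a.admission_id): a for a in admissions}

    seen_orders: dict[tuple[str, str], set[int]] = {}
    for c in cpis:
        key = (c.patient_id, c.admission_id)
        label = f"cpi {c.patient_id}/{c.admission_id}#{c.cpi_order}"
        if key not in adm:
            issues.append(Issue("error", label, "references unknown admission"))
        orders = seen_orders.setdefault(key, set())
        if c.cpi_order in orders:
            issues.append(Issue("error", label, "duplicate cpi_order within admission"))
        orders.add(c.cpi_order)

    for a in admissions:
        label = f"admission {a.patient_id}/{a.admission_id}"
        o = a.outcomes
        if o.losta > o.los_total + 1e-9:
            issues.append(Issue("error", label, f"losta {o.losta} exceeds los_total {o.los_total}"))
        if o.los_icu_total > o.los_total + 1e-9:
            issues.append(Issue("error", label, f"los_icu_total {o.los_icu_total} exceeds los_total {o.los_total}"))
        if o.losicua > o.los_icu_total + 1e-9:
            issues.append(Issue("error", label, f"losicua {o.losicua} exceeds los_icu_total {o.los_icu_total}"))
        if a.elderly_gt84 != (a.age_years > 84):
            issues.append(Issue("error", label, f"elderly_gt84={a.elderly_gt84} inconsistent with age {a.age_years}"))
        for name, v in [("age_years", a.age_years), ("los_before_index", a.los_before_index),
                        ("los_icu_before_index", a.los_icu_before_index), ("losta", o.losta),
                        ("losicua", o.losicua), ("cost", o.cost)]:
            if v < 0:
                issues.append(Issue("error", label, f"negative {name}: {v}"))
        if (a.patient_id, a.admission_id) not in {(c.patient_id, c.admission_id) for c in cpis}:
            issues.append(Issue("warning", label, "admission has no CPI"))
    return issues
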