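"""Record types, CSV round-trips, validation and feature encoding."""

import dataclasses
import math

import numpy as np
import pytest

from cpinet import (
    FULL_SCHEMA,
    REDUCED_SCHEMA,
    default_config,
    encode_features,
    generate,
    read_cpi_log,
    read_consolidated,
    validate_dataset,
    write_consolidated,
    write_cpi_log,
)
from cpinet.records import (
    Issue,
    Outcomes,
    RowParseError,
    SchemaError,
    ScoreSet,
)

from conftest import make_admission, make_cpi


class TestRoundTrip:
    def test_cpi_log_round_trip_is_lossless(self, small_dataset, tmp_path):
        path = tmp_path / "cpi_log.csv"
        write_cpi_log(path, small_dataset.cpis, small_dataset.admissions)
        cpis, admissions = read_cpi_log(path)
        assert len(cpis) == len(small_dataset.cpis)
        assert len(admissions) == len(small_dataset.admissions)
        for a, b in zip(cpis, small_dataset.cpis):
            assert (a.patient_id, a.admission_id, a.cpi_order) == (
                b.patient_id, b.admission_id, b.cpi_order)
            assert a.accepted == b.accepted
            assert a.phase == b.phase
            assert a.type_flags == b.type_flags
            assert a.complexity_code == b.complexity_code
        for a, b in zip(admissions, small_dataset.admissions):
            assert a.risk_flags == b.risk_flags
            assert a.diagnoses == b.diagnoses
            # reals reproduced to 12 significant digits
            assert math.isclose(a.age_years, b.age_years, rel_tol=1e-12)
            assert math.isclose(a.outcomes.cost, b.outcomes.cost, rel_tol=1e-12)
            assert a.outcomes.losta == b.outcomes.losta

    def test_consolidated_round_trip(self, small_consolidated, tmp_path):
        path = tmp_path / "consolidated.csv"
        write_consolidated(path, small_consolidated)
        back = read_consolidated(path)
        assert len(back) == len(small_consolidated)
        for a, b in zip(back, small_consolidated):
            assert a.key == b.key
            assert a.total_cpi == b.total_cpi
            assert a.type_flags == b.type_flags
            for name, v in a.scores.as_dict().items():
                assert math.isclose(v, getattr(b.scores, name), abs_tol=1e-12)


class TestReader:
    def _write_rows(self, tmp_path, mutate=None, drop_column=None):
        adm = make_admission()
        cpis = [make_cpi(order=i + 1, accepted=i % 2 == 0) for i in range(3)]
        path = tmp_path / "log.csv"
        write_cpi_log(path, cpis, [adm])
        if mutate or drop_column:
            lines = path.read_text().splitlines()
            if mutate:
                header = lines[0].split(",")
                for col, value in mutate.items():
                    idx = header.index(col)
                    row = lines[1].split(",")
                    row[idx] = value
                    lines[1] = ",".join(row)
            if drop_column:
                header = lines[0].split(",")
                idx = header.index(drop_column)
                lines = [",".join(r.split(",")[:idx] + r.split(",")[idx + 1:])
                         for r in lines]
            path.write_text("\n".join(lines) + "\n")
        return path

    def test_well_formed_file(self, tmp_path):
        adms = [make_admission(), make_admission(patient="P2", admission="P2A1")]
        cpis = [make_cpi(order=1), make_cpi(order=2), make_cpi(order=3),
                make_cpi(patient="P2", admission="P2A1", order=1),
                make_cpi(patient="P2", admission="P2A1", order=2)]
        path = tmp_path / "log.csv"
        write_cpi_log(path, cpis, adms)
        got_cpis, got_adms = read_cpi_log(path)
        assert len(got_cpis) == 5
        assert len(got_adms) == 2

    def test_header_only_file(self, tmp_path):
        path = self._write_rows(tmp_path)
        lines = path.read_text().splitlines()
        path.write_text(lines[0] + "\n")
        assert read_cpi_log(path) == ([], [])

    def test_invalid_boolean_is_row_error(self, tmp_path):
        path = self._write_rows(tmp_path, mutate={"accepted": "maybe"})
        with pytest.raises(RowParseError, match="row 2.*accepted.*maybe"):
            read_cpi_log(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = self._write_rows(tmp_path, drop_column="accepted")
        with pytest.raises(SchemaError, match="accepted"):
            read_cpi_log(path)

    def test_report_mode_collects_instead_of_raising(self, tmp_path):
        path = self._write_rows(tmp_path, mutate={"complexity": "bogus"})
        issues: list[Issue] = []
        cpis, _ = read_cpi_log(path, on_error="report", issues=issues)
        assert len(cpis) == 2  # bad row skipped
        assert len(issues) == 1 and issues[0].severity == "error"
        assert "line 2" in issues[0].key


class TestValidation:
    def test_clean_synthetic_dataset_has_no_issues(self, small_dataset):
        assert validate_dataset(small_dataset.cpis, small_dataset.admissions) == []

    def test_unknown_admission_reference(self):
        adm = make_admission()
        orphan = make_cpi(admission="GHOST")
        issues = validate_dataset([make_cpi(), orphan], [adm])
        assert sum(i.severity == "error" for i in issues) == 1
        assert "unknown admission" in issues[0].message

    def test_losta_exceeding_total_stay(self):
        adm = make_admission(outcomes=Outcomes(
            los_total=2.0, los_icu_total=0.0, losta=5.0, losicua=0.0,
            readmitted_30d=False, died=False, cost=100.0))
        issues = validate_dataset([make_cpi()], [adm])
        assert any("losta" in i.message and i.severity == "error" for i in issues)

    def test_elderly_flag_inconsistency(self):
        adm = make_admission(age_years=90.0, elderly_gt84=False)
        issues = validate_dataset([make_cpi()], [adm])
        assert any("elderly" in i.message for i in issues)


class TestEncoding:
    def test_full_schema_with_status_has_55_columns(self, small_consolidated):
        fm = encode_features(small_consolidated, FULL_SCHEMA, include_status=True)
        assert fm.n_columns == 55
        assert fm.column_names[-1] == "status_rejected"
        assert len(FULL_SCHEMA) == 54
        assert len(REDUCED_SCHEMA) == 18

    def test_booleans_encode_to_zero_one(self, small_consolidated):
        fm = encode_features(small_consolidated, FULL_SCHEMA)
        col = fm.column("critical")
        assert set(np.unique(col)) <= {0.0, 1.0}

    def test_continuous_columns_are_standardized(self, small_consolidated):
        fm = encode_features(small_consolidated, FULL_SCHEMA)
        for name in ("age_years", "los_before_index", "total_cpi"):
            col = fm.column(name)
            assert abs(col.mean()) < 1e-9
            assert abs(col.std() - 1.0) < 1e-9

    def test_frozen_scaling_reused_for_new_rows(self, small_consolidated):
        train, rest = small_consolidated[:40], small_consolidated[40:]
        fm = encode_features(train, FULL_SCHEMA)
        fm2 = encode_features(rest, FULL_SCHEMA, scaling=fm.scaling)
        assert fm2.scaling == fm.scaling
        # rest standardized with train center: generally non-zero mean
        assert fm2.column("age_years").mean() != pytest.approx(0.0, abs=1e-12)

    def test_encoding_deterministic(self, small_consolidated):
        a = encode_features(small_consolidated, FULL_SCHEMA)
        b = encode_features(small_consolidated, FULL_SCHEMA)
        assert np.array_equal(a.matrix, b.matrix)

    def test_scores_validate_range(self):
        with pytest.raises(ValueError, match="outside"):
            ScoreSet(problem_complexity=1.2, problem_intention=0, clinical_domain=0,
                     prescribing_step=0, consultancy=0, outcomes_driven=0, rejection=0,
                     combined_cp_success=0, physician_rejection=0, diagnosis_revision=0)


def test_dementia_prevalence_zero_generates_no_dementia():
    cfg = default_config(seed=3)
    prev = dict(cfg.prevalence)
    prev["dementia"] = 0.0
    ds = generate(dataclasses.replace(cfg, prevalence=prev, n_patients=80))
    assert not any(a.risk_flags["dementia"] for a in ds.admissions)
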