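"""Cohort I/O, validation, and inclusion criteria."""

import numpy as np
import pandas as pd
import pytest

import deescbias as db
from deescbias.cohort import EVENT_COLUMNS, REQUIRED_COLUMNS
from deescbias.errors import DataError, SchemaError


def _tiny_cohort(n=3, **overrides) -> db.AnalysisCohort:
    base = {
        "age": 70, "male": 1, "smoker": 0, "nursing_home": 0,
        "chronic_pulmonary": 0, "chronic_cardiovascular": 0, "chronic_renal": 0,
        "chronic_liver": 0, "diabetes": 0, "neoplastic": 0, "cerebrovascular": 0,
        "resp_rate": 22.0, "systolic_bp": 120.0, "temperature": 38.0,
        "heart_rate": 90.0, "ph": 7.4, "bun": 8.0, "sodium": 138.0,
        "glucose": 6.0, "hematocrit": 0.4, "po2": 75.0,
        "altered_mental_status": 0, "pleural_effusion": 0, "psi_score": 90,
        "prior_antibiotics": 0, "weekend_admission": 0, "season": "winter",
        "pathogen_identified": 0, "icu_admission": 0,
        "death_day": pd.NA, "last_followup_day": 30,
    }
    pat = pd.DataFrame([{"patient_id": f"p{i}", **base} for i in range(n)])
    for col, vals in overrides.items():
        pat[col] = vals
    pat["death_day"] = pd.array(pat["death_day"], dtype="Int64")
    events = pd.DataFrame(
        {"patient_id": [f"p{i}" for i in range(n)], "day": 0, "drug": "amoxicillin"}
    )
    return db.AnalysisCohort(patients=pat, events=events, provenance="user")


class TestRoundTrip:
    def test_fixture_round_trips_losslessly(self, fixture_cohort, tmp_path):
        db.write_cohort(fixture_cohort, tmp_path / "p.csv", tmp_path / "e.csv")
        back = db.read_cohort(tmp_path / "p.csv", tmp_path / "e.csv", provenance="fixture")
        pd.testing.assert_frame_equal(
            back.patients[list(fixture_cohort.patients.columns)],
            fixture_cohort.patients,
            check_dtype=False,
        )
        pd.testing.assert_frame_equal(back.events, fixture_cohort.events, check_dtype=False)

    def test_three_row_csv_gives_cohort_of_three(self, tmp_path):
        c = _tiny_cohort(3)
        db.write_cohort(c, tmp_path / "p.csv", tmp_path / "e.csv")
        assert len(db.read_cohort(tmp_path / "p.csv", tmp_path / "e.csv")) == 3

    def test_missing_column_is_schema_error_naming_it(self, tmp_path):
        c = _tiny_cohort(3)
        c.patients.drop(columns=["psi_score"]).to_csv(tmp_path / "p.csv", index=False)
        c.events.to_csv(tmp_path / "e.csv", index=False)
        with pytest.raises(SchemaError, match="psi_score"):
            db.read_cohort(tmp_path / "p.csv", tmp_path / "e.csv")

    def test_unparseable_value_is_row_error_with_id(self, tmp_path):
        c = _tiny_cohort(3)
        pat = c.patients.copy()
        pat["bun"] = pat["bun"].astype(object)
        pat.loc[1, "bun"] = "not-a-number"
        pat.to_csv(tmp_path / "p.csv", index=False)
        c.events.to_csv(tmp_path / "e.csv", index=False)
        with pytest.raises(DataError, match="p1"):
            db.read_cohort(tmp_path / "p.csv", tmp_path / "e.csv")

    def test_wide_regimen_columns_are_read(self, tmp_path):
        c = _tiny_cohort(2)
        pat = c.patients.copy()
        pat["regimen_day_0"] = ["amoxicillin", "ceftriaxone"]
        pat["regimen_day_3"] = ["", "co-amoxiclav"]
        pat.to_csv(tmp_path / "p.csv", index=False)
        back = db.read_cohort(tmp_path / "p.csv")
        course = back.course("p1")
        assert course.events == ((0, frozenset({"ceftriaxone"})), (3, frozenset({"co-amoxiclav"})))

    def test_schema_map_renames_columns(self, tmp_path):
        c = _tiny_cohort(2)
        c.patients.rename(columns={"psi_score": "PSI"}).to_csv(tmp_path / "p.csv", index=False)
        c.events.to_csv(tmp_path / "e.csv", index=False)
        back = db.read_cohort(tmp_path / "p.csv", tmp_path / "e.csv", schema={"PSI": "psi_score"})
        assert (back.patients["psi_score"] == 90).all()


class TestValidation:
    def test_age_below_65_rejected(self):
        with pytest.raises(DataError, match="age"):
            _tiny_cohort(2, age=[70, 60])

    def test_duplicate_patient_id_rejected(self):
        c = _tiny_cohort(2)
        pat = c.patients.copy()
        pat.loc[1, "patient_id"] = "p0"
        with pytest.raises(DataError, match="duplicate"):
            db.AnalysisCohort(patients=pat, events=c.events.iloc[:1], provenance="user")

    def test_followup_before_death_rejected(self):
        with pytest.raises(DataError, match="last_followup_day"):
            _tiny_cohort(2, death_day=[pd.NA, 20], last_followup_day=[30, 10])

    def test_course_invariants(self):
        with pytest.raises(DataError, match="day 0"):
            db.TreatmentCourse("x", ((1, frozenset({"amoxicillin"})),))
        with pytest.raises(DataError, match="strictly increase"):
            db.TreatmentCourse(
                "x", ((0, frozenset({"a"})), (2, frozenset({"b"})), (2, frozenset({"c"})))
            )

    def test_record_accessor(self, fixture_cohort):
        rec = fixture_cohort.record("P0001")
        assert rec.age >= 65 and rec.latent_stable_72h is None


class TestInclusion:
    def test_exclusion_reasons_and_tally(self):
        c = _tiny_cohort(
            5,
            icu_admission=[0, 1, 0, 0, 0],
            death_day=[pd.NA, pd.NA, 0, 5, pd.NA],
            last_followup_day=[30, 30, 0, 5, 30],
        )
        # patient p4 has no day-0 antibiotics
        c = db.AnalysisCohort(
            patients=c.patients,
            events=c.events[c.events["patient_id"] != "p4"],
            provenance="user",
        )
        out, tally = db.apply_inclusion(c)
        assert set(out.patients["patient_id"]) == {"p0", "p3"}
        assert tally == {"icu": 1, "no_day0_antibiotics": 1, "death<24h": 1}
        assert sum(tally.values()) == 5 - len(out)

    def test_no_exclusions_is_identity_with_empty_tally(self, fixture_cohort):
        out, tally = db.apply_inclusion(fixture_cohort)
        assert tally == {}
        pd.testing.assert_frame_equal(out.patients, fixture_cohort.patients)

    def test_idempotent(self):
        c = _tiny_cohort(4, icu_admission=[0, 1, 0, 0])
        once, _ = db.apply_inclusion(c)
        twice, tally2 = db.apply_inclusion(once)
        assert tally2 == {}
        pd.testing.assert_frame_equal(once.patients, twice.patients)

    def test_other_trial_flag_excludes(self):
        c = _tiny_cohort(3)
        c.patients["excluded_other"] = [0, 1, 0]
        out, tally = db.apply_inclusion(c)
        assert tally == {"other_trial": 1} and len(out) == 2
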