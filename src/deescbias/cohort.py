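"""Cohort containers, invariant checks, and tabular I/O.

A cohort is a pair of tables: one row per patient (baseline covariates and
outcome days) plus a long event table (patient_id, day, drug) recording the
antibiotic regimen on the day it was started or switched.  Days are integer
study days with day 0 = day of admission; "died within 24 hours" is encoded
as ``death_day == 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

SEASONS = ("winter", "spring", "summer", "autumn")

#: Binary 0/1 patient columns.
FLAG_COLUMNS = (
    "male",
    "smoker",
    "nursing_home",
    "chronic_pulmonary",
    "chronic_cardiovascular",
    "chronic_renal",
    "chronic_liver",
    "diabetes",
    "neoplastic",
    "cerebrovascular",
    "altered_mental_status",
    "pleural_effusion",
    "prior_antibiotics",
    "weekend_admission",
    "pathogen_identified",
    "icu_admission",
)

#: Continuous vitals/labs columns.
NUMERIC_COLUMNS = (
    "resp_rate",
    "systolic_bp",
    "temperature",
    "heart_rate",
    "ph",
    "bun",
    "sodium",
    "glucose",
    "hematocrit",
    "po2",
)

REQUIRED_COLUMNS = (
    ("patient_id", "age", "psi_score", "season")
    + FLAG_COLUMNS
    + NUMERIC_COLUMNS
    + ("death_day", "last_followup_day")
)

#: Optional columns that are carried through when present.
OPTIONAL_COLUMNS = ("latent_stable_72h", "excluded_other")

EVENT_COLUMNS = ("patient_id", "day", "drug")


@dataclass(frozen=True)
class TreatmentCourse:
    """Ordered antibiotic switch events of one patient.

    ``events`` is a list of ``(day, regimen)`` pairs with strictly increasing
    days; the day-0 entry is the empirical regimen started on admission.
    """

    patient_id: str
    events: tuple[tuple[int, frozenset[str]], ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise DataError(f"patient {self.patient_id}: empty treatment course")
        days = [d for d, _ in self.events]
        if days[0] != 0:
            raise DataError(
                f"patient {self.patient_id}: first regimen must be on day 0, got day {days[0]}"
            )
        if any(b <= a for a, b in zip(days, days[1:])):
            raise DataError(f"patient {self.patient_id}: event days must strictly increase")
        if any(len(r) == 0 for _, r in self.events):
            raise DataError(f"patient {self.patient_id}: empty regimen in course")


@dataclass
class PatientRecord:
    """One admitted patient; mirrors a row of the patient table."""

    patient_id: str
    age: int
    male: bool
    smoker: bool
    nursing_home: bool
    chronic_pulmonary: bool
    chronic_cardiovascular: bool
    chronic_renal: bool
    chronic_liver: bool
    diabetes: bool
    neoplastic: bool
    cerebrovascular: bool
    resp_rate: float
    systolic_bp: float
    temperature: float
    heart_rate: float
    ph: float
    bun: float
    sodium: float
    glucose: float
    hematocrit: float
    po2: float
    altered_mental_status: bool
    pleural_effusion: bool
    psi_score: int
    prior_antibiotics: bool
    weekend_admission: bool
    season: str
    pathogen_identified: bool
    icu_admission: bool
    death_day: int | None
    last_followup_day: int
    latent_stable_72h: bool | None = None


@dataclass
class AnalysisCohort:
    """Patient table joined to the event (treatment) table.

    ``patients`` has one row per patient; ``events`` is long-form
    (patient_id, day, drug).  ``provenance`` records where the cohort came
    from: "synthetic", "fixture", or "user".
    """

    patients: pd.DataFrame
    events: pd.DataFrame
    provenance: str = "user"

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.patients)

    def validate(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.patients.columns]
        if missing:
            raise SchemaError(f"patient table is missing column(s): {', '.join(missing)}")
        missing_ev = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing_ev:
            raise SchemaError(f"event table is missing column(s): {', '.join(missing_ev)}")
        pat = self.patients
        if pat["patient_id"].duplicated().any():
            dup = pat.loc[pat["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise DataError(f"duplicate patient_id {dup!r}")
        if (pat["age"] < 65).any():
            bad = pat.loc[pat["age"] < 65, "patient_id"].iloc[0]
            raise DataError(f"patient {bad!r}: age below 65 (cohort is restricted to >=65 y)")
        bad_season = ~pat["season"].isin(SEASONS)
        if bad_season.any():
            bad = pat.loc[bad_season, "patient_id"].iloc[0]
            raise DataError(f"patient {bad!r}: season must be one of {SEASONS}")
        death = pat["death_day"]
        has_death = death.notna()
        if (death[has_death] < 0).any():
            bad = pat.loc[has_death & (death < 0), "patient_id"].iloc[0]
            raise DataError(f"patient {bad!r}: negative death_day")
        fup = pat["last_followup_day"]
        if (fup < 0).any():
            bad = pat.loc[fup < 0, "patient_id"].iloc[0]
            raise DataError(f"patient {bad!r}: negative last_followup_day")
        if (has_death & (fup < death)).any():
            bad = pat.loc[has_death & (fup < death), "patient_id"].iloc[0]
            raise DataError(f"patient {bad!r}: last_followup_day before death_day")
        # every event id must resolve to a patient; one course per patient
        ids = set(pat["patient_id"])
        orphan = ~self.events["patient_id"].isin(ids)
        if orphan.any():
            bad = self.events.loc[orphan, "patient_id"].iloc[0]
            raise DataError(f"event table references unknown patient {bad!r}")
        # day-0 regimen need not exist (apply_inclusion removes such patients)

    def course(self, patient_id: str) -> TreatmentCourse:
        ev = self.events[self.events["patient_id"] == patient_id]
        return _events_to_course(patient_id, ev)

    def iter_courses(self) -> Iterable[TreatmentCourse]:
        for pid, ev in self.events.groupby("patient_id", sort=False):
            yield _events_to_course(pid, ev)

    def record(self, patient_id: str) -> PatientRecord:
        row = self.patients.loc[self.patients["patient_id"] == patient_id]
        if row.empty:
            raise DataError(f"unknown patient {patient_id!r}")
        d = row.iloc[0].to_dict()
        death = d["death_day"]
        d["death_day"] = None if pd.isna(death) else int(death)
        stable = d.pop("latent_stable_72h", None)
        d = {k: v for k, v in d.items() if k in PatientRecord.__dataclass_fields__}
        d["latent_stable_72h"] = None if stable is None or pd.isna(stable) else bool(stable)
        return PatientRecord(**d)


def _events_to_course(patient_id: str, events: pd.DataFrame) -> TreatmentCourse:
    pairs = []
    for day, grp in events.groupby("day", sort=True):
        pairs.append((int(day), frozenset(grp["drug"])))
    return TreatmentCourse(patient_id=patient_id, events=tuple(pairs))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cohort(
    patients_path: str | Path,
    events_path: str | Path | None = None,
    schema: Mapping[str, str] | None = None,
    provenance: str = "user",
) -> AnalysisCohort:
    """Read a cohort from CSV files (UTF-8, header row, '.' decimals).

    ``schema`` optionally maps file column names to the canonical names.
    Treatment events come either from a companion long CSV
    (patient_id, day, drug) or, when ``events_path`` is None, from wide
    ``regimen_day_<k>`` columns in the patient table whose cells hold
    '+'-joined drug names.
    """
    patients_path = Path(patients_path)
    if not patients_path.exists():
        raise FileNotFoundError(patients_path)
    pat = pd.read_csv(patients_path)
    if schema:
        pat = pat.rename(columns=dict(schema))

    wide_cols = [c for c in pat.columns if c.startswith("regimen_day_")]
    if events_path is not None:
        events_path = Path(events_path)
        if not events_path.exists():
            raise FileNotFoundError(events_path)
        events = pd.read_csv(events_path)
        if schema:
            events = events.rename(columns=dict(schema))
        missing = [c for c in EVENT_COLUMNS if c not in events.columns]
        if missing:
            raise SchemaError(f"event table is missing column(s): {', '.join(missing)}")
        events = events[list(EVENT_COLUMNS)]
    elif wide_cols:
        events = _wide_to_long(pat, wide_cols)
        pat = pat.drop(columns=wide_cols)
    else:
        raise SchemaError(
            "no treatment events: pass events_path or include regimen_day_<k> columns"
        )

    missing = [c for c in REQUIRED_COLUMNS if c not in pat.columns]
    if missing:
        raise SchemaError(f"patient table is missing column(s): {', '.join(missing)}")

    pat = _coerce_patient_types(pat)
    events = events.astype({"patient_id": str, "day": int, "drug": str})
    return AnalysisCohort(patients=pat, events=events, provenance=provenance)


def write_cohort(
    cohort: AnalysisCohort,
    patients_path: str | Path,
    events_path: str | Path,
) -> None:
    """Write the patient and event tables as CSV (lossless round-trip)."""
    Path(patients_path).parent.mkdir(parents=True, exist_ok=True)
    cohort.patients.to_csv(patients_path, index=False)
    cohort.events.to_csv(events_path, index=False)


def _wide_to_long(pat: pd.DataFrame, wide_cols: list[str]) -> pd.DataFrame:
    rows = []
    for col in wide_cols:
        day = int(col.rsplit("_", 1)[1])
        sub = pat[["patient_id", col]].dropna()
        sub = sub[sub[col].astype(str).str.len() > 0]
        for pid, cell in sub.itertuples(index=False):
            for drug in str(cell).split("+"):
                rows.append((str(pid), day, drug.strip()))
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def _coerce_patient_types(pat: pd.DataFrame) -> pd.DataFrame:
    pat = pat.copy()
    pat["patient_id"] = pat["patient_id"].astype(str)
    for col in ("age", "psi_score", "last_followup_day"):
        try:
            pat[col] = pat[col].astype(int)
        except (ValueError, TypeError) as exc:
            bad = pat.loc[pd.to_numeric(pat[col], errors="coerce").isna(), "patient_id"]
            pid = bad.iloc[0] if len(bad) else "?"
            raise DataError(f"patient {pid!r}: unparseable value in column {col!r}") from exc
    for col in FLAG_COLUMNS + tuple(c for c in OPTIONAL_COLUMNS if c in pat.columns):
        vals = pd.to_numeric(pat[col], errors="coerce")
        if col == "latent_stable_72h":
            ok = vals.isin([0, 1]) | vals.isna()
        else:
            ok = vals.isin([0, 1])
        if not ok.all():
            pid = pat.loc[~ok, "patient_id"].iloc[0]
            raise DataError(f"patient {pid!r}: column {col!r} must be 0/1")
        pat[col] = vals.astype("Int64") if col == "latent_stable_72h" else vals.astype(int)
    for col in NUMERIC_COLUMNS:
        vals = pd.to_numeric(pat[col], errors="coerce")
        if vals.isna().any():
            pid = pat.loc[vals.isna(), "patient_id"].iloc[0]
            raise DataError(f"patient {pid!r}: unparseable value in column {col!r}")
        pat[col] = vals.astype(float)
    pat["death_day"] = pd.to_numeric(pat["death_day"], errors="coerce").astype("Int64")
    return pat


# ---------------------------------------------------------------------------
# Inclusion / exclusion
# ---------------------------------------------------------------------------

#: Exclusion reasons in the order they are applied; a patient hitting several
#: is tallied under the first one.
EXCLUSION_REASONS = ("other_trial", "icu", "no_day0_antibiotics", "death<24h")


def apply_inclusion(cohort: AnalysisCohort) -> tuple[AnalysisCohort, dict[str, int]]:
    """Apply the study's inclusion criteria and return (cohort, tally).

    Excluded are: patients flagged ``excluded_other`` (co-enrolment in an
    interfering trial), baseline ICU admissions, patients without antibiotics
    on the day of admission, and deaths within 24 h (``death_day == 0``, not
    eligible for de-escalation).  The tally maps reason -> count and its
    values sum to the number of removed patients.  Idempotent.
    """
    pat = cohort.patients
    day0_ids = set(cohort.events.loc[cohort.events["day"] == 0, "patient_id"])

    reason = pd.Series("", index=pat.index, dtype=object)
    if "excluded_other" in pat.columns:
        reason[(reason == "") & (pat["excluded_other"] == 1)] = "other_trial"
    reason[(reason == "") & (pat["icu_admission"] == 1)] = "icu"
    reason[(reason == "") & ~pat["patient_id"].isin(day0_ids)] = "no_day0_antibiotics"
    death0 = pat["death_day"].notna() & (pat["death_day"] == 0)
    reason[(reason == "") & death0] = "death<24h"

    keep = reason == ""
    tally = {r: int((reason == r).sum()) for r in EXCLUSION_REASONS if (reason == r).any()}
    kept_ids = set(pat.loc[keep, "patient_id"])
    out = AnalysisCohort(
        patients=pat.loc[keep].reset_index(drop=True),
        events=cohort.events[cohort.events["patient_id"].isin(kept_ids)].reset_index(drop=True),
        provenance=cohort.provenance,
    )
    return out, tally
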