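"""Shared fixtures: the deterministic reference cohort and a synthetic one,
each carried through classification, propensity fitting and interval
construction once per session."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
import pytest

import deescbias as db
from deescbias.propensity import fit_propensity
from deescbias.ranking import DE_ESCALATION
from deescbias.survival import build_intervals, make_analysis_set

warnings.filterwarnings("ignore", category=FutureWarning)


@dataclass
class PreparedCohort:
    cohort: db.AnalysisCohort
    classified: pd.DataFrame
    analysis: pd.DataFrame  # analysis set (rank 2/3) joined to classification
    model: db.PropensityModel
    intervals: pd.DataFrame  # 30-day horizon, propensity attached


def _prepare(cohort: db.AnalysisCohort) -> PreparedCohort:
    included, _ = db.apply_inclusion(cohort)
    classified = db.classify_cohort(included)
    analysis = make_analysis_set(included.patients, classified)
    outcome = (analysis["label"] == DE_ESCALATION).astype(int)
    model = fit_propensity(analysis, outcome)
    cov = pd.DataFrame({"propensity": model.scores})
    intervals = build_intervals(analysis, horizon=30, covariates=cov)
    return PreparedCohort(included, classified, analysis, model, intervals)


@pytest.fixture(scope="session")
def fixture_cohort() -> db.AnalysisCohort:
    return db.make_fixture()


@pytest.fixture(scope="session")
def fixture_prepared(fixture_cohort) -> PreparedCohort:
    return _prepare(fixture_cohort)


@pytest.fixture(scope="session")
def synth_cohort() -> db.AnalysisCohort:
    cohort, _ = db.generate(db.GeneratorConfig(n_patients=1536, seed=1))
    return cohort


@pytest.fixture(scope="session")
def synth_prepared(synth_cohort) -> PreparedCohort:
    return _prepare(synth_cohort)


@pytest.fixture(scope="session")
def rank_table() -> db.RankTable:
    return db.RankTable.default()
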