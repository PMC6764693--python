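"""Counting-process construction and the time-dependent Cox engine."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import deescbias as db
from deescbias.errors import DataError
from deescbias.ranking import CONTINUATION, DE_ESCALATION, ESCALATION
from deescbias.simulate import DeescalationLogit, GeneratorConfig
from deescbias.survival import build_intervals, fit_cox, make_analysis_set, ph_diagnostic

NULL_KWARGS = dict(
    stability_mortality_or=1.0, deescalation_logit=DeescalationLogit(stable=0.0)
)


def _analysis_row(pid, label, switch=None, death=None, later=None, followup=90, rank=3):
    return dict(
        patient_id=pid,
        label=label,
        switch_day=switch,
        later_escalation_day=later,
        death_day=death,
        last_followup_day=followup,
        initial_rank=rank,
    )


def _frame(*rows):
    df = pd.DataFrame(list(rows))
    for col in ("switch_day", "death_day", "later_escalation_day"):
        df[col] = pd.array(df[col], dtype="Int64")
    return df


class TestBuildIntervals:
    def test_deescalated_then_died(self):
        iv = build_intervals(_frame(_analysis_row("a", DE_ESCALATION, switch=3, death=10)))
        expected = [("a", 0.0, 3.0, 0, 0), ("a", 3.0, 10.0, 1, 1)]
        assert list(iv.itertuples(index=False, name=None)) == expected

    def test_escalated_then_died_censored_at_escalation(self):
        iv = build_intervals(_frame(_analysis_row("b", ESCALATION, switch=2, death=9)))
        assert list(iv.itertuples(index=False, name=None)) == [("b", 0.0, 2.0, 0, 0)]

    def test_death_on_switch_day_counts_as_exposed(self):
        iv = build_intervals(_frame(_analysis_row("c", DE_ESCALATION, switch=4, death=4)))
        assert list(iv.itertuples(index=False, name=None)) == [
            ("c", 0.0, 4.0, 0, 0),
            ("c", 4.0, 4.5, 1, 1),
        ]

    def test_death_on_escalation_day_keeps_the_event(self):
        iv = build_intervals(_frame(_analysis_row("d", ESCALATION, switch=6, death=6)))
        assert list(iv.itertuples(index=False, name=None)) == [("d", 0.0, 6.0, 0, 1)]

    def test_later_escalation_censors_the_deescalated(self):
        iv = build_intervals(
            _frame(_analysis_row("e", DE_ESCALATION, switch=2, later=6, death=20))
        )
        assert list(iv.itertuples(index=False, name=None)) == [
            ("e", 0.0, 2.0, 0, 0),
            ("e", 2.0, 6.0, 1, 0),
        ]

    def test_continuation_censored_at_horizon(self):
        iv = build_intervals(_frame(_analysis_row("f", CONTINUATION, followup=90)))
        assert list(iv.itertuples(index=False, name=None)) == [("f", 0.0, 30.0, 0, 0)]

    def test_switch_after_death_is_data_error(self):
        with pytest.raises(DataError, match="g"):
            build_intervals(_frame(_analysis_row("g", DE_ESCALATION, switch=9, death=4)))

    def test_rank1_starters_rejected(self):
        with pytest.raises(DataError, match="rank-1"):
            build_intervals(_frame(_analysis_row("h", CONTINUATION, rank=1)))

    def test_person_time_is_conserved(self, synth_prepared):
        """Sum of interval lengths equals each patient's analysed follow-up
        (same-day deaths after a switch add the half-day event interval)."""
        ana, iv = synth_prepared.analysis, synth_prepared.intervals
        per_patient = iv.groupby("patient_id").apply(
            lambda g: (g["stop"] - g["start"]).sum(), include_groups=False
        )
        for t in ana.itertuples(index=False):
            death = None if pd.isna(t.death_day) else int(t.death_day)
            cens = min(30, int(t.last_followup_day))
            if t.label == ESCALATION:
                expected = min(int(t.switch_day), cens)
            else:
                limit = cens
                if t.label == DE_ESCALATION and not pd.isna(t.later_escalation_day):
                    limit = min(limit, int(t.later_escalation_day))
                expected = limit if death is None else min(death, limit)
                if t.label == DE_ESCALATION and death is not None and death == t.switch_day:
                    expected += 0.5
            got = per_patient.get(t.patient_id, 0.0)
            assert np.isclose(got, expected), t.patient_id


def _efron_risk_sets(df):
    out = []
    for t in sorted(df.loc[df["event"] == 1, "stop"].unique()):
        dead = df[(df["event"] == 1) & (df["stop"] == t)]
        risk = df[(df["start"] < t) & (t <= df["stop"])]
        out.append((risk["deescalated"].to_numpy(float), dead["deescalated"].to_numpy(float)))
    return out


def _efron_loglik(risk_sets, beta):
    ll = 0.0
    for xr, xd in risk_sets:
        w, wd, m = np.exp(beta * xr), np.exp(beta * xd), len(xd)
        ll += beta * xd.sum() - sum(np.log(w.sum() - l / m * wd.sum()) for l in range(m))
    return ll


class TestFitCox:
    def test_partial_likelihood_matches_brute_force_grid(self):
        """Six-patient hand-built start-stop data: the fitted log-HR agrees
        with an independent grid maximisation of the Efron partial
        likelihood to 1e-4."""
        iv = pd.DataFrame(
            {
                "patient_id": ["a", "a", "b", "c", "c", "d", "e", "f"],
                "start": [0, 3, 0, 0, 2, 0, 0, 0],
                "stop": [3, 10, 8, 2, 9, 12, 10, 30],
                "deescalated": [0, 1, 0, 0, 1, 0, 0, 0],
                "event": [0, 1, 1, 0, 1, 0, 1, 0],
            }
        )
        rs = _efron_risk_sets(iv)
        grid = np.arange(-4.0, 4.0, 1e-4)
        lls = np.array([_efron_loglik(rs, b) for b in grid])
        beta_grid = grid[int(np.argmax(lls))]
        fit = fit_cox(iv)
        assert abs(fit.log_hr - beta_grid) < 1e-4
        assert np.isclose(_efron_loglik(rs, fit.log_hr), fit.log_likelihood)

    def test_fixed_exposure_equals_standard_cox(self, synth_prepared):
        """On single-interval data (exposure coded at baseline) the
        start-stop engine reduces to an ordinary Cox fit."""
        iv = synth_prepared.intervals
        fixed = (
            iv.groupby("patient_id")
            .agg(stop=("stop", "max"), event=("event", "max"), deescalated=("deescalated", "max"))
            .reset_index()
        )
        fixed["start"] = 0.0
        ours = fit_cox(fixed)
        cph = CoxPHFitter()
        cph.fit(fixed[["stop", "event", "deescalated"]], duration_col="stop", event_col="event")
        assert abs(ours.log_hr - float(cph.params_.iloc[0])) < 1e-6

    def test_needs_events_in_both_exposure_states(self):
        iv = build_intervals(
            _frame(
                _analysis_row("a", CONTINUATION, death=5),
                _analysis_row("b", DE_ESCALATION, switch=3),
            )
        )
        with pytest.raises(DataError, match="exposure state"):
            fit_cox(iv)

    def test_immortal_time_bias_of_baseline_coding(self):
        """With no confounding and a true null effect, baseline-coded
        de-escalation shows spurious protection while the time-dependent
        coding stays at the null."""
        cohort, _ = db.generate(GeneratorConfig(n_patients=20_000, seed=3, **NULL_KWARGS))
        included, _ = db.apply_inclusion(cohort)
        analysis = make_analysis_set(included.patients, db.classify_cohort(included))
        iv = build_intervals(analysis, horizon=30)
        td = fit_cox(iv)
        fixed = (
            iv.groupby("patient_id")
            .agg(stop=("stop", "max"), event=("event", "max"), deescalated=("deescalated", "max"))
            .reset_index()
        )
        cph = CoxPHFitter()
        cph.fit(fixed[["stop", "event", "deescalated"]], duration_col="stop", event_col="event")
        hr_fixed = float(np.exp(cph.params_.iloc[0]))
        assert td.ci_low < 1.0 < td.ci_high
        assert hr_fixed < 0.95 < td.hr + 0.15
        assert hr_fixed < td.hr


@pytest.fixture(scope="module")
def piecewise():
    """Effect present (HR 0.3) before day 20, absent afterwards."""
    cohort, _ = db.generate(
        GeneratorConfig(
            n_patients=20_000, seed=5, causal_deescalation_hr=0.3,
            late_hr=1.0, late_hr_day=20, **NULL_KWARGS,
        )
    )
    included, _ = db.apply_inclusion(cohort)
    analysis = make_analysis_set(included.patients, db.classify_cohort(included))
    return build_intervals(analysis, horizon=90)


class TestPHDiagnostic:
    def test_late_vanishing_effect_is_detected(self, piecewise):
        d = ph_diagnostic(piecewise)
        tbl = d.window_table.set_index("start")
        assert tbl.loc[0.0, "ci_high"] < 1.0  # early protection
        assert tbl.loc[20.0, "ci_low"] < 1.0 < tbl.loc[20.0, "ci_high"]  # gone after day 20
        assert d.p_value < 1e-6

    def test_constant_effect_looks_flat(self):
        cohort, _ = db.generate(
            GeneratorConfig(n_patients=20_000, seed=5, causal_deescalation_hr=0.6, **NULL_KWARGS)
        )
        included, _ = db.apply_inclusion(cohort)
        analysis = make_analysis_set(included.patients, db.classify_cohort(included))
        d = ph_diagnostic(build_intervals(analysis, horizon=90))
        assert d.p_value > 0.01
        overall = fit_cox(build_intervals(analysis, horizon=90)).log_hr
        tbl = d.window_table
        assert ((tbl["log_hr"] - 1.96 * tbl["se"] < overall)
                & (overall < tbl["log_hr"] + 1.96 * tbl["se"])).all()

    def test_type_one_error_near_nominal(self):
        """Under a constant hazard ratio the global PH test rejects at
        roughly the nominal 5% level across replicate cohorts."""
        rejections = 0
        reps = 30
        for seed in range(100, 100 + reps):
            cohort, _ = db.generate(
                GeneratorConfig(n_patients=2_500, seed=seed,
                                causal_deescalation_hr=0.6, **NULL_KWARGS)
            )
            included, _ = db.apply_inclusion(cohort)
            analysis = make_analysis_set(included.patients, db.classify_cohort(included))
            d = ph_diagnostic(build_intervals(analysis, horizon=90), windows=(0, 15, 30, 90))
            rejections += d.p_value < 0.05
        # Binomial(30, 0.05): >=7 rejections has probability < 1e-3
        assert rejections <= 6
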