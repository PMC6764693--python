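"""Calibrated-confounder machinery: algebra, allocation, assignment, sweep."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import deescbias as db
from deescbias.bias import (
    GROUP_CONT,
    GROUP_DE,
    ConfounderScenario,
    analysis_groups,
    assign_confounder,
    default_grid,
    implied_continuation_prevalence,
    margins,
    run_sweep,
    solve_allocation,
)
from deescbias.errors import DataError, InfeasibleScenarioError

FIXTURE_MARGINS = (257, 986, 9, 107)


class TestImpliedPrevalence:
    def test_equal_prevalences_are_a_fixed_point(self):
        assert implied_continuation_prevalence(0.8, 0.8, 123, 456) == pytest.approx(0.8)

    def test_boundary_is_infeasible(self):
        # overall 50% cannot hold if the (large) de-escalated group is all stable
        with pytest.raises(InfeasibleScenarioError):
            implied_continuation_prevalence(0.5, 1.0, 986, 257)

    @settings(max_examples=200, deadline=None)
    @given(
        pi_de=st.floats(0.0, 1.0),
        pi_cont=st.floats(0.0, 1.0),
        n_de=st.integers(1, 2000),
        n_cont=st.integers(1, 2000),
    )
    def test_inverts_the_weighted_average(self, pi_de, pi_cont, n_de, n_cont):
        pi = (pi_de * n_de + pi_cont * n_cont) / (n_de + n_cont)
        back = implied_continuation_prevalence(pi, pi_de, n_de, n_cont)
        assert back == pytest.approx(pi_cont, abs=1e-9)


def _brute_force_best(sizes, T_de, T_cont, target):
    """Exhaustively enumerate integer allocations honouring the group totals
    and return the minimal |log OR - log target| attainable."""
    d_de, s_de = sizes[(GROUP_DE, 1)], sizes[(GROUP_DE, 0)]
    d_c, s_c = sizes[(GROUP_CONT, 1)], sizes[(GROUP_CONT, 0)]
    best = np.inf
    for k1 in range(max(0, T_de - s_de), min(d_de, T_de) + 1):
        for k2 in range(max(0, T_cont - s_c), min(d_c, T_cont) + 1):
            a = k1 + k2
            b = (T_de - k1) + (T_cont - k2)
            c = d_de + d_c - a
            d = s_de + s_c - b
            if min(a, b, c, d) <= 0:
                continue
            best = min(best, abs(np.log(a * d / (b * c)) - np.log(target)))
    return best


class TestSolveAllocation:
    def test_fixture_margins_hit_the_target_or(self):
        sc = ConfounderScenario(deescalated_prevalence=0.90)
        al = solve_allocation(sc, *FIXTURE_MARGINS)
        assert abs(np.log(al.realized_or) - np.log(0.14)) <= al.rounding_tol_log
        assert abs(al.realized_pi_de - 0.90) <= 1 / 257
        assert abs(al.realized_pi_cont - al.pi_cont_target) <= 1 / 986

    def test_degenerate_full_prevalence_in_deescalated(self):
        al = solve_allocation(ConfounderScenario(deescalated_prevalence=1.0), *FIXTURE_MARGINS)
        assert al.stable[(GROUP_DE, 1)] == 9  # every de-escalated death is stable
        assert al.stable[(GROUP_DE, 0)] == 248
        assert abs(np.log(al.realized_or) - np.log(0.14)) <= al.rounding_tol_log

    def test_or_one_with_equal_prevalences_means_independence(self):
        sc = ConfounderScenario(deescalated_prevalence=0.80, target_or=1.0)
        al = solve_allocation(sc, *FIXTURE_MARGINS)
        assert al.psi == pytest.approx(1.0, abs=1e-6)
        for (g, d), k in al.stable.items():
            assert k == pytest.approx(0.8 * al.sizes[(g, d)], abs=1.0)

    def test_unattainable_or_reports_range(self):
        with pytest.raises(InfeasibleScenarioError, match="attainable range"):
            solve_allocation(ConfounderScenario(target_or=1e-9), 20, 30, 5, 6)

    @pytest.mark.parametrize(
        "n_de,n_cont,d_de,d_cont,pi,pi_de,target",
        [
            (12, 28, 3, 9, 0.6, 0.75, 0.25),
            (10, 30, 2, 10, 0.7, 0.9, 0.4),
            (15, 25, 4, 7, 0.5, 0.6, 0.5),
            (8, 24, 1, 6, 0.75, 1.0, 0.2),
            (20, 20, 5, 5, 0.65, 0.7, 2.0),
        ],
    )
    def test_matches_exhaustive_search_on_small_cohorts(
        self, n_de, n_cont, d_de, d_cont, pi, pi_de, target
    ):
        sc = ConfounderScenario(
            overall_prevalence=pi, deescalated_prevalence=pi_de, target_or=target
        )
        al = solve_allocation(sc, n_de, n_cont, d_de, d_cont)
        T_de = al.stable[(GROUP_DE, 1)] + al.stable[(GROUP_DE, 0)]
        T_cont = al.stable[(GROUP_CONT, 1)] + al.stable[(GROUP_CONT, 0)]
        best = _brute_force_best(al.sizes, T_de, T_cont, target)
        got = abs(np.log(al.realized_or) - np.log(target))
        assert got == pytest.approx(best, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        n_de=st.integers(20, 400),
        n_cont=st.integers(50, 1500),
        f_de=st.floats(0.02, 0.3),
        f_cont=st.floats(0.02, 0.3),
        pi_de=st.floats(0.82, 1.0),
    )
    def test_conservation_of_stable_counts(self, n_de, n_cont, f_de, f_cont, pi_de):
        d_de = max(1, int(f_de * n_de))
        d_cont = max(1, int(f_cont * n_cont))
        sc = ConfounderScenario(deescalated_prevalence=pi_de)
        try:
            al = solve_allocation(sc, n_de, n_cont, d_de, d_cont)
        except InfeasibleScenarioError:
            return
        total = sum(al.stable.values())
        assert abs(total - round(0.8 * (n_de + n_cont))) <= 1


class TestAssignConfounder:
    @pytest.fixture()
    def fixture_groups(self, fixture_prepared):
        return analysis_groups(fixture_prepared.analysis)

    def test_margins_match_the_reference_counts(self, fixture_groups):
        assert margins(fixture_groups) == FIXTURE_MARGINS

    def test_exact_stratum_counts_any_seed(self, fixture_groups):
        al = solve_allocation(ConfounderScenario(deescalated_prevalence=0.9), *FIXTURE_MARGINS)
        for seed in (0, 1, 2):
            stable = assign_confounder(fixture_groups, al, seed=seed)
            for (g, d), k in al.stable.items():
                ids = fixture_groups.loc[
                    (fixture_groups["group"] == g) & (fixture_groups["died"] == d), "patient_id"
                ]
                assert stable.loc[ids].sum() == k

    def test_different_seeds_differ_at_patient_level(self, fixture_groups):
        al = solve_allocation(ConfounderScenario(deescalated_prevalence=0.9), *FIXTURE_MARGINS)
        s0 = assign_confounder(fixture_groups, al, seed=0)
        s1 = assign_confounder(fixture_groups, al, seed=1)
        assert (s0 != s1).any()

    def test_all_stable_allocation_gives_constant_column(self, fixture_groups):
        al = solve_allocation(ConfounderScenario(deescalated_prevalence=0.9), *FIXTURE_MARGINS)
        al.stable = dict(al.sizes)
        al.probs = {k: 1.0 for k in al.probs}
        stable = assign_confounder(fixture_groups, al, seed=0)
        assert (stable == 1).all()

    def test_stratum_mismatch_is_an_error(self, fixture_groups):
        al = solve_allocation(ConfounderScenario(deescalated_prevalence=0.9), 200, 986, 9, 107)
        with pytest.raises(DataError, match="stratum"):
            assign_confounder(fixture_groups, al, seed=0)


class TestSweep:
    def test_grid_always_contains_the_anchors(self):
        g = default_grid(0.83, 0.02)
        assert np.any(np.isclose(g, 0.90)) and np.any(np.isclose(g, 1.00))
        assert (np.diff(g) > 0).all()

    def test_non_confounder_gives_flat_curve(self, synth_prepared):
        """With target OR 1 and equal prevalences everywhere the stability
        flag is pure noise: the adjusted HR stays at the stability-free
        value across the grid."""
        sc = ConfounderScenario(target_or=1.0, seed=1, n_seed_repeats=2)
        sw = run_sweep(
            synth_prepared.analysis,
            synth_prepared.model.scores,
            sc,
            grid=np.array([0.80, 0.90, 1.00]),
        )
        base = db.fit_cox(synth_prepared.intervals, covariates=["propensity"])
        f = sw.frame
        assert f["error"].eq("").all()
        # the pure-noise point is the left edge (equal prevalences)
        assert f.loc[0, "hr"] == pytest.approx(base.hr, rel=0.05)

    def test_failures_are_recorded_not_fatal(self, synth_prepared):
        # a 5% overall prevalence is impossible once every de-escalated
        # patient is stable: the point fails, the sweep carries on
        sc = ConfounderScenario(overall_prevalence=0.05, seed=1, n_seed_repeats=1)
        sw = run_sweep(
            synth_prepared.analysis, synth_prepared.model.scores, sc,
            grid=np.array([0.05, 1.00]),
        )
        assert sw.frame.loc[1, "error"] != "" and np.isnan(sw.frame.loc[1, "hr"])
        assert sw.frame.loc[0, "error"] == ""
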