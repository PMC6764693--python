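"""Calibrated simulation of an unmeasured binary confounder.

The confounder — "clinically stable at 72 h" — is injected into an observed
cohort so that three assumptions hold simultaneously: its prevalence in the
de-escalated group, its prevalence in the continuation group (implied by the
overall prevalence, a weighted average of the two), and its crude odds ratio
with 30-day death (default 0.14).  Three constraint families leave the four
stratum probabilities (group x outcome) under-determined by one degree of
freedom; the closure adopted here is a *common within-group stability–death
odds ratio* psi in both exposure groups, solved by monotone one-dimensional
root finding.  Probabilities are then converted to exact integer stratum
counts, and patients inside each stratum are flagged stable uniformly at
random.  Exact counts (rather than independent Bernoulli draws) make the
stratum totals — the sufficient statistics of the downstream Cox refit given
the covariate pattern — identical across random seeds.

Sweeping the de-escalated-group prevalence from the overall prevalence up to
100% and re-fitting the propensity-adjusted time-dependent Cox model with
the simulated flag as an extra baseline covariate traces how the apparent
protective effect of de-escalation dissolves as the confounder concentrates
in the de-escalated group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DataError, DeescbiasError, InfeasibleScenarioError
from .ranking import CONTINUATION, DE_ESCALATION, ESCALATION
from .survival import build_intervals, fit_cox

GROUP_DE = "de-escalated"
GROUP_CONT = "continued"


@dataclass(frozen=True)
class ConfounderScenario:
    """The three bias parameters plus randomisation controls."""

    overall_prevalence: float = 0.80
    deescalated_prevalence: float = 0.90
    target_or: float = 0.14
    seed: int = 0
    n_seed_repeats: int = 3

    def __post_init__(self):
        if not 0 < self.overall_prevalence < 1:
            raise InfeasibleScenarioError("overall prevalence must be in (0,1)")
        if not 0 <= self.deescalated_prevalence <= 1:
            raise InfeasibleScenarioError("de-escalated-group prevalence must be in [0,1]")
        if self.target_or <= 0:
            raise InfeasibleScenarioError("target odds ratio must be positive")


def implied_continuation_prevalence(
    pi: float, pi_de: float, n_de: int, n_cont: int
) -> float:
    """Prevalence in the continuation group implied by the weighted average.

    The overall prevalence is the size-weighted average of the two group
    prevalences, so fixing the overall value and the de-escalated-group
    value determines the continuation-group value:
    ``pi_cont = (pi * (n_de + n_cont) - pi_de * n_de) / n_cont``.
    """
    if n_de < 0 or n_cont <= 0:
        raise DataError("group sizes must be positive")
    pi_cont = (pi * (n_de + n_cont) - pi_de * n_de) / n_cont
    if not -1e-12 <= pi_cont <= 1 + 1e-12:
        raise InfeasibleScenarioError(
            f"de-escalated prevalence {pi_de:.3f} with overall {pi:.3f} implies a "
            f"continuation prevalence of {pi_cont:.3f}, outside [0, 1]"
        )
    return float(min(max(pi_cont, 0.0), 1.0))


@dataclass
class CalibratedAllocation:
    """Solved stratum-level assignment of the simulated confounder.

    Strata are (exposure group) x (30-day death).  ``sizes`` and ``stable``
    map ``(group, died)`` to the stratum size and the number of patients
    assigned stable; ``probs`` holds the real-valued solution before integer
    rounding, and ``psi`` the solved common within-group stability–death
    odds ratio.
    """

    sizes: dict
    stable: dict
    probs: dict
    psi: float
    target_or: float
    pi_de_target: float
    pi_cont_target: float
    realized_pi_de: float
    realized_pi_cont: float
    realized_pi_overall: float
    realized_or: float
    rounding_tol_log: float

    def __post_init__(self) -> None:
        for key, k in self.stable.items():
            assert 0 <= k <= self.sizes[key], f"stratum {key}: {k} > size {self.sizes[key]}"
        n_de = self.sizes[(GROUP_DE, 1)] + self.sizes[(GROUP_DE, 0)]
        n_cont = self.sizes[(GROUP_CONT, 1)] + self.sizes[(GROUP_CONT, 0)]
        assert abs(self.realized_pi_de - self.pi_de_target) <= 1.0 / max(n_de, 1) + 1e-12
        assert abs(self.realized_pi_cont - self.pi_cont_target) <= 1.0 / n_cont + 1e-12

    def table(self) -> pd.DataFrame:
        """The pooled 2x2 stability-by-death table (integer counts)."""
        a = self.stable[(GROUP_DE, 1)] + self.stable[(GROUP_CONT, 1)]
        b = self.stable[(GROUP_DE, 0)] + self.stable[(GROUP_CONT, 0)]
        c = self.sizes[(GROUP_DE, 1)] + self.sizes[(GROUP_CONT, 1)] - a
        d = self.sizes[(GROUP_DE, 0)] + self.sizes[(GROUP_CONT, 0)] - b
        return pd.DataFrame(
            {"died": [a, c], "survived": [b, d]}, index=["stable", "unstable"]
        )


def _group_probs(pi_g: float, n_dead: int, n_surv: int, log_psi: float) -> tuple[float, float]:
    """Stability probabilities (survivor, death stratum) for one group.

    Solves for p0 (survivors) such that the group prevalence is ``pi_g``
    while the within-group stability–death odds ratio is exp(log_psi).
    """
    n_g = n_dead + n_surv
    if pi_g >= 1 - 1e-12:
        return 1.0, 1.0
    if pi_g <= 1e-12:
        return 0.0, 0.0
    f = n_dead / n_g

    def p1_of(p0: float) -> float:
        return 1.0 / (1.0 + np.exp(-(np.log(p0 / (1 - p0)) + log_psi)))

    if f == 0:
        return pi_g, p1_of(pi_g)

    def gap(p0: float) -> float:
        return f * p1_of(p0) + (1 - f) * p0 - pi_g

    lo, hi = 1e-15, 1 - 1e-15
    # at extreme psi the within-group equation saturates: clamp one stratum
    # at its boundary and solve the other from the prevalence constraint
    if gap(hi) < 0:
        return 1.0, min(1.0, max(0.0, (pi_g - (1 - f)) / f))
    if gap(lo) > 0:
        return 0.0, min(1.0, pi_g / f)
    p0 = brentq(gap, lo, hi, xtol=1e-14)
    return float(p0), float(p1_of(p0))


def _pooled_log_or(probs: dict, sizes: dict) -> float:
    a = sum(probs[(g, 1)] * sizes[(g, 1)] for g in (GROUP_DE, GROUP_CONT))
    b = sum(probs[(g, 0)] * sizes[(g, 0)] for g in (GROUP_DE, GROUP_CONT))
    c = sum((1 - probs[(g, 1)]) * sizes[(g, 1)] for g in (GROUP_DE, GROUP_CONT))
    d = sum((1 - probs[(g, 0)]) * sizes[(g, 0)] for g in (GROUP_DE, GROUP_CONT))
    if min(a, b, c, d) <= 0:
        return np.inf if c * b == 0 else -np.inf
    return float(np.log(a) + np.log(d) - np.log(b) - np.log(c))


def solve_allocation(
    scenario: ConfounderScenario,
    n_de: int,
    n_cont: int,
    d_de: int,
    d_cont: int,
) -> CalibratedAllocation:
    """Solve the stratum-level confounder assignment for given margins.

    The common within-group odds ratio psi is found by monotone root finding
    so that the pooled crude stability–death odds ratio equals
    ``scenario.target_or``; real-valued stratum probabilities are converted
    to integer counts that keep each group's stable total at the rounded
    prevalence target, choosing among those integer tables the one whose
    pooled odds ratio is closest to the target (ties resolved toward the
    real-valued solution).
    """
    if d_de > n_de or d_cont > n_cont:
        raise DataError("death counts cannot exceed group sizes")
    pi = scenario.overall_prevalence
    pi_de = scenario.deescalated_prevalence
    pi_cont = implied_continuation_prevalence(pi, pi_de, n_de, n_cont)
    sizes = {
        (GROUP_DE, 1): d_de,
        (GROUP_DE, 0): n_de - d_de,
        (GROUP_CONT, 1): d_cont,
        (GROUP_CONT, 0): n_cont - d_cont,
    }

    def probs_at(log_psi: float) -> dict:
        p_de0, p_de1 = _group_probs(pi_de, d_de, n_de - d_de, log_psi)
        p_c0, p_c1 = _group_probs(pi_cont, d_cont, n_cont - d_cont, log_psi)
        return {
            (GROUP_DE, 0): p_de0,
            (GROUP_DE, 1): p_de1,
            (GROUP_CONT, 0): p_c0,
            (GROUP_CONT, 1): p_c1,
        }

    target = np.log(scenario.target_or)
    span = 30.0
    lo, hi = _pooled_log_or(probs_at(-span), sizes), _pooled_log_or(probs_at(span), sizes)
    if not lo - 1e-9 <= target <= hi + 1e-9:
        raise InfeasibleScenarioError(
            f"target OR {scenario.target_or:.4g} outside the attainable range "
            f"[{np.exp(lo):.4g}, {np.exp(hi):.4g}] for these margins"
        )
    log_psi = brentq(
        lambda x: _pooled_log_or(probs_at(x), sizes) - target, -span, span, xtol=1e-12
    )
    probs = probs_at(log_psi)

    # ---- integer allocation -------------------------------------------------
    T_de = int(np.floor(pi_de * n_de + 0.5))
    T_cont = int(np.floor(pi_cont * n_cont + 0.5))
    e_de1 = probs[(GROUP_DE, 1)] * d_de
    e_c1 = probs[(GROUP_CONT, 1)] * d_cont
    stable = _best_integer_table(
        sizes, T_de, T_cont, target, expected=(e_de1, e_c1)
    )

    a = stable[(GROUP_DE, 1)] + stable[(GROUP_CONT, 1)]
    b = stable[(GROUP_DE, 0)] + stable[(GROUP_CONT, 0)]
    c = d_de + d_cont - a
    d = (n_de - d_de) + (n_cont - d_cont) - b
    realized_or = (a * d) / (b * c) if b * c > 0 else float("nan")
    cells = [
        sum(probs[(g, 1)] * sizes[(g, 1)] for g in (GROUP_DE, GROUP_CONT)),
        sum(probs[(g, 0)] * sizes[(g, 0)] for g in (GROUP_DE, GROUP_CONT)),
        sum((1 - probs[(g, 1)]) * sizes[(g, 1)] for g in (GROUP_DE, GROUP_CONT)),
        sum((1 - probs[(g, 0)]) * sizes[(g, 0)] for g in (GROUP_DE, GROUP_CONT)),
    ]
    tol = float(sum(1.0 / max(x, 1.0) for x in cells))
    return CalibratedAllocation(
        sizes=sizes,
        stable=stable,
        probs=probs,
        psi=float(np.exp(log_psi)),
        target_or=scenario.target_or,
        pi_de_target=pi_de,
        pi_cont_target=pi_cont,
        realized_pi_de=(stable[(GROUP_DE, 1)] + stable[(GROUP_DE, 0)]) / max(n_de, 1),
        realized_pi_cont=(stable[(GROUP_CONT, 1)] + stable[(GROUP_CONT, 0)]) / n_cont,
        realized_pi_overall=(a + b) / (n_de + n_cont),
        realized_or=float(realized_or),
        rounding_tol_log=tol,
    )


def _best_integer_table(sizes, T_de: int, T_cont: int, log_target: float, expected):
    """Integer stratum counts with fixed group totals, OR closest to target.

    Scans the de-escalated death-stratum count; for each value the optimal
    continuation death-stratum count solves a quadratic (the pooled OR is
    monotone in it), and the floor/ceil candidates are compared on
    |log OR - log target| with ties broken toward the real-valued solution.
    """
    d_de, s_de = sizes[(GROUP_DE, 1)], sizes[(GROUP_DE, 0)]
    d_c, s_c = sizes[(GROUP_CONT, 1)], sizes[(GROUP_CONT, 0)]
    d_tot, s_tot = d_de + d_c, s_de + s_c
    e_de1, e_c1 = expected
    t = np.exp(log_target)

    lo1 = max(0, T_de - s_de)
    hi1 = min(d_de, T_de)
    best = None
    for k1 in range(lo1, hi1 + 1):
        lo2 = max(0, T_cont - s_c)
        hi2 = min(d_c, T_cont)
        # pooled cells as a function of the continuation death-stratum count k:
        # A = k1 + k, C = d_tot - A, B = (T_de - k1) + (T_cont - k), D = s_tot - B
        a0, b0 = k1, (T_de - k1) + T_cont
        c0, d0 = d_tot - k1, s_tot - b0
        # (1-t) k^2 + (a0 + d0 + t(b0 + c0)) k + a0 d0 - t b0 c0 = 0
        A2, B2, C2 = (1 - t), (a0 + d0 + t * (b0 + c0)), (a0 * d0 - t * b0 * c0)
        roots = []
        if abs(A2) < 1e-12:
            if B2 != 0:
                roots = [-C2 / B2]
        else:
            disc = B2 * B2 - 4 * A2 * C2
            if disc >= 0:
                r = np.sqrt(disc)
                roots = [(-B2 - r) / (2 * A2), (-B2 + r) / (2 * A2)]
        cands = {lo2, hi2}
        for r in roots:
            if np.isfinite(r):
                for c in (int(np.floor(r)), int(np.ceil(r))):
                    if lo2 <= c <= hi2:
                        cands.add(c)
        for k in cands:
            A = k1 + k
            C = d_tot - A
            B = (T_de - k1) + (T_cont - k)
            D = s_tot - B
            if min(A, B, C, D) < 0:
                continue
            if min(A, B, C, D) == 0:
                dev = np.inf
            else:
                dev = abs(np.log(A * D / (B * C)) - log_target)
            tie = abs(k1 - e_de1) + abs(k - e_c1)
            key = (dev, tie, k1, k)
            if best is None or key < best[0]:
                best = (key, k1, k)
    if best is None:
        raise InfeasibleScenarioError("no feasible integer allocation for these margins")
    _, k1, k = best
    return {
        (GROUP_DE, 1): k1,
        (GROUP_DE, 0): T_de - k1,
        (GROUP_CONT, 1): k,
        (GROUP_CONT, 0): T_cont - k,
    }


# ---------------------------------------------------------------------------
# patient-level assignment
# ---------------------------------------------------------------------------

def analysis_groups(analysis: pd.DataFrame, horizon: int = 30) -> pd.DataFrame:
    """Exposure group and 30-day death flag per analysis-set patient.

    Escalated patients form their own group: by default they are outside the
    odds-ratio constraint (they are censored at escalation in the Cox model)
    but still receive a simulated value so their pre-escalation person-time
    can carry the covariate.
    """
    group = np.select(
        [analysis["label"] == DE_ESCALATION, analysis["label"] == CONTINUATION],
        [GROUP_DE, GROUP_CONT],
        default="escalated",
    )
    died = (
        analysis["death_day"].notna() & (analysis["death_day"].astype("float") <= horizon)
    ).astype(int)
    return pd.DataFrame(
        {"patient_id": analysis["patient_id"], "group": group, "died": died.to_numpy()}
    )


def margins(groups: pd.DataFrame) -> tuple[int, int, int, int]:
    """(n_de, n_cont, d_de, d_cont) from an :func:`analysis_groups` table."""
    de = groups["group"] == GROUP_DE
    cont = groups["group"] == GROUP_CONT
    return (
        int(de.sum()),
        int(cont.sum()),
        int(groups.loc[de, "died"].sum()),
        int(groups.loc[cont, "died"].sum()),
    )


def assign_confounder(
    groups: pd.DataFrame, allocation: CalibratedAllocation, seed: int
) -> pd.Series:
    """Flag exactly the allocated number of patients stable in each stratum.

    Within each (group x death) stratum the stable patients are chosen
    uniformly at random with the given seed; escalated patients (outside the
    allocation) are drawn as Bernoulli at the continuation-group stratum
    probability for their death status.  Returns a 0/1 Series indexed by
    patient_id.
    """
    rng = np.random.default_rng(seed)
    stable = pd.Series(0, index=groups["patient_id"].to_numpy(), name="stable_sim")
    for (g, died), k in allocation.stable.items():
        mask = (groups["group"] == g) & (groups["died"] == died)
        ids = groups.loc[mask, "patient_id"].to_numpy()
        if len(ids) != allocation.sizes[(g, died)]:
            raise DataError(
                f"stratum ({g}, died={died}): cohort has {len(ids)} patients but the "
                f"allocation was solved for {allocation.sizes[(g, died)]}"
            )
        chosen = rng.choice(ids, size=k, replace=False)
        stable.loc[chosen] = 1
    esc = groups["group"] == "escalated"
    if esc.any():
        p = {d: allocation.probs[(GROUP_CONT, d)] for d in (0, 1)}
        ids = groups.loc[esc, "patient_id"].to_numpy()
        died = groups.loc[esc, "died"].to_numpy()
        draw = rng.random(len(ids))
        stable.loc[ids] = (draw < np.where(died == 1, p[1], p[0])).astype(int)
    return stable


# ---------------------------------------------------------------------------
# prevalence sweep and confounder strength
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Adjusted hazard ratios along a grid of de-escalated-group prevalences."""

    frame: pd.DataFrame  # pi_de, pi_cont, hr, ci_low, ci_high, realized_or, psi, ...
    scenario: ConfounderScenario

    @property
    def crossing_threshold(self) -> float | None:
        """Smallest grid prevalence whose CI upper bound reaches 1."""
        ok = self.frame.dropna(subset=["ci_high"])
        hit = ok[ok["ci_high"] >= 1.0]
        return None if hit.empty else float(hit["pi_de"].iloc[0])


def default_grid(pi: float = 0.80, step: float = 0.01) -> np.ndarray:
    """pi -> 1.00 inclusive; the anchors 0.90 and 1.00 are always present."""
    grid = np.round(np.arange(pi, 1.0 + step / 2, step), 10)
    for anchor in (0.90, 1.00):
        if anchor >= pi and not np.any(np.isclose(grid, anchor)):
            grid = np.sort(np.append(grid, anchor))
    return grid


def run_sweep(
    analysis: pd.DataFrame,
    scores: pd.Series,
    scenario: ConfounderScenario,
    grid: np.ndarray | None = None,
    horizon: int = 30,
) -> SweepResult:
    """Re-fit the adjusted Cox model along a grid of de-escalated prevalences.

    For each grid value the allocation is solved, the confounder assigned
    (``n_seed_repeats`` times; the first seed's fit is reported and the
    spread across repeats logged), and the time-dependent Cox model re-fit
    with covariates = propensity score + simulated stability.  Per-point
    failures are recorded, not fatal.
    """
    groups = analysis_groups(analysis, horizon=horizon)
    n_de, n_cont, d_de, d_cont = margins(groups)
    cov = pd.DataFrame({"propensity": scores})
    base_intervals = build_intervals(analysis, horizon=horizon, covariates=cov)
    if grid is None:
        grid = default_grid(scenario.overall_prevalence)

    rows = []
    for pi_de in grid:
        row = {"pi_de": float(pi_de)}
        try:
            alloc = solve_allocation(
                replace(scenario, deescalated_prevalence=float(pi_de)),
                n_de, n_cont, d_de, d_cont,
            )
            hrs = []
            fits = []
            for r in range(scenario.n_seed_repeats):
                stable = assign_confounder(groups, alloc, seed=scenario.seed + r)
                iv = base_intervals.copy()
                iv["stable_sim"] = iv["patient_id"].map(stable).astype(int)
                fit = fit_cox(iv, covariates=["propensity", "stable_sim"])
                fits.append(fit)
                hrs.append(fit.hr)
            first = fits[0]
            row.update(
                pi_cont=alloc.pi_cont_target,
                hr=first.hr,
                ci_low=first.ci_low,
                ci_high=first.ci_high,
                realized_or=alloc.realized_or,
                psi=alloc.psi,
                hr_mean=float(np.mean(hrs)),
                hr_sem=float(np.std(hrs, ddof=1) / np.sqrt(len(hrs))) if len(hrs) > 1 else 0.0,
                hr_spread=float(np.max(hrs) - np.min(hrs)),
                error="",
            )
        except DeescbiasError as exc:
            row.update(
                pi_cont=np.nan, hr=np.nan, ci_low=np.nan, ci_high=np.nan,
                realized_or=np.nan, psi=np.nan, hr_mean=np.nan, hr_sem=np.nan,
                hr_spread=np.nan,
                error=str(exc),
            )
        rows.append(row)
    return SweepResult(frame=pd.DataFrame(rows), scenario=scenario)


def strength_table(
    analysis: pd.DataFrame,
    scores: pd.Series | None = None,
    scenario: ConfounderScenario | None = None,
    pi_de_values: tuple = (0.90, 1.00),
    horizon: int = 30,
) -> pd.DataFrame:
    """Percent change of the crude HR when each confounder is added alone.

    Covers every baseline covariate of the propensity model (season as a
    joint block of dummies, the day-1 rank as a rank-3 indicator), the
    propensity score itself when supplied, and the simulated stability
    confounder at the requested de-escalated-group prevalences.  The sign is
    preserved: a covariate whose addition raises the HR gets a positive
    percent change.  Sorted by absolute magnitude, descending.
    """
    from .propensity import BINARY_COVARIATES, CONTINUOUS_COVARIATES

    cov = pd.DataFrame(index=analysis["patient_id"].to_numpy())
    blocks: dict[str, list[str]] = {}
    for c in BINARY_COVARIATES + CONTINUOUS_COVARIATES:
        cov[c] = analysis[c].astype(float).to_numpy()
        blocks[c] = [c]
    for s in ("spring", "summer", "autumn"):
        cov[f"season_{s}"] = (analysis["season"] == s).astype(float).to_numpy()
    blocks["season"] = ["season_spring", "season_summer", "season_autumn"]
    cov["rank3"] = (analysis["initial_rank"] == 3).astype(float).to_numpy()
    blocks["rank_day1"] = ["rank3"]
    if scores is not None:
        cov["propensity"] = cov.index.map(scores)
        blocks["propensity_score"] = ["propensity"]

    intervals = build_intervals(analysis, horizon=horizon, covariates=cov)
    crude = fit_cox(intervals)

    rows = []
    for name, cols in blocks.items():
        try:
            # skip degenerate (constant) blocks
            use = [c for c in cols if intervals[c].nunique() > 1]
            if not use:
                raise DataError("constant covariate")
            fit = fit_cox(intervals, covariates=use)
            change = 100.0 * (fit.hr - crude.hr) / crude.hr
            rows.append({"confounder": name, "pct_change": change, "error": ""})
        except DeescbiasError as exc:
            rows.append({"confounder": name, "pct_change": np.nan, "error": str(exc)})

    if scenario is not None:
        groups = analysis_groups(analysis, horizon=horizon)
        n_de, n_cont, d_de, d_cont = margins(groups)
        for pi_de in pi_de_values:
            label = f"clinical_stability_simulated_pi_de_{pi_de:.2f}"
            try:
                alloc = solve_allocation(
                    replace(scenario, deescalated_prevalence=float(pi_de)),
                    n_de, n_cont, d_de, d_cont,
                )
                stable = assign_confounder(groups, alloc, seed=scenario.seed)
                iv = intervals.copy()
                iv["stable_sim"] = iv["patient_id"].map(stable).astype(int)
                fit = fit_cox(iv, covariates=["stable_sim"])
                change = 100.0 * (fit.hr - crude.hr) / crude.hr
                rows.append({"confounder": label, "pct_change": change, "error": ""})
            except DeescbiasError as exc:
                rows.append({"confounder": label, "pct_change": np.nan, "error": str(exc)})

    out = pd.DataFrame(rows)
    out["abs_change"] = out["pct_change"].abs()
    out = out.sort_values("abs_change", ascending=False, na_position="last")
    return out.drop(columns="abs_change").reset_index(drop=True)
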