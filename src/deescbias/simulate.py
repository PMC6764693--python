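"""Synthetic cohort generator and the deterministic reference fixture.

The generator emulates a cohort of elderly, non-ICU community-acquired
pneumonia patients in which a latent binary "clinically stable at 72 h"
variable drives both the decision to de-escalate antibiotics and 30-day
survival — the statistical structure a confounding-by-indication analysis
assumes.  Defaults target the reference marginals: rank distribution
13.7/40.6/45.6%, ~16.7% de-escalation with median switch day 3 (IQR 2–4),
~8% escalation, stability prevalence 0.80 with a crude stability–death odds
ratio of 0.14, and a configurable *true* conditional effect of de-escalation
on the death hazard (default hazard ratio 1, i.e. no causal effect).

Four scalar parameters are calibrated at generation time against the drawn
covariates by monotone root finding: the stability intercept (hits the
prevalence target), the de-escalation intercept (hits the de-escalation
share, net of deaths occurring before the intended switch day), and the
mortality intercept and stability coefficient (jointly hit the overall
30-day mortality and the crude stability–death odds ratio).  Calibration is
deterministic given the seed; infeasible targets raise
:class:`CalibrationError`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import AnalysisCohort, SEASONS
from .errors import CalibrationError
from .ranking import DE_ESCALATION, ESCALATION, CONTINUATION, classify_cohort

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Baseline covariate marginals (Bernoulli probabilities).
DEFAULT_MARGINALS = {
    "male": 0.712,
    "smoker": 0.126,
    "nursing_home": 0.08,
    "chronic_pulmonary": 0.553,
    "chronic_cardiovascular": 0.423,
    "chronic_renal": 0.007,
    "chronic_liver": 0.011,
    "diabetes": 0.210,
    "neoplastic": 0.10,
    "cerebrovascular": 0.10,
    "altered_mental_status": 0.05,
    "pleural_effusion": 0.10,
    "prior_antibiotics": 0.321,
    "weekend_admission": 0.399,
    "pathogen_identified": 0.305,
}

#: (mean, sd, lower clip, upper clip) for vitals and labs.
DEFAULT_VITALS = {
    "resp_rate": (24.0, 6.0, 10.0, 50.0),
    "systolic_bp": (130.0, 20.0, 70.0, 210.0),
    "temperature": (38.0, 0.9, 35.0, 41.5),
    "heart_rate": (95.0, 18.0, 40.0, 170.0),
    "ph": (7.42, 0.05, 7.10, 7.60),
    "bun": (9.0, 4.0, 1.5, 40.0),
    "sodium": (137.0, 4.0, 118.0, 152.0),
    "glucose": (7.5, 2.5, 2.5, 25.0),
    "hematocrit": (0.40, 0.05, 0.20, 0.60),
    "po2": (70.0, 12.0, 40.0, 110.0),
}


@dataclass(frozen=True)
class DeescalationLogit:
    """Log-odds model for the decision to de-escalate (rank-2/3 starters).

    The intercept is calibrated at generation time; the slopes are fixed
    conditions of the simulation.  ``stable`` is the log-odds advantage of a
    clinically stable patient (strongly positive: physicians rarely narrow
    therapy in unstable patients); ``rank3`` reflects that extended-spectrum
    starters have more room to step down; ``pathogen`` that an identified
    pathogen invites targeted (narrower) therapy.
    """

    stable: float = 2.4
    rank3: float = 1.8
    pathogen: float = 0.5


@dataclass(frozen=True)
class MortalityModel:
    """Discrete-time (daily) logistic hazard for 30-day death.

    ``rate_30d`` is the target overall 30-day mortality; the daily intercept
    and the stability coefficient are solved from (``rate_30d``,
    ``stability_mortality_or`` of the enclosing config).  ``psi`` and ``age``
    are log daily-odds slopes per sample standard deviation.
    """

    rate_30d: float = 0.097
    psi: float = 0.30
    age: float = 0.15


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 1536
    seed: int = 0
    rank_probs: tuple = (0.137, 0.406, 0.457)
    p_stable: float = 0.80
    stability_mortality_or: float = 0.14
    stability_psi_slope: float = -0.6  # log-odds of stability per SD of PSI
    deescalation_target: float = 0.167  # share of the whole cohort
    deescalation_logit: DeescalationLogit = field(default_factory=DeescalationLogit)
    switch_day_probs: tuple = (0.10, 0.23, 0.30, 0.20, 0.09, 0.05, 0.03)  # days 1..7
    escalation_prob: tuple = (0.194, 0.141, 0.0)  # per initial rank 1/2/3
    mortality: MortalityModel = field(default_factory=MortalityModel)
    causal_deescalation_hr: float = 1.0
    late_hr: float | None = None  # optional post-`late_hr_day` hazard ratio
    late_hr_day: int = 20
    followup_days: int = 90
    covariate_marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))

    def __post_init__(self):
        if abs(sum(self.rank_probs) - 1.0) > 0.01:
            raise CalibrationError("rank_probs must sum to ~1")
        if not 0 < self.p_stable < 1:
            raise CalibrationError("p_stable must be in (0,1)")
        if self.stability_mortality_or <= 0:
            raise CalibrationError("stability_mortality_or must be positive")
        if self.causal_deescalation_hr <= 0:
            raise CalibrationError("causal_deescalation_hr must be positive")
        if abs(sum(self.switch_day_probs) - 1.0) > 1e-6:
            raise CalibrationError("switch_day_probs must sum to 1")


@dataclass
class GenerationReport:
    """Marginals realised by one generated cohort (all recomputable from it)."""

    n_patients: int
    seed: int
    deescalation_share: float
    escalation_share: float
    stability_prevalence: float
    stability_death_or: float
    median_switch_day: float
    mortality_deescalated: float
    mortality_continuation: float
    mortality_overall_30d: float
    config: dict


# regimens used to realise each spectrum rank (drug names feed the rank table)
_RANK1_REGIMENS = [("amoxicillin",), ("doxycycline",)]
_RANK2_REGIMENS = [("co-amoxiclav",), ("azithromycin",), ("cefuroxime",)]
_RANK3_REGIMENS = [("ceftriaxone",), ("moxifloxacin",), ("amoxicillin", "azithromycin")]
_RANK1_PROBS = (0.8, 0.2)
_RANK2_PROBS = (0.6, 0.25, 0.15)
_RANK3_PROBS = (0.5, 0.3, 0.2)
_DEESC_TO_RANK2 = ("co-amoxiclav",)
_DEESC_TO_RANK1 = ("doxycycline",)
_ESC_TO_RANK3 = ("ceftriaxone",)
_ESC_TO_RANK2 = ("co-amoxiclav",)


def _solve_monotone(f, lo: float, hi: float, what: str) -> float:
    """brentq with an explicit infeasibility message when no sign change."""
    flo, fhi = f(lo), f(hi)
    if np.isnan(flo) or np.isnan(fhi) or flo * fhi > 0:
        raise CalibrationError(
            f"cannot calibrate {what}: target outside attainable range "
            f"[f({lo:.3g})={flo:.4g}, f({hi:.3g})={fhi:.4g}]"
        )
    return brentq(f, lo, hi, xtol=1e-10)


def _death_prob_30d(daily_logit: np.ndarray) -> np.ndarray:
    """P(death by day 30) under a constant daily hazard."""
    h = expit(daily_logit)
    return 1.0 - (1.0 - h) ** 30


def generate(config: GeneratorConfig) -> tuple[AnalysisCohort, GenerationReport]:
    """Draw one synthetic cohort; deterministic given ``config`` (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    # -- baseline covariates ------------------------------------------------
    pat = pd.DataFrame({"patient_id": [f"S{i:06d}" for i in range(1, n + 1)]})
    age = 65 + rng.gamma(shape=2.9, scale=4.2, size=n)
    pat["age"] = np.clip(np.round(age), 65, 100).astype(int)
    for name, p in config.covariate_marginals.items():
        pat[name] = (rng.random(n) < p).astype(int)
    for name, (mu, sd, lo, hi) in DEFAULT_VITALS.items():
        pat[name] = np.clip(rng.normal(mu, sd, size=n), lo, hi)
    pat["psi_score"] = np.clip(np.round(rng.normal(100, 26, size=n)), 20, 250).astype(int)
    pat["season"] = np.asarray(SEASONS)[rng.integers(0, 4, size=n)]
    pat["icu_admission"] = 0
    z_psi = (pat["psi_score"] - pat["psi_score"].mean()) / pat["psi_score"].std()
    z_age = (pat["age"] - pat["age"].mean()) / pat["age"].std()

    # -- latent clinical stability at 72 h ---------------------------------
    lin_s = config.stability_psi_slope * z_psi.to_numpy()
    a_s = _solve_monotone(
        lambda a: expit(a + lin_s).mean() - config.p_stable, -20, 20, "stability prevalence"
    )
    stable = (rng.random(n) < expit(a_s + lin_s)).astype(int)
    pat["latent_stable_72h"] = stable

    # -- empirical rank and intended treatment adjustments -------------------
    probs = np.asarray(config.rank_probs, dtype=float)
    rank0 = rng.choice([1, 2, 3], size=n, p=probs / probs.sum())
    pathogen = pat["pathogen_identified"].to_numpy()

    days = np.arange(1, 8)
    sd_probs = np.asarray(config.switch_day_probs)
    switch_day = rng.choice(days, size=n, p=sd_probs)

    # survival-to-switch weight: chance of still being alive when the switch
    # would happen, used so that calibration targets the *realised* share
    eligible = rank0 >= 2
    dl = config.deescalation_logit
    lin_d = dl.stable * stable + dl.rank3 * (rank0 == 3) + dl.pathogen * pathogen

    mort = config.mortality
    lin_m = mort.psi * z_psi.to_numpy() + mort.age * z_age.to_numpy()

    def _mortality_params() -> tuple[float, float]:
        """Solve (daily intercept, stability coefficient) for the 30-day
        mortality rate and the crude stability-death odds ratio."""
        target_or = config.stability_mortality_or

        def realized(b_st: float) -> tuple[float, float, float]:
            def mean_mort(a: float) -> float:
                return _death_prob_30d(a + b_st * stable + lin_m).mean() - mort.rate_30d

            a = _solve_monotone(mean_mort, -20, 5, "overall 30-day mortality")
            p = _death_prob_30d(a + b_st * stable + lin_m)
            p1 = p[stable == 1].mean()
            p0 = p[stable == 0].mean()
            return a, p1, p0

        if target_or == 1.0:
            a, _, _ = realized(0.0)
            return a, 0.0

        def or_gap(b_st: float) -> float:
            _, p1, p0 = realized(b_st)
            return np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0)) - np.log(target_or)

        b = _solve_monotone(or_gap, -8, 8, "stability-death odds ratio")
        a, _, _ = realized(b)
        return a, b

    a_m, b_st = _mortality_params()
    daily_logit = a_m + b_st * stable + lin_m
    # expected probability of surviving the days before the switch day
    h = expit(daily_logit)
    surv_pre = ((1.0 - h)[:, None] ** (days - 1)[None, :] * sd_probs[None, :]).sum(axis=1)

    target_count = config.deescalation_target * n

    def deesc_gap(b0: float) -> float:
        pi = expit(b0 + lin_d) * eligible
        return float((pi * surv_pre).sum() - target_count)

    if target_count <= 0:
        p_deesc = np.zeros(n)
    else:
        b0 = _solve_monotone(deesc_gap, -30, 20, "de-escalation share")
        p_deesc = expit(b0 + lin_d) * eligible
    intends_deesc = rng.random(n) < p_deesc

    esc_p = np.select([rank0 == 1, rank0 == 2], config.escalation_prob[:2], 0.0)
    intends_esc = (~intends_deesc) & (rng.random(n) < esc_p)
    esc_day = rng.choice(days, size=n, p=sd_probs)

    # -- death day: daily Bernoulli hazard, de-escalation scales the odds ----
    T = config.followup_days
    day_grid = np.arange(1, T + 1)
    logit_mat = np.broadcast_to(daily_logit[:, None], (n, T)).copy()
    exposed = intends_deesc[:, None] & (day_grid[None, :] >= switch_day[:, None])
    logit_mat[exposed] += np.log(config.causal_deescalation_hr)
    if config.late_hr is not None:
        late = exposed & (day_grid[None, :] > config.late_hr_day)
        logit_mat[late] += np.log(config.late_hr) - np.log(config.causal_deescalation_hr)
    died_mat = rng.random((n, T)) < expit(logit_mat)
    any_death = died_mat.any(axis=1)
    death_day = np.where(any_death, died_mat.argmax(axis=1) + 1, -1)

    # a death before the intended switch day cancels the switch
    deesc = intends_deesc & (~any_death | (death_day >= switch_day))
    esc = intends_esc & (~any_death | (death_day >= esc_day))

    pat["death_day"] = pd.Series(np.where(any_death, death_day, np.nan)).astype("Int64")
    pat["last_followup_day"] = np.where(any_death, death_day, T).astype(int)

    # -- treatment events ----------------------------------------------------
    events = _build_events(rng, pat["patient_id"].to_numpy(), rank0, deesc, switch_day, esc, esc_day)

    cohort = AnalysisCohort(patients=pat, events=events, provenance="synthetic")
    report = _report(cohort, config)
    return cohort, report


def _build_events(rng, ids, rank0, deesc, switch_day, esc, esc_day) -> pd.DataFrame:
    n = len(ids)
    reg_choice = {
        1: (rng.choice(len(_RANK1_REGIMENS), size=n, p=_RANK1_PROBS), _RANK1_REGIMENS),
        2: (rng.choice(len(_RANK2_REGIMENS), size=n, p=_RANK2_PROBS), _RANK2_REGIMENS),
        3: (rng.choice(len(_RANK3_REGIMENS), size=n, p=_RANK3_PROBS), _RANK3_REGIMENS),
    }
    # de-escalation destination: rank 3 steps to rank 2 (80%) or rank 1
    to_rank1 = rng.random(n) < 0.2
    pid_col, day_col, drug_col = [], [], []

    def add(pid, day, regimen):
        for drug in regimen:
            pid_col.append(pid)
            day_col.append(day)
            drug_col.append(drug)

    for i in range(n):
        r = int(rank0[i])
        idx, table = reg_choice[r]
        add(ids[i], 0, table[idx[i]])
        if deesc[i]:
            if r == 2 or to_rank1[i]:
                add(ids[i], int(switch_day[i]), _DEESC_TO_RANK1)
            else:
                add(ids[i], int(switch_day[i]), _DEESC_TO_RANK2)
        elif esc[i]:
            add(ids[i], int(esc_day[i]), _ESC_TO_RANK2 if r == 1 and rng.random() < 0.5 else _ESC_TO_RANK3)
    return pd.DataFrame({"patient_id": pid_col, "day": day_col, "drug": drug_col})


def _report(cohort: AnalysisCohort, config: GeneratorConfig) -> GenerationReport:
    classified = classify_cohort(cohort)
    pat = cohort.patients
    n = len(pat)
    died30 = (pat["death_day"].fillna(10_000) <= 30).to_numpy()
    stable = pat["latent_stable_72h"].to_numpy().astype(int)
    de = (classified["label"] == DE_ESCALATION).to_numpy()
    es = (classified["label"] == ESCALATION).to_numpy()
    cont = (classified["label"] == CONTINUATION).to_numpy() & (
        classified["initial_rank"].to_numpy() >= 2
    )
    a = float((stable & died30).sum())
    b = float((stable & ~died30).sum())
    c = float((~stable.astype(bool) & died30).sum())
    d = float((~stable.astype(bool) & ~died30).sum())
    or_ = (a * d) / (b * c) if b * c > 0 else float("nan")
    switch_days = classified.loc[de, "switch_day"].astype(float)
    cfg = asdict(config)
    cfg["covariate_marginals"] = dict(sorted(cfg["covariate_marginals"].items()))
    return GenerationReport(
        n_patients=n,
        seed=config.seed,
        deescalation_share=float(de.mean()),
        escalation_share=float(es.mean()),
        stability_prevalence=float(stable.mean()),
        stability_death_or=float(or_),
        median_switch_day=float(switch_days.median()) if de.any() else float("nan"),
        mortality_deescalated=float(died30[de].mean()) if de.any() else float("nan"),
        mortality_continuation=float(died30[cont].mean()) if cont.any() else float("nan"),
        mortality_overall_30d=float(died30.mean()),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# deterministic fixture
# ---------------------------------------------------------------------------

def make_fixture() -> AnalysisCohort:
    """Deterministic 1,536-patient cohort reproducing the reference marginals.

    Exactly 211/624/701 patients start in rank 1/2/3; 257 de-escalate
    (42 from rank 2, 215 from rank 3) with switch-day counts chosen so the
    median is day 3 (IQR 2–4); 123 escalate (41 from rank 1, 82 from
    rank 2); 1,156 continue unchanged.  Among the de-escalated there are
    9 deaths by day 30 and 14 later escalations (disjoint sets); among the
    986 continuation patients of rank 2–3 there are 107 deaths.  Death days
    are spread deterministically over days 2–29.  Covariates follow fixed
    modular stride patterns matching the reference frequencies, so repeated
    calls are byte-identical and model fits on the fixture are reproducible.
    """
    n = 1536
    i = np.arange(n)
    ids = np.array([f"P{k:04d}" for k in range(1, n + 1)])

    rank0 = np.empty(n, dtype=int)
    rank0[:211] = 1
    rank0[211:835] = 2
    rank0[835:] = 3

    label = np.full(n, CONTINUATION, dtype=object)
    switch_day = np.full(n, -1)
    # rank-1 escalations (41), rank-2 de-escalations (42) & escalations (82),
    # rank-3 de-escalations (215)
    esc_idx = np.concatenate([i[:41], i[253:335]])
    deesc_idx = np.concatenate([i[211:253], i[835:1050]])
    label[esc_idx] = ESCALATION
    label[deesc_idx] = DE_ESCALATION

    day_seq = np.repeat([1, 2, 3, 4, 5, 6, 7], [26, 51, 77, 51, 26, 15, 11])
    assert len(day_seq) == 257
    switch_day[deesc_idx] = day_seq
    switch_day[esc_idx] = np.tile([1, 2, 3, 4, 5], 25)[: len(esc_idx)]

    # deaths: 9 de-escalated (switch day 3), 107 rank-2/3 continuation
    death_day = np.full(n, -1)
    deesc_dead = deesc_idx[80:89]
    death_day[deesc_dead] = np.arange(5, 32, 3)
    cont_rank23 = np.concatenate([i[335:835], i[1050:]])
    assert len(cont_rank23) == 986
    # spread the 107 deaths across the whole continuation block (both ranks)
    death_day[cont_rank23[np.arange(107) * 9]] = 2 + (np.arange(107) % 28)

    # 14 later escalations after de-escalation (all alive, switch day 3)
    later_esc_idx = deesc_idx[100:114]
    later_esc_day = switch_day[later_esc_idx] + 3

    pat = pd.DataFrame({"patient_id": ids})
    pat["age"] = 65 + (i * 47) % 31

    def stride(mult: int, p: float) -> np.ndarray:
        return (((i * mult + mult) % 1000) < round(1000 * p)).astype(int)

    marg = DEFAULT_MARGINALS
    strides = {
        "male": 7, "smoker": 11, "nursing_home": 13, "chronic_pulmonary": 17,
        "chronic_cardiovascular": 19, "chronic_renal": 23, "chronic_liver": 27,
        "diabetes": 29, "neoplastic": 31, "cerebrovascular": 37,
        "altered_mental_status": 41, "pleural_effusion": 43,
        "prior_antibiotics": 49, "weekend_admission": 51, "pathogen_identified": 53,
    }
    for name, mult in strides.items():
        pat[name] = stride(mult, marg[name])
    pat["resp_rate"] = (18 + (i * 7) % 23).astype(float)
    pat["systolic_bp"] = (100 + (i * 11) % 61).astype(float)
    pat["temperature"] = 36.5 + ((i * 13) % 30) / 10.0
    pat["heart_rate"] = (70 + (i * 17) % 55).astype(float)
    pat["ph"] = 7.30 + ((i * 19) % 21) / 100.0
    pat["bun"] = (4 + (i * 23) % 14).astype(float)
    pat["sodium"] = (130 + (i * 29) % 15).astype(float)
    pat["glucose"] = (4 + (i * 31) % 10).astype(float)
    pat["hematocrit"] = 0.30 + ((i * 37) % 20) / 100.0
    pat["po2"] = (55 + (i * 41) % 40).astype(float)
    pat["psi_score"] = 70 + (i * 43) % 60
    pat["season"] = np.asarray(SEASONS)[i % 4]
    pat["icu_admission"] = 0
    pat["death_day"] = pd.Series(np.where(death_day > 0, death_day, np.nan)).astype("Int64")
    pat["last_followup_day"] = np.where(death_day > 0, death_day, 90)

    day0 = {1: ("amoxicillin",), 2: ("co-amoxiclav",), 3: ("ceftriaxone",)}
    pid_col, day_col, drug_col = [], [], []

    def add(k: int, day: int, regimen) -> None:
        for drug in regimen:
            pid_col.append(ids[k])
            day_col.append(day)
            drug_col.append(drug)

    for k in range(n):
        add(k, 0, day0[rank0[k]])
        if label[k] == DE_ESCALATION:
            dest = _DEESC_TO_RANK1 if rank0[k] == 2 else _DEESC_TO_RANK2
            add(k, int(switch_day[k]), dest)
        elif label[k] == ESCALATION:
            dest = _ESC_TO_RANK2 if rank0[k] == 1 else _ESC_TO_RANK3
            add(k, int(switch_day[k]), dest)
    for k, day in zip(later_esc_idx, later_esc_day):
        add(int(k), int(day), _ESC_TO_RANK3)

    events = pd.DataFrame({"patient_id": pid_col, "day": day_col, "drug": drug_col})
    return AnalysisCohort(patients=pat, events=events, provenance="fixture")
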