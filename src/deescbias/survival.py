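"""Counting-process dataset construction and time-dependent Cox models.

De-escalation is a time-dependent exposure: a patient contributes unexposed
person-time up to the switch day and exposed person-time from the switch day
on (start–stop risk intervals), which avoids the immortal-time bias that a
baseline-coded exposure would introduce.  Escalated patients are censored at
the day of escalation — including patients who escalate after first
de-escalating — and everyone else is censored at the horizon (day 30 in the
main analysis).  Ties are handled with the Efron approximation.

Same-day conventions: de-escalation precedes a same-day death (the patient
dies exposed; the event is kept and recorded half a day after the switch so
the interval has positive length), while death precedes a same-day
escalation (the event is kept).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter
from scipy.stats import chi2

from .errors import ConvergenceError, DataError
from .ranking import DE_ESCALATION, ESCALATION

INTERVAL_COLUMNS = ("patient_id", "start", "stop", "deescalated", "event")


@dataclass
class CoxFit:
    """Partial-likelihood fit with de-escalation as the exposure of interest."""

    hr: float
    ci_low: float
    ci_high: float
    log_hr: float
    se: float
    coefficients: pd.Series
    n_events: int
    n_intervals: int
    log_likelihood: float

    def __post_init__(self) -> None:
        assert self.ci_low <= self.hr <= self.ci_high
        assert abs(np.exp(self.log_hr) - self.hr) < 1e-8 * max(1.0, self.hr)


def make_analysis_set(patients: pd.DataFrame, classified: pd.DataFrame) -> pd.DataFrame:
    """Join classification onto patients and drop rank-1 starters.

    Rank-1 (narrow-spectrum) starters cannot de-escalate and are excluded
    from the effect analysis.
    """
    merged = patients.merge(classified, on="patient_id", how="inner", validate="1:1")
    return merged[merged["initial_rank"] >= 2].reset_index(drop=True)


def build_intervals(
    analysis: pd.DataFrame,
    horizon: int = 30,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Expand the classified analysis set into start–stop risk intervals.

    ``analysis`` is the output of :func:`make_analysis_set` (rank-1 starters
    already excluded).  ``covariates`` optionally supplies per-patient
    columns (e.g. the propensity score, a simulated stability flag) indexed
    by ``patient_id``; they are attached to every interval of the patient.
    """
    if (analysis["initial_rank"] == 1).any():
        raise DataError("analysis set still contains rank-1 starters")

    rows = []
    for t in analysis.itertuples(index=False):
        pid = t.patient_id
        death = None if pd.isna(t.death_day) else int(t.death_day)
        cens = min(horizon, int(t.last_followup_day))
        s = None if pd.isna(t.switch_day) else int(t.switch_day)
        label = t.label
        later = None if pd.isna(t.later_escalation_day) else int(t.later_escalation_day)

        if label == ESCALATION:
            if death is not None and death < s:
                raise DataError(f"patient {pid!r}: escalation on day {s} after death day {death}")
            stop = min(s, cens)
            event = int(death is not None and death == stop)
            rows.append((pid, 0.0, float(stop), 0, event))
        elif label == DE_ESCALATION:
            if death is not None and death < s:
                raise DataError(
                    f"patient {pid!r}: de-escalation on day {s} after death day {death}"
                )
            limit = cens if later is None else min(later, cens)
            stop = limit if death is None else min(death, limit)
            event = int(death is not None and death == stop)
            if stop < s or (stop == s and not event):
                rows.append((pid, 0.0, float(stop), 0, 0))
            elif stop == s:  # died on the switch day: dies exposed
                rows.append((pid, 0.0, float(s), 0, 0))
                rows.append((pid, float(s), s + 0.5, 1, 1))
            else:
                rows.append((pid, 0.0, float(s), 0, 0))
                rows.append((pid, float(s), float(stop), 1, event))
        else:  # continuation
            stop = cens if death is None else min(death, cens)
            event = int(death is not None and death == stop)
            rows.append((pid, 0.0, float(stop), 0, event))

    iv = pd.DataFrame(rows, columns=list(INTERVAL_COLUMNS))
    iv = iv[iv["stop"] > iv["start"]].reset_index(drop=True)
    if covariates is not None:
        iv = iv.join(covariates, on="patient_id", how="left")
        if iv[covariates.columns].isna().any().any():
            missing = iv.loc[iv[covariates.columns].isna().any(axis=1), "patient_id"].iloc[0]
            raise DataError(f"patient {missing!r}: missing covariate value for intervals")
    return iv


def fit_cox(intervals: pd.DataFrame, covariates: list[str] | None = None) -> CoxFit:
    """Efron partial-likelihood fit on start–stop data.

    ``covariates=None`` (or ``[]``) gives the crude model with de-escalation
    as the only term; otherwise the named interval columns (typically the
    propensity score, optionally a simulated stability flag) are added.
    """
    covariates = list(covariates or [])
    ev = intervals["event"].astype(bool)
    exp_events = int(intervals.loc[ev, "deescalated"].sum())
    unexp_events = int(ev.sum()) - exp_events
    if exp_events == 0 or unexp_events == 0:
        raise DataError(
            f"need >=1 death in each exposure state, got {exp_events} exposed / "
            f"{unexp_events} unexposed"
        )
    cols = ["patient_id", "start", "stop", "event", "deescalated"] + covariates
    ctv = CoxTimeVaryingFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(
                intervals[cols],
                id_col="patient_id",
                start_col="start",
                stop_col="stop",
                event_col="event",
                show_progress=False,
            )
    except Exception as exc:
        raise ConvergenceError(
            f"Cox partial-likelihood maximisation failed: {exc}; check for a "
            "monotone likelihood on toy-sized data"
        ) from exc
    summ = ctv.summary
    beta = float(summ.loc["deescalated", "coef"])
    se = float(summ.loc["deescalated", "se(coef)"])
    z = 1.959963984540054  # 95% Wald on the log scale
    return CoxFit(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        log_hr=beta,
        se=se,
        coefficients=summ["coef"].copy(),
        n_events=int(ev.sum()),
        n_intervals=len(intervals),
        log_likelihood=float(ctv.log_likelihood_),
    )


# ---------------------------------------------------------------------------
# proportional-hazards diagnostic
# ---------------------------------------------------------------------------

@dataclass
class PHDiagnostic:
    """Piecewise time-varying exposure effect over a long horizon."""

    window_table: pd.DataFrame  # start, stop, log_hr, se, hr, ci_low, ci_high, n_events
    curve: pd.DataFrame  # mid, log_hr, se (plot-ready time-varying coefficient)
    lr_stat: float
    lr_df: int
    p_value: float
    warnings: list = field(default_factory=list)


def _episode_split(intervals: pd.DataFrame, cuts: np.ndarray) -> pd.DataFrame:
    """Split each risk interval at the window boundaries."""
    out = []
    extra = [c for c in intervals.columns if c not in INTERVAL_COLUMNS]
    for t in intervals.itertuples(index=False):
        d = t._asdict()
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            a, b = max(d["start"], lo), min(d["stop"], hi)
            if b <= a:
                continue
            row = dict(d)
            row["start"], row["stop"] = a, b
            row["event"] = int(d["event"] and b == d["stop"])
            out.append(row)
    return pd.DataFrame(out)


def ph_diagnostic(
    intervals: pd.DataFrame,
    windows: tuple = (0, 10, 20, 30, 60, 90),
    covariates: list[str] | None = None,
) -> PHDiagnostic:
    """Estimate a piecewise-constant time-varying log-HR of de-escalation.

    Fits exposure-by-time-window interaction terms on episode-split data and
    compares against the constant-effect model with a likelihood-ratio test
    (the global proportional-hazards test).  Windows that contain no exposed
    event are merged into their left neighbour, with a warning (too few late
    events make the late effect inestimable).
    """
    covariates = list(covariates or [])
    cuts = np.asarray(windows, dtype=float)
    if len(cuts) < 3:
        raise DataError("need at least two windows for a PH diagnostic")
    split = _episode_split(intervals, cuts)

    notes: list[str] = []
    while True:
        labels = np.searchsorted(cuts, split["stop"].to_numpy(), side="left") - 1
        labels = np.clip(labels, 0, len(cuts) - 2)
        split["_win"] = labels
        exp_ev = split[(split["event"] == 1) & (split["deescalated"] == 1)]["_win"].value_counts()
        empty = [w for w in range(len(cuts) - 1) if exp_ev.get(w, 0) == 0]
        if not empty or len(cuts) <= 3:
            break
        w = empty[0]
        drop = cuts[w] if w > 0 else cuts[1]
        notes.append(
            f"window [{cuts[max(w - 1, 0)]:g}, {cuts[min(w + 1, len(cuts) - 1)]:g}) had no "
            "exposed events; merged with its neighbour"
        )
        cuts = np.delete(cuts, np.where(cuts == drop)[0][0])
        split = _episode_split(intervals, cuts)
    if notes:
        for msg in notes:
            warnings.warn(msg, stacklevel=2)

    nwin = len(cuts) - 1
    win_cols = []
    for w in range(nwin):
        col = f"deesc_w{w}"
        split[col] = split["deescalated"] * (split["_win"] == w)
        win_cols.append(col)

    def _ctv(cols: list[str]) -> CoxTimeVaryingFitter:
        f = CoxTimeVaryingFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f.fit(
                split[["patient_id", "start", "stop", "event"] + cols],
                id_col="patient_id",
                start_col="start",
                stop_col="stop",
                event_col="event",
                show_progress=False,
            )
        return f

    try:
        fit_win = _ctv(win_cols + covariates)
        fit_const = _ctv(["deescalated"] + covariates)
    except Exception as exc:
        raise ConvergenceError(f"PH diagnostic fit failed: {exc}") from exc

    lr = 2.0 * (fit_win.log_likelihood_ - fit_const.log_likelihood_)
    df = nwin - 1
    p = float(chi2.sf(max(lr, 0.0), df))

    z = 1.959963984540054
    recs = []
    for w, col in enumerate(win_cols):
        b = float(fit_win.summary.loc[col, "coef"])
        se = float(fit_win.summary.loc[col, "se(coef)"])
        n_ev = int(exp_ev.get(w, 0))
        recs.append(
            dict(
                start=cuts[w],
                stop=cuts[w + 1],
                log_hr=b,
                se=se,
                hr=np.exp(b),
                ci_low=np.exp(b - z * se),
                ci_high=np.exp(b + z * se),
                n_exposed_events=n_ev,
            )
        )
    table = pd.DataFrame(recs)
    curve = pd.DataFrame(
        {
            "mid": 0.5 * (table["start"] + table["stop"]),
            "log_hr": table["log_hr"],
            "se": table["se"],
        }
    )
    return PHDiagnostic(
        window_table=table, curve=curve, lr_stat=float(max(lr, 0.0)), lr_df=df, p_value=p,
        warnings=notes,
    )
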