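"""Propensity for de-escalation: logistic model, scores, and AUC.

The analysis set excludes rank-1 starters (a narrow-spectrum regimen cannot
be de-escalated).  The fitted probability of de-escalation given baseline
covariates is used downstream as a single continuous adjustment covariate in
the Cox model.  Discrimination is summarised by the AUC with a
distribution-free (DeLong) confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .errors import DataError, SeparationError

#: Baseline covariates of the propensity model: demographics, history, the
#: day-1 empirical rank, admission context, culture result, and the
#: component variables of the pneumonia severity index.
BINARY_COVARIATES = [
    "male",
    "smoker",
    "diabetes",
    "chronic_pulmonary",
    "prior_antibiotics",
    "weekend_admission",
    "pathogen_identified",
    "nursing_home",
    "neoplastic",
    "chronic_liver",
    "chronic_cardiovascular",
    "cerebrovascular",
    "chronic_renal",
    "altered_mental_status",
    "pleural_effusion",
]
CONTINUOUS_COVARIATES = [
    "age",
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
]


@dataclass
class PropensityModel:
    """Fitted logistic model: coefficients, per-patient scores, and AUC."""

    coefficients: pd.Series
    scores: pd.Series  # indexed by patient_id, values in (0, 1)
    auc: float
    auc_ci: tuple[float, float]
    n: int
    n_events: int
    ridge: bool = False

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(design, has_constant="add")
        lin = X[self.coefficients.index] @ self.coefficients
        return 1.0 / (1.0 + np.exp(-lin))


def build_design(patients: pd.DataFrame, include_stability: bool = False) -> pd.DataFrame:
    """Design matrix for the propensity model.

    Continuous covariates are standardised internally, so scores are
    invariant to affine rescaling of the inputs.  ``include_stability``
    additionally exposes the latent stability flag to the model — only
    meaningful on synthetic cohorts, and never the default ("blinded")
    behaviour.
    """
    cols = {}
    for c in BINARY_COVARIATES:
        cols[c] = patients[c].astype(float).to_numpy()
    for c in CONTINUOUS_COVARIATES:
        x = patients[c].astype(float).to_numpy()
        bad = ~np.isfinite(x)
        if bad.any():
            pid = patients.loc[patients.index[bad][0], "patient_id"]
            raise DataError(f"patient {pid!r}: non-finite value in covariate {c!r}")
        sd = x.std()
        cols[c] = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    if "initial_rank" in patients.columns:
        cols["rank3"] = (patients["initial_rank"] == 3).astype(float).to_numpy()
    for s in ("spring", "summer", "autumn"):  # winter is the reference
        cols[f"season_{s}"] = (patients["season"] == s).astype(float).to_numpy()
    if include_stability:
        if "latent_stable_72h" not in patients.columns:
            raise DataError("cohort has no latent_stable_72h column")
        cols["latent_stable_72h"] = patients["latent_stable_72h"].astype(float).to_numpy()
    X = pd.DataFrame(cols, index=patients.index)
    bad = ~np.isfinite(X.to_numpy()).all(axis=1)
    if bad.any():
        pid = patients.loc[X.index[bad][0], "patient_id"]
        raise DataError(f"patient {pid!r}: non-finite covariate value")
    # drop constant columns (degenerate in small/toy cohorts)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    return X[keep]


def fit_propensity(
    patients: pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    ridge: bool = False,
    include_stability: bool = False,
) -> PropensityModel:
    """Maximum-likelihood logistic fit of de-escalation on baseline covariates.

    ``patients`` must already be restricted to the analysis set (rank-2/3
    starters).  ``outcome`` is the 0/1 de-escalation flag aligned with
    ``patients``.  On complete separation the fit aborts with
    :class:`SeparationError` advising ``ridge=True`` (an L2-penalised rescue
    fit; logged in the returned model).
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DataError("outcome must be a 0/1 de-escalation flag")
    X = build_design(patients, include_stability=include_stability)
    Xc = sm.add_constant(X, has_constant="add")

    if ridge:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)  # L2 penalty
        lr.fit(X.to_numpy(), y)
        coefs = pd.Series(
            np.concatenate([[lr.intercept_[0]], lr.coef_[0]]), index=["const"] + list(X.columns)
        )
        p = lr.predict_proba(X.to_numpy())[:, 1]
    else:
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=500, method="lbfgs")
        except Exception as exc:  # statsmodels raises PerfectSeparationError
            if "separation" in str(type(exc).__name__).lower() or "Separation" in str(exc):
                raise SeparationError(
                    "complete separation in the propensity fit; retry with ridge=True"
                ) from exc
            raise
        if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 30:
            raise SeparationError(
                "propensity fit did not converge (quasi-separation?); retry with ridge=True"
            )
        coefs = pd.Series(res.params, index=Xc.columns)
        p = np.asarray(res.predict(Xc))

    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    auc, lo, hi = delong_auc_ci(y, p)
    scores = pd.Series(p, index=patients["patient_id"].to_numpy(), name="propensity")
    return PropensityModel(
        coefficients=coefs,
        scores=scores,
        auc=auc,
        auc_ci=(lo, hi),
        n=len(y),
        n_events=int(y.sum()),
        ridge=ridge,
    )


def delong_auc_ci(y: np.ndarray, score: np.ndarray, alpha: float = 0.05):
    """AUC with DeLong's distribution-free confidence interval."""
    y = np.asarray(y).astype(int)
    score = np.asarray(score, dtype=float)
    pos, neg = score[y == 1], score[y == 0]
    m, k = len(pos), len(neg)
    if m == 0 or k == 0:
        raise DataError("AUC needs both outcome classes present")
    # placement values via midranks
    all_ = np.concatenate([pos, neg])
    order = np.argsort(all_, kind="mergesort")
    ranks = np.empty(m + k)
    sorted_ = all_[order]
    # midranks (ties averaged)
    idx = 0
    while idx < m + k:
        j = idx
        while j < m + k - 1 and sorted_[j + 1] == sorted_[idx]:
            j += 1
        ranks[order[idx : j + 1]] = 0.5 * (idx + j) + 1
        idx = j + 1
    r_pos, r_neg = ranks[:m], ranks[m:]
    auc = (r_pos.sum() - m * (m + 1) / 2) / (m * k)
    # structural components from midranks (fast DeLong)
    v10 = (r_pos - _midranks(pos)) / k
    v01 = 1.0 - (r_neg - _midranks(neg)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if k > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / k)
    z = norm.ppf(1 - alpha / 2)
    return float(auc), float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se))


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sorted_ = x[order]
    idx = 0
    while idx < len(x):
        j = idx
        while j < len(x) - 1 and sorted_[j + 1] == sorted_[idx]:
            j += 1
        ranks[order[idx : j + 1]] = 0.5 * (idx + j) + 1
        idx = j + 1
    return ranks
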