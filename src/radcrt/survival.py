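"""Prognosis analysis: Kaplan-Meier curves, log-rank comparison and Cox
proportional-hazards regression for PFS and OS endpoints.

Estimation is delegated to lifelines (product-limit estimator, log-rank
test, Efron-tie Cox partial likelihood); this module fixes the study's
covariate codings, the univariate-to-multivariate promotion rule
(univariate p < 0.05) and the report layout.

Covariates are coded as indicators of the first-listed (protective) group:
age below the cohort median, female sex, T stage 1-2, nodal stage 0-1,
SCC antigen <= 1.5, mid/lower tumor location, and high prediction score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import ConvergenceWarning

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "CoxFit",
    "km_estimate",
    "logrank",
    "cox_fit",
    "derive_covariate_groups",
    "run_prognosis",
    "UNIVARIATE_VARIABLES",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """A single time-to-event observation (months; event=1, censored=0)."""

    time: float
    event: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"survival time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0 or 1")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: S(t) at each distinct event time.

    ``median`` is the first time at which S(t) drops to 0.5 or below; None
    when the curve never reaches 0.5 ("not reached").
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


@dataclass(frozen=True)
class CoxFit:
    """Per-covariate Cox summaries plus fit diagnostics."""

    coefficients: dict[str, float]
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    log_likelihood: float
    converged: bool
    stable: bool
    ties: str = "efron"


def _to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate over a set of records."""
    if not records:
        raise ValueError("need at least one record")
    times, events = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        return KMCurve(np.array([]), np.array([]), np.array([]), None)
    surv = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    )
    at_risk = np.array([int((times >= t).sum()) for t in event_times])
    crossing = event_times[surv <= 0.5]
    median = float(crossing[0]) if crossing.size else None
    return KMCurve(event_times, surv, at_risk, median)


def logrank(group_a: list[SurvivalRecord],
            group_b: list[SurvivalRecord]) -> tuple[float, float]:
    """One-degree-of-freedom log-rank statistic and two-sided p-value."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1")
        return 0.0, 1.0
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(frame: pd.DataFrame, covariates: list[str],
            duration_col: str = "time", event_col: str = "event",
            ties: str = "efron") -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Wald CIs).

    Raises on constant/collinear covariates and on non-convergence; flags
    (rather than fails) monotone-likelihood instability from separation.
    """
    if frame[event_col].sum() < 1:
        raise ValueError("Cox model needs at least one event")
    x = frame[covariates].astype(float)
    if (x.std(ddof=0) == 0).any():
        bad = [c for c in covariates if x[c].std(ddof=0) == 0]
        raise ValueError(f"constant covariate(s): {bad}")
    if len(covariates) > 1:
        rank = np.linalg.matrix_rank(x.values - x.values.mean(axis=0))
        if rank < len(covariates):
            raise ValueError(f"collinear covariates among {covariates}")
    cph = CoxPHFitter()
    data = frame[[duration_col, event_col] + covariates].copy()
    stable = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(data, duration_col=duration_col, event_col=event_col)
        except ConvergenceError as err:
            raise RuntimeError(f"Cox fit did not converge: {err}") from err
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                stable = False
    summ = cph.summary
    return CoxFit(
        coefficients={c: float(summ.loc[c, "coef"]) for c in covariates},
        hazard_ratios={c: float(summ.loc[c, "exp(coef)"]) for c in covariates},
        ci_lower={c: float(summ.loc[c, "exp(coef) lower 95%"]) for c in covariates},
        ci_upper={c: float(summ.loc[c, "exp(coef) upper 95%"]) for c in covariates},
        p_values={c: float(summ.loc[c, "p"]) for c in covariates},
        log_likelihood=float(cph.log_likelihood_),
        converged=True,
        stable=stable,
        ties=ties,
    )


#: the seven univariate variables of the prognosis tables, in report order
UNIVARIATE_VARIABLES = (
    "age_group", "sex_group", "t_stage_group", "n_group",
    "scc_group", "location_group", "score_group",
)


def derive_covariate_groups(clinical: pd.DataFrame,
                            scores: pd.Series | None = None,
                            score_threshold: float | None = None) -> pd.DataFrame:
    """Dichotomize raw clinical covariates into the analysis groups.

    Indicator = 1 codes the first-listed category of each comparison:
    age < cohort median, female, T 1-2, N 0-1, SCC <= 1.5, mid/lower
    location, high prediction score.
    """
    out = clinical.copy()
    out["age_group"] = (out["age"] < out["age"].median()).astype(int)
    out["sex_group"] = (out["sex"].astype(str).str.upper().str.startswith("F")).astype(int)
    out["t_stage_group"] = (out["t_stage"] <= 2).astype(int)
    out["n_group"] = (out["n_stage"] <= 1).astype(int)
    out["scc_group"] = (out["scc"] <= 1.5).astype(int)
    out["location_group"] = (out["location"].astype(str) != "Ut").astype(int)
    if scores is not None:
        if score_threshold is None:
            raise ValueError("score_threshold required when scores are given")
        out["score"] = scores.reindex(out.index)
        out["score_group"] = (out["score"] >= score_threshold).astype(int)
    return out


def _records_from_frame(frame: pd.DataFrame, time_col: str, event_col: str):
    return [
        SurvivalRecord(float(t), int(e))
        for t, e in zip(frame[time_col], frame[event_col])
    ]


def run_prognosis(clinical: pd.DataFrame, scores: pd.Series,
                  score_threshold: float,
                  endpoints=(("pfs_months", "pfs_event"), ("os_months", "os_event")),
                  alpha: float = 0.05) -> dict:
    """Full prognosis report: score-stratified KM + log-rank, univariate Cox
    for the seven study variables, multivariate Cox with the univariately
    significant ones (p < ``alpha``).
    """
    data = derive_covariate_groups(clinical, scores, score_threshold)
    high = data[data["score_group"] == 1]
    low = data[data["score_group"] == 0]
    if len(high) == 0 or len(low) == 0:
        raise ValueError(
            f"score threshold {score_threshold} leaves an empty stratum "
            f"(high={len(high)}, low={len(low)})"
        )
    report: dict = {"n": len(data), "threshold": score_threshold, "endpoints": {}}
    for time_col, event_col in endpoints:
        km_high = km_estimate(_records_from_frame(high, time_col, event_col))
        km_low = km_estimate(_records_from_frame(low, time_col, event_col))
        chi2, p = logrank(
            _records_from_frame(high, time_col, event_col),
            _records_from_frame(low, time_col, event_col),
        )
        frame = data.rename(columns={time_col: "time", event_col: "event"})
        univariate = {}
        for var in UNIVARIATE_VARIABLES:
            try:
                fit = cox_fit(frame, [var])
                univariate[var] = {
                    "hr": fit.hazard_ratios[var],
                    "ci": (fit.ci_lower[var], fit.ci_upper[var]),
                    "p": fit.p_values[var],
                }
            except (ValueError, RuntimeError) as err:
                # degenerate covariate or non-convergence on a small stratum
                univariate[var] = {"hr": None, "ci": None, "p": None,
                                   "error": str(err)}
        selected = [v for v, r in univariate.items()
                    if r.get("p") is not None and r["p"] < alpha]
        multivariate = None
        if len(selected) >= 2:
            try:
                mfit = cox_fit(frame, selected)
                multivariate = {
                    v: {
                        "hr": mfit.hazard_ratios[v],
                        "ci": (mfit.ci_lower[v], mfit.ci_upper[v]),
                        "p": mfit.p_values[v],
                    }
                    for v in selected
                }
            except (ValueError, RuntimeError) as err:
                multivariate = {"error": str(err)}
        report["endpoints"][time_col.replace("_months", "")] = {
            "median_high": km_high.median,
            "median_low": km_low.median,
            "logrank_chi2": chi2,
            "logrank_p": p,
            "univariate": univariate,
            "multivariate_variables": selected,
            "multivariate": multivariate,
        }
    return report
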