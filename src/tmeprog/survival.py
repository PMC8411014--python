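"""Survival endpoints, estimators and risk-stratified reporting.

Endpoints follow the trial conventions: time to recurrence (TTR) counts
local/regional recurrence, distant recurrence and death from the index
cancer as events, censoring deaths from other causes, treatment-related
deaths and loss to follow-up; overall survival (OS) counts death from any
cause.  Kaplan-Meier estimation (Greenwood variance, log-log confidence
intervals), the Mantel-Cox log-rank test and Cox proportional-hazards fits
(Efron ties, Wald tests) are delegated to lifelines.

Clinicopathological risk strata: LOW_RISK is all stage II plus stage III
pT1-3 pN1 without lymphatic or venous invasion; HIGH_RISK is stage III
with pT3 pN1 and lympho-/vascular invasion, pT4, or pN2.  Combinations the
published definitions do not cover (e.g. stage III pT1-2 pN1 with
invasion) are UNCLASSIFIED and excluded from stratified reports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .marker import MarkerLevel, MarkerThresholds, classify_cohort

TTR_EVENT_CODES = frozenset({"local_recurrence", "distant_recurrence", "death_crc"})
DEATH_CODES = frozenset({"death_crc", "death_other_cancer", "death_noncancer", "death_treatment"})
CENSOR_CODES = frozenset({"none", "lost"})
ALL_OUTCOME_CODES = TTR_EVENT_CODES | DEATH_CODES | CENSOR_CODES


class RiskStratum(enum.Enum):
    LOW_RISK = "low_risk"
    HIGH_RISK = "high_risk"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Endpoint:
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be non-negative")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class KmCurve:
    event_times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value of S at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return 1.0, 1.0
        return float(self.ci_lower[idx]), float(self.ci_upper[idx])


@dataclass
class CoxFit:
    coefficients: pd.DataFrame  # index covariate; columns coef, hazard_ratio, ci_lower, ci_upper, wald_p
    c_index: float
    n_used: int
    n_dropped: int


def _check_outcome(code: str) -> str:
    if code not in ALL_OUTCOME_CODES:
        raise ValueError(f"unknown outcome code: {code!r}")
    return code


def derive_ttr(followup_years: float, outcome_code: str) -> Endpoint:
    """Time-to-recurrence endpoint for one record.

    Recurrence (local/regional or distant) and death from the index cancer
    are events; all other outcomes censor.
    """
    return Endpoint(followup_years, int(_check_outcome(outcome_code) in TTR_EVENT_CODES))


def derive_os(followup_years: float, outcome_code: str) -> Endpoint:
    """Overall-survival endpoint: death from any cause is an event."""
    return Endpoint(followup_years, int(_check_outcome(outcome_code) in DEATH_CODES))


def derive_endpoints(cohort: pd.DataFrame, endpoint: str = "ttr") -> pd.DataFrame:
    """Vectorized endpoint derivation; returns columns ``time`` and ``event``.

    Rows with a missing outcome code or follow-up time are excluded.
    """
    if endpoint not in ("ttr", "os"):
        raise ValueError("endpoint must be 'ttr' or 'os'")
    ok = cohort["outcome_code"].notna() & cohort["followup_years"].notna()
    sub = cohort.loc[ok]
    unknown = set(sub["outcome_code"]) - ALL_OUTCOME_CODES
    if unknown:
        raise ValueError(f"unknown outcome codes: {sorted(unknown)}")
    event_codes = TTR_EVENT_CODES if endpoint == "ttr" else DEATH_CODES
    return pd.DataFrame(
        {
            "time": sub["followup_years"].to_numpy(float),
            "event": sub["outcome_code"].isin(event_codes).astype(int).to_numpy(),
        },
        index=sub.index,
    )


def assign_risk_stratum(
    stage: str, pT: int, pN: int, lymphatic_invasion: str, venous_invasion: str
) -> RiskStratum:
    """Clinicopathological risk stratum for one record."""
    if stage not in ("II", "III") or pd.isna(pT) or pd.isna(pN):
        return RiskStratum.UNCLASSIFIED
    if stage == "II":
        return RiskStratum.LOW_RISK
    invaded = lymphatic_invasion == "yes" or venous_invasion == "yes"
    if pT == 4 or pN == 2:
        return RiskStratum.HIGH_RISK
    if pT in (1, 2, 3) and pN == 1 and lymphatic_invasion == "no" and venous_invasion == "no":
        return RiskStratum.LOW_RISK
    if pT == 3 and pN == 1 and invaded:
        return RiskStratum.HIGH_RISK
    return RiskStratum.UNCLASSIFIED


def assign_risk_strata(cohort: pd.DataFrame) -> pd.Series:
    """Row-wise risk stratum assignment for a patient table."""
    return cohort.apply(
        lambda r: assign_risk_stratum(
            r["stage"], r["pT"], r["pN"], r["lymphatic_invasion"], r["venous_invasion"]
        ),
        axis=1,
    )


def km_estimate(times, events) -> KmCurve:
    """Product-limit estimator with Greenwood variance and log-log 95% CI."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if t.size == 0:
        raise ValueError("need at least one endpoint")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    timeline = table.index.to_numpy(float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    ci = kmf.confidence_interval_
    return KmCurve(
        event_times=timeline,
        survival=surv,
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        at_risk=table["at_risk"].to_numpy(),
    )


def logrank_test(groups: list[tuple[np.ndarray, np.ndarray]]) -> tuple[float, float]:
    """Mantel-Cox log-rank test over two or more groups.

    ``groups`` is a list of (times, events) pairs.  Returns the chi-squared
    statistic (df = groups - 1) and its two-sided p-value.  With no events
    anywhere the statistic is 0 and p is 1.
    """
    if len(groups) < 2 or any(len(t) == 0 for t, _ in groups):
        raise ValueError("need >= 2 non-empty groups")
    times = np.concatenate([np.asarray(t, float) for t, _ in groups])
    events = np.concatenate([np.asarray(e, int) for _, e in groups])
    labels = np.concatenate(
        [np.full(len(t), i) for i, (t, _) in enumerate(groups)]
    )
    if events.sum() == 0:
        return 0.0, 1.0
    res = multivariate_logrank_test(times, labels, events)
    stat, p = float(res.test_statistic), float(res.p_value)
    if np.isnan(stat):
        return 0.0, 1.0
    return stat, p


def cox_fit(
    cohort: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Proportional-hazards fit with Efron ties and per-covariate Wald tests.

    Rows with missing values in any used column are dropped (listwise
    deletion; the dropped count is reported).  Zero-variance covariates and
    non-convergence raise with the offending covariate named.
    """
    cols = list(covariates) + [time_col, event_col]
    df = cohort[cols]
    n_in = len(df)
    df = df.dropna()
    n_used = len(df)
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"zero-variance covariate: {c}")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # convergence / separation
        raise RuntimeError(f"Cox fit failed for covariates {covariates}: {exc}") from exc
    summary = cph.summary
    coef = pd.DataFrame(
        {
            "coef": summary["coef"],
            "hazard_ratio": summary["exp(coef)"],
            "ci_lower": summary["exp(coef) lower 95%"],
            "ci_upper": summary["exp(coef) upper 95%"],
            "wald_p": summary["p"],
        }
    )
    return CoxFit(
        coefficients=coef,
        c_index=float(cph.concordance_index_),
        n_used=n_used,
        n_dropped=n_in - n_used,
    )


def _group_summary(times, events) -> dict:
    curve = km_estimate(times, events)
    lo, hi = curve.ci_at(5.0)
    return {
        "n": int(len(times)),
        "events": int(np.asarray(events).sum()),
        "survival_5y": curve.survival_at(5.0),
        "survival_5y_ci": [lo, hi],
    }


def _extreme_group_hr(df: pd.DataFrame, group_col: str, low, high) -> float | None:
    sub = df[df[group_col].isin([low, high])].copy()
    if sub[group_col].nunique() < 2 or sub["event"].sum() == 0:
        return None
    sub["indicator"] = (sub[group_col] == high).astype(int)
    try:
        fit = cox_fit(sub, ["indicator"])
    except (RuntimeError, ValueError):
        return None
    return float(fit.coefficients.loc["indicator", "hazard_ratio"])


def stratified_report(
    cohort: pd.DataFrame,
    thresholds: MarkerThresholds,
    endpoint: str = "ttr",
) -> dict:
    """Risk-stratified survival report for the combined marker.

    In the LOW_RISK stratum patients split on stroma fraction alone
    (high = fraction >= stroma threshold); in the HIGH_RISK stratum the
    three-level combined marker is used.  Each populated stratum reports
    per-group sizes, 5-year survival with confidence intervals, the
    log-rank test (when >= 2 groups have patients) and the hazard ratio
    between the extreme groups.  UNCLASSIFIED patients are counted and
    excluded.
    """
    ep = derive_endpoints(cohort, endpoint)
    data = cohort.loc[ep.index].copy()
    data["time"], data["event"] = ep["time"], ep["event"]
    data["stratum"] = assign_risk_strata(data)
    data["marker_level"] = classify_cohort(
        data["cd8_fraction"], data["stroma_fraction"], thresholds
    )
    data["stroma_high"] = (
        data["stroma_fraction"] >= thresholds.stroma_threshold
    ).astype(int)

    report: dict = {
        "endpoint": endpoint,
        "thresholds": {
            "cd8": thresholds.cd8_threshold,
            "stroma": thresholds.stroma_threshold,
        },
        "n_total": int(len(data)),
        "n_unclassified": int((data["stratum"] == RiskStratum.UNCLASSIFIED).sum()),
    }

    def build(sub: pd.DataFrame, group_col: str, level_names: dict) -> dict | None:
        if sub.empty:
            return None
        groups = {}
        present = sorted(sub[group_col].unique())
        for g in present:
            rows = sub[sub[group_col] == g]
            groups[level_names[g]] = _group_summary(rows["time"], rows["event"])
        out: dict = {"n": int(len(sub)), "groups": groups}
        if len(present) >= 2:
            stat, p = logrank_test(
                [
                    (sub.loc[sub[group_col] == g, "time"].to_numpy(),
                     sub.loc[sub[group_col] == g, "event"].to_numpy())
                    for g in present
                ]
            )
            out["logrank"] = {"chi_squared": stat, "p_value": p}
            hr = _extreme_group_hr(sub, group_col, present[0], present[-1])
            if hr is not None:
                out["hazard_ratio_extremes"] = hr
        return out

    low = build(
        data[data["stratum"] == RiskStratum.LOW_RISK],
        "stroma_high",
        {0: "low_stroma", 1: "high_stroma"},
    )
    high = build(
        data[data["stratum"] == RiskStratum.HIGH_RISK],
        "marker_level",
        {
            int(MarkerLevel.FAVORABLE): "favorable",
            int(MarkerLevel.INTERMEDIATE): "intermediate",
            int(MarkerLevel.ADVERSE): "adverse",
        },
    )
    if low is not None:
        report["low_risk"] = low
    if high is not None:
        report["high_risk"] = high
    return report
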