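"""Outcome analysis: median-threshold biomarker grouping, Kaplan-Meier
with log-rank tests, univariate Cox regression, IPCW time-dependent
ROC AUC, and RECIST response-rate comparisons.

Time is in months throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import fisher_exact

__all__ = [
    "median_groups",
    "km_logrank",
    "KMResult",
    "cox_univariate",
    "time_dependent_auc",
    "response_rates",
    "biomarker_table",
]

RESPONSE_LABELS = ("CR", "PR", "SD", "PD")
SD_RESPONDER_MONTHS = 6.0


def median_groups(values: pd.Series) -> pd.Series:
    """High/low split at the cohort median.

    High group = strictly greater than the median; ties at the median go
    to the low group. All-equal input leaves one group empty and raises.
    """
    if len(values) < 2:
        raise ValueError("need >= 2 samples to split at the median")
    med = values.median()
    high = values > med
    if high.all() or (~high).all():
        raise ValueError("median split produced an empty group (constant values?)")
    return high.rename("high")


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]       # per group: time, survival, at_risk
    median_survival: dict[str, float]     # earliest t with S(t) <= 0.5; inf if never
    logrank_statistic: float
    logrank_p: float


def km_logrank(time: pd.Series, event: pd.Series, groups: pd.Series) -> KMResult:
    """Product-limit curves per group and the two-group log-rank test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups, dtype=bool)
    if event.sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    curves, medians = {}, {}
    for flag, name in ((True, "high"), (False, "low")):
        mask = groups == flag
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=name)
        tab = kmf.event_table
        curves[name] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.values,
                "survival": kmf.survival_function_[name].values,
                "at_risk": tab["at_risk"].reindex(kmf.survival_function_.index).values,
            }
        )
        medians[name] = float(kmf.median_survival_time_)
    res = logrank_test(time[groups], time[~groups], event[groups], event[~groups])
    return KMResult(curves, medians, float(res.test_statistic), float(res.p_value))


def cox_univariate(
    time: pd.Series,
    event: pd.Series,
    covariate: pd.Series,
    ties: str = "efron",
) -> dict:
    """Univariate Cox proportional-hazards fit.

    Returns hazard ratio, 95% Wald CI, p-value and the log hazard beta.
    Efron tie handling by default (Breslow available via statsmodels).
    """
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events; Cox model undefined")
    if event.sum() < 10:
        warnings.warn(f"only {event.sum()} events; estimates may be unstable", stacklevel=2)
    df = pd.DataFrame({"time": np.asarray(time, dtype=float), "event": event,
                       "x": np.asarray(covariate, dtype=float)})
    if ties == "efron":
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        beta = float(cph.params_["x"])
        se = float(cph.standard_errors_["x"])
        p = float(cph.summary.loc["x", "p"])
    elif ties == "breslow":
        import statsmodels.duration.hazard_regression as hr

        mod = hr.PHReg(df["time"], df[["x"]], status=df["event"], ties="breslow")
        res = mod.fit()
        beta = float(res.params[0])
        se = float(res.bse[0])
        p = float(res.pvalues[0])
    else:
        raise ValueError("ties must be 'efron' or 'breslow'")
    return {
        "hr": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
        "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
        "p": p,
        "beta": beta,
        "se": se,
    }


def _censoring_survival(time: np.ndarray, event: np.ndarray):
    """KM of the censoring distribution; returns G(t-) as a callable."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - event)
    timeline = kmf.survival_function_.index.values
    surv = kmf.survival_function_.iloc[:, 0].values

    def g_minus(t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(timeline, t, side="left") - 1
        return np.where(idx < 0, 1.0, surv[np.clip(idx, 0, len(surv) - 1)])

    return g_minus


def time_dependent_auc(
    time: pd.Series,
    event: pd.Series,
    marker: pd.Series,
    time_grid,
) -> pd.DataFrame:
    """Cumulative-case / dynamic-control AUC(t) with IPCW weights.

    Cases at horizon t are subjects with an event by t, weighted by the
    inverse left-limit of the censoring Kaplan-Meier at their event
    time; controls are subjects still at risk beyond t (their common
    IPCW weight cancels). Ties in the marker count 0.5. Grid times
    beyond the last observed time are dropped with a warning. Without
    censoring this reduces to the pairwise concordance between cases and
    controls at each t.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    marker = np.asarray(marker, dtype=float)
    g_minus = _censoring_survival(time, event)
    t_max = time.max()
    rows = []
    for t in np.asarray(time_grid, dtype=float):
        if t > t_max:
            warnings.warn(f"grid time {t} beyond last observed time {t_max}; dropped",
                          stacklevel=2)
            continue
        cases = (time <= t) & (event == 1)
        controls = time > t
        if cases.sum() == 0 or controls.sum() == 0:
            rows.append({"time": t, "auc": np.nan, "n_cases": int(cases.sum()),
                         "n_controls": int(controls.sum())})
            continue
        w = 1.0 / np.clip(g_minus(time[cases]), 1e-12, None)
        mc = marker[cases]
        mk = marker[controls]
        greater = (mc[:, None] > mk[None, :]).sum(axis=1)
        ties = (mc[:, None] == mk[None, :]).sum(axis=1)
        conc = (greater + 0.5 * ties) / len(mk)
        auc = float(np.sum(w * conc) / np.sum(w))
        rows.append({"time": t, "auc": auc, "n_cases": int(cases.sum()),
                     "n_controls": int(controls.sum())})
    return pd.DataFrame(rows)


def response_rates(
    response: pd.Series,
    sd_duration_months: pd.Series,
    groups: pd.Series,
) -> dict:
    """RECIST responder / objective-responder rates by group with Fisher p.

    Responder: CR, PR, or SD lasting >= 6 months. Objective responder:
    CR or PR. SD records without a duration are excluded (with warning)
    from the responder comparison.
    """
    response = response.astype(str)
    groups = groups.astype(bool)
    objective = response.isin(("CR", "PR"))
    sd = response == "SD"
    missing_sd = sd & sd_duration_months.isna()
    if missing_sd.any():
        warnings.warn(f"{int(missing_sd.sum())} SD record(s) without duration excluded",
                      stacklevel=2)
    responder = objective | (sd & (sd_duration_months >= SD_RESPONDER_MONTHS))

    def table_and_p(flag: pd.Series, keep: pd.Series):
        f, g = flag[keep], groups[keep]
        tab = [
            [int((f & g).sum()), int((~f & g).sum())],
            [int((f & ~g).sum()), int((~f & ~g).sum())],
        ]
        _, p = fisher_exact(tab, alternative="two-sided")
        return tab, float(p)

    resp_tab, resp_p = table_and_p(responder, ~missing_sd)
    obj_tab, obj_p = table_and_p(objective, pd.Series(True, index=groups.index))
    return {
        "responder_table": resp_tab,
        "responder_p": resp_p,
        "objective_table": obj_tab,
        "objective_p": obj_p,
    }


def biomarker_table(
    clinical: pd.DataFrame,
    biomarkers: list[str],
    time_col: str = "os_months",
    event_col: str = "os_event",
    mode: str = "binary",
) -> pd.DataFrame:
    """Per-biomarker survival statistics (median split, Cox, log-rank).

    ``mode='binary'`` fits Cox on the high/low indicator (comparable
    across biomarkers); ``mode='continuous'`` fits on the raw value.
    """
    rows = []
    for name in biomarkers:
        high = median_groups(clinical[name])
        km = km_logrank(clinical[time_col], clinical[event_col], high)
        cov = high.astype(float) if mode == "binary" else clinical[name]
        cox = cox_univariate(clinical[time_col], clinical[event_col], cov)
        rows.append(
            {
                "biomarker": name,
                "hr": cox["hr"],
                "ci_low": cox["ci_low"],
                "ci_high": cox["ci_high"],
                "cox_p": cox["p"],
                "logrank_p": km.logrank_p,
                "median_high": km.median_survival["high"],
                "median_low": km.median_survival["low"],
            }
        )
    return pd.DataFrame(rows).set_index("biomarker")
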