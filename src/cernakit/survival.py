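"""Survival analysis: Kaplan–Meier, G-rho tests, univariate Cox.

The G-rho (Fleming–Harrington) family compares two survival curves
with the weighted log-rank statistic: at each distinct event time t_j
with d_j pooled events, n_j at risk and n_1j/d_1j in group 1,

    U = sum_j w_j (d_1j - d_j n_1j / n_j)
    V = sum_j w_j^2 d_j (n_1j/n_j)(1 - n_1j/n_j)(n_j - d_j)/(n_j - 1)

with weights w_j = S_pool(t_j-)^rho from the pooled Kaplan–Meier
left limit; rho = 0 is the ordinary log-rank test and U^2/V is
chi-square with 1 df. Kaplan–Meier estimation and Cox proportional
hazards (Efron tie handling, Newton–Raphson on the partial
likelihood) are delegated to lifelines; the prognostic screen reports,
per expression feature, the univariate Cox Wald p (normative) and a
median-split G-rho p for the matching Kaplan–Meier display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .matrix import ExpressionMatrix, ValidationError


def _check_times(time: np.ndarray) -> None:
    if (time <= 0).any():
        raise ValidationError("survival times must be positive")


def km_estimate(time, event) -> pd.Series:
    """Product-limit survival estimate S(t) at distinct event times.

    Returns a step function as a Series indexed by time (starting at
    0 with S=1); censoring decrements the risk set without an event.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValidationError("at least one record required")
    _check_times(time)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    s = kmf.survival_function_["KM_estimate"]
    s.index.name = "time"
    return s.rename("S")


@dataclass
class SurvTestResult:
    statistic: float
    df: int
    p: float
    rho: float


def grho_test(time, event, groups, rho: float = 0.0) -> SurvTestResult:
    """Two-group Fleming–Harrington G-rho weighted log-rank test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    _check_times(time)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValidationError("exactly two groups required")
    if (groups == labels[0]).sum() == 0 or (groups == labels[1]).sum() == 0:
        raise ValidationError("both groups must be non-empty")
    if event.sum() == 0:
        raise ValidationError("at least one event required")

    event_times = np.unique(time[event == 1])
    in1 = groups == labels[0]
    # pooled KM left limits at each event time
    s_left = np.empty(len(event_times))
    s = 1.0
    for j, t in enumerate(event_times):
        s_left[j] = s
        n_at_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        if n_at_risk > 0:
            s *= 1.0 - d / n_at_risk
    U = 0.0
    V = 0.0
    for t, sl in zip(event_times, s_left):
        at_risk = time >= t
        n_j = at_risk.sum()
        n_1j = (at_risk & in1).sum()
        d_j = np.sum((time == t) & (event == 1))
        d_1j = np.sum((time == t) & (event == 1) & in1)
        w = sl**rho
        U += w * (d_1j - d_j * n_1j / n_j)
        if n_j > 1:
            V += (
                w**2
                * d_j
                * (n_1j / n_j)
                * (1.0 - n_1j / n_j)
                * (n_j - d_j)
                / (n_j - 1.0)
            )
    if V == 0:
        return SurvTestResult(0.0, 1, 1.0, rho)
    chi2 = U**2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return SurvTestResult(float(chi2), 1, p, rho)


@dataclass
class CoxResult:
    beta: float
    hazard_ratio: float
    se: float
    p: float
    converged: bool = True


def cox_univariate(time, event, covariate) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    covariate = np.asarray(covariate, dtype=float)
    _check_times(time)
    if np.std(covariate) == 0:
        raise ValidationError("covariate has no variation")
    if event.sum() < 2:
        raise ValidationError("at least two events required")
    df = pd.DataFrame({"time": time, "event": event, "x": covariate})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        return CoxResult(np.nan, np.nan, np.nan, np.nan, converged=False)
    row = cph.summary.loc["x"]
    return CoxResult(
        beta=float(row["coef"]),
        hazard_ratio=float(row["exp(coef)"]),
        se=float(row["se(coef)"]),
        p=float(row["p"]),
        converged=True,
    )


def prognostic_screen(
    expression: ExpressionMatrix,
    survival: pd.DataFrame,
    alpha: float = 0.05,
    rho: float = 0.0,
) -> pd.DataFrame:
    """Per-feature prognostic association screen.

    ``survival`` is a DataFrame indexed by sample with ``time`` and
    ``event`` columns; only samples present in both tables are used.
    Each feature gets the univariate Cox Wald p (on its transformed
    expression) and, for Kaplan–Meier display, a median-split G-rho
    test p; ``significant`` is Cox p < alpha. One output row per
    feature.
    """
    shared = expression.sample_ids.intersection(survival.index)
    if len(shared) < 4:
        raise ValidationError("fewer than 4 samples with survival data")
    V = expression.values[list(shared)]
    time = survival.loc[shared, "time"].to_numpy(dtype=float)
    event = survival.loc[shared, "event"].to_numpy(dtype=int)
    rows = []
    for fid, x in V.iterrows():
        xv = x.to_numpy(dtype=float)
        if np.std(xv) == 0:
            rows.append((fid, np.nan, np.nan, np.nan, np.nan, False))
            continue
        cox = cox_univariate(time, event, xv)
        high = xv > np.median(xv)
        km_p = np.nan
        if 0 < high.sum() < len(xv) and event.sum() > 0:
            try:
                km_p = grho_test(
                    time, event, np.where(high, "high", "low"), rho=rho
                ).p
            except ValidationError:
                km_p = np.nan
        rows.append(
            (fid, cox.beta, cox.hazard_ratio, cox.p, km_p,
             bool(cox.p < alpha) if np.isfinite(cox.p) else False)
        )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "cox_beta", "hazard_ratio", "cox_p",
                 "km_p", "significant"],
    ).set_index("feature_id")
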