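"""Kaplan–Meier estimation, the weighted log-rank test family, and Cox
proportional-hazards fitting.

Conventions: the median is the smallest time at which the survival curve
drops to 0.5 or below (undefined when the curve never reaches 0.5); the
mean is the restricted mean up to the largest observed time; the median CI
is the Brookmeyer–Crowley band inversion and the restricted-mean CI uses a
Greenwood-style standard error. The weighted log-rank family uses weights
w(t) = 1 (log-rank), n-at-risk (Breslow / generalized Wilcoxon) and
sqrt(n-at-risk) (Tarone–Ware); Cox ties are handled with the Efron
approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times, restricted_mean_survival_time

from omicsurv.exceptions import ValidationError

SCHEMES = {"logrank": None, "breslow": "wilcoxon", "tarone": "tarone-ware"}


@dataclass
class KMCurve:
    """Product-limit estimate with at-risk counts, Greenwood CIs, and
    median / restricted-mean summaries."""

    table: pd.DataFrame  # time, at_risk, events, survival, ci_lower, ci_upper
    median: float  # NaN when the curve never reaches 0.5
    median_ci: tuple[float, float]
    mean: float  # restricted mean up to the largest observed time
    mean_se: float
    mean_ci: tuple[float, float]

    @property
    def median_defined(self) -> bool:
        return np.isfinite(self.median)


@dataclass
class SurvivalTestResult:
    statistic: float
    p_value: float
    scheme: str


@dataclass
class CoxModel:
    """Per-covariate coefficients/SE/HR/Wald p plus the global LR test."""

    summary: pd.DataFrame  # index: covariate; columns: coef, se, hr, p
    lr_p: float
    penalized: bool = False


def km_estimate(times, events, alpha: float = 0.05) -> KMCurve:
    """Kaplan–Meier curve with median and restricted-mean summaries."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("km_estimate: empty input")
    if (times < 0).any():
        raise ValidationError("km_estimate: negative survival time")

    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events)
    surv = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    event_table = kmf.event_table
    table = pd.DataFrame(
        {
            "time": surv.index.to_numpy(float),
            "at_risk": event_table["at_risk"].to_numpy(float),
            "events": event_table["observed"].to_numpy(float),
            "survival": surv.to_numpy(float),
            "ci_lower": ci.iloc[:, 0].to_numpy(float),
            "ci_upper": ci.iloc[:, 1].to_numpy(float),
        }
    )

    median = float(kmf.median_survival_time_)
    if np.isinf(median):
        median = float("nan")
        median_ci = (float("nan"), float("nan"))
    else:
        med_ci = median_survival_times(kmf.confidence_interval_)
        median_ci = (float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1]))

    horizon = float(times.max())
    mean, var = restricted_mean_survival_time(kmf, t=horizon, return_variance=True)
    se = float(np.sqrt(var)) if var >= 0 else float("nan")
    z = 1.959963984540054
    return KMCurve(
        table=table,
        median=median,
        median_ci=median_ci,
        mean=float(mean),
        mean_se=se,
        mean_ci=(float(mean) - z * se, float(mean) + z * se),
    )


def weighted_logrank(times, events, group, scheme: str = "logrank") -> SurvivalTestResult:
    """Two-group weighted log-rank test.

    ``scheme`` is one of ``"logrank"`` (w = 1), ``"breslow"`` (w = number at
    risk; generalized Wilcoxon) or ``"tarone"`` (w = sqrt(number at risk);
    Tarone–Ware). The statistic is (sum w (O - E))^2 / Var, chi-square with
    1 df.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"weighted_logrank: unknown scheme {scheme!r}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValidationError("weighted_logrank: exactly two non-empty groups required")
    a = group == levels[0]
    res = logrank_test(
        times[a], times[~a], events[a], events[~a], weightings=SCHEMES[scheme]
    )
    return SurvivalTestResult(
        statistic=float(res.test_statistic), p_value=float(res.p_value), scheme=scheme
    )


def cox_fit(covariates: pd.DataFrame, times, events) -> CoxModel:
    """Cox proportional-hazards model (Efron ties).

    Reports per-covariate coefficient, SE, HR = exp(coef) and Wald p, plus
    the global likelihood-ratio p. Non-convergence (e.g. complete
    separation) falls back to a ridge-penalized fit with a warning,
    flagged in the result.
    """
    covariates = pd.DataFrame(covariates)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValidationError("cox_fit: no events observed")
    nunique = covariates.nunique(axis=0)
    constant = nunique[nunique <= 1].index.tolist()
    if constant:
        raise ValidationError(f"cox_fit: constant covariate(s) {constant}")

    df = covariates.copy()
    df["_time"] = times
    df["_event"] = events
    penalized = False
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError:
        warnings.warn(
            "cox_fit: partial likelihood did not converge (possible complete "
            "separation); refitting with a ridge penalty",
            stacklevel=2,
        )
        penalized = True
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")

    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "p": s["p"],
        }
    )
    lr_p = float(cph.log_likelihood_ratio_test().p_value)
    return CoxModel(summary=summary, lr_p=lr_p, penalized=penalized)


def hazard_fold_change(hr: float) -> float:
    """Protective-HR fold-change interpretation: 1 / HR."""
    if hr <= 0:
        raise ValidationError("hazard_fold_change: hazard ratio must be positive")
    return 1.0 / hr
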