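"""Local tumor progression (LTP) analysis.

Kaplan-Meier curves and log-rank tests compare progression-free time
between prognostic groups formed by dichotomizing a per-patient
statistic (e.g. the percent change of GLCM contrast at a 30.5% cut).
Cox proportional-hazards models quantify the association; because the
image-derived predictors are highly collinear, the multivariate models
enter one image feature at a time alongside the visual score
("separate-entry" models).  One-year discrimination is summarized by
the empirical ROC curve with the operating point at the maximum of
Youden's J.

Estimation is delegated to lifelines (KaplanMeierFitter, logrank_test,
CoxPHFitter with Efron tie handling) and scikit-learn (ROC); this module
owns the contracts: group construction, the 1-year label rule, flagging
of degenerate fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KMEstimate",
    "CoxResult",
    "ROCResult",
    "DICHOTOMIZATION_PRESETS",
    "km_fit",
    "km_median",
    "logrank",
    "dichotomize",
    "cox_fit",
    "roc_1year",
    "cumulative_incidence",
]


@dataclass
class KMEstimate:
    """Product-limit survival estimate."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    covariate: str
    hazard_ratio: float  # reported as "odds ratio" in some clinical tables
    ci95: tuple
    p_value: float
    log_hr: float
    se_log_hr: float
    model_id: str = ""
    n: int = 0
    n_events: int = 0
    flag: str = ""


@dataclass
class ROCResult:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    n_evaluable: int
    n_excluded: int


#: Named dichotomization cuts: value -> high group via strict ">" (gt)
#: or non-strict ">=" (ge).
DICHOTOMIZATION_PRESETS = {
    "dcontrast_gt_30_5": ("delta_contrast", 30.5, "gt"),
    "dzone_percentage_gt_21_5": ("delta_zone_percentage", 21.5, "gt"),
    "rvisu_ge_3": ("rvisu", 3.0, "ge"),
    "diameter_ge_3_6": ("diameter_cm", 3.6, "ge"),
    "volume_ge_4_1": ("volume_cm3", 4.1, "ge"),
    "age_ge_67": ("age", 67.0, "ge"),
}


def _clean(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("no survival records")
    if (t <= 0).any():
        raise ValueError("follow-up times must be positive")
    return t, e


def km_fit(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    At tied times events are handled before censorings, the standard
    convention.
    """
    from lifelines import KaplanMeierFitter

    t, e = _clean(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return KMEstimate(
        times=surv.index.to_numpy(dtype=float),
        survival=surv.to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(dtype=float),
        n=int(t.size),
        n_events=int(e.sum()),
    )


def km_median(est: KMEstimate) -> float:
    """Earliest time with S(t) <= 0.5; NaN when the curve never reaches 0.5."""
    below = est.survival <= 0.5
    if not below.any():
        return float("nan")
    return float(est.times[np.argmax(below)])


def logrank(times_a, events_a, times_b, events_b) -> dict:
    """Two-group log-rank test (1 df, two-sided)."""
    from lifelines.statistics import logrank_test

    ta, ea = _clean(times_a, events_a)
    tb, eb = _clean(times_b, events_b)
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return {"chi2": float(res.test_statistic), "p": float(res.p_value)}


def dichotomize(values, threshold: float, direction: str = "gt"):
    """Split a per-patient statistic into high/low groups at a threshold.

    direction "gt": high group is value > threshold (strict);
    direction "ge": high group is value >= threshold.
    NaN (undefined) values are excluded; their count is returned.

    Returns
    -------
    high : boolean ndarray over the defined values' positions
    defined : boolean ndarray, True where the input was finite
    n_excluded : int
    """
    v = np.asarray(values, dtype=float)
    defined = np.isfinite(v)
    if direction == "gt":
        high = v > threshold
    elif direction == "ge":
        high = v >= threshold
    else:
        raise ValueError(f"direction must be 'gt' or 'ge', got {direction!r}")
    high = high & defined
    return high, defined, int((~defined).sum())


def cox_fit(
    df: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "followup_months",
    event_col: str = "ltp_event",
    model_id: str = "",
    min_events: int = 10,
) -> list:
    """Cox proportional-hazards fit, one :class:`CoxResult` per covariate.

    Uses lifelines' partial likelihood with Efron tie handling; Wald 95%
    CIs and p-values.  Degenerate inputs (constant covariate, complete
    separation, non-convergence) yield flagged results instead of raising.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cols = [duration_col, event_col] + list(covariates)
    data = df[cols].dropna().copy()
    data[event_col] = data[event_col].astype(int)
    n = len(data)
    n_events = int(data[event_col].sum())
    results = []

    for cov in covariates:
        if data[cov].nunique() <= 1:
            results.append(CoxResult(cov, np.nan, (np.nan, np.nan), np.nan, np.nan,
                                     np.nan, model_id, n, n_events,
                                     flag="non-identifiable: constant covariate"))
            return results

    flag = ""
    if len(covariates) > 1 and n_events < min_events:
        flag = f"only {n_events} events for a {len(covariates)}-covariate model (floor {min_events})"

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, Exception) as exc:  # noqa: BLE001 - flagged, not fatal
        for cov in covariates:
            results.append(CoxResult(cov, np.nan, (np.nan, np.nan), np.nan, np.nan,
                                     np.nan, model_id, n, n_events,
                                     flag=f"fit failed: {exc}"))
        return results

    summ = cph.summary
    old = np.seterr(over="ignore")  # huge CIs on degenerate fits -> inf, fine
    for cov in covariates:
        row = summ.loc[cov]
        cov_flag = flag
        if abs(float(row["coef"])) > 15:
            cov_flag = (cov_flag + "; " if cov_flag else "") + "possible complete separation"
        results.append(CoxResult(
            covariate=cov,
            hazard_ratio=float(np.exp(row["coef"])),
            ci95=(float(np.exp(row["coef lower 95%"])), float(np.exp(row["coef upper 95%"]))),
            p_value=float(row["p"]),
            log_hr=float(row["coef"]),
            se_log_hr=float(row["se(coef)"]),
            model_id=model_id,
            n=n,
            n_events=n_events,
            flag=cov_flag,
        ))
    np.seterr(**old)
    return results


def separate_entry_cox(
    df: pd.DataFrame,
    image_features: Sequence[str],
    always_include: Sequence[str] = ("rvisu_high",),
    **kwargs,
) -> list:
    """One multivariate Cox model per image feature.

    Mirrors the collinearity handling of clinical delta-radiomics
    reports: each image-derived predictor is entered in its own model
    together with the visual-score covariate.
    """
    results = []
    for feat in image_features:
        covs = [feat] + [c for c in always_include if c != feat]
        results.extend(cox_fit(df, covs, model_id=f"multivariate[{feat}]", **kwargs))
    return results


def one_year_labels(times, events, horizon: float = 12.0):
    """Binary 'progressed within the horizon' labels.

    Patients censored event-free before the horizon are not evaluable
    and are excluded.
    """
    t, e = _clean(times, events)
    evaluable = (e & (t <= horizon)) | (t >= horizon)
    labels = e & (t <= horizon)
    return labels[evaluable], evaluable


def roc_1year(times, events, predictor, horizon: float = 12.0) -> ROCResult:
    """Empirical ROC for discriminating progression within *horizon* months.

    *predictor* is a risk score (higher = more likely to progress).  AUC
    is the trapezoidal area (equivalently the midrank concordance
    probability); the operating point maximizes Youden's J = sens + spec - 1.
    """
    from sklearn.metrics import roc_curve

    p = np.asarray(predictor, dtype=float)
    labels, evaluable = one_year_labels(times, events, horizon)
    p_eval = p[evaluable]
    ok = np.isfinite(p_eval)
    labels, p_eval = labels[ok], p_eval[ok]
    n_excluded = int(len(p) - len(p_eval))
    if labels.all() or not labels.any():
        raise ValueError("one class is empty after the 1-year evaluability exclusion")
    fpr, tpr, thresholds = roc_curve(labels.astype(int), p_eval)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))
    return ROCResult(
        auc=auc,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        threshold=float(thresholds[best]),
        n_evaluable=int(len(p_eval)),
        n_excluded=n_excluded,
    )


def cumulative_incidence(events) -> float:
    """Crude event proportion (events / n) as a fraction."""
    e = np.asarray(events, dtype=bool)
    if e.size == 0:
        raise ValueError("empty group")
    return float(e.mean())
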