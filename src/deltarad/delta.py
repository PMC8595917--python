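"""Percent-change statistics, visual response scoring and paired analyses.

The change statistic for a feature with pre-ablation value P1 and
immediate post-ablation value P2 is

    dP = (P2 - P1) / P1 * 100  [%]

signed, so negative values mean the feature decreased after ablation.
Cohort summaries average the per-patient ratios (mean +/- SD of dP), not
the ratio of cohort means — with baselines that cross zero the two
differ wildly, so the aggregation rule matters.

The visual response score (Rvisu) follows an mRECIST-style rubric on the
1-month contrast-enhanced CT: 5 = complete ablation with volume
shrinkage, 4 = complete ablation with unchanged/slightly enlarged
volume, 3 = residual enhancing zone <50% of baseline, 2 = residual zone
>=50% or a newly developed enhancing zone.  Each lesion is read by three
observers and the arithmetic mean is the working score; a mean >= 4
defines complete ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .texture import CORE_FEATURES

__all__ = [
    "Enhancement",
    "VolumeChange",
    "ResponseObservation",
    "Rvisu",
    "CohortTable",
    "delta_percent",
    "cohort_delta",
    "score_response",
    "aggregate_rvisu",
    "paired_change_tests",
    "correlate_with_response",
]

COMPLETE_ABLATION_CUT = 4.0


class Enhancement(str, Enum):
    """Enhancing-zone finding on the 1-month CT."""

    NONE = "none"
    RESIDUAL_LT50 = "residual_lt50"
    RESIDUAL_GE50 = "residual_ge50"
    NEW_ZONE = "new_zone"


class VolumeChange(str, Enum):
    SHRUNK = "shrunk"
    UNCHANGED_OR_SLIGHTLY_ENLARGED = "unchanged_or_slightly_enlarged"
    ENLARGED = "enlarged"


@dataclass
class ResponseObservation:
    enhancement: Enhancement
    volume_change: VolumeChange
    observer_id: str = ""

    def __post_init__(self):
        self.enhancement = Enhancement(self.enhancement)
        self.volume_change = VolumeChange(self.volume_change)


@dataclass
class Rvisu:
    """Mean visual response score over the observers."""

    score: float
    observer_scores: tuple
    complete_ablation: bool


def score_response(obs: ResponseObservation) -> int:
    """Map a single observer's reading to the integer 2-5 rubric score."""
    e = obs.enhancement
    if e is Enhancement.NONE:
        if obs.volume_change is VolumeChange.SHRUNK:
            return 5
        if obs.volume_change is VolumeChange.UNCHANGED_OR_SLIGHTLY_ENLARGED:
            return 4
        raise ValueError(
            "no rubric score is defined for a non-enhancing but frankly enlarged lesion"
        )
    if e is Enhancement.RESIDUAL_LT50:
        return 3
    # residual >= 50% and newly developed zone both score 2
    return 2


def aggregate_rvisu(scores: Sequence[int], n_observers: int = 3) -> Rvisu:
    """Arithmetic mean of the observers' scores; >= 4 means complete ablation."""
    scores = tuple(int(s) for s in scores)
    if len(scores) != n_observers:
        raise ValueError(f"expected {n_observers} observer scores, got {len(scores)}")
    if any(s < 2 or s > 5 for s in scores):
        raise ValueError(f"observer scores must lie in 2..5, got {scores}")
    mean = float(np.mean(scores))
    return Rvisu(score=mean, observer_scores=scores,
                 complete_ablation=mean >= COMPLETE_ABLATION_CUT)


def delta_percent(p1: float, p2: float, p1_floor: float = 0.0) -> float:
    """Signed percent change (P2 - P1)/P1 * 100.

    NaN inputs propagate; a baseline with ``|P1| < p1_floor`` (or exactly
    zero) yields NaN — the ratio is meaningless against a vanishing
    baseline and the caller is expected to flag it.
    """
    if not (np.isfinite(p1) and np.isfinite(p2)):
        return float("nan")
    if abs(p1) <= max(p1_floor, 0.0) or p1 == 0.0:
        return float("nan")
    return (p2 - p1) / p1 * 100.0


@dataclass
class CohortTable:
    """A cohort of patients with paired feature vectors and clinical data.

    ``clinical`` is indexed by patient_id with (at least) columns
    ``rvisu_obs1..rvisu_obs3``, ``followup_months``, ``ltp_event``;
    ``features`` is long-format with columns
    ``patient_id``, ``timepoint`` ("pre"/"post"), ``feature``, ``value``.
    """

    clinical: pd.DataFrame
    features: pd.DataFrame
    observer_cols: tuple = ("rvisu_obs1", "rvisu_obs2", "rvisu_obs3")

    def __post_init__(self):
        if self.clinical.index.name != "patient_id":
            if "patient_id" in self.clinical.columns:
                self.clinical = self.clinical.set_index("patient_id")
        missing = [c for c in self.features.columns if c not in
                   ("patient_id", "timepoint", "feature", "value")]
        if missing or set(self.features.columns) != {"patient_id", "timepoint", "feature", "value"}:
            raise ValueError(
                "features must have exactly columns patient_id, timepoint, feature, value"
            )

    @property
    def patient_ids(self):
        return list(self.clinical.index)

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    def timepoint_wide(self, timepoint: str) -> pd.DataFrame:
        sub = self.features[self.features["timepoint"] == timepoint]
        return sub.pivot(index="patient_id", columns="feature", values="value").reindex(
            self.clinical.index
        )

    def rvisu_scores(self) -> pd.Series:
        """Per-patient mean observer score."""
        obs = self.clinical[list(self.observer_cols)]
        return obs.mean(axis=1).rename("rvisu")

    def complete_ablation(self) -> pd.Series:
        return (self.rvisu_scores() >= COMPLETE_ABLATION_CUT).rename("complete_ablation")


def cohort_delta(
    cohort: CohortTable,
    features: Optional[Sequence[str]] = None,
    p1_floor_scale: float = 1e-6,
    max_missing_fraction: float = 0.5,
):
    """Per-patient dP vectors and the per-feature cohort summary.

    The per-feature baseline floor is ``p1_floor_scale`` times the
    cohort interquartile range of P1 for that feature; patients whose
    baseline magnitude falls below it get an undefined (NaN) dP and are
    excluded from the summary, with the exclusion count reported.
    Features missing for more than ``max_missing_fraction`` of patients
    are dropped with a warning column in the summary.

    Returns
    -------
    delta : DataFrame (patient x feature), dP in percent.
    summary : DataFrame indexed by feature with columns
        mean, sd, n, n_undefined, dropped.
    """
    pre = cohort.timepoint_wide("pre")
    post = cohort.timepoint_wide("post")
    if features is None:
        features = [f for f in CORE_FEATURES if f in pre.columns]
    delta = pd.DataFrame(index=pre.index, columns=list(features), dtype=float)
    rows = []
    for feat in features:
        p1 = pre[feat] if feat in pre.columns else pd.Series(np.nan, index=pre.index)
        p2 = post[feat] if feat in post.columns else pd.Series(np.nan, index=pre.index)
        iqr = float(np.nanpercentile(p1, 75) - np.nanpercentile(p1, 25)) if p1.notna().any() else 0.0
        floor = p1_floor_scale * iqr
        vals = np.array([
            delta_percent(a, b, p1_floor=floor) for a, b in zip(p1.to_numpy(), p2.to_numpy())
        ])
        delta[feat] = vals
        defined = np.isfinite(vals)
        n_undef = int((~defined & p1.notna().to_numpy()).sum())
        dropped = defined.sum() < (1.0 - max_missing_fraction) * len(vals)
        rows.append({
            "feature": feat,
            "mean": float(np.nanmean(vals)) if defined.any() else np.nan,
            "sd": float(np.nanstd(vals, ddof=1)) if defined.sum() > 1 else np.nan,
            "n": int(defined.sum()),
            "n_undefined": n_undef,
            "dropped": bool(dropped),
        })
    summary = pd.DataFrame(rows).set_index("feature")
    return delta, summary


@dataclass
class PairedTestResult:
    feature_name: str
    test_used: str  # "paired_t" | "wilcoxon_signed_rank" | "skipped"
    statistic: float
    p_value: float
    shapiro_p: float
    note: str = ""


def paired_change_tests(
    cohort: CohortTable,
    features: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    min_pairs: int = 6,
):
    """Shapiro-Wilk-gated paired tests of P2 vs P1 per feature.

    The Shapiro-Wilk test is applied to the paired differences; when its
    p-value is >= *alpha* the differences are treated as normal and a
    paired t-test is used, otherwise the Wilcoxon signed-rank test
    (zero differences dropped; exact p for small n without ties, normal
    approximation with continuity correction otherwise).  Two-sided
    throughout.
    """
    pre = cohort.timepoint_wide("pre")
    post = cohort.timepoint_wide("post")
    if features is None:
        features = [f for f in CORE_FEATURES if f in pre.columns]
    results = []
    for feat in features:
        d = (post[feat] - pre[feat]).dropna().to_numpy()
        if d.size < min_pairs:
            results.append(PairedTestResult(feat, "skipped", np.nan, np.nan, np.nan,
                                            f"only {d.size} pairs (min {min_pairs})"))
            continue
        if np.allclose(d, 0.0):
            results.append(PairedTestResult(feat, "skipped", np.nan, np.nan, np.nan,
                                            "all paired differences are zero"))
            continue
        if np.ptp(d) == 0:
            sh_p = 0.0  # constant nonzero differences: trivially non-normal
        else:
            sh_p = float(stats.shapiro(d).pvalue)
        if sh_p >= alpha:
            t = stats.ttest_1samp(d, 0.0)  # paired t == one-sample t on differences
            results.append(PairedTestResult(feat, "paired_t", float(t.statistic),
                                            float(t.pvalue), sh_p))
        else:
            nz = d[d != 0]
            w = stats.wilcoxon(nz, method="auto", correction=True)
            results.append(PairedTestResult(feat, "wilcoxon_signed_rank",
                                            float(w.statistic), float(w.pvalue), sh_p))
    return results


@dataclass
class CorrelationResult:
    feature_name: str
    spearman_r: float
    p_value: float
    n: int
    note: str = ""


def correlate_with_response(
    values: pd.Series | np.ndarray,
    rvisu: pd.Series | np.ndarray,
    name: str = "",
    min_patients: int = 5,
) -> CorrelationResult:
    """Spearman rank correlation (average-rank ties, two-sided t-approx p)."""
    x = pd.Series(values).astype(float)
    y = pd.Series(rvisu).astype(float)
    ok = x.notna() & y.notna()
    x, y = x[ok].to_numpy(), y[ok].to_numpy()
    if x.size < min_patients:
        return CorrelationResult(name, np.nan, np.nan, int(x.size),
                                 f"only {x.size} patients (min {min_patients})")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(name, np.nan, np.nan, int(x.size),
                                 "constant input: correlation undefined")
    r, p = stats.spearmanr(x, y)
    return CorrelationResult(name, float(r), float(p), int(x.size))


def correlation_table(
    cohort: CohortTable,
    delta: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
    baseline_cols: Sequence[str] = ("diameter_cm", "volume_cm3"),
) -> pd.DataFrame:
    """Spearman correlations of dP (and baseline geometry) with Rvisu."""
    rvisu = cohort.rvisu_scores()
    rows = []
    for col in baseline_cols:
        if col in cohort.clinical.columns:
            res = correlate_with_response(cohort.clinical[col], rvisu, name=f"baseline_{col}")
            rows.append(res)
    for feat in (features or delta.columns):
        res = correlate_with_response(delta[feat], rvisu, name=f"delta_{feat}")
        rows.append(res)
    return pd.DataFrame(
        [{"parameter": r.feature_name, "r": r.spearman_r, "p_value": r.p_value,
          "n": r.n, "note": r.note} for r in rows]
    ).set_index("parameter")
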