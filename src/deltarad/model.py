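"""Cohort-level delta-radiomics analysis as a model/results pair.

:class:`AblationDeltaModel` is built from a :class:`~deltarad.delta.CohortTable`
(paired pre/post feature vectors plus clinical observations); its
:meth:`~AblationDeltaModel.fit` runs the full analysis —

1. per-patient percent changes (dP) and their cohort summary,
2. Shapiro-Wilk-gated paired tests of P2 vs P1 per feature,
3. Spearman correlations of dP (and baseline geometry) with the visual
   response score Rvisu,
4. Kaplan-Meier / log-rank comparisons of local-tumor-progression time
   between dichotomized groups, separate-entry multivariate Cox models,
   and 1-year ROC discrimination —

and returns an :class:`AblationDeltaResults` carrying the tables, with a
``summary()`` rendering them in the shape of a clinical report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import delta as _delta
from . import survival as _survival
from .delta import CohortTable

__all__ = ["AblationDeltaModel", "AblationDeltaResults"]

#: delta-features dichotomized for the survival analysis, with presets.
SURVIVAL_IMAGE_PRESETS = {
    "dcontrast_gt_30_5": ("contrast", 30.5, "gt"),
    "dzone_percentage_gt_21_5": ("zone_percentage", 21.5, "gt"),
}
CLINICAL_PRESETS = {
    "rvisu_ge_3": ("rvisu", 3.0, "ge"),
    "diameter_ge_3_6": ("diameter_cm", 3.6, "ge"),
    "volume_ge_4_1": ("volume_cm3", 4.1, "ge"),
    "age_ge_67": ("age", 67.0, "ge"),
}


class AblationDeltaModel:
    """Delta-radiomics response/progression model for one cohort.

    Parameters
    ----------
    cohort : CohortTable
    alpha : float
        Level for the Shapiro-Wilk normality gate.
    roc_horizon : float
        Discrimination horizon in months (default 12 = 1-year LTP).
    """

    def __init__(self, cohort: CohortTable, alpha: float = 0.05,
                 roc_horizon: float = 12.0):
        self.cohort = cohort
        self.alpha = float(alpha)
        self.roc_horizon = float(roc_horizon)

    @classmethod
    def from_manifest(cls, manifest_path, extract_kwargs: Optional[dict] = None,
                      on_error: str = "skip", **kwargs):
        """Build the model by extracting features for every manifest row.

        ``on_error="skip"`` records per-patient failures instead of
        aborting; they are available as ``model.failures``.
        """
        from .pipeline import load_cohort_from_manifest

        cohort, failures = load_cohort_from_manifest(
            manifest_path, extract_kwargs=extract_kwargs or {}, on_error=on_error
        )
        model = cls(cohort, **kwargs)
        model.failures = failures
        return model

    @classmethod
    def from_frames(cls, features: pd.DataFrame, clinical: pd.DataFrame, **kwargs):
        return cls(CohortTable(clinical=clinical, features=features), **kwargs)

    # ------------------------------------------------------------------
    def fit(self) -> "AblationDeltaResults":
        cohort = self.cohort
        delta_wide, delta_summary = _delta.cohort_delta(cohort)
        paired = _delta.paired_change_tests(cohort, alpha=self.alpha)
        paired_df = pd.DataFrame(
            [{"feature": r.feature_name, "test_used": r.test_used,
              "statistic": r.statistic, "p_value": r.p_value,
              "shapiro_p": r.shapiro_p, "note": r.note} for r in paired]
        ).set_index("feature")
        corr = _delta.correlation_table(cohort, delta_wide)

        rvisu = cohort.rvisu_scores()
        surv = cohort.clinical[["followup_months", "ltp_event"]].copy()
        surv["ltp_event"] = surv["ltp_event"].astype(bool)
        surv["rvisu"] = rvisu

        # group indicators
        groups = pd.DataFrame(index=surv.index)
        group_defs = {}
        for name, (feat, thr, direction) in SURVIVAL_IMAGE_PRESETS.items():
            if feat in delta_wide.columns:
                vals = delta_wide[feat]
                high, defined, n_excl = _survival.dichotomize(vals, thr, direction)
                groups[name] = np.where(defined, high, np.nan)
                group_defs[name] = {"variable": f"delta_{feat}", "threshold": thr,
                                    "direction": direction, "n_excluded": n_excl}
        for name, (col, thr, direction) in CLINICAL_PRESETS.items():
            source = rvisu if col == "rvisu" else (
                cohort.clinical[col] if col in cohort.clinical.columns else None
            )
            if source is None:
                continue
            high, defined, n_excl = _survival.dichotomize(source, thr, direction)
            groups[name] = np.where(defined, high, np.nan)
            group_defs[name] = {"variable": col, "threshold": thr,
                                "direction": direction, "n_excluded": n_excl}

        # KM + log-rank per grouping
        km_rows, km_curves = [], {}
        for name in groups.columns:
            g = groups[name]
            ok = g.notna()
            hi, lo = ok & (g == 1), ok & (g == 0)
            if hi.sum() == 0 or lo.sum() == 0:
                km_rows.append({"group": name, "note": "one side empty"})
                continue
            est_hi = _survival.km_fit(surv.loc[hi, "followup_months"], surv.loc[hi, "ltp_event"])
            est_lo = _survival.km_fit(surv.loc[lo, "followup_months"], surv.loc[lo, "ltp_event"])
            lr = _survival.logrank(
                surv.loc[hi, "followup_months"], surv.loc[hi, "ltp_event"],
                surv.loc[lo, "followup_months"], surv.loc[lo, "ltp_event"],
            )
            km_curves[name] = {"high": est_hi, "low": est_lo}
            km_rows.append({
                "group": name,
                "n_high": int(hi.sum()), "n_low": int(lo.sum()),
                "events_high": est_hi.n_events, "events_low": est_lo.n_events,
                "incidence_high": _survival.cumulative_incidence(surv.loc[hi, "ltp_event"]),
                "incidence_low": _survival.cumulative_incidence(surv.loc[lo, "ltp_event"]),
                "median_high": _survival.km_median(est_hi),
                "median_low": _survival.km_median(est_lo),
                "logrank_chi2": lr["chi2"], "logrank_p": lr["p"], "note": "",
            })
        km_df = pd.DataFrame(km_rows).set_index("group")

        # Cox: univariate per group indicator; separate-entry multivariate
        cox_data = surv.copy()
        for name in groups.columns:
            cox_data[name] = groups[name].astype(float)
        uni = []
        for name in groups.columns:
            uni.extend(_survival.cox_fit(cox_data, [name], model_id="univariate"))
        image_groups = [n for n in SURVIVAL_IMAGE_PRESETS if n in groups.columns]
        multi = _survival.separate_entry_cox(
            cox_data, image_groups, always_include=("rvisu_ge_3",)
        ) if "rvisu_ge_3" in groups.columns else []

        def cox_frame(results):
            return pd.DataFrame(
                [{"model": r.model_id, "covariate": r.covariate,
                  "hazard_ratio": r.hazard_ratio, "ci95_low": r.ci95[0],
                  "ci95_high": r.ci95[1], "p_value": r.p_value,
                  "log_hr": r.log_hr, "se_log_hr": r.se_log_hr,
                  "n": r.n, "n_events": r.n_events, "flag": r.flag}
                 for r in results]
            )

        # 1-year ROC: risk score = negative of the protective predictor
        roc = {}
        if "contrast" in delta_wide.columns:
            try:
                roc["delta_contrast"] = _survival.roc_1year(
                    surv["followup_months"], surv["ltp_event"],
                    -delta_wide["contrast"], horizon=self.roc_horizon)
            except ValueError:
                pass
        try:
            roc["rvisu"] = _survival.roc_1year(
                surv["followup_months"], surv["ltp_event"], -rvisu,
                horizon=self.roc_horizon)
        except ValueError:
            pass

        return AblationDeltaResults(
            model=self,
            delta=delta_wide,
            delta_summary=delta_summary,
            paired_tests=paired_df,
            correlations=corr,
            groups=groups,
            group_definitions=group_defs,
            km_table=km_df,
            km_curves=km_curves,
            cox_univariate=cox_frame(uni),
            cox_multivariate=cox_frame(multi),
            roc=roc,
            rvisu=rvisu,
            complete_ablation_rate=float(cohort.complete_ablation().mean()),
            ltp_crude_incidence=_survival.cumulative_incidence(surv["ltp_event"]),
        )


@dataclass
class AblationDeltaResults:
    """Fitted tables of the cohort analysis; see :class:`AblationDeltaModel`."""

    model: AblationDeltaModel
    delta: pd.DataFrame
    delta_summary: pd.DataFrame
    paired_tests: pd.DataFrame
    correlations: pd.DataFrame
    groups: pd.DataFrame
    group_definitions: dict
    km_table: pd.DataFrame
    km_curves: dict
    cox_univariate: pd.DataFrame
    cox_multivariate: pd.DataFrame
    roc: dict
    rvisu: pd.Series
    complete_ablation_rate: float
    ltp_crude_incidence: float

    def summary(self) -> str:
        lines = []
        n = self.model.cohort.n_patients
        lines.append("Delta-radiomics ablation response analysis")
        lines.append("=" * 58)
        lines.append(f"patients: {n}   complete ablation (Rvisu>=4): "
                     f"{self.complete_ablation_rate * 100:.1f}%   "
                     f"crude LTP incidence: {self.ltp_crude_incidence * 100:.1f}%")
        lines.append("")
        lines.append("Per-feature change (dP %, mean +/- SD over patients):")
        for feat, row in self.delta_summary.iterrows():
            test = self.paired_tests.loc[feat] if feat in self.paired_tests.index else None
            p_txt = (f"p={test['p_value']:.4f} ({test['test_used']})"
                     if test is not None and np.isfinite(test["p_value"]) else "")
            lines.append(f"  {feat:38s} {row['mean']:+9.1f} +/- {row['sd']:7.1f}  {p_txt}")
        lines.append("")
        lines.append("Spearman correlation with Rvisu:")
        for name, row in self.correlations.iterrows():
            if np.isfinite(row["r"]):
                lines.append(f"  {name:38s} r={row['r']:+.3f}  p={row['p_value']:.4f}")
        lines.append("")
        lines.append("LTP group comparisons (Kaplan-Meier / log-rank):")
        for name, row in self.km_table.iterrows():
            if row.get("note"):
                lines.append(f"  {name:28s} ({row['note']})")
                continue
            lines.append(
                f"  {name:28s} n={row['n_high']:.0f}/{row['n_low']:.0f}  "
                f"incidence {row['incidence_high'] * 100:.1f}%/{row['incidence_low'] * 100:.1f}%  "
                f"logrank p={row['logrank_p']:.4f}"
            )
        if len(self.cox_multivariate):
            lines.append("")
            lines.append("Separate-entry multivariate Cox (HR [95% CI], p):")
            for _, row in self.cox_multivariate.iterrows():
                if np.isfinite(row["hazard_ratio"]):
                    lines.append(
                        f"  {row['model']:34s} {row['covariate']:26s} "
                        f"{row['hazard_ratio']:.2f} [{row['ci95_low']:.2f}-{row['ci95_high']:.2f}] "
                        f"p={row['p_value']:.4f}"
                    )
        if self.roc:
            lines.append("")
            lines.append(f"{self.model.roc_horizon:.0f}-month LTP discrimination (ROC):")
            for name, r in self.roc.items():
                lines.append(
                    f"  {name:28s} AUC={r.auc:.3f}  sens={r.sensitivity * 100:.1f}%  "
                    f"spec={r.specificity * 100:.1f}%  (n={r.n_evaluable})"
                )
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def plot_km(self, group: str, ax=None):
        """Kaplan-Meier curves for one dichotomized grouping."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curves = self.km_curves[group]
        for side, est in curves.items():
            ax.step(np.concatenate(([0], est.times)),
                    np.concatenate(([1.0], est.survival)),
                    where="post", label=f"{group} {side} (n={est.n})")
        ax.set_xlabel("months since ablation")
        ax.set_ylabel("LTP-free probability")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax

    def plot_roc(self, ax=None):
        """Point summary of the fitted ROC operating points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        for name, r in self.roc.items():
            ax.scatter(1 - r.specificity, r.sensitivity,
                       label=f"{name} (AUC {r.auc:.2f})")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax
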