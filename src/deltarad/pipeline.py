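"""Manifest-driven orchestration: extract -> delta -> response -> survival.

The cohort manifest is a CSV with one row per patient:

    patient_id, pre_image, pre_mask, post_image, post_mask,
    rvisu_obs1..rvisu_obs3, followup_months, ltp_event
    [, age, sex, smoker, diameter_cm, volume_cm3, censor_reason]

``run_pipeline`` produces a report bundle (five CSV tables plus a JSON
run log) in the output directory; a corrupt patient is skipped and
reported rather than aborting the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .delta import CohortTable
from .image_io import MaskedVolume, read_mask, read_volume
from .model import AblationDeltaModel
from .texture import extract_all

__all__ = ["RunConfig", "validate_manifest", "load_cohort_from_manifest", "run_pipeline"]

REQUIRED_COLUMNS = (
    "patient_id", "pre_image", "pre_mask", "post_image", "post_mask",
    "rvisu_obs1", "rvisu_obs2", "rvisu_obs3", "followup_months", "ltp_event",
)

REPORT_FILES = (
    "features_long.csv",
    "delta_report.csv",
    "correlation_table.csv",
    "survival_tables.csv",
    "roc_summary.csv",
)


@dataclasses.dataclass
class RunConfig:
    """Serializable pipeline configuration."""

    discretization_scheme: str = "fixed_bin_width"
    discretization_param: float = 25.0
    glcm_distance: int = 1
    resegment_low: float = -1000.0
    resegment_high: float = 400.0
    resegment_mode: str = "remove"
    min_roi_voxels: int = 64
    alpha: float = 0.05
    roc_horizon_months: float = 12.0
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            if str(path).endswith((".yaml", ".yml")):
                import yaml  # optional; JSON is the primary config format

                data = yaml.safe_load(fh)
            else:
                data = json.load(fh)
        return cls(**data)


def _resolve(path, base: Path) -> Path:
    """Manifest file paths may be relative to the manifest's directory."""
    p = Path(str(path))
    return p if p.is_absolute() else base / p


def validate_manifest(manifest_path) -> list:
    """Machine-readable issue list for a cohort manifest CSV."""
    issues = []
    base = Path(manifest_path).parent
    try:
        df = pd.read_csv(manifest_path)
    except Exception as exc:
        return [{"row": None, "column": None, "issue": f"unparsable CSV: {exc}"}]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            issues.append({"row": None, "column": col, "issue": "missing column"})
    if issues:
        return issues
    for idx, row in df.iterrows():
        for col in ("pre_image", "pre_mask", "post_image", "post_mask"):
            if not _resolve(row[col], base).exists():
                issues.append({"row": int(idx), "column": col,
                               "issue": f"file not found: {row[col]}"})
        for col in ("rvisu_obs1", "rvisu_obs2", "rvisu_obs3"):
            try:
                s = float(row[col])
            except (TypeError, ValueError):
                issues.append({"row": int(idx), "column": col, "issue": "not a number"})
                continue
            if not (2 <= s <= 5 and float(s).is_integer()):
                issues.append({"row": int(idx), "column": col,
                               "issue": f"score {row[col]} outside integer range 2..5"})
        try:
            t = float(row["followup_months"])
            if not t > 0:
                issues.append({"row": int(idx), "column": "followup_months",
                               "issue": f"non-positive follow-up time {t}"})
        except (TypeError, ValueError):
            issues.append({"row": int(idx), "column": "followup_months",
                           "issue": "not a number"})
        if row["ltp_event"] not in (0, 1, True, False):
            issues.append({"row": int(idx), "column": "ltp_event",
                           "issue": f"event flag must be 0/1, got {row['ltp_event']}"})
    return issues


def _extract_patient(row, config: RunConfig, base: Path):
    reseg = (config.resegment_low, config.resegment_high)
    out = {}
    for tp in ("pre", "post"):
        img = read_volume(_resolve(row[f"{tp}_image"], base))
        msk = read_mask(_resolve(row[f"{tp}_mask"], base), img)
        mv = MaskedVolume(image=img, roi=msk, resegment_range=reseg,
                          resegment_mode=config.resegment_mode)
        out[tp] = extract_all(
            mv,
            scheme=config.discretization_scheme,
            param=config.discretization_param,
            distance=config.glcm_distance,
            min_voxels=config.min_roi_voxels,
        )
    return out


def load_cohort_from_manifest(manifest_path, extract_kwargs: Optional[dict] = None,
                              config: Optional[RunConfig] = None,
                              on_error: str = "skip"):
    """Read a manifest, extract features per patient, build a CohortTable.

    Returns ``(cohort, failures)`` where failures maps patient_id to the
    error message (empty when all rows succeeded).
    """
    config = config or RunConfig(**(extract_kwargs or {}))
    base = Path(manifest_path).parent
    df = pd.read_csv(manifest_path)
    if df.empty:
        raise ValueError(f"{manifest_path}: empty manifest")
    feat_rows, failures, timings = [], {}, {}
    kept = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        t0 = time.perf_counter()
        try:
            fvs = _extract_patient(row, config, base)
        except Exception as exc:
            if on_error != "skip":
                raise
            failures[pid] = str(exc)
            continue
        timings[pid] = time.perf_counter() - t0
        kept.append(pid)
        for tp, fv in fvs.items():
            for name, value in fv.values.items():
                feat_rows.append({"patient_id": pid, "timepoint": tp,
                                  "feature": name, "value": value})
    if not kept:
        raise ValueError("no patient could be analyzed")
    clinical = df[df["patient_id"].astype(str).isin(kept)].copy()
    drop = [c for c in ("pre_image", "pre_mask", "post_image", "post_mask") if c in clinical]
    clinical = clinical.drop(columns=drop).set_index("patient_id")
    cohort = CohortTable(clinical=clinical, features=pd.DataFrame(feat_rows))
    cohort._timings = timings  # exposed for the run log
    return cohort, failures


def run_pipeline(manifest_path, config: Optional[RunConfig] = None, out_dir="results"):
    """Run the full analysis and write the report bundle.

    Writes features_long.csv, delta_report.csv, correlation_table.csv,
    survival_tables.csv, roc_summary.csv, run_log.json and config.json
    to *out_dir*; returns the fitted :class:`AblationDeltaResults`.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    issues = validate_manifest(manifest_path)
    if any(i["row"] is None for i in issues):
        raise ValueError(f"manifest schema violation: {issues}")

    cohort, failures = load_cohort_from_manifest(manifest_path, config=config)
    model = AblationDeltaModel(cohort, alpha=config.alpha,
                               roc_horizon=config.roc_horizon_months)
    res = model.fit()

    meta = {"config_hash": config.config_hash(), "code_version": __version__}

    cohort.features.assign(**meta).to_csv(out / "features_long.csv", index=False)
    delta_long = res.delta.reset_index().melt(
        id_vars="patient_id", var_name="feature_name", value_name="delta_percent")
    delta_long["undefined_flag"] = ~np.isfinite(delta_long["delta_percent"])
    delta_long.assign(**meta).to_csv(out / "delta_report.csv", index=False)
    res.correlations.assign(**meta).to_csv(out / "correlation_table.csv")
    surv = pd.concat([
        res.cox_univariate.assign(table="cox"),
        res.cox_multivariate.assign(table="cox"),
        res.km_table.reset_index().assign(table="km_logrank"),
    ], ignore_index=True)
    surv.assign(**meta).to_csv(out / "survival_tables.csv", index=False)
    roc_df = pd.DataFrame([
        {"predictor": name, "auc": r.auc, "sensitivity": r.sensitivity,
         "specificity": r.specificity, "threshold": r.threshold,
         "n_evaluable": r.n_evaluable, "n_excluded": r.n_excluded}
        for name, r in res.roc.items()
    ])
    roc_df.assign(**meta).to_csv(out / "roc_summary.csv", index=False)

    flagged = {
        "undefined_delta": int(delta_long["undefined_flag"].sum()),
        "skipped_tests": res.paired_tests[res.paired_tests["test_used"] == "skipped"]
        .index.tolist(),
    }
    log = {
        **meta,
        "n_patients": cohort.n_patients,
        "failures": failures,
        "manifest_issues": issues,
        "per_patient_seconds": {k: round(v, 4) for k, v in
                                getattr(cohort, "_timings", {}).items()},
        "flagged": flagged,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
    return res
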