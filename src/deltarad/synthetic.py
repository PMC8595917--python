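"""Synthetic paired-CT phantoms and cohorts with known ground truth.

The generator emulates the statistical structure a thermal-ablation
delta-radiomics analysis assumes, so every pipeline stage can be tested
without patient data:

* a **phantom pair** is a spherical/ellipsoidal/lobulated lesion of
  baseline mean density plus a correlated Gaussian texture field inside
  the mask, lung-density background outside; the post-ablation twin
  shares the geometry (ablation does not change tumor volume acutely),
  with the mean shifted *down* and the texture amplitude *scaled up* —
  density drops while heterogeneity rises;
* a **cohort** draws a response class per patient (visual scores 5..2),
  applies class-dependent ablation effects, simulates three observers
  reading the true class with symmetric +/-1 misclassification noise,
  and draws progression times from an exponential proportional-hazards
  model whose covariate is the patient's true ablation-effect group.

Ground truth (latent response strength, true effects, true event times,
true group memberships) is stored alongside but never consumed by the
analysis stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import ImageVolume, MaskedVolume, ROIMask, write_mask, write_volume

__all__ = [
    "PhantomConfig",
    "CohortConfig",
    "SyntheticPatient",
    "SyntheticCohort",
    "make_phantom_pair",
    "make_cohort",
    "export_fixtures",
    "preset",
    "PRESETS",
]

#: Per-response-class ablation effects: visual score -> (mean HU drop,
#: texture-amplitude multiplier).  Strong responders (scores 5/4) show a
#: deep density drop and a large heterogeneity increase; weak responders
#: barely change.  Chosen for clear class separation; not fitted to any
#: patient data.
CLASS_EFFECTS = {
    5: (110.0, 2.1),
    4: (90.0, 1.85),
    3: (45.0, 1.12),
    2: (15.0, 1.02),
}

#: Visual-score mixture of the default cohort (fractions of scores
#: 5/4/3/2), mirroring a published 50-patient ablation series
#: (20/16/9/5 patients).
DEFAULT_MIXTURE = {5: 0.40, 4: 0.32, 3: 0.18, 2: 0.10}

#: True high-effect group: texture multiplier at or above this cut.
TRUE_GROUP_MULTIPLIER_CUT = 1.5


@dataclass
class PhantomConfig:
    """Geometry and intensity model of one synthetic lesion pair."""

    shape: tuple = (12, 32, 32)
    spacing: tuple = (5.0, 1.0, 1.0)  # mm, emulating thick-slice chest CT
    radius_mm: float = 14.0
    baseline_mean_hu: float = 30.0
    texture_sd_hu: float = 40.0
    mean_drop_hu: float = 90.0
    heterogeneity_multiplier: float = 1.85
    lesion_shape: str = "sphere"  # sphere | ellipsoid | lobulated
    background_hu: float = -800.0
    background_sd_hu: float = 30.0
    smoothing_voxels: float = 1.0
    seed: int = 0

    def __post_init__(self):
        half_extent = min(n * s for n, s in zip(self.shape, self.spacing)) / 2.0
        if self.radius_mm >= half_extent:
            raise ValueError(
                f"radius {self.radius_mm} mm does not fit inside the grid "
                f"(half extent {half_extent} mm)"
            )
        if self.heterogeneity_multiplier <= 0:
            raise ValueError("heterogeneity multiplier must be positive")
        if self.lesion_shape not in ("sphere", "ellipsoid", "lobulated"):
            raise ValueError(f"unknown lesion shape {self.lesion_shape!r}")


def _lesion_mask(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    shape = cfg.shape
    spacing = np.array(cfg.spacing)
    center = (np.array(shape) - 1) / 2.0 * spacing
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1) * spacing
    d = coords - center
    if cfg.lesion_shape == "sphere":
        mask = (d**2).sum(axis=-1) <= cfg.radius_mm**2
    elif cfg.lesion_shape == "ellipsoid":
        semi = np.array([0.8, 1.0, 1.2]) * cfg.radius_mm
        mask = ((d / semi) ** 2).sum(axis=-1) <= 1.0
    else:  # lobulated: union of the main sphere and two offset lobes
        mask = (d**2).sum(axis=-1) <= cfg.radius_mm**2
        for _ in range(2):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            off = center + direction * 0.7 * cfg.radius_mm
            dd = coords - off
            mask |= (dd**2).sum(axis=-1) <= (0.5 * cfg.radius_mm) ** 2
    return mask


def _correlated_field(shape, sigma_voxels, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with short-range correlation."""
    white = rng.standard_normal(shape)
    if sigma_voxels > 0:
        f = ndimage.gaussian_filter(white, sigma_voxels)
        sd = f.std()
        if sd > 0:
            f = f / sd
        return f
    return white


def make_phantom_pair(cfg: PhantomConfig):
    """Generate (pre, post, truth) for one lesion.

    The post volume reuses the pre texture field, scaled by the
    heterogeneity multiplier, so a zero-effect configuration reproduces
    the pre volume voxel for voxel and the change statistics respond
    only to the configured effects.
    """
    rng = np.random.default_rng(cfg.seed)
    mask = _lesion_mask(cfg, rng)
    field = _correlated_field(cfg.shape, cfg.smoothing_voxels, rng)
    bg_noise = _correlated_field(cfg.shape, cfg.smoothing_voxels, rng)
    background = cfg.background_hu + cfg.background_sd_hu * bg_noise

    pre_vox = np.where(mask, cfg.baseline_mean_hu + cfg.texture_sd_hu * field, background)
    post_inside = (
        cfg.baseline_mean_hu
        - cfg.mean_drop_hu
        + cfg.heterogeneity_multiplier * cfg.texture_sd_hu * field
    )
    post_vox = np.where(mask, post_inside, background)

    def mv(vox):
        return MaskedVolume(
            image=ImageVolume(vox, spacing=cfg.spacing),
            roi=ROIMask(mask.copy(), label="lesion"),
            resegment_range=(-1000.0, 400.0),
        )

    truth = {
        "mean_drop_hu": cfg.mean_drop_hu,
        "heterogeneity_multiplier": cfg.heterogeneity_multiplier,
        "mask_voxels": int(mask.sum()),
        "seed": cfg.seed,
    }
    return mv(pre_vox), mv(post_vox), truth


@dataclass
class CohortConfig:
    """Cohort-level generator settings."""

    n_patients: int = 50
    mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    class_effects: dict = field(default_factory=lambda: dict(CLASS_EFFECTS))
    #: Hazard (per month) of the low-effect (poor ablation) group.
    baseline_hazard: float = np.log(2) / 10.0
    #: log hazard ratio of the low-effect group relative to the
    #: high-effect group (hazard_low = hazard_high * exp(log_hr)).
    log_hr: float = float(np.log(5.61))
    #: Follow-up window (months): censoring time ~ Uniform(lo, hi).
    followup_window: tuple = (12.0, 28.0)
    #: Extra independent exponential censoring rate (per month; 0 = off).
    censoring_rate: float = 0.0
    #: Each observer reports the true score +/-1 with this probability
    #: per side (clipped to [2, 5]).
    observer_flip_prob: float = 0.1
    n_observers: int = 3
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        total = sum(self.mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"mixture fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.mixture.values()):
            raise ValueError("mixture fractions must be non-negative")


@dataclass
class SyntheticPatient:
    patient_id: str
    pre: MaskedVolume
    post: MaskedVolume
    clinical: dict
    truth: dict


@dataclass
class SyntheticCohort:
    patients: list
    clinical: pd.DataFrame  # indexed by patient_id
    ground_truth: dict
    config: CohortConfig


def _draw_observer_scores(true_score: int, rng, flip_prob: float, n_obs: int):
    steps = rng.choice([-1, 0, 1], size=n_obs,
                       p=[flip_prob, 1 - 2 * flip_prob, flip_prob])
    return tuple(int(np.clip(true_score + s, 2, 5)) for s in steps)


def make_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth.

    Deterministic given ``cfg.seed``; per-patient randomness is derived
    from a spawned substream so patients are independent.
    """
    rng = np.random.default_rng(cfg.seed)
    scores = sorted(cfg.mixture)  # [2, 3, 4, 5]
    probs = np.array([cfg.mixture[s] for s in scores])
    # deterministic class counts closest to the mixture, then shuffle
    counts = np.floor(probs * cfg.n_patients).astype(int)
    remainder = cfg.n_patients - counts.sum()
    order = np.argsort(-(probs * cfg.n_patients - counts))
    for k in range(remainder):
        counts[order[k % len(scores)]] += 1
    for s, c, p in zip(scores, counts, probs):
        if c > 0 and p == 0:
            raise ValueError(f"class {s} has zero probability but nonzero count")
    class_list = np.repeat(scores, counts)
    rng.shuffle(class_list)

    patients = []
    clin_rows = []
    truth_all = {}
    lo, hi = cfg.followup_window
    for i, true_score in enumerate(class_list):
        pid = f"SYN{i + 1:03d}"
        prng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        drop, mult = cfg.class_effects[int(true_score)]
        # mild patient-level variability around the class effect and in
        # baseline lesion size (so baseline geometry is non-degenerate)
        drop = float(drop * prng.uniform(0.85, 1.15))
        mult = float(mult * prng.uniform(0.92, 1.08))
        pcfg_kwargs = asdict(cfg.phantom)
        pcfg_kwargs.update(
            radius_mm=float(cfg.phantom.radius_mm * prng.uniform(0.75, 1.05)),
            mean_drop_hu=drop,
            heterogeneity_multiplier=mult,
            seed=int(prng.integers(0, 2**31 - 1)),
        )
        pcfg = PhantomConfig(**pcfg_kwargs)
        pre, post, ph_truth = make_phantom_pair(pcfg)

        strong = mult >= TRUE_GROUP_MULTIPLIER_CUT
        latent = float(np.clip((int(true_score) - 2) / 3.0 + prng.normal(0, 0.05), 0, 1))
        hazard = cfg.baseline_hazard * (1.0 if not strong else np.exp(-cfg.log_hr))
        t_event = float(prng.exponential(1.0 / hazard))
        t_censor = float(prng.uniform(lo, hi))
        if cfg.censoring_rate > 0:
            t_censor = min(t_censor, float(prng.exponential(1.0 / cfg.censoring_rate)))
        t_obs = min(t_event, t_censor)
        event = t_event <= t_censor

        obs_scores = _draw_observer_scores(int(true_score), prng,
                                           cfg.observer_flip_prob, cfg.n_observers)

        from .image_io import roi_geometry

        geom = roi_geometry(pre)
        clin = {
            "patient_id": pid,
            "rvisu_obs1": obs_scores[0],
            "rvisu_obs2": obs_scores[1],
            "rvisu_obs3": obs_scores[2],
            "followup_months": round(max(t_obs, 0.1), 3),
            "ltp_event": int(event),
            "age": int(prng.integers(52, 83)),
            "sex": str(prng.choice(["M", "F"], p=[0.74, 0.26])),
            "smoker": int(prng.integers(0, 2)),
            "diameter_cm": round(geom["max_diameter_cm"], 3),
            "volume_cm3": round(geom["volume_cm3"], 3),
        }
        truth = {
            "true_score": int(true_score),
            "latent_response_strength": latent,
            "true_mean_drop_hu": drop,
            "true_heterogeneity_multiplier": mult,
            "true_high_effect_group": bool(strong),
            "true_event_time_months": t_event,
            "censor_time_months": t_censor,
            **ph_truth,
        }
        patients.append(SyntheticPatient(pid, pre, post, clin, truth))
        clin_rows.append(clin)
        truth_all[pid] = truth

    clinical = pd.DataFrame(clin_rows).set_index("patient_id")
    return SyntheticCohort(patients=patients, clinical=clinical,
                           ground_truth=truth_all, config=cfg)


def extract_cohort_features(cohort: SyntheticCohort, **extract_kwargs) -> pd.DataFrame:
    """Run feature extraction on every phantom pair; long-format frame."""
    from .texture import extract_all

    extract_kwargs.setdefault("min_voxels", 16)
    rows = []
    for p in cohort.patients:
        for tp, mv in (("pre", p.pre), ("post", p.post)):
            fv = extract_all(mv, **extract_kwargs)
            for name, value in fv.values.items():
                rows.append({"patient_id": p.patient_id, "timepoint": tp,
                             "feature": name, "value": value})
    return pd.DataFrame(rows)


def export_fixtures(cohort: SyntheticCohort, out_dir) -> Path:
    """Write NIfTI volumes/masks, the cohort manifest CSV, ground-truth
    JSON and the serialized config; returns the manifest path."""
    out = Path(out_dir)
    if cohort.config.n_patients == 0 or not cohort.patients:
        raise ValueError("cannot export an empty cohort")
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.patients:
        paths = {}
        for tp, mv in (("pre", p.pre), ("post", p.post)):
            ipath = img_dir / f"{p.patient_id}_{tp}.nii.gz"
            mpath = img_dir / f"{p.patient_id}_{tp}_mask.nii.gz"
            write_volume(mv.image, ipath)
            write_mask(mv.roi, mv.image, mpath)
            # paths relative to the manifest: the bundle is relocatable and
            # re-exports with the same seed are byte-identical
            paths[f"{tp}_image"] = str(ipath.relative_to(out))
            paths[f"{tp}_mask"] = str(mpath.relative_to(out))
        row = {"patient_id": p.patient_id, **paths, **{k: v for k, v in p.clinical.items()
                                                       if k != "patient_id"}}
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False, float_format="%.6g")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=1, sort_keys=True, default=float)
    cfg = asdict(cohort.config)
    with open(out / "cohort_config.json", "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True, default=str)
    return manifest_path


def preset(name: str, seed: int = 0, n_patients: Optional[int] = None) -> CohortConfig:
    """Named cohort presets.

    * ``tiny`` — 8x16x16 grids, 10 patients: fast smoke testing.
    * ``default`` — 12x32x32 grids, 50 patients.
    * ``paper_mimic`` — the published 50-patient score mixture
      (20/16/9/5) on small grids; ``n_patients`` can upscale it while
      keeping the mixture.
    """
    if name == "tiny":
        ph = PhantomConfig(shape=(8, 16, 16), spacing=(2.5, 1.25, 1.25), radius_mm=7.0)
        cfg = CohortConfig(n_patients=n_patients or 10, phantom=ph, seed=seed)
    elif name == "default":
        cfg = CohortConfig(n_patients=n_patients or 50, seed=seed)
    elif name == "paper_mimic":
        ph = PhantomConfig(shape=(8, 16, 16), spacing=(2.5, 1.25, 1.25), radius_mm=7.0)
        cfg = CohortConfig(n_patients=n_patients or 50,
                           mixture=dict(DEFAULT_MIXTURE), phantom=ph, seed=seed)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return cfg


PRESETS = ("tiny", "default", "paper_mimic")
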