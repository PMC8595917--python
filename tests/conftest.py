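import numpy as np
import pandas as pd
import pytest

from deltarad.delta import CohortTable
from deltarad.image_io import ImageVolume, MaskedVolume, ROIMask
from deltarad.texture import DiscretizedROI


def droi_from_levels(levels: np.ndarray, ng: int | None = None) -> DiscretizedROI:
    """DiscretizedROI straight from an integer level array (0 = outside)."""
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim < 3:
        levels = levels.reshape((1,) * (3 - levels.ndim) + levels.shape)
    ng = int(ng if ng is not None else levels.max())
    edges = np.arange(0.5, ng + 1.5)
    return DiscretizedROI(levels=levels, ng=ng, bin_edges=edges)


def mv_from_array(arr, mask=None, spacing=(1.0, 1.0, 1.0), resegment_range=None,
                  resegment_mode="remove"):
    arr = np.asarray(arr, dtype=float)
    if arr.ndim < 3:
        arr = arr.reshape((1,) * (3 - arr.ndim) + arr.shape)
    if mask is None:
        mask = np.ones(arr.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim < 3:
            mask = mask.reshape((1,) * (3 - mask.ndim) + mask.shape)
    return MaskedVolume(
        image=ImageVolume(arr, spacing=spacing),
        roi=ROIMask(mask),
        resegment_range=resegment_range,
        resegment_mode=resegment_mode,
    )


def random_droi(rng, max_shape=6, ng=5):
    """Random ROI with levels 0..ng, guaranteed to hold a co-occurring pair."""
    while True:
        shape = tuple(rng.integers(2, max_shape + 1, size=3))
        levels = rng.integers(0, ng + 1, size=shape)
        inmask = levels > 0
        if inmask.sum() < 2:
            continue
        # need at least one adjacent in-mask pair for the GLCM
        from scipy import ndimage
        lab, nlab = ndimage.label(inmask, structure=np.ones((3, 3, 3)))
        sizes = np.bincount(lab.ravel())[1:]
        if (sizes >= 2).any():
            return droi_from_levels(levels, ng=int(levels.max()))


def cohort_from_feature_arrays(feature_values: dict, clinical: pd.DataFrame) -> CohortTable:
    """Build a CohortTable from {feature: (pre array, post array)}."""
    pids = list(clinical.index)
    rows = []
    for feat, (pre, post) in feature_values.items():
        for pid, v in zip(pids, pre):
            rows.append({"patient_id": pid, "timepoint": "pre", "feature": feat, "value": v})
        for pid, v in zip(pids, post):
            rows.append({"patient_id": pid, "timepoint": "post", "feature": feat, "value": v})
    return CohortTable(clinical=clinical.copy(), features=pd.DataFrame(rows))


def minimal_clinical(n, rng=None, scores=None):
    rng = rng or np.random.default_rng(0)
    scores = scores if scores is not None else rng.integers(2, 6, size=n)
    return pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "rvisu_obs1": scores, "rvisu_obs2": scores, "rvisu_obs3": scores,
        "followup_months": rng.uniform(1, 28, size=n).round(2),
        "ltp_event": rng.integers(0, 2, size=n),
    }).set_index("patient_id")


@pytest.fixture(scope="session")
def tiny_cohort():
    """One shared tiny synthetic cohort with extracted features."""
    from deltarad.synthetic import extract_cohort_features, make_cohort, preset

    cfg = preset("tiny", seed=7)
    synth = make_cohort(cfg)
    feats = extract_cohort_features(synth)
    cohort = CohortTable(clinical=synth.clinical, features=feats)
    return synth, cohort
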