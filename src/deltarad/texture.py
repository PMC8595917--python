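"""3D texture features of a masked CT volume.

The features quantify intratumor density heterogeneity at three scales:

* **global** — first-order statistics of the raw HU histogram inside the
  ROI (mean, median, 10th percentile, robust mean absolute deviation,
  kurtosis, variance);
* **regional** — gray-level size-zone (GLSZM) and run-length (GLRLM)
  statistics of the discretized ROI;
* **local** — gray-level co-occurrence (GLCM) statistics, plus the
  neighborhood gray-tone difference matrix (NGTDM) as an optional extra.

All matrix features are fully 3D: co-occurrences and runs are aggregated
over the 13 unique 3D direction offsets into a single merged matrix
before any feature is computed, and zones use 26-connectivity.  Gray
levels are 1-based (level 0 marks out-of-mask voxels everywhere).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .image_io import MaskedVolume

__all__ = [
    "DiscretizedROI",
    "GLCM",
    "GLRLM",
    "GLSZM",
    "NGTDM",
    "FeatureVector",
    "DIRECTIONS_13",
    "GLOBAL_FEATURES",
    "REGIONAL_FEATURES",
    "LOCAL_FEATURES",
    "CORE_FEATURES",
    "NGTDM_FEATURES",
    "discretize",
    "global_features",
    "glcm_compute",
    "glcm_features",
    "glrlm_compute",
    "glrlm_features",
    "glszm_compute",
    "glszm_features",
    "ngtdm_compute",
    "ngtdm_features",
    "extract_all",
]

#: The 13 unique 3D direction offsets (one per +/- pair of the 26
#: neighbors), in (dz, dy, dx) voxel steps.
DIRECTIONS_13 = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1),
    (1, 0, 1), (1, 0, -1),
    (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

GLOBAL_FEATURES = (
    "mean", "median", "percentile10",
    "robust_mean_absolute_deviation", "kurtosis", "variance",
)
REGIONAL_FEATURES = (
    "zone_percentage", "small_area_emphasis", "large_area_emphasis",
    "short_run_low_gray_level_emphasis", "long_run_low_gray_level_emphasis",
)
LOCAL_FEATURES = (
    "cluster_prominence", "maximum_probability", "cluster_tendency",
    "joint_energy", "contrast", "joint_entropy", "correlation", "sum_squares",
)
#: The 19 features of the default report.
CORE_FEATURES = GLOBAL_FEATURES + REGIONAL_FEATURES + LOCAL_FEATURES
NGTDM_FEATURES = ("coarseness", "busyness", "ngtdm_contrast")

_EPS = 1e-12


@dataclass
class DiscretizedROI:
    """Gray-level map of a ROI: ``levels`` is 0 outside the mask, 1..Ng inside."""

    levels: np.ndarray  # int array, full grid
    ng: int
    bin_edges: np.ndarray

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=np.int32)
        inside = self.levels > 0
        if not inside.any():
            raise ValueError("discretized ROI is empty")
        if self.levels[inside].max() > self.ng:
            raise ValueError("level exceeds Ng")

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def voxel_count(self) -> int:
        return int((self.levels > 0).sum())


@dataclass
class GLCM:
    p: np.ndarray  # Ng x Ng joint probabilities
    distance: int
    directions: tuple = DIRECTIONS_13


@dataclass
class GLRLM:
    r: np.ndarray  # Ng x Lmax run counts
    directions: tuple = DIRECTIONS_13

    @property
    def n_runs(self) -> float:
        return float(self.r.sum())


@dataclass
class GLSZM:
    s: np.ndarray  # Ng x Smax zone counts
    n_voxels: int

    @property
    def n_zones(self) -> float:
        return float(self.s.sum())


@dataclass
class NGTDM:
    s_i: np.ndarray  # per-level summed |level - neighborhood mean|
    n_i: np.ndarray  # per-level voxel counts (voxels with >=1 in-mask neighbor)


@dataclass
class FeatureVector:
    """Named feature values for one volume at one timepoint.

    ``flags`` records features that could not be computed and why; flagged
    features carry NaN in ``values`` (never a silent zero).
    """

    values: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name):
        return self.values[name]

    def get(self, name, default=np.nan):
        return self.values.get(name, default)

    def update(self, other: dict):
        self.values.update(other)

    def flag(self, name: str, reason: str):
        self.values[name] = np.nan
        self.flags[name] = reason

    def to_series(self):
        import pandas as pd

        return pd.Series(self.values)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize(
    mv: MaskedVolume,
    scheme: str = "fixed_bin_width",
    param: float = 25.0,
    range_low: Optional[float] = None,
) -> DiscretizedROI:
    """Map ROI intensities to integer gray levels 1..Ng.

    ``fixed_bin_width`` (default, width *param* HU): level =
    floor((x - low)/w) + 1, anchored at ``range_low`` (the resegmentation
    lower bound when set, else the masked minimum).  Anchoring at an
    absolute HU keeps pre and post scans on a common level scale, which
    the percent-change statistic requires.

    ``fixed_bin_count``: *param* equal-width bins spanning the observed
    masked min..max (errors on a constant ROI).
    """
    mask, vox = mv.analysis_mask_and_values()
    values = vox[mask]
    if values.size == 0:
        raise ValueError("empty ROI")
    levels = np.zeros(mask.shape, dtype=np.int32)
    if scheme == "fixed_bin_width":
        w = float(param)
        if w <= 0:
            raise ValueError("bin width must be positive")
        if range_low is None:
            if mv.resegment_range is not None and mv.resegment_mode == "remove":
                low = mv.resegment_range[0]
            else:
                low = float(values.min())
        else:
            low = float(range_low)
        lv = np.floor((values - low) / w).astype(np.int64) + 1
        lv = np.clip(lv, 1, None)
        ng = int(lv.max())
        edges = low + w * np.arange(ng + 1)
    elif scheme == "fixed_bin_count":
        ng = int(param)
        if ng < 1:
            raise ValueError("bin count must be >= 1")
        vmin, vmax = float(values.min()), float(values.max())
        if vmax == vmin:
            raise ValueError("zero intensity range: fixed_bin_count undefined on a constant ROI")
        w = (vmax - vmin) / ng
        lv = np.floor((values - vmin) / w).astype(np.int64) + 1
        lv = np.clip(lv, 1, ng)
        edges = vmin + w * np.arange(ng + 1)
    else:
        raise ValueError(f"unknown discretization scheme {scheme!r}")
    levels[mask] = lv
    return DiscretizedROI(levels=levels, ng=ng, bin_edges=np.asarray(edges))


# ---------------------------------------------------------------------------
# global (first-order) features — computed on raw HU, not on levels
# ---------------------------------------------------------------------------

def global_features(values: np.ndarray) -> FeatureVector:
    """First-order histogram statistics of the masked HU values.

    Variance is population-style (divide by N); kurtosis is the
    **non-excess** ratio m4/m2^2 (a Gaussian scores 3); the robust mean
    absolute deviation is the mean absolute deviation of the values
    restricted to the closed [P10, P90] percentile range, taken about the
    mean of that restricted set.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 voxels for global features")
    fv = FeatureVector()
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    p10, p90 = np.percentile(x, [10, 90])  # linear interpolation
    sub = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(sub - sub.mean()).mean()) if sub.size else 0.0
    fv.update({
        "mean": mean,
        "median": float(np.median(x)),
        "percentile10": float(p10),
        "robust_mean_absolute_deviation": rmad,
        "variance": m2,
    })
    if m2 > 0:
        m4 = float(((x - mean) ** 4).mean())
        fv.values["kurtosis"] = m4 / m2**2
    else:
        fv.flag("kurtosis", "zero variance")
    return fv


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _offset_slices(shape, off):
    """Slice pairs (src, dst) selecting voxels v and v+off inside the grid."""
    src, dst = [], []
    for n, d in zip(shape, off):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


def glcm_compute(
    d: DiscretizedROI,
    distance: int = 1,
    directions: Sequence = DIRECTIONS_13,
) -> GLCM:
    """Merged symmetric gray-level co-occurrence matrix.

    Counts ordered pairs (v, v+offset) and their reverses over all
    direction offsets scaled by *distance*; only pairs with both voxels
    in-mask contribute.  Normalized to sum to 1.
    """
    lv = d.levels
    ng = d.ng
    counts = np.zeros((ng, ng), dtype=np.float64)
    for off in directions:
        off_d = tuple(int(c) * int(distance) for c in off)
        src, dst = _offset_slices(lv.shape, off_d)
        a = lv[src].ravel()
        b = lv[dst].ravel()
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        np.add.at(counts, (a[ok] - 1, b[ok] - 1), 1.0)
    counts = counts + counts.T  # symmetric: count both orderings
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid co-occurring voxel pairs in the ROI")
    return GLCM(p=counts / total, distance=int(distance), directions=tuple(directions))


def glcm_features(g: GLCM) -> FeatureVector:
    """Local-scale texture statistics of a GLCM.

    With marginal mean mu = sum_i i*p_x(i) (identical marginals by
    symmetry) and sigma^2 = sum_squares; entropy is in bits with
    0 log 0 := 0.  A constant texture has sigma^2 = 0; its correlation is
    defined as 1 (perfectly predictable) and flagged.
    """
    p = g.p
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    fv = FeatureVector()
    sum_squares = float((p * (ii - mu) ** 2).sum())
    fv.update({
        "contrast": float((p * (ii - jj) ** 2).sum()),
        "cluster_tendency": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "cluster_prominence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "joint_energy": float((p**2).sum()),
        "joint_entropy": float(-(p[p > 0] * np.log2(p[p > 0])).sum()),
        "maximum_probability": float(p.max()),
        "sum_squares": sum_squares,
    })
    if sum_squares > 0:
        fv.values["correlation"] = float((p * (ii - mu) * (jj - mu)).sum()) / sum_squares
    else:
        fv.values["correlation"] = 1.0
        fv.flags["correlation"] = "degenerate: zero gray-level variance (set to 1 by convention)"
    return fv


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _direction_line_indices(shape: tuple, off: tuple) -> np.ndarray:
    """Flat voxel indices of all maximal lattice lines along *off*,
    concatenated with -1 separators.  Cached per (shape, direction)."""
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    pz, py, px = zz - off[0], yy - off[1], xx - off[2]
    is_start = (
        (pz < 0) | (pz >= nz) | (py < 0) | (py >= ny) | (px < 0) | (px >= nx)
    )
    starts = np.argwhere(is_start)
    chunks = []
    for z, y, x in starts:
        line = []
        while 0 <= z < nz and 0 <= y < ny and 0 <= x < nx:
            line.append((z * ny + y) * nx + x)
            z += off[0]; y += off[1]; x += off[2]
        line.append(-1)
        chunks.append(np.array(line, dtype=np.int64))
    return np.concatenate(chunks)


def _run_length_encode(seq: np.ndarray):
    """Values and lengths of maximal constant runs in a 1D sequence."""
    if seq.size == 0:
        return seq, seq
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [seq.size]))
    return seq[starts], ends - starts


def glrlm_compute(
    d: DiscretizedROI, directions: Sequence = DIRECTIONS_13
) -> GLRLM:
    """Merged gray-level run-length matrix over the given directions.

    A run is a maximal collinear sequence of in-mask voxels sharing one
    gray level; out-of-mask voxels break runs.
    """
    lv = d.levels
    flat = np.concatenate((lv.ravel(), [0]))  # index -1 -> level 0 separator
    lmax = max(lv.shape)
    r = np.zeros((d.ng, lmax), dtype=np.float64)
    for off in directions:
        idx = _direction_line_indices(lv.shape, tuple(off))
        seq = flat[idx]
        vals, lens = _run_length_encode(seq)
        ok = vals > 0
        if ok.any():
            np.add.at(r, (vals[ok] - 1, lens[ok] - 1), 1.0)
    return GLRLM(r=r, directions=tuple(directions))


def glrlm_features(m: GLRLM) -> FeatureVector:
    """Low-gray-level run emphases of a GLRLM.

    SRLGLE = (1/Nr) sum r(i,j) / (i^2 j^2);
    LRLGLE = (1/Nr) sum r(i,j) j^2 / i^2.
    """
    r = m.r
    nr = r.sum()
    if nr == 0:
        raise ValueError("empty run-length matrix")
    i = np.arange(1, r.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, r.shape[1] + 1, dtype=np.float64)[None, :]
    fv = FeatureVector()
    fv.update({
        "short_run_low_gray_level_emphasis": float((r / (i**2 * j**2)).sum() / nr),
        "long_run_low_gray_level_emphasis": float((r * j**2 / i**2).sum() / nr),
    })
    return fv


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_compute(d: DiscretizedROI) -> GLSZM:
    """Gray-level size-zone matrix: 26-connected equal-level zones."""
    lv = d.levels
    nv = d.voxel_count
    zone_counts = {}
    smax = 1
    for level in np.unique(lv[lv > 0]):
        lab, n_lab = ndimage.label(lv == level, structure=_STRUCT_26)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for size in sizes:
            zone_counts[(int(level), int(size))] = zone_counts.get((int(level), int(size)), 0) + 1
            smax = max(smax, int(size))
    s = np.zeros((d.ng, smax), dtype=np.float64)
    for (level, size), c in zone_counts.items():
        s[level - 1, size - 1] = c
    return GLSZM(s=s, n_voxels=nv)


def glszm_features(m: GLSZM) -> FeatureVector:
    """Zone percentage and small/large-area emphases of a GLSZM."""
    s = m.s
    nz = s.sum()
    if nz == 0:
        raise ValueError("empty size-zone matrix")
    j = np.arange(1, s.shape[1] + 1, dtype=np.float64)[None, :]
    fv = FeatureVector()
    fv.update({
        "zone_percentage": float(nz / m.n_voxels),
        "small_area_emphasis": float((s / j**2).sum() / nz),
        "large_area_emphasis": float((s * j**2).sum() / nz),
    })
    return fv


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

_KERNEL_26 = np.ones((3, 3, 3), dtype=np.float64)
_KERNEL_26[1, 1, 1] = 0.0


def ngtdm_compute(d: DiscretizedROI) -> NGTDM:
    """Neighborhood gray-tone difference aggregates.

    For each voxel with at least one in-mask 26-neighbor, the absolute
    difference between its level and the mean level of those neighbors is
    accumulated per level (s_i); n_i counts the contributing voxels.
    """
    lv = d.levels.astype(np.float64)
    inmask = d.levels > 0
    nb_sum = ndimage.correlate(lv * inmask, _KERNEL_26, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(inmask.astype(np.float64), _KERNEL_26, mode="constant", cval=0.0)
    valid = inmask & (nb_cnt > 0.5)
    if not valid.any():
        raise ValueError("no ROI voxel has an in-mask neighbor")
    diffs = np.abs(lv[valid] - nb_sum[valid] / nb_cnt[valid])
    levels = d.levels[valid]
    s_i = np.zeros(d.ng)
    n_i = np.zeros(d.ng)
    np.add.at(s_i, levels - 1, diffs)
    np.add.at(n_i, levels - 1, 1.0)
    return NGTDM(s_i=s_i, n_i=n_i)


def ngtdm_features(m: NGTDM) -> dict:
    """Coarseness, busyness and NGTDM contrast.

    coarseness = 1 / (eps + sum_i p_i s_i) with p_i = n_i / N and
    eps = 1e-12 guarding the all-uniform case; a single occupied level
    yields busyness = 0 and contrast = 0.
    """
    n = m.n_i.sum()
    p = m.n_i / n
    i = np.arange(1, len(p) + 1, dtype=np.float64)
    occupied = p > 0
    n_gp = int(occupied.sum())
    coarseness = 1.0 / (_EPS + float((p * m.s_i).sum()))
    if n_gp > 1:
        pi, pj = np.meshgrid(p[occupied], p[occupied], indexing="ij")
        ii, jj = np.meshgrid(i[occupied], i[occupied], indexing="ij")
        contrast = float((pi * pj * (ii - jj) ** 2).sum()) / (n_gp * (n_gp - 1))
        contrast *= float(m.s_i.sum()) / n
        denom = float(np.abs(ii * pi - jj * pj).sum())
        busyness = float((p * m.s_i).sum()) / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    return {"coarseness": coarseness, "busyness": busyness, "ngtdm_contrast": contrast}


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def extract_all(
    mv: MaskedVolume,
    scheme: str = "fixed_bin_width",
    param: float = 25.0,
    distance: int = 1,
    min_voxels: int = 64,
    include_ngtdm: bool = True,
) -> FeatureVector:
    """Discretize once and compute every feature block.

    Global features use the raw (resegmented) HU values; matrix features
    use the discretized levels.  Features a block cannot deliver are
    flagged-missing (NaN + reason), never silently zero.  Provenance
    records the discretization config, Ng and voxel count.
    """
    from .image_io import extract_masked_voxels

    values = extract_masked_voxels(mv, min_voxels=min_voxels)
    fv = global_features(values)

    d = discretize(mv, scheme=scheme, param=param)
    try:
        g = glcm_compute(d, distance=distance)
        gf = glcm_features(g)
        fv.values.update(gf.values)
        fv.flags.update(gf.flags)
    except ValueError as exc:
        for name in LOCAL_FEATURES:
            fv.flag(name, str(exc))
    try:
        fv.values.update(glrlm_features(glrlm_compute(d)).values)
    except ValueError as exc:
        for name in ("short_run_low_gray_level_emphasis", "long_run_low_gray_level_emphasis"):
            fv.flag(name, str(exc))
    try:
        fv.values.update(glszm_features(glszm_compute(d)).values)
    except ValueError as exc:
        for name in ("zone_percentage", "small_area_emphasis", "large_area_emphasis"):
            fv.flag(name, str(exc))
    if include_ngtdm:
        try:
            fv.values.update(ngtdm_features(ngtdm_compute(d)))
        except ValueError as exc:
            for name in NGTDM_FEATURES:
                fv.flag(name, str(exc))

    config = {"scheme": scheme, "param": param, "distance": distance, "min_voxels": min_voxels}
    fv.provenance = {
        "config": config,
        "config_hash": hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12],
        "ng": d.ng,
        "voxel_count": d.voxel_count,
    }
    return fv
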