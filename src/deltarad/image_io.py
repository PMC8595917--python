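"""Reading, writing and masking of CT volumes.

Conventions used throughout the package:

* voxel arrays are indexed ``(z, y, x)`` with 0-based indices;
* ``spacing`` is the per-axis voxel size in millimetres, in the same
  ``(z, y, x)`` order;
* physical coordinates are voxel-centre based:
  ``position = origin + index * spacing``.

Intensities are Hounsfield units (HU) everywhere.  NIfTI files written by
:func:`write_volume` store the array transposed to the ``(x, y, z)`` layout
nibabel expects, with a diagonal affine carrying the spacing; reading
reverses the transform, so write/read round-trips are exact up to float
precision.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "ROIMask",
    "MaskedVolume",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "extract_masked_voxels",
    "roi_geometry",
    "resample_isotropic",
]

#: Default HU analysis range for resegmentation ("remove" mode): voxels
#: outside it (air artefacts, bone, metal) are dropped from the ROI.
DEFAULT_RESEGMENT_RANGE = (-1000.0, 400.0)


@dataclass
class ImageVolume:
    """A 3D intensity volume in Hounsfield units.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensities in HU.
    spacing : tuple of float
        Voxel size in mm per axis, ``(z, y, x)`` order; strictly positive.
    origin : tuple of float
        Physical position (mm) of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(
                f"volume must be 3D with each axis >= 1, got shape {self.voxels.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ROIMask:
    """A binary region-of-interest congruent with its :class:`ImageVolume`."""

    mask: np.ndarray
    label: str = "lesion"

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError("empty ROI: mask has no true voxels")

    @property
    def shape(self):
        return self.mask.shape

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class MaskedVolume:
    """An :class:`ImageVolume` restricted to an :class:`ROIMask`.

    ``resegment_range`` optionally restricts the analyzed HU range before
    any feature computation.  In ``"remove"`` mode (the default) voxels
    outside the range are dropped from the ROI; in ``"clip"`` mode their
    intensities are clamped to the range bounds.
    """

    image: ImageVolume
    roi: ROIMask
    resegment_range: Optional[tuple] = None
    resegment_mode: str = "remove"

    def __post_init__(self):
        if self.image.shape != self.roi.shape:
            raise ValueError(
                f"mask shape {self.roi.shape} does not match image shape {self.image.shape}"
            )
        if self.resegment_range is not None:
            lo, hi = self.resegment_range
            if not lo < hi:
                raise ValueError("resegment_range must be (low, high) with low < high")
            self.resegment_range = (float(lo), float(hi))
        if self.resegment_mode not in ("remove", "clip"):
            raise ValueError(f"unknown resegment_mode {self.resegment_mode!r}")

    def analysis_mask_and_values(self):
        """Effective boolean mask and full-grid HU values after resegmentation.

        Returns ``(mask, voxels)`` where ``mask`` may be smaller than the
        stored ROI in "remove" mode and ``voxels`` may be clamped in
        "clip" mode.
        """
        mask = self.roi.mask
        vox = self.image.voxels
        if self.resegment_range is not None:
            lo, hi = self.resegment_range
            if self.resegment_mode == "remove":
                mask = mask & (vox >= lo) & (vox <= hi)
            else:
                vox = np.clip(vox, lo, hi)
        return mask, vox


def _load_nifti(path: Path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    # nibabel layout is (x, y, z); package convention is (z, y, x)
    voxels = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return ImageVolume(voxels=voxels, spacing=spacing, origin=origin)


def _load_dicom_series(path: Path) -> ImageVolume:
    import pydicom

    files = sorted(
        p for p in Path(path).iterdir()
        if p.is_file() and not p.name.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if not hasattr(ds, "PixelData"):
            continue
        slices.append((f, ds))
    if not slices:
        raise ValueError(f"{path}: no readable DICOM slices found")

    def zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "SliceLocation", getattr(ds, "InstanceNumber", 0)))

    slices.sort(key=lambda fd: zpos(fd[1]))
    zs = np.array([zpos(ds) for _, ds in slices])
    if len(slices) > 1:
        gaps = np.diff(zs)
        med = np.median(gaps)
        if med <= 0:
            raise ValueError(f"{path}: slices do not have ascending positions")
        bad = np.flatnonzero(np.abs(gaps - med) > 0.01 * abs(med))
        if bad.size:
            names = ", ".join(slices[i + 1][0].name for i in bad[:5])
            raise ValueError(
                f"{path}: inconsistent slice spacing (>1% variation) at slices: {names}"
            )
        dz = float(med)
    else:
        dz = float(getattr(slices[0][1], "SliceThickness", 1.0))

    ref = slices[0][1]
    ps = getattr(ref, "PixelSpacing", [1.0, 1.0])
    arrs = []
    for _, ds in slices:
        a = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        arrs.append(a * slope + inter)
    voxels = np.stack(arrs, axis=0)
    origin = (float(zs[0]), 0.0, 0.0)
    if hasattr(ref, "ImagePositionPatient"):
        ipp = ref.ImagePositionPatient
        origin = (float(zs[0]), float(ipp[1]), float(ipp[0]))
    return ImageVolume(voxels=voxels, spacing=(dz, float(ps[0]), float(ps[1])), origin=origin)


def read_volume(path, format: Optional[str] = None) -> ImageVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path : str or Path
    format : {"nifti", "dicom_series", None}
        Inferred from the path when ``None`` (directory -> DICOM series).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def write_volume(volume: ImageVolume, path) -> None:
    """Write an :class:`ImageVolume` as single-file NIfTI (.nii/.nii.gz)."""
    data = np.transpose(volume.voxels, (2, 1, 0))
    affine = np.diag([volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
    affine[:3, 3] = list(volume.origin)[::-1]
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((volume.spacing[2], volume.spacing[1], volume.spacing[0]))
    nib.save(img, str(path))


def read_mask(path, reference: ImageVolume, label: str = "lesion") -> ROIMask:
    """Read a stored label image as a boolean ROI congruent with *reference*."""
    vol = read_volume(path)
    if vol.shape != reference.shape:
        raise ValueError(
            f"mask shape {vol.shape} does not match reference shape {reference.shape}"
        )
    mask = vol.voxels != 0
    if not mask.any():
        raise ValueError(f"{path}: empty ROI (all-zero label image)")
    return ROIMask(mask=mask, label=label)


def write_mask(roi: ROIMask, reference: ImageVolume, path) -> None:
    vol = ImageVolume(
        voxels=roi.mask.astype(np.float64),
        spacing=reference.spacing,
        origin=reference.origin,
    )
    write_volume(vol, path)


def extract_masked_voxels(mv: MaskedVolume, min_voxels: int = 1) -> np.ndarray:
    """Return the HU values of the analyzed ROI voxels in z-major raster order.

    Resegmentation (per ``mv.resegment_range`` / ``mv.resegment_mode``) is
    applied first.  Raises ``ValueError`` if fewer than *min_voxels* remain.
    """
    mask, vox = mv.analysis_mask_and_values()
    values = vox[mask]  # boolean indexing of a C-ordered array is raster order
    if values.size < max(min_voxels, 1):
        raise ValueError(
            f"ROI has {values.size} analyzable voxels, fewer than the minimum {min_voxels}"
        )
    return values


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (N, 3) of masked voxels with at least one exposed face."""
    padded = np.pad(mask, 1)
    core = padded[1:-1, 1:-1, 1:-1]
    n_face = np.zeros(mask.shape, dtype=np.int8)
    for ax in range(3):
        n_face += np.roll(padded, 1, axis=ax)[1:-1, 1:-1, 1:-1].astype(np.int8)
        n_face += np.roll(padded, -1, axis=ax)[1:-1, 1:-1, 1:-1].astype(np.int8)
    surf = core & (n_face < 6)
    return np.argwhere(surf)


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) == 1:
        return 0.0
    if len(points) > 400:
        from scipy.spatial import ConvexHull, QhullError

        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) sets: brute force below
    from scipy.spatial.distance import pdist

    return float(pdist(points).max())


def _surface_area_mm2(mask: np.ndarray, spacing) -> float:
    """ROI surface area from a marching-cubes mesh.

    Face counting overestimates the area of smooth digital shapes (the
    staircase artifact would make a ball look rougher than a cube), so
    the mesh area is used for sphericity; :func:`_face_area_mm2` keeps
    the raw face count available.
    """
    from skimage import measure

    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    return float(measure.mesh_surface_area(verts, faces))


def _face_area_mm2(mask: np.ndarray, spacing) -> float:
    """Total exposed-face area by face counting."""
    dz, dy, dx = spacing
    face_area = {0: dy * dx, 1: dz * dx, 2: dz * dy}
    padded = np.pad(mask, 1)
    core = padded[1:-1, 1:-1, 1:-1]
    area = 0.0
    for ax in range(3):
        for shift in (1, -1):
            nb = np.roll(padded, shift, axis=ax)[1:-1, 1:-1, 1:-1]
            area += float((core & ~nb).sum()) * face_area[ax]
    return area


def roi_geometry(mv: MaskedVolume) -> dict:
    """Volume, maximum 3D diameter and shape descriptors of the ROI.

    Returns
    -------
    dict with keys ``volume_cm3``, ``max_diameter_cm``, ``sphericity``,
    ``elongation``, ``flatness``.

    Notes
    -----
    * volume = voxel count x voxel volume;
    * max diameter = largest pairwise distance between surface-voxel
      centres (3D Feret diameter);
    * sphericity = (36 pi V^2)^(1/3) / A with A the face-counted surface
      area — 1 for a perfect sphere, smaller for rougher shapes;
    * elongation = sqrt(l2/l1) and flatness = sqrt(l3/l1) from the ordered
      eigenvalues l1 >= l2 >= l3 of the voxel-centre covariance.
    """
    mask, _ = mv.analysis_mask_and_values()
    if not mask.any():
        raise ValueError("empty ROI after resegmentation")
    spacing = np.array(mv.image.spacing)
    n = int(mask.sum())
    volume_mm3 = n * float(np.prod(spacing))

    surf_idx = _surface_voxels(mask)
    pts = surf_idx * spacing
    max_diam_mm = _max_pairwise_distance(pts)

    area_mm2 = _surface_area_mm2(mask, spacing)
    sphericity = (36.0 * np.pi * volume_mm3**2) ** (1.0 / 3.0) / area_mm2

    coords = np.argwhere(mask) * spacing
    if n > 1:
        cov = np.cov(coords, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
        flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0
    else:
        elongation = flatness = 1.0

    return {
        "volume_cm3": volume_mm3 / 1000.0,
        "max_diameter_cm": max_diam_mm / 10.0,
        "sphericity": float(sphericity),
        "elongation": elongation,
        "flatness": flatness,
    }


def resample_isotropic(mv: MaskedVolume, new_spacing_mm: float = 1.0) -> MaskedVolume:
    """Resample to isotropic spacing (linear for image, nearest for mask).

    Off by default in the pipeline: paired same-session scans share
    acquisition geometry, so resampling only adds interpolation noise.
    """
    from scipy.ndimage import zoom

    factors = np.array(mv.image.spacing) / new_spacing_mm
    img = zoom(mv.image.voxels, factors, order=1)
    msk = zoom(mv.roi.mask.astype(np.uint8), factors, order=0).astype(bool)
    if not msk.any():
        raise ValueError("ROI vanished during resampling")
    return MaskedVolume(
        image=ImageVolume(img, spacing=(new_spacing_mm,) * 3, origin=mv.image.origin),
        roi=ROIMask(msk, label=mv.roi.label),
        resegment_range=mv.resegment_range,
        resegment_mode=mv.resegment_mode,
    )
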