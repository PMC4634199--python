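"""Volumetric image infrastructure.

A light container (:class:`VolumetricImage`) around a numpy grid plus a
voxel-index -> mm affine, with the three operations every later stage needs:
spatial Gaussian smoothing, mean time-series extraction from a sphere at mm
coordinates, and a simplified first-level block-design GLM that produces a
contrast image.

Conventions
-----------
* Coordinates are mm in the image's RAS space; voxel indices are 0-based.
* 4D images store time on the last axis.
* Smoothing kernels are specified as full width at half maximum (FWHM) in mm
  and converted per axis to voxel units through the affine column norms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import nibabel as nib
from scipy import ndimage, stats

from .errors import (
    CoordinateError,
    CollinearityError,
    DesignError,
    EmptyRegionError,
    GeometryError,
    UnsupportedGeometryError,
)

__all__ = [
    "VolumetricImage",
    "TaskDesign",
    "default_affine",
    "smooth",
    "extract_sphere_timeseries",
    "double_gamma_hrf",
    "build_design_matrix",
    "first_level_glm",
    "FWHM_TO_SIGMA",
]

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def default_affine(shape: Sequence[int], voxel_size_mm: float) -> np.ndarray:
    """RAS affine with isotropic voxels and the volume centred on mm (0,0,0)."""
    shape = np.asarray(shape[:3], dtype=float)
    aff = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    aff[:3, 3] = -voxel_size_mm * (shape - 1) / 2.0
    return aff


@dataclass
class VolumetricImage:
    """3D or 4D intensity grid with a voxel-to-mm affine and optional mask.

    Parameters
    ----------
    data:
        3D spatial grid or 4D grid with time on the last axis.
    affine:
        4x4 invertible matrix mapping 0-based voxel indices to mm.
    mask:
        Optional binary 3D grid matching the spatial shape.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise GeometryError(f"expected 3D or 4D data, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is not invertible")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.spatial_shape:
                raise GeometryError(
                    f"mask shape {self.mask.shape} != spatial shape {self.spatial_shape}"
                )

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]

    @property
    def is_4d(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3] if self.is_4d else 1

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    def nearest_voxel(self, xyz_mm: Sequence[float]) -> tuple[int, int, int]:
        """Index of the voxel whose centre is nearest to an mm coordinate."""
        ijk = np.round(self.mm_to_voxel(xyz_mm)[0]).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.asarray(self.spatial_shape)):
            raise CoordinateError(
                f"mm coordinate {tuple(xyz_mm)} maps to voxel {tuple(ijk)}, "
                f"outside grid {self.spatial_shape}"
            )
        return tuple(int(v) for v in ijk)

    def same_geometry(self, other: "VolumetricImage", atol: float = 1e-6) -> bool:
        return self.spatial_shape == other.spatial_shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VolumetricImage":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata()), np.asarray(img.affine))


def _orthogonal_voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel sizes; reject sheared/oblique affines.

    Smoothing applies a separable kernel along array axes, which is only a
    Gaussian in mm space when the axes are mutually orthogonal.
    """
    A = affine[:3, :3]
    gram = A.T @ A
    off = gram - np.diag(np.diag(gram))
    if np.max(np.abs(off)) > 1e-6 * np.max(np.abs(np.diag(gram))):
        raise UnsupportedGeometryError("affine has non-orthogonal (sheared) axes")
    return np.sqrt(np.diag(gram))


def smooth(image: VolumetricImage, fwhm_mm: float) -> VolumetricImage:
    """Spatial Gaussian smoothing with an FWHM given in mm.

    4D images are smoothed frame-wise in space only. ``fwhm_mm = 0`` is the
    identity. The kernel is the sampled Gaussian normalized to unit sum, so a
    constant image is exactly unchanged and total intensity of a nonnegative
    image is conserved away from the boundary.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return replace(image, data=image.data.copy())
    vox = _orthogonal_voxel_sizes(image.affine)
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / vox
    if image.is_4d:
        sigma = tuple(sigma_vox) + (0.0,)
    else:
        sigma = tuple(sigma_vox)
    out = ndimage.gaussian_filter(np.asarray(image.data, dtype=float), sigma=sigma)
    return replace(image, data=out)


def sphere_voxel_mask(
    image: VolumetricImage, center_mm: Sequence[float], radius_mm: float
) -> np.ndarray:
    """Boolean 3D mask of voxels whose centres lie within ``radius_mm`` of a point."""
    shape = image.spatial_shape
    grid = np.indices(shape).reshape(3, -1).T.astype(float)
    mm = image.voxel_to_mm(grid)
    dist = np.linalg.norm(mm - np.asarray(center_mm, dtype=float), axis=1)
    mask = (dist <= radius_mm).reshape(shape)
    return mask


def extract_sphere_timeseries(
    image4d: VolumetricImage,
    center_mm: Sequence[float],
    radius_mm: float,
) -> tuple[np.ndarray, int]:
    """Mean time series over a sphere of voxel centres around ``center_mm``.

    Sphere membership is by voxel-centre Euclidean distance in mm (no partial
    volumes). Returns ``(series, n_voxels)``; a 3D input yields a length-1
    array holding the spatial mean.
    """
    lo = image4d.voxel_to_mm([0, 0, 0])[0]
    hi = image4d.voxel_to_mm(np.asarray(image4d.spatial_shape) - 1)[0]
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    c = np.asarray(center_mm, dtype=float)
    if np.any(c < lo - radius_mm) or np.any(c > hi + radius_mm):
        raise CoordinateError(f"sphere centre {tuple(c)} outside field of view")
    mask = sphere_voxel_mask(image4d, center_mm, radius_mm)
    n = int(mask.sum())
    if n == 0:
        raise EmptyRegionError(
            f"no voxel centre within {radius_mm} mm of {tuple(center_mm)}"
        )
    if image4d.is_4d:
        series = image4d.data[mask, :].mean(axis=0)
    else:
        series = np.atleast_1d(image4d.data[mask].mean())
    return series, n


# ---------------------------------------------------------------------------
# First-level task GLM
# ---------------------------------------------------------------------------


@dataclass
class TaskDesign:
    """Block design for a first-level GLM.

    Onsets/durations are seconds relative to the first *retained* volume
    (i.e. after any dummy scans have been discarded). ``motion`` must have
    exactly six columns; ``nuisance`` holds extra labelled regressors such as
    an instruction screen or wrong-condition blocks.
    """

    onsets_s: Sequence[float]
    durations_s: Sequence[float]
    conditions: Sequence[str]
    tr_s: float
    n_volumes: int
    motion: np.ndarray | None = None
    nuisance: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        self.conditions = list(self.conditions)
        if not (len(self.onsets_s) == len(self.durations_s) == len(self.conditions)):
            raise DesignError("onsets, durations and conditions must align")
        if self.tr_s <= 0:
            raise DesignError("tr_s must be positive")
        scan_end = self.tr_s * self.n_volumes
        if np.any(self.onsets_s < 0) or np.any(self.onsets_s + self.durations_s > scan_end):
            raise DesignError("block onsets/durations fall outside the scan")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.n_volumes, 6):
                raise DesignError(
                    f"motion must be (n_volumes, 6), got {self.motion.shape}"
                )
        for name, col in self.nuisance.items():
            col = np.asarray(col, dtype=float)
            if col.shape != (self.n_volumes,):
                raise DesignError(f"nuisance column {name!r} has wrong length")
            self.nuisance[name] = col

    @property
    def condition_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen


def double_gamma_hrf(t_s: np.ndarray, peak_s: float = 6.0,
                     undershoot_s: float = 16.0, ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak normalized to 1.

    The SPM-style convention: a gamma density peaking at ``peak_s`` minus a
    ``ratio``-scaled gamma density peaking at ``undershoot_s`` (unit scale).
    """
    t = np.asarray(t_s, dtype=float)
    h = stats.gamma.pdf(t, peak_s) - ratio * stats.gamma.pdf(t, undershoot_s)
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def _convolved_regressor(onsets, durations, tr_s, n_volumes, dt=0.1) -> np.ndarray:
    """Boxcar convolved with the canonical HRF, sampled at frame times."""
    duration_total = tr_s * n_volumes
    n_fine = int(np.ceil(duration_total / dt)) + 1
    fine_t = np.arange(n_fine) * dt
    box = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        box[(fine_t >= onset) & (fine_t < onset + dur)] = 1.0
    hrf = double_gamma_hrf(np.arange(0, 32.0, dt))
    conv = np.convolve(box, hrf)[:n_fine] * dt
    frame_idx = np.round(np.arange(n_volumes) * tr_s / dt).astype(int)
    return conv[frame_idx]


def build_design_matrix(design: TaskDesign) -> tuple[np.ndarray, list[str]]:
    """Design matrix: HRF-convolved condition boxcars, nuisance, motion, intercept."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cond in design.condition_names:
        sel = [i for i, c in enumerate(design.conditions) if c == cond]
        reg = _convolved_regressor(
            design.onsets_s[sel], design.durations_s[sel], design.tr_s, design.n_volumes
        )
        cols.append(reg)
        names.append(cond)
    for name, col in design.nuisance.items():
        cols.append(col)
        names.append(name)
    if design.motion is not None:
        for j in range(6):
            cols.append(design.motion[:, j])
            names.append(f"motion{j + 1}")
    cols.append(np.ones(design.n_volumes))
    names.append("intercept")
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * diag.max()
    bad = [names[j] for j in range(len(names)) if diag[j] <= tol]
    if bad:
        raise CollinearityError(bad, f"rank-deficient design; collinear columns: {bad}")


def first_level_glm(
    image4d: VolumetricImage,
    design: TaskDesign,
    contrast_weights: dict[str, float],
    drop_initial: int = 4,
) -> VolumetricImage:
    """Per-voxel OLS block-design GLM returning a contrast image.

    The first ``drop_initial`` frames of the series are discarded before
    fitting (dummy scans acquired before steady state); ``design.n_volumes``
    must equal the retained count and its onsets are relative to the first
    retained frame. ``contrast_weights`` maps condition names to weights,
    e.g. ``{"2back": 1, "1back": -1}``; unnamed columns get weight 0.
    """
    if not image4d.is_4d:
        raise GeometryError("first_level_glm needs a 4D image")
    data = image4d.data[..., drop_initial:]
    if data.shape[-1] != design.n_volumes:
        raise DesignError(
            f"design has {design.n_volumes} volumes but {data.shape[-1]} frames "
            f"remain after discarding the first {drop_initial}"
        )
    X, names = build_design_matrix(design)
    _check_full_rank(X, names)
    unknown = set(contrast_weights) - set(names)
    if unknown:
        raise DesignError(f"contrast names not in design: {sorted(unknown)}")
    w = np.array([contrast_weights.get(name, 0.0) for name in names])

    Y = data.reshape(-1, design.n_volumes).T  # (time, voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    cmap = (w @ beta).reshape(image4d.spatial_shape)
    return VolumetricImage(cmap, image4d.affine, mask=image4d.mask)
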