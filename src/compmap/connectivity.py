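"""Seed-based resting-state functional connectivity.

Per subject: extract the mean series of a small sphere at the seed
coordinate, remove nuisance signals (white matter, CSF, six motion traces)
from seed and voxel series, and map the Fisher-z transformed partial
correlation of every voxel with the seed. Across subjects: a one-tailed
one-sample t-test of the z maps, family-wise error control (Bonferroni by
default, sign-flip max-statistic permutation optionally), 26-connected
cluster extraction, and per-subject cluster-mean features — the scalar f
values that enter the compensation model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import (
    DegenerateNuisanceError,
    EmptyRegionError,
    GeometryError,
)
from .images import VolumetricImage, extract_sphere_timeseries

__all__ = [
    "NuisanceSet",
    "Cluster",
    "ClusterSet",
    "Z_CEILING",
    "seed_correlation_map",
    "group_onesample_t",
    "threshold_fwe",
    "extract_cluster_means",
]

#: Correlations are clipped to +/-(1 - 1e-7) before the Fisher transform, so
#: |z| never exceeds atanh(1 - 1e-7) ~ 8.38 (self-correlation would otherwise
#: map to infinity).
Z_CEILING = float(np.arctanh(1.0 - 1e-7))

#: Cap for t statistics at voxels with zero across-subject variance.
T_CEILING = 1e6


@dataclass
class NuisanceSet:
    """White-matter, CSF and six motion nuisance series of equal length."""

    wm: np.ndarray
    csf: np.ndarray
    motion: np.ndarray  # (n_volumes, 6)

    def __post_init__(self) -> None:
        self.wm = np.asarray(self.wm, dtype=float).ravel()
        self.csf = np.asarray(self.csf, dtype=float).ravel()
        self.motion = np.asarray(self.motion, dtype=float)
        T = self.wm.shape[0]
        if self.csf.shape[0] != T or self.motion.shape != (T, 6):
            raise ValueError(
                f"nuisance lengths disagree: wm {self.wm.shape}, "
                f"csf {self.csf.shape}, motion {self.motion.shape}"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NuisanceSet":
        motion = frame[[f"motion{j}" for j in range(1, 7)]].to_numpy()
        return cls(wm=frame["wm"].to_numpy(), csf=frame["csf"].to_numpy(), motion=motion)

    @property
    def n_volumes(self) -> int:
        return self.wm.shape[0]

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.wm, self.csf, self.motion])


def _residualize(Y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of the columns of Y after regression on C (with intercept).

    Uses the orthogonal projector from a thin QR of the design — one matrix
    product per side, which matters when Y holds every voxel of a volume.
    """
    X = np.column_stack([np.ones(C.shape[0]), C]) if C.size else np.ones((Y.shape[0], 1))
    Q, _ = np.linalg.qr(X)
    return Y - Q @ (Q.T @ Y)


def seed_correlation_map(
    image4d: VolumetricImage,
    seed_center_mm: Sequence[float],
    nuisance: NuisanceSet | None = None,
    radius_mm: float = 4.0,
) -> VolumetricImage:
    """Fisher-z map of the partial correlation of every voxel with the seed.

    The seed series is the mean over a ``radius_mm`` sphere of voxel centres;
    seed and voxel series are residualized against the nuisance regressors
    (plus an intercept) and correlated. Zero-variance voxels map to z = 0;
    |z| is capped at :data:`Z_CEILING`.
    """
    if not image4d.is_4d:
        raise GeometryError("seed_correlation_map needs a 4D image")
    T = image4d.n_volumes
    if T < 20:
        raise ValueError(f"need >= 20 retained volumes, got {T}")
    seed, _ = extract_sphere_timeseries(image4d, seed_center_mm, radius_mm)
    if nuisance is not None:
        if nuisance.n_volumes != T:
            raise ValueError("nuisance length does not match the series")
        C = nuisance.as_matrix()
        seed_res = _residualize(seed[:, None], C)[:, 0]
        norm_seed = np.linalg.norm(seed - seed.mean())
        if norm_seed == 0 or np.linalg.norm(seed_res) / max(norm_seed, 1e-300) < np.sqrt(1 - 0.999**2):
            raise DegenerateNuisanceError(
                "nuisance regressors are collinear with the seed series (|r| > 0.999)"
            )
    else:
        C = np.empty((T, 0))
        seed_res = seed - seed.mean()

    Y = image4d.data.reshape(-1, T).T  # (time, voxels)
    Y_res = _residualize(Y, C)
    seed_c = seed_res - seed_res.mean()
    Y_c = Y_res - Y_res.mean(axis=0)
    norms_res = np.linalg.norm(Y_c, axis=0)
    denom = np.linalg.norm(seed_c) * norms_res
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (seed_c @ Y_c) / denom
    # voxels fully explained by the nuisance (or constant) carry no signal
    norms_raw = np.linalg.norm(Y - Y.mean(axis=0), axis=0)
    degenerate = (denom <= 0) | (norms_res <= 1e-8 * np.maximum(norms_raw, 1e-300))
    r = np.where(degenerate, 0.0, r)
    z = np.arctanh(np.clip(r, -(1 - 1e-7), 1 - 1e-7))
    return VolumetricImage(z.reshape(image4d.spatial_shape), image4d.affine,
                           mask=image4d.mask)


def group_onesample_t(
    maps: Sequence[VolumetricImage],
    mask: np.ndarray | None = None,
) -> tuple[VolumetricImage, VolumetricImage]:
    """Voxelwise one-tailed (positive) one-sample t-test across subjects.

    Returns (t map, one-tailed p map with df = n - 1). Outside the mask both
    are 0 and 1 respectively. Voxels with zero across-subject variance get
    t = +/-T_CEILING (sign of the mean) and the corresponding limit p.
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 maps")
    ref = maps[0]
    for m in maps[1:]:
        if not ref.same_geometry(m):
            raise GeometryError("maps do not share shape/affine")
    data = np.stack([m.data for m in maps], axis=-1)
    n = data.shape[-1]
    mean = data.mean(axis=-1)
    sd = data.std(axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t = np.where(zero_var, np.sign(mean) * T_CEILING, t)
    p = stats.t.sf(t, df=n - 1)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != ref.spatial_shape:
            raise GeometryError("mask shape mismatch")
        t = np.where(mask, t, 0.0)
        p = np.where(mask, p, 1.0)
    return (
        VolumetricImage(t, ref.affine, mask=mask),
        VolumetricImage(p, ref.affine, mask=mask),
    )


@dataclass(frozen=True)
class Cluster:
    label: int
    peak_mm: tuple[float, float, float]
    size: int


@dataclass
class ClusterSet:
    """Disjoint suprathreshold clusters from a thresholded group map."""

    labels: VolumetricImage  # integer label image, 0 = background
    clusters: list[Cluster]

    def __len__(self) -> int:
        return len(self.clusters)

    def contains_mm(self, xyz_mm: Sequence[float]) -> int | None:
        """Label of the cluster containing an mm coordinate, else None."""
        ijk = self.labels.nearest_voxel(xyz_mm)
        lab = int(self.labels.data[ijk])
        return lab if lab > 0 else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"label": c.label, "peak_x_mm": c.peak_mm[0], "peak_y_mm": c.peak_mm[1],
                 "peak_z_mm": c.peak_mm[2], "size": c.size}
                for c in self.clusters
            ]
        )


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _label_clusters(sig: np.ndarray, tmap: VolumetricImage,
                    min_cluster_size: int) -> ClusterSet:
    labels, n_lab = ndimage.label(sig, structure=_CONN26)
    clusters = []
    keep = np.zeros_like(labels)
    new_label = 0
    for lab in range(1, n_lab + 1):
        voxels = labels == lab
        size = int(voxels.sum())
        if size < min_cluster_size:
            continue
        new_label += 1
        keep[voxels] = new_label
        masked_t = np.where(voxels, tmap.data, -np.inf)
        peak_ijk = np.unravel_index(np.argmax(masked_t), masked_t.shape)
        peak_mm = tuple(float(v) for v in tmap.voxel_to_mm(np.asarray(peak_ijk))[0])
        clusters.append(Cluster(label=new_label, peak_mm=peak_mm, size=size))
    return ClusterSet(VolumetricImage(keep, tmap.affine), clusters)


def threshold_fwe(
    tmap: VolumetricImage,
    pmap: VolumetricImage,
    alpha: float = 0.05,
    method: str = "bonferroni",
    mask: np.ndarray | None = None,
    maps: Sequence[VolumetricImage] | None = None,
    n_permutations: int = 1000,
    min_cluster_size: int = 1,
    rng: np.random.Generator | None = None,
) -> ClusterSet:
    """Family-wise-error thresholding of a one-tailed group t map.

    ``method="bonferroni"`` keeps voxels with p <= alpha / m over the m
    in-mask voxels (deterministic default). ``method="permutation"`` uses the
    sign-flip maximum-statistic null distribution (requires the per-subject
    ``maps``). ``method="none"`` applies the uncorrected threshold p <= alpha.
    Surviving voxels are grouped by 26-connectivity.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if mask is None:
        mask = tmap.mask if tmap.mask is not None else np.ones(tmap.spatial_shape, bool)
    mask = np.asarray(mask, dtype=bool)
    m = int(mask.sum())
    if m < 1:
        raise EmptyRegionError("mask selects no voxels")

    if method == "bonferroni":
        sig = mask & (pmap.data <= alpha / m)
    elif method == "none":
        sig = mask & (pmap.data <= alpha)
    elif method == "permutation":
        if maps is None:
            raise ValueError("permutation FWE needs the per-subject maps")
        rng = rng or np.random.default_rng(0)
        data = np.stack([mp.data[mask] for mp in maps], axis=-1)
        n = data.shape[-1]
        max_t = np.empty(n_permutations)
        for b in range(n_permutations):
            signs = rng.choice([-1.0, 1.0], size=n)
            flipped = data * signs
            mu = flipped.mean(axis=-1)
            sd = flipped.std(axis=-1, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                tb = mu / (sd / np.sqrt(n))
            tb = np.where(sd == 0, np.sign(mu) * T_CEILING, tb)
            max_t[b] = tb.max()
        thr = np.quantile(max_t, 1 - alpha)
        sig = np.zeros(tmap.spatial_shape, bool)
        sig[mask] = tmap.data[mask] > thr
    else:
        raise ValueError(f"unknown FWE method {method!r}")
    return _label_clusters(sig, tmap, min_cluster_size)


def extract_cluster_means(
    cluster_set: ClusterSet,
    maps: Sequence[VolumetricImage],
    subject_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-subject mean map value over each cluster's voxels.

    Returns a DataFrame (subjects x clusters, columns ``cluster_<label>``) —
    the scalar fMRI features f entering the compensation model.
    """
    if not cluster_set.clusters:
        raise EmptyRegionError("cluster set is empty")
    lab_img = cluster_set.labels
    out = {}
    for c in cluster_set.clusters:
        voxels = lab_img.data == c.label
        if not voxels.any():
            raise EmptyRegionError(f"cluster {c.label} has no voxels")
        col = []
        for mp in maps:
            if not mp.same_geometry(lab_img):
                raise GeometryError("subject map geometry differs from cluster labels")
            col.append(float(mp.data[voxels].mean()))
        out[f"cluster_{c.label}"] = col
    index = list(subject_ids) if subject_ids is not None else range(len(maps))
    return pd.DataFrame(out, index=index)
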