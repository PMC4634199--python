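"""Synthetic study generator with known ground truth.

Emulates a two-group premanifest Huntington's disease (preHD) cohort study:
gene-carriers plus healthy controls, with disease-load-dependent atrophy,
behavioral outcomes, task-fMRI contrast images and resting-state series —
everything a compensation analysis consumes — generated from a fully known
parameter set so every downstream stage has a parameter-recovery oracle.

The planted structure
---------------------
Performance follows the moderated-regression (compensation) model

    y = alpha + beta1*d + beta2*f + beta3*d*f + gamma.c + e,   e ~ N(0, sigma_e^2)

where ``d`` is a regional volume as a fraction of intracranial volume (small
volume = high structural disease load), ``f`` an fMRI feature and ``c`` the
covariates (age, gender, site, education, cumulative probability of onset).
The latent ``f`` is drawn first and ``y`` generated from it, so the identity
above holds exactly with an exogenous regressor; the task-contrast images
plant ``f`` at one designated "compensation" voxel, and the resting-state
series plant a per-subject seed-target coupling whose Fisher z plays the same
role for the connectivity branch.

Carriers' volume fractions decline linearly in a simulated cumulative
probability of onset (CPO), itself a logistic function of the disease-burden
score ``age * (CAG - 35.5)``; recruits with burden <= 250 are resampled,
mirroring study inclusion rules.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .errors import CoordinateError, InvalidSpecError
from .images import FWHM_TO_SIGMA, VolumetricImage, default_affine, sphere_voxel_mask

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "SubjectRecord",
    "RestSubject",
    "DISEASE_LOADS",
    "BATTERY_HIGHER_IS_BETTER",
    "generate_cohort_table",
    "records_to_frame",
    "generate_task_contrast_images",
    "generate_rest_series",
    "write_cohort_csv",
    "simulate_to_disk",
]

#: The four structural disease-load measures, each a volume fraction of ICV.
DISEASE_LOADS = ("caudate_frac", "putamen_frac", "gray_frac", "white_frac")

#: Orientation of the nine synthetic cognitive tests (two are error/latency
#: scores where lower is better).
BATTERY_HIGHER_IS_BETTER = (True, True, True, False, True, True, True, False, True)

_BATTERY_LOADINGS = np.array([0.85, 0.80, 0.75, 0.70, 0.65, 0.80, 0.70, 0.60, 0.75])


@dataclass(frozen=True)
class GroundTruth:
    """True generating parameters of the synthetic study.

    ``beta3`` is the compensation interaction; with the defaults the
    performance-activity slope ``beta2 + beta3*d`` is strongly positive at
    high load (small gray-matter fraction, d ~ 0.40) and near zero at low
    load (d ~ 0.50) — a compensatory pattern. ``gamma`` maps covariate names
    to coefficients; ``site_effects`` are additive site mean shifts.
    """

    alpha: float = -0.55
    beta1: float = 4.0
    beta2: float = 6.0
    beta3: float = -12.0
    gamma: Mapping[str, float] = field(
        default_factory=lambda: {"age": -0.01, "gender": 0.1, "education": 0.05, "cpo": -0.8}
    )
    site_effects: Sequence[float] = (0.0, 0.05, -0.05, 0.1)
    sigma_e: float = 0.5
    load_name: str = "gray_frac"
    # Task branch: mm coordinates of main-effect blobs; the first-listed
    # compensation_coord carries the planted interaction. Defaults lie on
    # voxel centres of the default 24x28x24 @ 4 mm grid.
    effect_coords: tuple[tuple[float, float, float], ...] = (
        (18.0, -26.0, 18.0),
        (-18.0, -26.0, 18.0),
        (2.0, 22.0, 6.0),
    )
    compensation_coord: tuple[float, float, float] = (18.0, -26.0, 18.0)
    main_effect_amplitude: float = 3.0
    blob_sigma_mm: float = 4.0
    # Resting-state branch: a seed and a target region share a latent time
    # course with per-subject coupling strength.
    seed_coord: tuple[float, float, float] = (-26.0, 18.0, 10.0)
    target_coord: tuple[float, float, float] = (22.0, -18.0, -6.0)
    coupling_mean: float = 0.6
    coupling_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_e <= 0:
            raise InvalidSpecError("sigma_e must be positive")
        if self.load_name not in DISEASE_LOADS:
            raise InvalidSpecError(f"load_name must be one of {DISEASE_LOADS}")

    def null(self, **overrides) -> "GroundTruth":
        """Copy with beta3 = 0 (no compensation), for calibration studies."""
        return dataclasses.replace(self, beta3=0.0, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gamma"] = dict(self.gamma)
        return d


@dataclass(frozen=True)
class CohortSpec:
    """Study dimensions. Defaults emulate a large multi-site premanifest-HD
    design (106 carriers / 111 controls, 4 sites, TR 3 s, 165 resting
    volumes); the image grid is desk-scale (24x28x24 voxels at 4 mm)."""

    n_carriers: int = 106
    n_controls: int = 111
    n_sites: int = 4
    image_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 4.0
    tr_s: float = 3.0
    n_volumes_rest: int = 165
    n_volumes_task: int = 186

    def __post_init__(self) -> None:
        if self.n_carriers < 1 or self.n_controls < 1 or self.n_sites < 1:
            raise InvalidSpecError("subject and site counts must be >= 1")
        if self.tr_s <= 0:
            raise InvalidSpecError("tr_s must be positive")
        if len(self.image_shape) != 3 or any(s < 2 for s in self.image_shape):
            raise InvalidSpecError("image_shape must be three dims >= 2")
        if self.voxel_size_mm <= 0:
            raise InvalidSpecError("voxel_size_mm must be positive")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.image_shape, self.voxel_size_mm)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's covariates, disease loads and behavioral outcomes."""

    subject_id: str
    group: str  # "preHD" or "control"
    site: int
    age: float
    gender: int  # 0/1
    education: int
    cag: int
    disease_burden: float
    cpo: float
    caudate_frac: float
    putamen_frac: float
    gray_frac: float
    white_frac: float
    vwm_performance: float
    tms: float
    gfv: float
    cognitive: tuple[float, ...]  # nine test scores
    nback1_targets: int
    nback1_hits: int
    nback1_nontargets: int
    nback1_false_alarms: int
    nback2_targets: int
    nback2_hits: int
    nback2_nontargets: int
    nback2_false_alarms: int
    latent_task_f: float
    latent_rest_coupling: float

    def __post_init__(self) -> None:
        for name in DISEASE_LOADS:
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InvalidSpecError(f"{name}={v} outside (0, 1)")
        if not 0 <= self.cpo <= 1:
            raise InvalidSpecError(f"cpo={self.cpo} outside [0, 1]")


@dataclass
class RestSubject:
    """One subject's resting-state series plus its true nuisance table."""

    subject_id: str
    image: VolumetricImage
    nuisance: pd.DataFrame  # columns motion1..motion6, wm, csf


def _rng(seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, *extra]))


def _covariate_effect(truth: GroundTruth, age, gender, education, cpo, site):
    g = truth.gamma
    eff = (
        g.get("age", 0.0) * age
        + g.get("gender", 0.0) * gender
        + g.get("education", 0.0) * education
        + g.get("cpo", 0.0) * cpo
    )
    site_eff = np.asarray(truth.site_effects, dtype=float)[site - 1]
    return eff + site_eff


def _eq1(truth: GroundTruth, d, f, cov_eff, e):
    return truth.alpha + truth.beta1 * d + truth.beta2 * f + truth.beta3 * d * f + cov_eff + e


def generate_cohort_table(spec: CohortSpec, truth: GroundTruth) -> list[SubjectRecord]:
    """Generate the tabular cohort: covariates, atrophy, behavior, latents.

    Deterministic in ``truth.seed``: the same spec and truth always yield an
    identical table.
    """
    if len(truth.site_effects) < spec.n_sites:
        raise InvalidSpecError(
            f"truth.site_effects has {len(truth.site_effects)} entries "
            f"but spec.n_sites={spec.n_sites}"
        )
    rng = _rng(truth.seed, 0)
    nc, nh = spec.n_carriers, spec.n_controls
    n = nc + nh

    # --- carriers: recruitment with disease-burden > 250 ------------------
    age_c = np.clip(rng.normal(43.0, 9.0, nc), 23.0, 64.0)
    cag_c = rng.integers(40, 48, nc)
    burden = age_c * (cag_c - 35.5)
    while True:
        bad = burden <= 250.0
        if not bad.any():
            break
        k = int(bad.sum())
        age_c[bad] = np.clip(rng.normal(43.0, 9.0, k), 23.0, 64.0)
        cag_c[bad] = rng.integers(40, 48, k)
        burden[bad] = age_c[bad] * (cag_c[bad] - 35.5)
    cpo_c = expit((burden - 350.0) / 80.0)

    # --- controls ----------------------------------------------------------
    age_h = np.clip(rng.normal(48.0, 10.0, nh), 23.0, 64.0)
    cag_h = rng.integers(15, 27, nh)
    cpo_h = np.zeros(nh)

    age = np.concatenate([age_c, age_h])
    cag = np.concatenate([cag_c, cag_h])
    cpo = np.concatenate([cpo_c, cpo_h])
    burden_all = np.concatenate([burden, np.zeros(nh)])
    group = np.array(["preHD"] * nc + ["control"] * nh)

    site = rng.integers(1, spec.n_sites + 1, n)
    gender = rng.integers(0, 2, n)
    education = rng.integers(1, 7, n)

    # Atrophy: volume fractions of ICV, declining linearly in CPO.
    def frac(mean, slope, sd):
        return np.clip(mean - slope * cpo + rng.normal(0.0, sd, n), 1e-4, 0.999)

    caudate = frac(0.0048, 0.0015, 0.0004)
    putamen = frac(0.0065, 0.0020, 0.0005)
    gray = frac(0.50, 0.08, 0.015)
    white = frac(0.33, 0.03, 0.012)
    loads = {"caudate_frac": caudate, "putamen_frac": putamen,
             "gray_frac": gray, "white_frac": white}
    d = loads[truth.load_name]

    cov_eff = _covariate_effect(truth, age, gender, education, cpo, site)

    # Task branch: latent activity f and in-scanner working-memory score y.
    f_task = rng.standard_normal(n)
    y = _eq1(truth, d, f_task, cov_eff, rng.normal(0.0, truth.sigma_e, n))

    # Rest branch: planted seed-target coupling; latent cognition follows the
    # same model with f = Fisher z of the coupling, and the nine-test battery
    # loads on that latent factor.
    coupling = np.clip(rng.normal(truth.coupling_mean, truth.coupling_sd, n), 0.05, 0.95)
    f_rest = np.arctanh(coupling)
    g_lat = _eq1(truth, d, f_rest, cov_eff, rng.normal(0.0, truth.sigma_e, n))
    zg = (g_lat - g_lat.mean()) / g_lat.std(ddof=1)
    L = _BATTERY_LOADINGS
    battery = zg[:, None] * L[None, :] + np.sqrt(1 - L**2)[None, :] * rng.standard_normal((n, 9))
    battery = battery * np.where(np.asarray(BATTERY_HIGHER_IS_BETTER), 1.0, -1.0)[None, :]

    # n-back counts: a binomial realization tied to the continuous score.
    ty = np.tanh(y)
    p_hit1 = np.clip(0.60 + 0.30 * ty, 0.02, 0.98)
    p_fa1 = np.clip(0.15 - 0.08 * ty, 0.01, 0.50)
    p_hit2 = np.clip(0.45 + 0.30 * ty, 0.02, 0.98)
    p_fa2 = np.clip(0.22 - 0.08 * ty, 0.01, 0.50)
    n_t, n_nt = 24, 48
    hits1 = rng.binomial(n_t, p_hit1)
    fa1 = rng.binomial(n_nt, p_fa1)
    hits2 = rng.binomial(n_t, p_hit2)
    fa2 = rng.binomial(n_nt, p_fa2)

    # Motor outcomes (no planted compensation in the motor branch).
    tms = np.where(group == "preHD", rng.poisson(1.0 + 8.0 * cpo), rng.poisson(1.0, n)).astype(float)
    gfv = np.exp(rng.normal(np.log(0.08) + 0.5 * cpo, 0.25))

    records = []
    for i in range(n):
        records.append(
            SubjectRecord(
                subject_id=f"S{i + 1:03d}",
                group=str(group[i]),
                site=int(site[i]),
                age=float(age[i]),
                gender=int(gender[i]),
                education=int(education[i]),
                cag=int(cag[i]),
                disease_burden=float(burden_all[i]),
                cpo=float(cpo[i]),
                caudate_frac=float(caudate[i]),
                putamen_frac=float(putamen[i]),
                gray_frac=float(gray[i]),
                white_frac=float(white[i]),
                vwm_performance=float(y[i]),
                tms=float(tms[i]),
                gfv=float(gfv[i]),
                cognitive=tuple(float(v) for v in battery[i]),
                nback1_targets=n_t, nback1_hits=int(hits1[i]),
                nback1_nontargets=n_nt, nback1_false_alarms=int(fa1[i]),
                nback2_targets=n_t, nback2_hits=int(hits2[i]),
                nback2_nontargets=n_nt, nback2_false_alarms=int(fa2[i]),
                latent_task_f=float(f_task[i]),
                latent_rest_coupling=float(coupling[i]),
            )
        )
    return records


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten records into a tidy DataFrame (cog01..cog09 for the battery)."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        cog = d.pop("cognitive")
        for j, v in enumerate(cog, start=1):
            d[f"cog{j:02d}"] = v
        rows.append(d)
    return pd.DataFrame(rows)


def write_cohort_csv(records: Sequence[SubjectRecord], path) -> pd.DataFrame:
    frame = records_to_frame(records)
    frame.to_csv(path, index=False)
    return frame


# ---------------------------------------------------------------------------
# Task contrast images
# ---------------------------------------------------------------------------


def _blob_profile(spec: CohortSpec, truth: GroundTruth) -> np.ndarray:
    """Sum of Gaussian main-effect blobs over the grid (same for everyone)."""
    img = VolumetricImage(np.zeros(spec.image_shape), spec.affine)
    grid = np.indices(spec.image_shape).reshape(3, -1).T.astype(float)
    mm = img.voxel_to_mm(grid)
    profile = np.zeros(mm.shape[0])
    for coord in truth.effect_coords:
        img.nearest_voxel(coord)  # raises CoordinateError if outside the grid
        d2 = np.sum((mm - np.asarray(coord)) ** 2, axis=1)
        profile += truth.main_effect_amplitude * np.exp(-d2 / (2 * truth.blob_sigma_mm**2))
    return profile.reshape(spec.image_shape)


def _smoothed_noise_scale(shape, sigma_vox: float) -> float:
    """1/sd of unit white noise after Gaussian filtering (from the kernel's
    sum of squared weights, measured on an impulse)."""
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    k = ndimage.gaussian_filter(impulse, sigma_vox)
    return 1.0 / float(np.sqrt(np.sum(k**2)))


def generate_task_contrast_images(
    records: Sequence[SubjectRecord],
    spec: CohortSpec,
    truth: GroundTruth,
    background_sd: float = 0.8,
    noise_fwhm_mm: float = 6.0,
) -> list[VolumetricImage]:
    """Per-subject 3D task-contrast maps with planted structure.

    Each map is spatially smooth background noise plus a fixed main-effect
    blob at every ``truth.effect_coords`` (so a group one-sample t-test
    recovers the task main-effect mask), and at the single designated
    compensation voxel the value is ``main_effect_amplitude + latent_task_f``
    — i.e. the subject's latent f, offset so the voxel also carries the main
    effect. The compensation model is invariant to that affine offset.
    """
    affine = spec.affine
    profile = _blob_profile(spec, truth)
    ref = VolumetricImage(np.zeros(spec.image_shape), affine)
    comp_ijk = ref.nearest_voxel(truth.compensation_coord)
    sigma_vox = noise_fwhm_mm * FWHM_TO_SIGMA / spec.voxel_size_mm
    scale = background_sd * _smoothed_noise_scale(spec.image_shape, sigma_vox)
    rng = _rng(truth.seed, 1)
    images = []
    for r in records:
        bg = ndimage.gaussian_filter(rng.standard_normal(spec.image_shape), sigma_vox) * scale
        data = bg + profile
        data[comp_ijk] = truth.main_effect_amplitude + r.latent_task_f
        images.append(VolumetricImage(data, affine))
    return images


# ---------------------------------------------------------------------------
# Resting-state series
# ---------------------------------------------------------------------------


def generate_rest_series(
    records: Sequence[SubjectRecord],
    spec: CohortSpec,
    truth: GroundTruth,
    seed_region_radius_mm: float = 4.0,
    target_region_radius_mm: float = 6.0,
) -> Iterator[RestSubject]:
    """Yield per-subject 4D resting series plus the true nuisance table.

    A latent time course drives a seed region; a target region follows it
    with the subject's planted coupling ``latent_rest_coupling``. Global
    white-matter and CSF confound time courses (and a mild leakage of the
    first motion trace) are added to every voxel and reported, along with six
    synthetic motion regressors, in the nuisance table. Lazily generated one
    subject at a time (a full cohort of 4D series would not fit in memory).
    """
    if spec.n_volumes_rest < 20:
        raise InvalidSpecError(
            "n_volumes_rest must be >= 20 (too short to estimate correlations stably)"
        )
    affine = spec.affine
    ref = VolumetricImage(np.zeros(spec.image_shape), affine)
    ref.nearest_voxel(truth.seed_coord)
    ref.nearest_voxel(truth.target_coord)
    seed_mask = sphere_voxel_mask(ref, truth.seed_coord, seed_region_radius_mm)
    target_mask = sphere_voxel_mask(ref, truth.target_coord, target_region_radius_mm)
    T = spec.n_volumes_rest
    return _rest_series_iter(records, spec, truth, affine, seed_mask, target_mask, T)


def _rest_series_iter(records, spec, truth, affine, seed_mask, target_mask, T):
    for i, r in enumerate(records):
        rng = _rng(truth.seed, 2, i)
        s = rng.standard_normal(T)
        eta = rng.standard_normal(T)
        rho = r.latent_rest_coupling
        u = rho * s + np.sqrt(max(0.0, 1.0 - rho**2)) * eta

        wm = rng.standard_normal(T)
        csf = rng.standard_normal(T)
        motion = np.cumsum(rng.normal(0.0, 0.02, (T, 6)), axis=0)
        m1 = (motion[:, 0] - motion[:, 0].mean())
        m1_sd = m1.std()
        m1 = m1 / m1_sd if m1_sd > 0 else m1

        data = rng.standard_normal(spec.image_shape + (T,))
        data[seed_mask, :] = s + 0.2 * rng.standard_normal((int(seed_mask.sum()), T))
        data[target_mask, :] = u + 0.1 * rng.standard_normal((int(target_mask.sum()), T))
        data += 0.8 * wm + 0.5 * csf + 0.15 * m1  # global confounds, every voxel

        nuis = pd.DataFrame(
            {f"motion{j + 1}": motion[:, j] for j in range(6)} | {"wm": wm, "csf": csf}
        )
        yield RestSubject(r.subject_id, VolumetricImage(data, affine), nuis)


# ---------------------------------------------------------------------------
# Disk layout
# ---------------------------------------------------------------------------


def simulate_to_disk(spec: CohortSpec, truth: GroundTruth, outdir,
                     write_rest: bool = True) -> dict:
    """Write the full synthetic study to ``outdir`` and return the manifest.

    Layout: ``cohort.csv``, ``task_contrast/<id>.nii.gz``,
    ``rest/<id>.nii.gz`` + ``rest/<id>_nuisance.tsv``, ``manifest.json``.
    """
    outdir = Path(outdir)
    (outdir / "task_contrast").mkdir(parents=True, exist_ok=True)
    records = generate_cohort_table(spec, truth)
    write_cohort_csv(records, outdir / "cohort.csv")
    manifest: dict = {
        "ground_truth": truth.to_dict(),
        "cohort_spec": dataclasses.asdict(spec),
        "cohort_csv": "cohort.csv",
        "subjects": {},
    }
    for rec, img in zip(records, generate_task_contrast_images(records, spec, truth)):
        rel = f"task_contrast/{rec.subject_id}.nii.gz"
        img.save(outdir / rel)
        manifest["subjects"][rec.subject_id] = {"task_contrast": rel}
    if write_rest:
        (outdir / "rest").mkdir(exist_ok=True)
        for rest in generate_rest_series(records, spec, truth):
            rel = f"rest/{rest.subject_id}.nii.gz"
            rest.image.save(outdir / rel)
            nrel = f"rest/{rest.subject_id}_nuisance.tsv"
            rest.nuisance.to_csv(outdir / nrel, sep="\t", index=False)
            manifest["subjects"][rest.subject_id]["rest"] = rel
            manifest["subjects"][rest.subject_id]["nuisance"] = nrel
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
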