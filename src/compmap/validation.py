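"""Monte-Carlo validation studies of the compensation pipeline.

Self-contained simulation studies that quantify, on the synthetic cohort,
the statistical behaviour the method is supposed to have: type-I error of
the interaction test under a true null, confidence-interval coverage and
bias of the planted interaction coefficient, exact agreement of the
voxelwise engine with an independent pseudoinverse regression, detection of
the planted compensation voxel and of the planted resting-state cluster in
end-to-end runs, and the equal-count properties of conditioning-plot
intervals. Each function is deterministic in its ``seed``.
"""

from __future__ import annotations

import dataclasses
import tempfile

import numpy as np
from scipy import stats

from .behavior import NbackCounts, dprime
from .cohort import (
    CohortSpec,
    GroundTruth,
    generate_cohort_table,
    generate_task_contrast_images,
    records_to_frame,
)
from .connectivity import group_onesample_t, threshold_fwe
from .model import (
    DEFAULT_COVARIATES,
    bonferroni_disease_load,
    coplot_intervals,
    fit_compensation,
    voxelwise_compensation,
    _design_matrix,
    _prepare_frame,
)
from .pipeline import RunConfig, run_pipeline

__all__ = [
    "type1_rejection_rate",
    "beta3_recovery",
    "voxelwise_oracle_deviation",
    "planted_detection_rates",
    "coplot_count_check",
    "behavioral_worked_examples",
    "DEMO_SPEC",
]

#: Desk-scale study dimensions for the end-to-end detection runs: the carrier
#: group is kept at the full design's ~100 (the compensation fits draw their
#: power from it) while controls — who only enter the group-mean maps — and
#: the resting series length are scaled down to keep one full
#: simulate->analyze cycle around ten seconds.
DEMO_SPEC = CohortSpec(n_carriers=100, n_controls=60, n_volumes_rest=80)


def _subseed(seed: int, *tags: int) -> int:
    """Derive a reproducible 31-bit sub-seed from a user seed and stream tags."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *tags])
    return int(ss.generate_state(1)[0] % (2**31))


def _carrier_frame(spec: CohortSpec, truth: GroundTruth):
    frame = records_to_frame(generate_cohort_table(spec, truth))
    return frame[frame["group"] == "preHD"].reset_index(drop=True)


def type1_rejection_rate(
    n_reps: int = 1000,
    n_carriers: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of H0: beta3 = 0 across null cohorts (true beta3 = 0).

    Each replicate simulates a fresh carrier cohort with no planted
    interaction and fits the compensation model using the subject's latent
    fMRI feature; the nominal test should reject at ~``alpha``.
    """
    spec = CohortSpec(n_carriers=n_carriers, n_controls=1)
    base = GroundTruth().null()
    rejections = 0
    for rep in range(n_reps):
        truth = dataclasses.replace(base, seed=_subseed(seed, 1, rep))
        carriers = _carrier_frame(spec, truth)
        fit = fit_compensation(
            carriers, y="vwm_performance", f="latent_task_f",
            disease_load=truth.load_name,
        )
        rejections += fit.p_beta3 <= alpha
    rate = rejections / n_reps
    return {
        "rate": rate,
        "nominal": alpha,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
        "n_reps": n_reps,
        "n": n_carriers,
    }


def beta3_recovery(
    n_reps: int = 200,
    n_carriers: int = 100,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Coverage of the beta3 confidence interval and bias of its estimate."""
    spec = CohortSpec(n_carriers=n_carriers, n_controls=1)
    base = GroundTruth()
    covered = 0
    errors = np.empty(n_reps)
    for rep in range(n_reps):
        truth = dataclasses.replace(base, seed=_subseed(seed, 2, rep))
        carriers = _carrier_frame(spec, truth)
        fit = fit_compensation(
            carriers, y="vwm_performance", f="latent_task_f",
            disease_load=truth.load_name,
        )
        lo, hi = fit.ci_beta3(level)
        covered += lo <= truth.beta3 <= hi
        errors[rep] = fit.beta3 - truth.beta3
    return {
        "coverage": covered / n_reps,
        "level": level,
        "mean_bias": float(errors.mean()),
        "se_bias": float(errors.std(ddof=1) / np.sqrt(n_reps)),
        "true_beta3": base.beta3,
        "n_reps": n_reps,
        "n": n_carriers,
    }


def _pinv_oracle_maps(images, mask, table, y, disease_load):
    """Independent per-voxel regression via explicit pseudoinverse formulas.

    Deliberately a different numerical route from the package engine (which
    uses QR): beta = pinv(X) y and cov = sigma^2 pinv(X'X).
    """
    frame, y_col, _ = _prepare_frame(
        table.reset_index(drop=True), y, np.zeros(len(table)), disease_load,
        DEFAULT_COVARIATES,
    )
    rows = frame.index.to_numpy()
    Z, _ = _design_matrix(frame, disease_load, DEFAULT_COVARIATES, ("site",))
    d = frame[disease_load].to_numpy(dtype=float)
    yv = frame[y_col].to_numpy(dtype=float)
    F = np.stack([images[i].data[mask] for i in rows], axis=0)
    n = len(rows)
    p = Z.shape[1] + 2
    t_vals = np.empty(F.shape[1])
    b3_vals = np.empty(F.shape[1])
    for v in range(F.shape[1]):
        X = np.column_stack([Z[:, :2], F[:, v], d * F[:, v], Z[:, 2:]])
        beta = np.linalg.pinv(X) @ yv
        resid = yv - X @ beta
        sigma2 = resid @ resid / (n - p)
        cov = sigma2 * np.linalg.pinv(X.T @ X)
        b3_vals[v] = beta[3]
        t_vals[v] = beta[3] / np.sqrt(cov[3, 3])
    return b3_vals, t_vals, n - p


def voxelwise_oracle_deviation(n_carriers: int = 60, seed: int = 0) -> dict:
    """Max deviation between the voxelwise engine and the pinv oracle.

    Runs both routes over every voxel of a full synthetic volume (whole-grid
    mask) and reports the largest absolute difference in the interaction
    t statistic and coefficient.
    """
    spec = CohortSpec(n_carriers=n_carriers, n_controls=1)
    truth = dataclasses.replace(GroundTruth(), seed=_subseed(seed, 3))
    records = generate_cohort_table(spec, truth)
    frame = records_to_frame(records)
    carriers_mask = (frame["group"] == "preHD").to_numpy()
    images = generate_task_contrast_images(records, spec, truth)
    car_images = [img for img, c in zip(images, carriers_mask) if c]
    carriers = frame[frame["group"] == "preHD"].reset_index(drop=True)
    mask = np.ones(spec.image_shape, dtype=bool)
    vw = voxelwise_compensation(
        car_images, mask, carriers, y="vwm_performance",
        disease_load=truth.load_name,
    )
    b3_o, t_o, df_o = _pinv_oracle_maps(
        car_images, mask, carriers, "vwm_performance", truth.load_name
    )
    dt = np.max(np.abs(vw.t_map.data[mask] - t_o))
    db = np.max(np.abs(vw.beta3_map.data[mask] - b3_o))
    p_o = 2 * stats.t.sf(np.abs(t_o), df_o)
    dp = np.max(np.abs(vw.p_map.data[mask] - p_o))
    return {
        "max_abs_dt": float(dt),
        "max_abs_dbeta3": float(db),
        "max_abs_dp": float(dp),
        "n_voxels": int(mask.sum()),
        "n": len(carriers),
    }


def planted_detection_rates(
    n_runs: int = 20,
    seed: int = 0,
    spec: CohortSpec = DEMO_SPEC,
) -> dict:
    """End-to-end detection of the planted effects across seeded runs.

    For each run the full pipeline is executed on a fresh synthetic study;
    recorded are (a) whether the planted compensation voxel is the minimum-p
    in-mask voxel for the generating disease load and (b) whether the planted
    resting-state target falls inside a cluster surviving FWE 0.05.
    """
    task_hits = 0
    rest_hits = 0
    for run in range(n_runs):
        with tempfile.TemporaryDirectory() as tmp:
            config = RunConfig(
                seed=_subseed(seed, 4, run), output_dir=tmp, cohort=spec
            )
            rep = run_pipeline(config)
        load = config.resolved_truth().load_name
        task_hits += rep["task"]["by_disease_load"][load]["planted_is_min_p"]
        rest_hits += rep["rest"]["target_cluster_label"] is not None
    return {
        "task_top_rate": task_hits / n_runs,
        "rest_recovery_rate": rest_hits / n_runs,
        "n_runs": n_runs,
        "n_subjects": spec.n_carriers + spec.n_controls,
    }


def coplot_count_check(
    n: int = 100, k: int = 4, overlap: float = 0.5, seed: int = 0
) -> dict:
    """Brute-force check of the equal-count interval properties."""
    rng = np.random.default_rng(_subseed(seed, 5))
    d = rng.uniform(0.35, 0.55, n)
    spec = coplot_intervals(d, k=k, overlap=overlap)
    m = spec.target_count
    counts = spec.counts()
    shared = [
        len(set(spec.index_sets[j].tolist()) & set(spec.index_sets[j + 1].tolist()))
        for j in range(k - 1)
    ]
    return {
        "counts": counts,
        "target_count": m,
        "max_count_dev": float(max(abs(c - m) for c in counts)),
        "shared": shared,
        "expected_shared": m * overlap,
        "max_overlap_dev": float(max(abs(s - m * overlap) for s in shared)) if shared else 0.0,
        "n": n,
        "covers_all": bool(
            np.array_equal(
                np.unique(np.concatenate(spec.index_sets)), np.arange(n)
            )
        ),
    }


def behavioral_worked_examples() -> dict:
    """Worked d-prime and Bonferroni examples with hand-checkable answers."""
    d_perfect = dprime(NbackCounts(20, 20, 20, 0))
    d_mid = dprime(NbackCounts(20, 15, 20, 5))
    d_chance = dprime(NbackCounts(20, 10, 20, 10))
    fam = bonferroni_disease_load(
        {"gray_frac": 0.010, "white_frac": 0.019,
         "caudate_frac": 0.20, "putamen_frac": 0.40},
        alpha=0.05,
    )
    return {
        "dprime_perfect": d_perfect,
        "dprime_mid": d_mid,
        "dprime_chance": d_chance,
        "bonferroni_n_adjusted_significant": int(fam["adjusted_significant"].sum()),
        "p010_survives": bool(fam.loc["gray_frac", "adjusted_significant"]),
        "p019_survives": bool(fam.loc["white_frac", "adjusted_significant"]),
    }
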