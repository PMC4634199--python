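"""End-to-end orchestration: simulate -> behavior -> maps -> compensation.

:func:`run_pipeline` executes the full synthetic study under one seed and
writes a machine-readable JSON report of every fit, decision and file
produced. All randomness flows from ``RunConfig.seed``; rerunning the same
config yields an identical report (wall-clock timings aside).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .behavior import NbackCounts, cognitive_composite, dprime
from .cohort import (
    BATTERY_HIGHER_IS_BETTER,
    DISEASE_LOADS,
    CohortSpec,
    GroundTruth,
    generate_cohort_table,
    generate_rest_series,
    generate_task_contrast_images,
    records_to_frame,
)
from .connectivity import (
    NuisanceSet,
    extract_cluster_means,
    group_onesample_t,
    seed_correlation_map,
    threshold_fwe,
)
from .errors import InvalidSpecError
from .model import (
    bonferroni_disease_load,
    classify_pattern,
    coplot_intervals,
    fit_compensation,
)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

logger = logging.getLogger("compmap.pipeline")


@dataclass
class RunConfig:
    """Configuration of an end-to-end synthetic run.

    Thresholds follow the study conventions: main-effect mask at FWE 0.05,
    connectivity clusters at FWE 0.05, voxelwise compensation findings
    reported at p < 0.001 uncorrected, nominal alpha 0.05 for the interaction
    test, Bonferroni family = the four disease loads.
    """

    seed: int = 0
    output_dir: str = "compmap_run"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    truth: GroundTruth = field(default_factory=GroundTruth)
    disease_loads: tuple[str, ...] = DISEASE_LOADS
    task_outcome: str = "vwm_performance"
    rest_outcome: str = "composite"
    fit_group: str = "preHD"
    seed_radius_mm: float = 4.0
    main_effect_fwe_alpha: float = 0.05
    connectivity_fwe_alpha: float = 0.05
    voxel_report_p: float = 0.001
    nominal_alpha: float = 0.05
    fwe_method: str = "bonferroni"
    coplot_k: int = 4
    coplot_overlap: float = 0.5
    run_rest: bool = True
    write_images: bool = False

    def resolved_truth(self) -> GroundTruth:
        """Ground truth with the run seed folded in."""
        return dataclasses.replace(self.truth, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortSpec(**{
                k: tuple(v) if k == "image_shape" else v
                for k, v in kwargs["cohort"].items()
            })
        if "truth" in kwargs:
            t = dict(kwargs["truth"])
            for key in ("effect_coords",):
                if key in t:
                    t[key] = tuple(tuple(c) for c in t[key])
            for key in ("compensation_coord", "seed_coord", "target_coord", "site_effects"):
                if key in t:
                    t[key] = tuple(t[key])
            kwargs["truth"] = GroundTruth(**t)
        if "disease_loads" in kwargs:
            kwargs["disease_loads"] = tuple(kwargs["disease_loads"])
        return cls(**kwargs)


def validate_config(config: RunConfig) -> list[str]:
    """Schema/range checks; returns a list of problems (empty = valid)."""
    problems: list[str] = []
    for key in ("main_effect_fwe_alpha", "connectivity_fwe_alpha",
                "voxel_report_p", "nominal_alpha"):
        v = getattr(config, key)
        if not 0 < v < 1:
            problems.append(f"{key}={v} not in (0, 1)")
    if config.coplot_k < 1:
        problems.append(f"coplot_k={config.coplot_k} must be >= 1")
    if not 0 <= config.coplot_overlap < 1:
        problems.append(f"coplot_overlap={config.coplot_overlap} not in [0, 1)")
    if config.seed_radius_mm <= 0:
        problems.append("seed_radius_mm must be positive")
    if config.fwe_method not in ("bonferroni", "permutation", "none"):
        problems.append(f"unknown fwe_method {config.fwe_method!r}")
    for name in config.disease_loads:
        if name not in DISEASE_LOADS:
            problems.append(f"unknown disease load {name!r}")
    if config.cohort.n_volumes_rest < 20 and config.run_rest:
        problems.append("cohort.n_volumes_rest must be >= 20 for the rest branch")
    out_parent = Path(config.output_dir).resolve().parent
    if not out_parent.exists():
        problems.append(f"parent of output_dir does not exist: {out_parent}")
    return problems


def _augment_behavior(frame):
    """Add d-prime columns and the PCA cognitive composite to the table."""
    for cond in ("nback1", "nback2"):
        vals = []
        for _, row in frame.iterrows():
            counts = NbackCounts(
                n_targets=int(row[f"{cond}_targets"]),
                n_hits=int(row[f"{cond}_hits"]),
                n_nontargets=int(row[f"{cond}_nontargets"]),
                n_false_alarms=int(row[f"{cond}_false_alarms"]),
                condition=cond,
            )
            vals.append(dprime(counts))
        frame[f"{cond}_dprime"] = vals
    battery = frame[[f"cog{j:02d}" for j in range(1, 10)]]
    comp = cognitive_composite(battery, higher_is_better=BATTERY_HIGHER_IS_BETTER)
    frame["composite"] = comp.scores
    return frame, comp


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return (and write) the run report."""
    problems = validate_config(config)
    if problems:
        raise InvalidSpecError("invalid config: " + "; ".join(problems))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.cohort
    truth = config.resolved_truth()
    report: dict = {
        "seed": config.seed,
        "ground_truth": truth.to_dict(),
        "files": {},
        "timings_s": {},
    }
    t_all = time.perf_counter()

    # --- stage 1: simulate -------------------------------------------------
    t0 = time.perf_counter()
    records = generate_cohort_table(spec, truth)
    frame = records_to_frame(records)
    report["timings_s"]["simulate"] = time.perf_counter() - t0
    logger.info("simulate: %d subjects", len(records))

    # --- stage 2: behavior -------------------------------------------------
    t0 = time.perf_counter()
    frame, comp = _augment_behavior(frame)
    frame.to_csv(outdir / "cohort.csv", index=False)
    report["files"]["cohort_csv"] = "cohort.csv"
    report["behavior"] = {
        "composite_explained_variance_ratio": comp.explained_variance_ratio,
        "composite_loadings": [float(v) for v in comp.loadings],
    }
    report["timings_s"]["behavior"] = time.perf_counter() - t0

    carriers = frame[frame["group"] == config.fit_group].reset_index(drop=True)
    carrier_idx = np.flatnonzero((frame["group"] == config.fit_group).to_numpy())

    # --- stage 3: task contrast maps + voxelwise compensation --------------
    t0 = time.perf_counter()
    images = generate_task_contrast_images(records, spec, truth)
    tmap, pmap = group_onesample_t(images)
    mask_clusters = threshold_fwe(tmap, pmap, alpha=config.main_effect_fwe_alpha,
                                  method="bonferroni")
    mask = mask_clusters.labels.data > 0
    if config.write_images:
        tmap.save(outdir / "task_main_tmap.nii.gz")
        mask_clusters.labels.save(outdir / "task_main_mask.nii.gz")
        report["files"]["task_main_tmap"] = "task_main_tmap.nii.gz"
        report["files"]["task_main_mask"] = "task_main_mask.nii.gz"
    comp_ijk = images[0].nearest_voxel(truth.compensation_coord)
    task: dict = {
        "mask_voxels": int(mask.sum()),
        "planted_voxel_ijk": list(comp_ijk),
        "planted_voxel_in_mask": bool(mask[comp_ijk]),
        "by_disease_load": {},
    }
    carrier_images = [images[i] for i in carrier_idx]
    comp_feature = np.array([img.data[comp_ijk] for img in carrier_images])
    pvals_planted: dict[str, float] = {}
    from .model import voxelwise_compensation  # local import avoids cycle in docs

    for load in config.disease_loads:
        vw = voxelwise_compensation(
            carrier_images, mask, carriers, y=config.task_outcome,
            disease_load=load, report_threshold=config.voxel_report_p,
        )
        min_ijk, min_p = vw.min_p_voxel()
        fit = fit_compensation(carriers, y=config.task_outcome, f=comp_feature,
                               disease_load=load, feature_name="task_contrast")
        pattern = classify_pattern(fit, d_values=carriers[load],
                                   alpha=config.nominal_alpha)
        pvals_planted[load] = fit.p_beta3
        task["by_disease_load"][load] = {
            "min_p_voxel_ijk": list(min_ijk),
            "min_p": min_p,
            "planted_is_min_p": list(min_ijk) == list(comp_ijk),
            "n_reported_voxels": int(len(vw.report)),
            "fit_at_planted_voxel": fit.to_dict(),
            "pattern": dataclasses.asdict(pattern),
        }
    task["bonferroni"] = bonferroni_disease_load(
        pvals_planted, alpha=config.nominal_alpha
    ).reset_index().to_dict(orient="records")
    report["task"] = task
    report["timings_s"]["task"] = time.perf_counter() - t0

    # coplot spec at the planted voxel for the generating disease load
    cop = coplot_intervals(
        carriers[truth.load_name].to_numpy(), k=config.coplot_k,
        overlap=config.coplot_overlap,
        y=carriers[config.task_outcome].to_numpy(), f=comp_feature,
    )
    (outdir / "coplot_task.json").write_text(cop.to_json())
    report["files"]["coplot_task_json"] = "coplot_task.json"
    report["coplot_task"] = {
        "counts": cop.counts(), "target_count": cop.target_count,
        "slopes": cop.slopes,
    }

    # --- stage 4: resting-state connectivity + compensation ----------------
    if config.run_rest:
        t0 = time.perf_counter()
        zmaps = []
        for rest in generate_rest_series(records, spec, truth):
            zmaps.append(
                seed_correlation_map(
                    rest.image, truth.seed_coord,
                    nuisance=NuisanceSet.from_frame(rest.nuisance),
                    radius_mm=config.seed_radius_mm,
                )
            )
        gt, gp = group_onesample_t(zmaps)
        clusters = threshold_fwe(
            gt, gp, alpha=config.connectivity_fwe_alpha, method=config.fwe_method,
            maps=zmaps, rng=np.random.default_rng(config.seed),
        )
        target_label = clusters.contains_mm(truth.target_coord) if len(clusters) else None
        seed_label = clusters.contains_mm(truth.seed_coord) if len(clusters) else None
        rest_rep: dict = {
            "n_clusters": len(clusters),
            "clusters": clusters.to_frame().to_dict(orient="records"),
            "target_cluster_label": target_label,
            "seed_cluster_label": seed_label,
            "by_disease_load": {},
        }
        if target_label is not None:
            feats = extract_cluster_means(
                clusters, [zmaps[i] for i in carrier_idx],
                subject_ids=list(carriers["subject_id"]),
            )
            fcol = feats[f"cluster_{target_label}"].to_numpy()
            pvals_rest: dict[str, float] = {}
            for load in config.disease_loads:
                fit = fit_compensation(
                    carriers, y=config.rest_outcome, f=fcol,
                    disease_load=load, feature_name=f"cluster_{target_label}",
                )
                pattern = classify_pattern(fit, d_values=carriers[load],
                                           alpha=config.nominal_alpha)
                pvals_rest[load] = fit.p_beta3
                rest_rep["by_disease_load"][load] = {
                    "fit_target_cluster": fit.to_dict(),
                    "pattern": dataclasses.asdict(pattern),
                }
            rest_rep["bonferroni"] = bonferroni_disease_load(
                pvals_rest, alpha=config.nominal_alpha
            ).reset_index().to_dict(orient="records")
            cop_rest = coplot_intervals(
                carriers[truth.load_name].to_numpy(), k=config.coplot_k,
                overlap=config.coplot_overlap,
                y=carriers[config.rest_outcome].to_numpy(), f=fcol,
            )
            (outdir / "coplot_rest.json").write_text(cop_rest.to_json())
            report["files"]["coplot_rest_json"] = "coplot_rest.json"
        report["rest"] = rest_rep
        report["timings_s"]["rest"] = time.perf_counter() - t0

    report["timings_s"]["total"] = time.perf_counter() - t_all
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["files"]["report_json"] = "report.json"
    logger.info("pipeline done in %.1fs", report["timings_s"]["total"])
    return report
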