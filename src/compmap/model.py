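"""The compensation model and its mass-univariate application.

The central object is the moderated regression

    y = alpha + beta1*d + beta2*f + beta3*d*f + gamma.c + e

fitted by ordinary least squares, where y is a performance measure, d a
structural disease-load measure (regional volume as a fraction of
intracranial volume; SMALL d = HIGH load), f a scalar fMRI feature and c the
covariates (age, gender, study site, education, cumulative probability of
onset). Evidence for compensation is rejection of H0: beta3 = 0 — the
performance-activity relationship varies with disease load — at the nominal
p <= 0.05 criterion, with a pre-planned Bonferroni correction applied only
across the four disease-load measures, never across features or voxels.

Also here: the voxelwise application of the model within a task main-effect
mask, the compensatory / non-compensatory sign classification based on the
fitted slope beta2 + beta3*d at the extremes of the observed load range, and
the equal-count overlapping-interval machinery behind conditioning plots.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .errors import CollinearityError, EmptyRegionError, MissingDataError
from .images import VolumetricImage

__all__ = [
    "CompensationFit",
    "fit_compensation",
    "VoxelwiseResult",
    "voxelwise_compensation",
    "bonferroni_disease_load",
    "PatternResult",
    "classify_pattern",
    "CoplotSpec",
    "coplot_intervals",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "gender", "site", "education", "cpo")

_COND_LIMIT = 1e8  # condition number above which the design is rejected


def _design_matrix(
    frame: pd.DataFrame,
    d_col: str,
    covariates: Sequence[str],
    categorical: Sequence[str],
) -> tuple[np.ndarray, list[str]]:
    """Fixed part of the design: intercept, d, then reference-coded covariates.

    The f and d*f columns are appended by the callers (they vary per feature
    or per voxel). Categorical covariates are reference-coded against their
    first (sorted) level.
    """
    n = len(frame)
    cols: list[np.ndarray] = [np.ones(n), frame[d_col].to_numpy(dtype=float)]
    names: list[str] = ["intercept", d_col]
    for cov in covariates:
        if cov in categorical:
            dummies = pd.get_dummies(frame[cov], prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(str(c))
        else:
            cols.append(frame[cov].to_numpy(dtype=float))
            names.append(cov)
    return np.column_stack(cols), names


def _check_condition(X: np.ndarray, names: Sequence[str]) -> None:
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        bad = [names[j] for j in np.flatnonzero(norms == 0)]
        raise CollinearityError(bad, f"all-zero design columns: {bad}")
    Xn = X / norms
    cond = np.linalg.cond(Xn)
    if cond > _COND_LIMIT:
        # Name columns with near-zero contribution in the QR factorization.
        _, R = np.linalg.qr(Xn)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in np.flatnonzero(diag < 1e-8 * diag.max())] or list(names)
        raise CollinearityError(
            bad, f"design condition number {cond:.3g} exceeds {_COND_LIMIT:.0e}; "
            f"offending columns: {bad}"
        )


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS via QR: returns beta, se, residual sd, df_resid."""
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    beta = solve_triangular(R, Q.T @ y)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    Rinv = solve_triangular(R, np.eye(p))
    se = np.sqrt(sigma2 * np.sum(Rinv**2, axis=1))
    return beta, se, math.sqrt(sigma2), df


@dataclass
class CompensationFit:
    """Fitted compensation model for one feature x disease-load pair."""

    params: dict[str, float]
    bse: dict[str, float]
    beta3: float
    se_beta3: float
    t_beta3: float
    p_beta3: float
    resid_sd: float
    n: int
    df_resid: int
    disease_load: str
    feature_name: str
    alternative: str = "two-sided"
    design_names: list[str] = field(default_factory=list)

    @property
    def alpha_(self) -> float:
        return self.params["intercept"]

    @property
    def beta1(self) -> float:
        return self.params[self.disease_load]

    @property
    def beta2(self) -> float:
        return self.params[self.feature_name]

    def ci_beta3(self, level: float = 0.95) -> tuple[float, float]:
        q = stats.t.ppf(0.5 + level / 2, self.df_resid)
        return (self.beta3 - q * self.se_beta3, self.beta3 + q * self.se_beta3)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_beta3 <= alpha

    def to_dict(self) -> dict:
        return {
            "params": self.params, "bse": self.bse,
            "beta3": self.beta3, "se_beta3": self.se_beta3,
            "t_beta3": self.t_beta3, "p_beta3": self.p_beta3,
            "resid_sd": self.resid_sd, "n": self.n, "df_resid": self.df_resid,
            "disease_load": self.disease_load, "feature_name": self.feature_name,
            "alternative": self.alternative,
        }


def _prepare_frame(
    table: pd.DataFrame,
    y, f,
    disease_load: str,
    covariates: Sequence[str],
) -> tuple[pd.DataFrame, str, str]:
    frame = table.copy()
    if isinstance(y, str):
        y_col = y
    else:
        frame["_y"] = np.asarray(y, dtype=float)
        y_col = "_y"
    if isinstance(f, str):
        f_col = f
    else:
        frame["_f"] = np.asarray(f, dtype=float)
        f_col = "_f"
    needed = [y_col, f_col, disease_load, *covariates]
    frame = frame[needed + [c for c in frame.columns if c not in needed]]
    complete = frame[needed].notna().all(axis=1)
    return frame.loc[complete], y_col, f_col


def fit_compensation(
    table: pd.DataFrame,
    y,
    f,
    disease_load: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    categorical: Sequence[str] = ("site",),
    alternative: str = "two-sided",
    feature_name: str | None = None,
) -> CompensationFit:
    """Fit the compensation model for one fMRI feature and one disease load.

    Parameters
    ----------
    table:
        Cohort table, one row per subject (complete cases are used; rows with
        missing values in any model variable are dropped).
    y, f:
        Performance outcome and fMRI feature: column names or arrays aligned
        with ``table``.
    disease_load:
        Column holding the volume fraction (e.g. ``"gray_frac"``).
    covariates, categorical:
        Adjustment covariates; those listed in ``categorical`` are
        reference-coded against their first level.
    alternative:
        ``"two-sided"`` (default), ``"greater"`` or ``"less"`` for the beta3
        test.
    """
    frame, y_col, f_col = _prepare_frame(table, y, f, disease_load, covariates)
    Z, names = _design_matrix(frame, disease_load, covariates, categorical)
    d_vals = frame[disease_load].to_numpy(dtype=float)
    f_vals = frame[f_col].to_numpy(dtype=float)
    inter_name = f"{disease_load}:{f_col}"
    X = np.column_stack([Z[:, :2], f_vals, d_vals * f_vals, Z[:, 2:]])
    all_names = names[:2] + [f_col, inter_name] + names[2:]
    n, p = X.shape
    if n < p + 10:
        raise ValueError(f"need n >= parameters + 10 ({p + 10}), got n = {n}")
    _check_condition(X, all_names)
    yv = frame[y_col].to_numpy(dtype=float)
    if np.isnan(yv).any():
        raise MissingDataError("missing values in the outcome after filtering")
    beta, se, resid_sd, df = _ols(X, yv)
    j = all_names.index(inter_name)
    t3 = beta[j] / se[j]
    if alternative == "two-sided":
        p3 = 2 * stats.t.sf(abs(t3), df)
    elif alternative == "greater":
        p3 = stats.t.sf(t3, df)
    elif alternative == "less":
        p3 = stats.t.cdf(t3, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return CompensationFit(
        params=dict(zip(all_names, map(float, beta))),
        bse=dict(zip(all_names, map(float, se))),
        beta3=float(beta[j]), se_beta3=float(se[j]),
        t_beta3=float(t3), p_beta3=float(min(p3, 1.0)),
        resid_sd=resid_sd, n=n, df_resid=df,
        disease_load=disease_load, feature_name=f_col,
        alternative=alternative, design_names=all_names,
    )


# ---------------------------------------------------------------------------
# Voxelwise application
# ---------------------------------------------------------------------------


@dataclass
class VoxelwiseResult:
    """Maps of the interaction test applied per voxel within a mask."""

    t_map: VolumetricImage
    p_map: VolumetricImage  # two-sided p for beta3; 1 outside the mask
    beta2_map: VolumetricImage
    beta3_map: VolumetricImage
    mask: np.ndarray
    n: int
    df_resid: int
    report_threshold: float
    report: pd.DataFrame  # voxels with p < report_threshold

    def min_p_voxel(self) -> tuple[tuple[int, int, int], float]:
        p = np.where(self.mask, self.p_map.data, np.inf)
        ijk = np.unravel_index(np.argmin(p), p.shape)
        return tuple(int(v) for v in ijk), float(p[ijk])


def voxelwise_compensation(
    images: Sequence[VolumetricImage],
    mask: np.ndarray,
    table: pd.DataFrame,
    y,
    disease_load: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    categorical: Sequence[str] = ("site",),
    report_threshold: float = 1e-3,
) -> VoxelwiseResult:
    """Fit the compensation model at every in-mask voxel of the contrast maps.

    ``images`` must align row-for-row with ``table`` (one 3D contrast map per
    subject); at each voxel the map value is the feature f. Output maps are
    in the input geometry; p values are two-sided and voxels with
    p < ``report_threshold`` (default 0.001, uncorrected) are tabulated.
    """
    if len(images) != len(table):
        raise ValueError("one image per table row is required")
    mask = np.asarray(mask, dtype=bool)
    ref = images[0]
    if mask.shape != ref.spatial_shape:
        raise ValueError("mask shape does not match the images")
    if not mask.any():
        raise EmptyRegionError("empty analysis mask")
    for img in images[1:]:
        if not ref.same_geometry(img):
            raise ValueError("images do not share a common geometry")

    frame, y_col, _ = _prepare_frame(
        table.reset_index(drop=True), y, np.zeros(len(table)), disease_load, covariates
    )
    rows = frame.index.to_numpy()
    Z, names = _design_matrix(frame, disease_load, covariates, categorical)
    d_vals = frame[disease_load].to_numpy(dtype=float)
    yv = frame[y_col].to_numpy(dtype=float)
    n = len(rows)
    p_n = Z.shape[1] + 2
    if n < p_n + 10:
        raise ValueError(f"need n >= parameters + 10 ({p_n + 10}), got n = {n}")

    F = np.stack([images[i].data[mask] for i in rows], axis=0)  # (n, n_voxels)
    n_vox = F.shape[1]
    X = np.empty((n, p_n))
    X[:, :2] = Z[:, :2]
    X[:, 4:] = Z[:, 2:]
    j3 = 3  # interaction column index

    b2 = np.empty(n_vox)
    b3 = np.empty(n_vox)
    tv = np.empty(n_vox)
    df = n - p_n
    for v in range(n_vox):
        fv = F[:, v]
        X[:, 2] = fv
        X[:, 3] = d_vals * fv
        beta, se, _, _ = _ols(X, yv)
        b2[v] = beta[2]
        b3[v] = beta[j3]
        tv[v] = beta[j3] / se[j3] if se[j3] > 0 else 0.0
    pv = 2 * stats.t.sf(np.abs(tv), df)

    def to_map(values, fill):
        out = np.full(ref.spatial_shape, fill, dtype=float)
        out[mask] = values
        return VolumetricImage(out, ref.affine, mask=mask)

    t_map = to_map(tv, 0.0)
    p_map = to_map(pv, 1.0)
    idx = np.argwhere(mask)
    sig = pv < report_threshold
    rep_rows = []
    for vi in np.flatnonzero(sig):
        ijk = idx[vi]
        mm = t_map.voxel_to_mm(ijk)[0]
        rep_rows.append({
            "i": int(ijk[0]), "j": int(ijk[1]), "k": int(ijk[2]),
            "x_mm": float(mm[0]), "y_mm": float(mm[1]), "z_mm": float(mm[2]),
            "beta3": float(b3[vi]), "t": float(tv[vi]), "p": float(pv[vi]),
        })
    report = pd.DataFrame(
        rep_rows, columns=["i", "j", "k", "x_mm", "y_mm", "z_mm", "beta3", "t", "p"]
    )
    return VoxelwiseResult(
        t_map=t_map, p_map=p_map,
        beta2_map=to_map(b2, 0.0), beta3_map=to_map(b3, 0.0),
        mask=mask, n=n, df_resid=df,
        report_threshold=report_threshold, report=report,
    )


# ---------------------------------------------------------------------------
# Multiplicity over disease loads, pattern classification
# ---------------------------------------------------------------------------


def bonferroni_disease_load(
    pvalues: Mapping[str, float], alpha: float = 0.05
) -> pd.DataFrame:
    """Pre-planned Bonferroni correction across the disease-load family.

    ``pvalues`` maps disease-load names to the beta3 p-values of one feature
    tested against each load (default family size 4: caudate, putamen, gray,
    white). A load is adjusted-significant iff p <= alpha / m. Both raw and
    adjusted decisions are reported.
    """
    if not pvalues:
        raise ValueError("empty disease-load family")
    m = len(pvalues)
    rows = [
        {
            "disease_load": name,
            "p": float(p),
            "raw_significant": bool(p <= alpha),
            "adjusted_significant": bool(p <= alpha / m),
            "threshold": alpha / m,
        }
        for name, p in pvalues.items()
    ]
    return pd.DataFrame(rows).set_index("disease_load")


@dataclass(frozen=True)
class PatternResult:
    label: str  # "compensatory" | "non-compensatory" | "none"
    slope_high_load: float  # beta2 + beta3 * d_low  (small volume = high load)
    slope_low_load: float  # beta2 + beta3 * d_high
    d_low: float
    d_high: float


def classify_pattern(
    fit: CompensationFit,
    d_low: float | None = None,
    d_high: float | None = None,
    d_values: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> PatternResult:
    """Classify a significant interaction as compensatory or not.

    The performance-activity slope ``beta2 + beta3*d`` is evaluated at the
    extremes of the observed load range (defaults: 10th and 90th percentile
    of d; note d is a volume, so LOW d means HIGH disease load). A pattern is
    *compensatory* when the slope at high load exceeds the slope at low load
    and is positive (the brain-behavior coupling strengthens, and stays
    performance-supporting, as atrophy accumulates); it is *non-compensatory*
    when the slope weakens with load or is negative at high load; with a
    non-significant beta3 the label is "none".
    """
    if d_low is None or d_high is None:
        if d_values is None:
            raise ValueError("provide d_low/d_high or the observed d_values")
        d_low = float(np.percentile(d_values, 10))
        d_high = float(np.percentile(d_values, 90))
    if not d_low < d_high:
        raise ValueError("need d_low < d_high")
    s_high_load = fit.beta2 + fit.beta3 * d_low
    s_low_load = fit.beta2 + fit.beta3 * d_high
    if not fit.significant(alpha):
        label = "none"
    elif s_high_load > s_low_load and s_high_load > 0:
        label = "compensatory"
    else:
        label = "non-compensatory"
    return PatternResult(label, float(s_high_load), float(s_low_load),
                         float(d_low), float(d_high))


# ---------------------------------------------------------------------------
# Conditioning-plot (coplot) intervals
# ---------------------------------------------------------------------------


@dataclass
class CoplotSpec:
    """Equal-count overlapping intervals of the conditioning variable.

    ``intervals`` are (lower, upper) d-values; ``index_sets`` the original
    observation indices falling in each; slopes/intercepts are per-interval
    least-squares fits of y on f for display only (never inference).
    """

    intervals: list[tuple[float, float]]
    index_sets: list[np.ndarray]
    target_count: float
    overlap: float
    slopes: list[float] | None = None
    intercepts: list[float] | None = None

    @property
    def k(self) -> int:
        return len(self.intervals)

    def counts(self) -> list[int]:
        return [len(s) for s in self.index_sets]

    def to_json(self) -> str:
        return json.dumps(
            {
                "intervals": [[lo, hi] for lo, hi in self.intervals],
                "index_sets": [s.tolist() for s in self.index_sets],
                "target_count": self.target_count,
                "overlap": self.overlap,
                "slopes": self.slopes,
                "intercepts": self.intercepts,
            },
            indent=2,
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def coplot_intervals(
    d: Sequence[float],
    k: int,
    overlap: float = 0.5,
    y: Sequence[float] | None = None,
    f: Sequence[float] | None = None,
) -> CoplotSpec:
    """Equal-count algorithm for conditioning-plot intervals.

    Produces ``k`` ordered intervals of d such that approximately the same
    number of observations lies in each interval and approximately
    ``overlap`` of each interval's observations is shared with the next. The
    target per-interval count is ``m = n / (k*(1-overlap) + overlap)``;
    interval j spans sorted ranks ``round((j-1)*m*(1-overlap))`` through that
    start plus ``ceil(m) - 1``, clipped to the data. With ``overlap=0`` this
    is an ordinary equal-count partition.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if n < 2 * k:
        raise ValueError(f"too few observations: n={n} < 2k={2 * k}")
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    m = n / (k * (1 - overlap) + overlap)
    size = math.ceil(m)
    intervals: list[tuple[float, float]] = []
    index_sets: list[np.ndarray] = []
    for j in range(1, k + 1):
        start = _round_half_up((j - 1) * m * (1 - overlap))
        start = max(0, min(start, n - 1))
        end = min(start + size - 1, n - 1)
        intervals.append((float(d_sorted[start]), float(d_sorted[end])))
        index_sets.append(order[start : end + 1].copy())

    slopes = intercepts = None
    if y is not None and f is not None:
        y = np.asarray(y, dtype=float)
        f = np.asarray(f, dtype=float)
        slopes, intercepts = [], []
        for idx in index_sets:
            coef = np.polyfit(f[idx], y[idx], 1)
            slopes.append(float(coef[0]))
            intercepts.append(float(coef[1]))
    return CoplotSpec(
        intervals=intervals, index_sets=index_sets,
        target_count=float(m), overlap=float(overlap),
        slopes=slopes, intercepts=intercepts,
    )
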