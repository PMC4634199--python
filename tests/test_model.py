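"""Compensation model: OLS fits, voxelwise maps, multiplicity, coplots."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from compmap import (
    CompensationFit,
    VolumetricImage,
    bonferroni_disease_load,
    classify_pattern,
    coplot_intervals,
    default_affine,
    fit_compensation,
    voxelwise_compensation,
)
from compmap.errors import CollinearityError, EmptyRegionError


# ---------------------------------------------------------------------------
# fit_compensation
# ---------------------------------------------------------------------------


def test_noiseless_coefficients_recovered_exactly(carriers):
    """With zero noise the OLS fit returns the generating coefficients."""
    d = carriers["gray_frac"].to_numpy()
    f = carriers["latent_task_f"].to_numpy()
    y = (
        1.5 - 2.0 * d + 0.8 * f + 3.0 * d * f
        + 0.01 * carriers["age"].to_numpy()
        - 0.2 * carriers["gender"].to_numpy()
        + 0.05 * carriers["education"].to_numpy()
        + 0.3 * carriers["cpo"].to_numpy()
    )
    fit = fit_compensation(carriers, y=y, f=f, disease_load="gray_frac")
    assert fit.alpha_ == pytest.approx(1.5, abs=1e-8)
    assert fit.beta1 == pytest.approx(-2.0, abs=1e-8)
    assert fit.beta2 == pytest.approx(0.8, abs=1e-8)
    assert fit.beta3 == pytest.approx(3.0, abs=1e-8)
    assert fit.resid_sd == pytest.approx(0.0, abs=1e-7)


def test_fit_matches_statsmodels_oracle(carriers):
    """beta3, its SE, t and p agree with a statsmodels formula fit."""
    smf = pytest.importorskip("statsmodels.formula.api")
    rng = np.random.default_rng(5)
    df = carriers.copy()
    df["feat"] = rng.standard_normal(len(df))
    df["yy"] = rng.standard_normal(len(df))
    fit = fit_compensation(df, y="yy", f="feat", disease_load="gray_frac")
    res = smf.ols(
        "yy ~ gray_frac * feat + age + gender + C(site) + education + cpo", data=df
    ).fit()
    assert fit.beta3 == pytest.approx(res.params["gray_frac:feat"], abs=1e-8)
    assert fit.se_beta3 == pytest.approx(res.bse["gray_frac:feat"], abs=1e-8)
    assert fit.t_beta3 == pytest.approx(res.tvalues["gray_frac:feat"], abs=1e-8)
    assert fit.p_beta3 == pytest.approx(res.pvalues["gray_frac:feat"], abs=1e-10)
    assert fit.params["intercept"] == pytest.approx(res.params["Intercept"], abs=1e-8)


def test_interaction_test_invariant_to_centering_and_scaling(carriers):
    """t and p for beta3 are unchanged by centering d or rescaling f."""
    rng = np.random.default_rng(8)
    df = carriers.copy()
    f = rng.standard_normal(len(df))
    y = rng.standard_normal(len(df)) + 0.5 * f * df["gray_frac"].to_numpy()
    base = fit_compensation(df, y=y, f=f, disease_load="gray_frac")

    centered = df.copy()
    centered["gray_frac"] = centered["gray_frac"] - centered["gray_frac"].mean()
    fit_c = fit_compensation(centered, y=y, f=f, disease_load="gray_frac")
    assert fit_c.t_beta3 == pytest.approx(base.t_beta3, abs=1e-8)
    assert fit_c.p_beta3 == pytest.approx(base.p_beta3, abs=1e-10)

    fit_s = fit_compensation(df, y=y, f=3.7 * f - 1.2, disease_load="gray_frac")
    assert fit_s.t_beta3 == pytest.approx(base.t_beta3, abs=1e-8)
    assert fit_s.p_beta3 == pytest.approx(base.p_beta3, abs=1e-10)


def test_one_sided_alternatives(carriers):
    rng = np.random.default_rng(9)
    f = rng.standard_normal(len(carriers))
    y = rng.standard_normal(len(carriers))
    two = fit_compensation(carriers, y=y, f=f, disease_load="gray_frac")
    less = fit_compensation(carriers, y=y, f=f, disease_load="gray_frac",
                            alternative="less")
    greater = fit_compensation(carriers, y=y, f=f, disease_load="gray_frac",
                               alternative="greater")
    assert less.p_beta3 + greater.p_beta3 == pytest.approx(1.0)
    assert min(less.p_beta3, greater.p_beta3) == pytest.approx(two.p_beta3 / 2)


def test_collinear_feature_rejected(carriers):
    with pytest.raises(CollinearityError):
        fit_compensation(carriers, y="vwm_performance",
                         f=carriers["gray_frac"].to_numpy(),  # f == d
                         disease_load="gray_frac")


def test_too_few_subjects_rejected(carriers):
    tiny = carriers.iloc[:12]
    with pytest.raises(ValueError, match="n >= parameters"):
        fit_compensation(tiny, y="vwm_performance", f="latent_task_f",
                         disease_load="gray_frac")


def test_complete_case_filtering(carriers):
    df = carriers.copy().reset_index(drop=True)
    df.loc[3, "vwm_performance"] = np.nan
    df.loc[7, "cpo"] = np.nan
    fit = fit_compensation(df, y="vwm_performance", f="latent_task_f",
                           disease_load="gray_frac")
    assert fit.n == len(df) - 2


# ---------------------------------------------------------------------------
# voxelwise_compensation
# ---------------------------------------------------------------------------


def _toy_images(rng, n, shape=(5, 4, 3)):
    aff = default_affine(shape, 4.0)
    return [VolumetricImage(rng.standard_normal(shape), aff) for _ in range(n)]


def test_single_voxel_mask_reduces_to_fit_compensation(carriers, rng):
    images = _toy_images(rng, len(carriers))
    mask = np.zeros((5, 4, 3), bool)
    mask[2, 1, 1] = True
    vw = voxelwise_compensation(images, mask, carriers, y="vwm_performance",
                                disease_load="gray_frac")
    f = np.array([img.data[2, 1, 1] for img in images])
    fit = fit_compensation(carriers, y="vwm_performance", f=f,
                           disease_load="gray_frac")
    assert vw.t_map.data[2, 1, 1] == pytest.approx(fit.t_beta3, abs=1e-10)
    assert vw.p_map.data[2, 1, 1] == pytest.approx(fit.p_beta3, abs=1e-12)
    assert vw.beta3_map.data[2, 1, 1] == pytest.approx(fit.beta3, abs=1e-10)


def test_voxelwise_matches_pinv_oracle(carriers, rng):
    """Every in-mask voxel equals an independent pseudoinverse regression."""
    from compmap.validation import _pinv_oracle_maps

    images = _toy_images(rng, len(carriers))
    mask = rng.random((5, 4, 3)) < 0.5
    vw = voxelwise_compensation(images, mask, carriers, y="vwm_performance",
                                disease_load="gray_frac")
    b3_o, t_o, _ = _pinv_oracle_maps(images, mask, carriers,
                                     "vwm_performance", "gray_frac")
    np.testing.assert_allclose(vw.t_map.data[mask], t_o, atol=1e-8)
    np.testing.assert_allclose(vw.beta3_map.data[mask], b3_o, atol=1e-8)


def test_voxelwise_error_handling(carriers, rng):
    images = _toy_images(rng, len(carriers))
    with pytest.raises(EmptyRegionError):
        voxelwise_compensation(images, np.zeros((5, 4, 3), bool), carriers,
                               y="vwm_performance", disease_load="gray_frac")
    with pytest.raises(ValueError, match="one image per table row"):
        voxelwise_compensation(images[:-1], np.ones((5, 4, 3), bool), carriers,
                               y="vwm_performance", disease_load="gray_frac")


# ---------------------------------------------------------------------------
# bonferroni_disease_load
# ---------------------------------------------------------------------------


def test_bonferroni_survival_split():
    """With m=4 and alpha 0.05: p=0.010 survives, p=0.019 does not."""
    res = bonferroni_disease_load(
        {"gray_frac": 0.010, "white_frac": 0.019,
         "caudate_frac": 0.2, "putamen_frac": 0.7}
    )
    assert bool(res.loc["gray_frac", "adjusted_significant"]) is True
    assert bool(res.loc["white_frac", "adjusted_significant"]) is False
    assert bool(res.loc["white_frac", "raw_significant"]) is True
    assert res["threshold"].unique() == pytest.approx(0.0125)


def test_bonferroni_single_family_equals_raw():
    res = bonferroni_disease_load({"gray_frac": 0.04})
    assert bool(res.loc["gray_frac", "adjusted_significant"]) is True
    assert (res["raw_significant"] == res["adjusted_significant"]).all()


def test_bonferroni_empty_family_rejected():
    with pytest.raises(ValueError):
        bonferroni_disease_load({})


# ---------------------------------------------------------------------------
# classify_pattern
# ---------------------------------------------------------------------------


def _fit(beta2, beta3, p=1e-4, load="gray_frac", feat="f"):
    return CompensationFit(
        params={"intercept": 0.0, load: 0.0, feat: beta2, f"{load}:{feat}": beta3},
        bse={}, beta3=beta3, se_beta3=1.0, t_beta3=beta3, p_beta3=p,
        resid_sd=1.0, n=100, df_resid=90, disease_load=load, feature_name=feat,
    )


def test_pattern_positive_slope_strengthening_with_load_is_compensatory():
    """beta3<0 with slope positive at small volume, ~0 at large volume."""
    res = classify_pattern(_fit(5.0, -10.0), d_low=0.40, d_high=0.50)
    assert res.label == "compensatory"
    assert res.slope_high_load > res.slope_low_load > -1e-12
    assert res.slope_high_load > 0


def test_pattern_negative_slope_at_high_load_is_non_compensatory():
    """beta3>0 with a negative slope at small volume (high load)."""
    res = classify_pattern(_fit(-5.0, 10.0), d_low=0.40, d_high=0.50)
    assert res.label == "non-compensatory"
    assert res.slope_high_load < 0


def test_pattern_nonsignificant_interaction_is_none():
    res = classify_pattern(_fit(1.0, -10.0, p=0.5), d_low=0.40, d_high=0.50)
    assert res.label == "none"


def test_pattern_percentile_defaults():
    d = np.linspace(0.40, 0.50, 101)
    res = classify_pattern(_fit(6.0, -12.0), d_values=d)
    assert res.d_low == pytest.approx(0.41)
    assert res.d_high == pytest.approx(0.49)
    assert res.label == "compensatory"


def test_pattern_joint_negation_swaps_labels():
    """Negating (f, beta2, beta3) flips compensatory <-> non-compensatory:
    the sign of the performance-activity relationship is part of the
    definition, so relabelling the feature axis flips the call."""
    a = classify_pattern(_fit(6.0, -12.0), d_low=0.40, d_high=0.50)
    b = classify_pattern(_fit(-6.0, 12.0), d_low=0.40, d_high=0.50)
    assert a.label == "compensatory"
    assert b.label == "non-compensatory"
    assert b.slope_high_load == pytest.approx(-a.slope_high_load)


# ---------------------------------------------------------------------------
# coplot_intervals
# ---------------------------------------------------------------------------


def test_coplot_disjoint_partition_case(rng):
    d = rng.standard_normal(12)
    spec = coplot_intervals(d, k=3, overlap=0.0)
    assert spec.counts() == [4, 4, 4]
    all_idx = np.concatenate(spec.index_sets)
    assert len(set(all_idx.tolist())) == 12
    d_sorted = np.sort(d)
    assert spec.intervals[0] == (d_sorted[0], d_sorted[3])
    assert spec.intervals[2] == (d_sorted[8], d_sorted[11])


def test_coplot_equal_count_and_overlap_properties(rng):
    """n=100, k=4, overlap 0.5: counts 40 +/- 1, shared points 20 +/- 2."""
    d = rng.uniform(0, 1, 100)
    spec = coplot_intervals(d, k=4, overlap=0.5)
    m = 100 / (4 * 0.5 + 0.5)
    assert spec.target_count == pytest.approx(m)
    for c in spec.counts():
        assert abs(c - m) <= 1
    for j in range(3):
        shared = set(spec.index_sets[j].tolist()) & set(spec.index_sets[j + 1].tolist())
        assert abs(len(shared) - m * 0.5) <= 2


def test_coplot_single_interval_matches_global_regression(rng):
    d = rng.uniform(0, 1, 30)
    f = rng.standard_normal(30)
    y = 2.0 * f + rng.standard_normal(30)
    spec = coplot_intervals(d, k=1, overlap=0.5, y=y, f=f)
    assert spec.counts() == [30]
    slope, intercept = np.polyfit(f, y, 1)
    assert spec.slopes[0] == pytest.approx(slope)
    assert spec.intercepts[0] == pytest.approx(intercept)


def test_coplot_too_few_observations(rng):
    with pytest.raises(ValueError, match="too few"):
        coplot_intervals(rng.standard_normal(7), k=4)


@given(
    n=st.integers(10, 150),
    k=st.integers(1, 5),
    overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    seed=st.integers(0, 2**16),
)
def test_coplot_properties_hold_generally(n, k, overlap, seed):
    """Union covers all points; counts near target; intervals ordered."""
    if n < 2 * k:
        return
    d = np.random.default_rng(seed).standard_normal(n)
    spec = coplot_intervals(d, k=k, overlap=overlap)
    union = np.unique(np.concatenate(spec.index_sets))
    assert np.array_equal(union, np.arange(n))
    m = spec.target_count
    for c in spec.counts():
        assert abs(c - m) <= 2
    lowers = [lo for lo, _ in spec.intervals]
    assert lowers == sorted(lowers)
    json_spec = spec.to_json()
    assert '"target_count"' in json_spec
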