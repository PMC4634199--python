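"""Fit the compensation model at the planted voxel, across disease loads.

The moderated regression y = alpha + b1*d + b2*f + b3*d*f + gamma*c + e is
fitted once per structural disease-load measure (caudate, putamen, gray,
white volume fractions); the interaction p-values then receive the
pre-planned Bonferroni correction over that four-member family, and each fit
is classified as compensatory or not from the sign and ordering of the
slope b2 + b3*d at the extremes of the observed load range.
"""

import numpy as np

from compmap import (
    DISEASE_LOADS,
    CohortSpec,
    GroundTruth,
    bonferroni_disease_load,
    classify_pattern,
    fit_compensation,
    generate_cohort_table,
    generate_task_contrast_images,
    records_to_frame,
)

spec = CohortSpec(n_carriers=100, n_controls=1)
truth = GroundTruth(seed=21)
records = generate_cohort_table(spec, truth)
frame = records_to_frame(records)
carriers = frame[frame["group"] == "preHD"].reset_index(drop=True)

images = generate_task_contrast_images(records, spec, truth)
ijk = images[0].nearest_voxel(truth.compensation_coord)
f = np.array([img.data[ijk] for img, r in zip(images, records) if r.group == "preHD"])

pvals = {}
print(f"planted: beta3 = {truth.beta3} on {truth.load_name}\n")
for load in DISEASE_LOADS:
    fit = fit_compensation(carriers, y="vwm_performance", f=f, disease_load=load)
    pattern = classify_pattern(fit, d_values=carriers[load])
    pvals[load] = fit.p_beta3
    print(f"{load:13s} beta3 = {fit.beta3:+9.2f} +/- {fit.se_beta3:6.2f}   "
          f"p = {fit.p_beta3:.2e}   pattern: {pattern.label}")

print("\npre-planned Bonferroni over the 4 disease loads:")
print(bonferroni_disease_load(pvals).to_string())
print("\n  -> the generating load shows the strongest interaction; the other")
print("     loads co-vary with it through CPO and carry attenuated versions.")
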