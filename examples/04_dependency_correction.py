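"""Modelling and removing a feature's dependence on bin width.

Eight invertible forms f(x) = a*g(x) + b are fitted to the cohort mean
curve by variance-weighted robust regression; the AIC-best form is
inverted per subject: f_corrected(x) = (f(x) - b) / g(x).
"""

import radrobust as rr

grid = rr.build_parameter_grid("discretisation", "FBW")
spec = rr.SyntheticCohortSpec(
    n_subjects=25,
    grid=grid,
    features=(("glcm_like", rr.DependencyProfile(rr.FunctionId.INV, 2.0, 5.0)),),
    intercept_sd=0.03,
    slope_sd=0.01,
    noise_sd=0.02,
    seed=3,
)
table = rr.generate_cohort(spec)
result = rr.correct_feature(table, "glcm_like", grid)

print("AIC per candidate form (lower is better):")
for fid, aic in result.all_aics.items():
    marker = " <- selected" if fid == result.best_model.function_id.value else ""
    print(f"  {fid:>7}: {aic:9.1f}{marker}")
print(
    f"\nfitted f(x) = {result.best_model.alpha:.3f} * g(x) + "
    f"{result.best_model.beta:.3f}"
)
print(
    f"CV_mean : {result.metrics_before.cv_mean:6.2f} % -> "
    f"{result.metrics_after.cv_mean:6.2f} %"
)
print(
    f"|r_rm|  : {result.metrics_before.rrm_abs:6.3f}  -> "
    f"{result.metrics_after.rrm_abs:6.3f}"
)
print(
    f"Wilcoxon p = {result.wilcoxon_p:.2e}, CI overlap = {result.ci_overlap}"
)
print(f"category: {result.category.value}")
print(
    "\n'correctable' means the correction reduced both metrics "
    "significantly and the\ncorrected feature meets the robust criteria."
)
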