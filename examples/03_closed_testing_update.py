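"""Run the closed testing procedure on a miscalibrated cohort.

Generates a cohort whose true risk is shifted by +1.5 log-odds relative to
the published model (systematic under-prediction), then lets the CTP decide
how much updating the model needs.
"""

from ntcpvalid import (
    CohortRecipe,
    MiscalibrationSpec,
    ctp_select,
    generate_cohort,
    load_nipp_model,
)

model = load_nipp_model()
recipe = CohortRecipe(
    n=3000, seed=7, miscalibration=MiscalibrationSpec(delta_intercept=1.5)
)
cohort = generate_cohort(recipe)
result = ctp_select(model, cohort, alpha_sig=0.05)

print("level                    log-lik   free params")
for level, fit in result.fits.items():
    print(f"{level:24s} {fit.log_lik:9.2f}   {fit.n_free_params}")
print()
print("LR tests against the revision:")
for test in result.tests:
    flag = "" if test.used else "  (past stopping point)"
    print(
        f"  {test.comparison[0]:24s} X2 = {test.statistic:7.2f}, "
        f"df = {test.df}, p = {test.p_value:.3g}{flag}"
    )
print()
print(f"selected level: {result.selected}")
alpha = result.fits["intercept_update"].alpha
print(f"fitted calibration intercept: {alpha:.3f} (truth: 1.5)")
print()
print("The CTP detects the intercept-only departure and stops at")
print("re-calibration in the large instead of refitting all coefficients.")
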