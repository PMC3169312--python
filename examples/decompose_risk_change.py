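"""Attribute a risk change to individual risk factors.

Under the SCORE proportional-hazards form, a change delta in one factor
multiplies the cumulative hazard by exp(beta * delta).  This closed form
gives the risk ratio a single factor's observed change would produce on its
own; the per-patient counterfactual re-scores the cohort with only that
factor advanced to follow-up and cross-checks the closed form.
"""

from scorerisk import (
    CHD_COEFFICIENTS,
    CohortSpec,
    build_model,
    cohort_counterfactual_rr,
    generate,
    single_factor_rr,
)

# observed mean six-week changes in a statin add-on cohort
sbp_change = -3.75  # mmHg
tc_change = 4.40 - 5.60  # mmol/L

rr_sbp = single_factor_rr("sbp", sbp_change, CHD_COEFFICIENTS)
rr_tc = single_factor_rr("tc", tc_change, CHD_COEFFICIENTS)
print(f"SBP change of {sbp_change:+.2f} mmHg alone:  "
      f"CHD RR = {rr_sbp:.3f} ({100 * (1 - rr_sbp):.1f}% risk reduction)")
print(f"TC change of {tc_change:+.2f} mmol/L alone: "
      f"CHD RR = {rr_tc:.2f} ({100 * (1 - rr_tc):.1f}% risk reduction)")
print()
print("The cholesterol change drives most of the risk reduction; the")
print("blood-pressure change contributes a further ~6.5%.")

cohort, _ = generate(CohortSpec(seed=42))
model = build_model("low_risk")
print()
print("per-patient counterfactual cross-check (synthetic cohort):")
for factor in ("sbp", "tc"):
    rr = cohort_counterfactual_rr(cohort, model, factor, endpoint="chd")
    print(f"  only {factor} advanced to follow-up: mean CHD risk ratio {rr:.3f}")
print("The counterfactual ratios agree with the closed form to first order;")
print("risk-scale convexity leaves them slightly closer to 1.")
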