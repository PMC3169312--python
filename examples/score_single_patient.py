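"""Estimate one patient's 10-year fatal cardiovascular risk.

A 62-year-old male smoker with total cholesterol 5.60 mmol/L and systolic
blood pressure 132 mmHg, scored with the low-risk-region SCORE calibration.
"""

from scorerisk import RiskProfile, build_model, score_risk

model = build_model("low_risk")
profile = RiskProfile(age=62, sex="male", smoker=True, sbp=132, tc=5.60)
est = score_risk(profile, model)

print(f"CHD mortality risk:       {est.chd_risk:.4f} ({100 * est.chd_risk:.2f}%)")
print(f"non-CHD CVD risk:         {est.non_chd_risk:.4f} ({100 * est.non_chd_risk:.2f}%)")
print(f"total CVD mortality risk: {est.total_cvd_risk:.4f} ({100 * est.total_cvd_risk:.2f}%)")
print()
print("The total is the sum of the two fatal-endpoint risks: this patient has")
print(f"about a {100 * est.total_cvd_risk:.1f}% chance of dying of cardiovascular")
print("disease within 10 years if nothing changes.")
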