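# Methods

## Risk model

The SCORE model estimates an individual's 10-year risk of a fatal
cardiovascular event from age, sex, current smoking, systolic blood
pressure (SBP, mmHg) and total cholesterol (TC, mmol/L). It consists of
two parallel Weibull proportional-hazards components — fatal coronary
heart disease (CHD) and fatal non-coronary cardiovascular disease — whose
10-year risks are summed into the total CVD mortality risk. Per endpoint:

- baseline survival `S0(a) = exp(−exp(α)(a − 20)^p)` with sex- and
  region-specific location α and shape p (the model's age domain starts at
  20, where S0 = 1);
- linear predictor `w = β_chol(TC − 6) + β_SBP(SBP − 120) + β_smoker·smoker`,
  zero at the reference profile (non-smoker, TC 6 mmol/L, SBP 120 mmHg);
- individual survival `S(a) = S0(a)^exp(w)` and 10-year risk
  `1 − S(a+10)/S(a)`.

Parameter sets for both the low-risk and high-risk European calibrations
ship with the package (`parameters.py`); the betas are shared between
regions and sexes, so any quantity depending only on betas (notably the
single-factor decomposition) is region-independent. The default region is
`low_risk`; it is an explicit analysis setting because absolute calibration
for a North American cohort is genuinely ambiguous. Coefficients are
package data but can be overridden through `build_model` for sensitivity
analysis.

Model assumptions worth keeping in view: risks are *predicted* mortality
under a European-derived calibration, not observed events; diabetes and
the metabolic syndrome do not enter the risk equation (they are
stratification flags only); smoking is treated as fixed between visits;
age enters as a real number, with no rounding to chart bands (the classic
SCORE charts round — chart-cell comparisons must band explicitly). Ages
above 90 are accepted with an extrapolation warning rather than rejected.

## Cohort analysis

The analysis unit is a patient with paired baseline/follow-up SBP and TC,
fixed age, sex and smoking, and physician-assigned comorbidity flags
(consumed as given, never derived from the measurements). Patients missing
any paired measurement are excluded before analysis and counted
(complete-case accounting: n input / excluded / analyzed).

For each of five overlapping groups (total, hypertension, diabetes,
metabolic syndrome, smokers) and each variable (SBP, TC, CHD risk, total
CVD risk):

- absolute change = follow-up − baseline, with mean, SD, a t-distribution
  CI (n−1 df) and a paired Student t test;
- percent change = the **mean of per-patient fractional changes**
  `(f_i − b_i)/b_i`, not the ratio of group means. The two differ
  materially in skewed risk distributions, and published change tables in
  this study design are consistent only with the per-patient average.

Zero-variance differences (identity cohorts) yield a flagged degenerate
result (t and p undefined) rather than an error; single-patient groups
likewise get defined means with NaN dispersion. Empty subgroups produce
absent cells, never zeros.

Mean 10-year risk r̄ is converted to an estimated death rate by uniform
spreading over the horizon: `r̄ × 100,000 / 10` deaths per 100,000
person-years. The follow-up/baseline rate ratio gets a log-scale CI with
`SE = sqrt(1/d_f + 1/d_b)`, treating the per-100,000-PY figures as Poisson
counts. This convention is an estimation convenience, not a claim that the
rates are observed counts; it reproduces published CI bounds for this
design to within ±0.002 per bound.

## Decomposition

Because `−ln S` scales by `exp(βΔ)` exactly when one factor moves by Δ,
the risk ratio attributable to a single factor's change is `exp(β·Δ)` —
exact on the cumulative-hazard scale and first-order on the risk scale.
The closed form at the cohort's mean change is the primary output. A
per-patient counterfactual (re-score every patient with only that factor
advanced to follow-up; ratio of mean risks) serves as a cross-check. At
study-scale deltas (TC ≈ −1.2 mmol/L) the two differ by a few hundredths,
the per-patient form sitting closer to 1: risk-scale convexity and
between-patient heterogeneity are second-order effects the hazard-scale
form ignores. Smoking is excluded from decomposition (assumed unchanged
over a six-week follow-up).

## Synthetic cohort generator

The generator (`simulate.py`) emulates the marginal structure of an
825-patient statin add-on cohort: 62.3% male; age truncated-normal
62 (10.5) on [21, 89]; independent Bernoulli comorbidity flags at
prevalences 0.513 / 0.415 / 0.479 / 0.228 (hypertension, diabetes,
metabolic syndrome, smoking); normal baseline SBP 132.0 (14.0) mmHg and TC
5.60 (1.00) mmol/L; normal six-week changes −3.75 (13.3) mmHg and
−1.18 (0.89) mmol/L; follow-up = baseline + change.

Subgroup heterogeneity is reproduced by an additive per-flag effect model.
With independent flags `F_f ~ Bernoulli(prev_f)` and
`value_i = c0 + Σ_f c_f F_if + noise`, requiring the whole-sample mean m0
and every subgroup mean m_f gives `c_f = (m_f − m0)/(1 − prev_f)` and
`c0 = m0 − Σ prev_f c_f`. This matches all five group means in
expectation simultaneously, despite overlapping membership. Per-patient
noise uses the whole-sample SD (subgroup-specific SDs are close and
under-identified from marginal summaries).

Draws are clipped to plausibility floors (SBP ≥ 80 mmHg, TC ≥ 2.0 mmol/L)
rather than redrawn, with clip counts logged. At default conditions ~3% of
follow-up TC values hit the floor, which deflates the realized TC-change
SD slightly (≈0.88 marginal vs the nominal 0.89 conditional) and shifts
its mean by ≈+0.02–0.04; parameter-recovery checks therefore compare
against the generator's true clipped moments (estimated from a large
reference draw) rather than the nominal inputs.

What the generator does **not** emulate: comorbidity correlation (only
marginals are known; real flags are positively correlated),
baseline–change covariance (no regression to the mean), dropout, and any
lipid fractions beyond TC. Consequently, pipeline tests on synthetic data
demonstrate the estimation arithmetic and its invariances, not clinical
effect sizes: absolute mean risks on the synthetic cohort differ from any
real cohort's, while ratio-type outputs (RRs, decompositions) are
structurally faithful.

## Numerical and testing choices

- All statistics use scipy (paired t, t/normal quantiles); test oracles
  are independent direct-formula evaluations.
- The hazard-ratio identity is asserted at relative 1e−9 where the 10-year
  cumulative hazard exceeds 1e−6; below that, cancellation in
  `1 − S^exp(w)` limits verifiable precision.
- Stochastic tests are seeded and sized for one CPU: property suites use a
  few hundred random profiles; parameter recovery runs 20 cohorts of
  n = 825 against a 300,000-row reference draw. Per-seed bounds use a
  Bonferroni-adjusted 4.2σ guard (80 simultaneous checks), with the
  calibrated 3 SE recovery criterion applied to the 20-seed average; the
  SE of a sample SD uses the fourth-moment formula since clipping makes
  the change distribution non-normal.
- Report CSVs are deterministic (fixed column/group order, LF endings,
  decimal point) with a rounding profile of risks to 3 decimals, rates to
  integers, ratios to 3 decimals; full precision is kept internally.
- Cohort CSVs round-trip losslessly (full float precision on write).

## Limitations

The package reproduces estimation arithmetic: a change in predicted risk
is not evidence of a treatment effect on mortality. The rate conversion
assumes the 10-year risk spreads uniformly over the horizon, and the
Poisson CI convention treats estimated rates as counts; both are
conventions of the study design being mirrored, adopted for
comparability. The SCORE calibrations are European; applying either
region's parameters elsewhere is an acknowledged extrapolation.
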