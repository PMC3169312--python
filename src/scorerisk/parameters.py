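"""Published SCORE parameter sets.

Values transcribed from the SCORE project's coefficient table (Conroy et
al., "Estimation of ten-year risk of fatal cardiovascular disease in
Europe: the SCORE project", Eur Heart J 2003;24:987-1003, Appendix A).
Weibull baseline-survival parameters (alpha, p) differ by endpoint, sex
and calibration region; the risk-factor betas differ by endpoint only.

These are package data, not user input, but ``build_model`` accepts
overrides for sensitivity analysis.
"""

from __future__ import annotations

from .model import (
    BaselineSurvivalParams,
    Endpoint,
    EndpointCoefficients,
    Region,
    SCOREModel,
    Sex,
)

__all__ = ["CHD_COEFFICIENTS", "NON_CHD_COEFFICIENTS", "BASELINE_PARAMS", "build_model"]

# Per-endpoint log-hazard coefficients: cholesterol (per mmol/L),
# SBP (per mmHg), current smoking.  Shared across sexes and regions.
CHD_COEFFICIENTS = EndpointCoefficients(beta_chol=0.24, beta_sbp=0.018, beta_smoker=0.71)
NON_CHD_COEFFICIENTS = EndpointCoefficients(beta_chol=0.02, beta_sbp=0.022, beta_smoker=0.63)

# (region, endpoint, sex) -> Weibull (alpha, p)
BASELINE_PARAMS = {
    (Region.LOW_RISK, Endpoint.CHD, Sex.MALE): BaselineSurvivalParams(-22.1, 4.71),
    (Region.LOW_RISK, Endpoint.CHD, Sex.FEMALE): BaselineSurvivalParams(-29.8, 6.36),
    (Region.LOW_RISK, Endpoint.NON_CHD_CVD, Sex.MALE): BaselineSurvivalParams(-26.7, 5.64),
    (Region.LOW_RISK, Endpoint.NON_CHD_CVD, Sex.FEMALE): BaselineSurvivalParams(-31.0, 6.62),
    (Region.HIGH_RISK, Endpoint.CHD, Sex.MALE): BaselineSurvivalParams(-21.0, 4.62),
    (Region.HIGH_RISK, Endpoint.CHD, Sex.FEMALE): BaselineSurvivalParams(-28.7, 6.23),
    (Region.HIGH_RISK, Endpoint.NON_CHD_CVD, Sex.MALE): BaselineSurvivalParams(-25.7, 5.47),
    (Region.HIGH_RISK, Endpoint.NON_CHD_CVD, Sex.FEMALE): BaselineSurvivalParams(-30.0, 6.42),
}


def build_model(
    region: Region | str = Region.LOW_RISK,
    *,
    baseline_overrides: dict | None = None,
    coefficient_overrides: dict | None = None,
) -> SCOREModel:
    """Assemble a :class:`SCOREModel` for one calibration region.

    Parameters
    ----------
    region : Region or str
        ``low_risk`` or ``high_risk`` European calibration.
    baseline_overrides : dict, optional
        (endpoint, sex) -> BaselineSurvivalParams replacements.
    coefficient_overrides : dict, optional
        endpoint -> EndpointCoefficients replacements.
    """
    region = Region(region)
    baseline = {
        (ep, sex): BASELINE_PARAMS[(region, ep, sex)] for ep in Endpoint for sex in Sex
    }
    coefficients = {
        Endpoint.CHD: CHD_COEFFICIENTS,
        Endpoint.NON_CHD_CVD: NON_CHD_COEFFICIENTS,
    }
    if baseline_overrides:
        baseline.update({(Endpoint(e), Sex(s)): v for (e, s), v in baseline_overrides.items()})
    if coefficient_overrides:
        coefficients.update({Endpoint(e): v for e, v in coefficient_overrides.items()})
    return SCOREModel(region=region, baseline=baseline, coefficients=coefficients)
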