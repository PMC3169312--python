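"""SCORE 10-year fatal cardiovascular risk equations.

The SCORE (Systematic COronary Risk Evaluation) model predicts an
individual's 10-year risk of a fatal cardiovascular event from age, sex,
current smoking, systolic blood pressure (SBP, mmHg) and total cholesterol
(TC, mmol/L).  It is built from two parallel Weibull proportional-hazards
components — one for fatal coronary heart disease (CHD) and one for fatal
non-coronary cardiovascular disease — whose 10-year risks are summed to
give the total CVD mortality risk.

For one endpoint the model is

    S0(age) = exp(-exp(alpha) * (age - 20)^p)        baseline survival
    w       = b_chol*(TC - 6) + b_sbp*(SBP - 120) + b_smoker*smoker
    S(age)  = S0(age)^exp(w)                         individual survival
    risk10  = 1 - S(age + 10) / S(age)               10-year risk

with endpoint- and sex-specific (alpha, p) and endpoint-specific betas.
All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Sex",
    "Endpoint",
    "Region",
    "RiskProfile",
    "EndpointCoefficients",
    "BaselineSurvivalParams",
    "SCOREModel",
    "RiskEstimate",
    "baseline_survival",
    "linear_predictor",
    "ten_year_endpoint_risk",
    "score_risk",
]

AGE_FLOOR = 20.0
AGE_SUPPORTED_MAX = 90.0
TC_REFERENCE = 6.0
SBP_REFERENCE = 120.0
HORIZON_YEARS = 10.0


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Endpoint(str, Enum):
    CHD = "chd"
    NON_CHD_CVD = "non_chd_cvd"


class Region(str, Enum):
    LOW_RISK = "low_risk"
    HIGH_RISK = "high_risk"


def _parse_sex(value) -> Sex:
    if isinstance(value, Sex):
        return value
    token = str(value).strip().lower()
    if token in ("male", "m", "1"):
        return Sex.MALE
    if token in ("female", "f", "0"):
        return Sex.FEMALE
    raise ValueError(f"unrecognised sex token {value!r}; expected male/female/M/F/1/0")


@dataclass(frozen=True)
class RiskProfile:
    """One person's SCORE inputs at a single time point.

    Parameters
    ----------
    age : float
        Age in years; the model domain starts at 20.  Ages above 90 are
        accepted with an extrapolation warning.
    sex : Sex or str
        "male"/"female" (also accepts M/F/1/0 tokens).
    smoker : bool
        Current smoker.
    sbp : float
        Systolic blood pressure, mmHg; must be positive.
    tc : float
        Total cholesterol, mmol/L; must be positive.
    """

    age: float
    sex: Sex
    smoker: bool
    sbp: float
    tc: float

    def __post_init__(self):
        object.__setattr__(self, "sex", _parse_sex(self.sex))
        object.__setattr__(self, "smoker", bool(self.smoker))
        if self.age < AGE_FLOOR:
            raise ValueError(
                f"age {self.age} below the SCORE age floor of {AGE_FLOOR:g} years"
            )
        if self.age > AGE_SUPPORTED_MAX:
            warnings.warn(
                f"age {self.age:g} exceeds the supported SCORE domain "
                f"[{AGE_FLOOR:g}, {AGE_SUPPORTED_MAX:g}]; risk is an extrapolation",
                stacklevel=2,
            )
        if not self.sbp > 0:
            raise ValueError("sbp must be positive (mmHg)")
        if not self.tc > 0:
            raise ValueError("tc must be positive (mmol/L)")


@dataclass(frozen=True)
class EndpointCoefficients:
    """Log-hazard coefficients of the SCORE linear predictor for one endpoint."""

    beta_chol: float  # per mmol/L total cholesterol
    beta_sbp: float  # per mmHg systolic blood pressure
    beta_smoker: float  # current smoking indicator

    def __post_init__(self):
        for name in ("beta_chol", "beta_sbp", "beta_smoker"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class BaselineSurvivalParams:
    """Weibull baseline-survival parameters (alpha location, p shape)."""

    alpha: float
    p: float

    def __post_init__(self):
        if not self.p > 0:
            raise ValueError("Weibull shape p must be positive")
        if not np.isfinite(self.alpha):
            raise ValueError("Weibull location alpha must be finite")


@dataclass(frozen=True)
class SCOREModel:
    """Full SCORE parameter set for one calibration region.

    ``baseline`` maps (endpoint, sex) to Weibull parameters; ``coefficients``
    maps endpoint to its risk-factor betas (betas are shared across regions
    and sexes in the published model).
    """

    region: Region
    baseline: dict
    coefficients: dict
    horizon: float = HORIZON_YEARS

    def __post_init__(self):
        for ep in Endpoint:
            for sex in Sex:
                if (ep, sex) not in self.baseline:
                    raise ValueError(f"missing baseline parameters for {(ep, sex)}")
            if ep not in self.coefficients:
                raise ValueError(f"missing coefficients for endpoint {ep}")
        if self.horizon != HORIZON_YEARS:
            raise ValueError("SCORE is a 10-year risk model; horizon must be 10")


@dataclass(frozen=True)
class RiskEstimate:
    """10-year fatal-event risks for one profile: CHD, non-CHD CVD, and total."""

    chd_risk: float
    non_chd_risk: float
    total_cvd_risk: float


def baseline_survival(age, params: BaselineSurvivalParams):
    """Weibull baseline survival S0(age) = exp(-exp(alpha)*(age-20)^p).

    Strictly decreasing in age for age > 20; equals 1 at age 20.
    Accepts scalar or array ``age``.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < AGE_FLOOR):
        raise ValueError(
            f"age below the SCORE age floor of {AGE_FLOOR:g} years: "
            "the baseline survival is defined for age >= 20"
        )
    out = np.exp(-np.exp(params.alpha) * (age - AGE_FLOOR) ** params.p)
    return out if out.ndim else float(out)


def linear_predictor(profile: RiskProfile, coeffs: EndpointCoefficients) -> float:
    """SCORE linear predictor w, zero at the reference profile.

    w = b_chol*(TC - 6) + b_sbp*(SBP - 120) + b_smoker*smoker.
    """
    return (
        coeffs.beta_chol * (profile.tc - TC_REFERENCE)
        + coeffs.beta_sbp * (profile.sbp - SBP_REFERENCE)
        + coeffs.beta_smoker * float(profile.smoker)
    )


def ten_year_endpoint_risk(
    profile: RiskProfile, model: SCOREModel, endpoint: Endpoint
) -> float:
    """10-year risk of the fatal endpoint: 1 - [S0(a+10)/S0(a)]^exp(w)."""
    endpoint = Endpoint(endpoint)
    params = model.baseline[(endpoint, profile.sex)]
    w = linear_predictor(profile, model.coefficients[endpoint])
    s_now = baseline_survival(profile.age, params)
    s_later = baseline_survival(profile.age + model.horizon, params)
    return 1.0 - (s_later / s_now) ** np.exp(w)


def score_risk(profile: RiskProfile, model: SCOREModel) -> RiskEstimate:
    """Full SCORE estimate: CHD risk, non-CHD CVD risk, and their sum."""
    chd = ten_year_endpoint_risk(profile, model, Endpoint.CHD)
    non_chd = ten_year_endpoint_risk(profile, model, Endpoint.NON_CHD_CVD)
    return RiskEstimate(chd_risk=chd, non_chd_risk=non_chd, total_cvd_risk=chd + non_chd)


def endpoint_risk_arrays(
    age, male, smoker, sbp, tc, model: SCOREModel, endpoint: Endpoint
):
    """Vectorised 10-year endpoint risk over parallel arrays.

    ``male`` and ``smoker`` are boolean arrays; all inputs broadcast.  Used by
    the cohort pipeline where per-row RiskProfile construction would dominate.
    """
    endpoint = Endpoint(endpoint)
    age = np.asarray(age, dtype=float)
    male = np.asarray(male, dtype=bool)
    smoker = np.asarray(smoker, dtype=bool)
    sbp = np.asarray(sbp, dtype=float)
    tc = np.asarray(tc, dtype=float)
    if np.any(age < AGE_FLOOR):
        raise ValueError(f"age below the SCORE age floor of {AGE_FLOOR:g} years")
    coeffs = model.coefficients[endpoint]
    w = (
        coeffs.beta_chol * (tc - TC_REFERENCE)
        + coeffs.beta_sbp * (sbp - SBP_REFERENCE)
        + coeffs.beta_smoker * smoker.astype(float)
    )
    pm = model.baseline[(endpoint, Sex.MALE)]
    pf = model.baseline[(endpoint, Sex.FEMALE)]
    alpha = np.where(male, pm.alpha, pf.alpha)
    p = np.where(male, pm.p, pf.p)
    s_now = np.exp(-np.exp(alpha) * (age - AGE_FLOOR) ** p)
    s_later = np.exp(-np.exp(alpha) * (age + model.horizon - AGE_FLOOR) ** p)
    return 1.0 - (s_later / s_now) ** np.exp(w)
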