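"""Single-factor counterfactual decomposition of a SCORE risk change.

Under the SCORE proportional-hazards form, moving one risk factor by delta
multiplies the cumulative hazard -ln S by exp(beta * delta) exactly; for
small risks this is also the risk ratio to first order.  The decomposition
asks: had ONLY systolic blood pressure (or only total cholesterol) moved to
its follow-up value, what risk ratio would have resulted?

Two routes are provided: the closed-form hazard ratio at the mean factor
change (:func:`single_factor_rr`), and a per-patient counterfactual that
re-scores the cohort with one factor advanced
(:func:`cohort_counterfactual_rr`).  Smoking is excluded: it is treated as
fixed over a short follow-up.
"""

from __future__ import annotations

import math

import pandas as pd

from .cohort import compute_risks
from .model import EndpointCoefficients, SCOREModel

__all__ = ["FACTOR_BETAS", "single_factor_rr", "cohort_counterfactual_rr"]

#: decomposable factors -> coefficient attribute on EndpointCoefficients
FACTOR_BETAS = {"sbp": "beta_sbp", "tc": "beta_chol"}


def single_factor_rr(
    factor: str, delta: float, coeffs: EndpointCoefficients
) -> float:
    """Risk ratio attributable to a change ``delta`` in one factor.

    Returns exp(beta_factor * delta): the exact ratio of cumulative hazards,
    and the risk ratio to first order in small risks.  The corresponding
    percent change in risk is 1 - RR.  ``factor`` is "sbp" (delta in mmHg)
    or "tc" (delta in mmol/L).
    """
    try:
        beta = getattr(coeffs, FACTOR_BETAS[factor])
    except KeyError:
        raise ValueError(
            f"unknown factor {factor!r}; decomposable factors: {sorted(FACTOR_BETAS)}"
        ) from None
    if not math.isfinite(delta):
        raise ValueError("delta must be finite")
    return math.exp(beta * delta)


def cohort_counterfactual_rr(
    cohort: pd.DataFrame,
    model: SCOREModel,
    factor: str,
    endpoint: str = "chd",
) -> float:
    """Per-patient counterfactual risk ratio for one factor.

    Re-scores every patient with ONLY the named factor advanced to its
    follow-up value (everything else at baseline) and returns the ratio of
    the mean counterfactual risk to the mean baseline risk.  ``endpoint``
    is "chd" (fatal coronary events) or "cvd" (total CVD mortality).
    """
    if factor not in FACTOR_BETAS:
        raise ValueError(
            f"unknown factor {factor!r}; decomposable factors: {sorted(FACTOR_BETAS)}"
        )
    if endpoint not in ("chd", "cvd"):
        raise ValueError(f"unknown endpoint {endpoint!r}; expected 'chd' or 'cvd'")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    counterfactual = cohort.copy()
    # move only the chosen factor to follow-up; the other stays at baseline
    counterfactual[f"{factor}_baseline"] = cohort[f"{factor}_followup"]

    col = f"{endpoint}_baseline"
    base_mean = compute_risks(cohort, model)[col].mean()
    cf_mean = compute_risks(counterfactual, model)[col].mean()
    return float(cf_mean / base_mean)
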