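"""Paired pre/post cohort analysis of SCORE risks.

Reproduces the statistical pipeline of a single-cohort before/after study:
per-patient 10-year risks at baseline and follow-up (age and smoking held
fixed, SBP and TC advanced), paired-sample t statistics for absolute and
percent change, overlapping comorbidity-subgroup stratification, conversion
of mean 10-year risk to deaths per 100,000 person-years, and rate-ratio
relative risks with log-scale confidence intervals.

Cohorts are pandas DataFrames with the columns in :data:`COHORT_COLUMNS`;
one row per patient, booleans as 0/1 or bool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import Endpoint, SCOREModel, _parse_sex, Sex
from .parameters import build_model

__all__ = [
    "COHORT_COLUMNS",
    "PatientRecord",
    "PairedChangeStats",
    "RateComparison",
    "CohortAccounting",
    "GroupResult",
    "CohortReport",
    "complete_case_filter",
    "paired_change",
    "stratify",
    "risk_to_rate",
    "rate_rr_ci",
    "compute_risks",
    "analyze_cohort",
]

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "smoker",
    "sbp_baseline",
    "sbp_followup",
    "tc_baseline",
    "tc_followup",
    "hypertension",
    "diabetes",
    "metabolic_syndrome",
]

#: stratification groups -> flag column (None = whole cohort); groups overlap
SUBGROUP_FLAGS = {
    "total": None,
    "hypertension": "hypertension",
    "diabetes": "diabetes",
    "metabolic_syndrome": "metabolic_syndrome",
    "smokers": "smoker",
}

PERSON_YEARS_SCALE = 100_000.0


@dataclass(frozen=True)
class PatientRecord:
    """One patient: paired baseline/follow-up measurements plus comorbidity flags."""

    patient_id: str
    age: float
    sex: Sex
    smoker: bool
    sbp_baseline: float
    sbp_followup: float
    tc_baseline: float
    tc_followup: float
    hypertension: bool
    diabetes: bool
    metabolic_syndrome: bool

    def __post_init__(self):
        object.__setattr__(self, "sex", _parse_sex(self.sex))
        for name in ("sbp_baseline", "sbp_followup", "tc_baseline", "tc_followup"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be positive, got {v!r}")


@dataclass(frozen=True)
class PairedChangeStats:
    """Paired-sample change summary for one variable in one patient group.

    Absolute change is follow-up minus baseline in the variable's units;
    percent change is the mean of per-patient fractional changes
    (followup - baseline)/baseline, not the ratio of group means.
    """

    n: int
    mean_baseline: float
    sd_baseline: float
    mean_followup: float
    sd_followup: float
    mean_abs_change: float
    sd_abs_change: float
    ci95_abs: tuple
    mean_pct_change: float
    sd_pct_change: float
    ci95_pct: tuple
    t_statistic: float
    p_value: float
    degenerate: bool = False  # zero variance of differences: t/p undefined


@dataclass(frozen=True)
class RateComparison:
    """Baseline vs follow-up estimated death rates per 100,000 person-years."""

    deaths_baseline: float
    deaths_followup: float
    rr: float
    rr_ci95_low: float
    rr_ci95_high: float


@dataclass(frozen=True)
class CohortAccounting:
    """Complete-case accounting: rows in, rows excluded, rows analyzed."""

    n_input: int
    n_excluded: int
    n_analyzed: int

    @property
    def completion_pct(self) -> float:
        return 100.0 * self.n_analyzed / self.n_input if self.n_input else float("nan")


@dataclass
class GroupResult:
    """All report cells for one patient group (None where the group is empty)."""

    name: str
    n: int
    changes: dict = field(default_factory=dict)  # variable -> PairedChangeStats | None
    rates: dict = field(default_factory=dict)  # endpoint -> RateComparison | None


@dataclass
class CohortReport:
    region: str
    confidence: float
    accounting: CohortAccounting
    groups: dict = field(default_factory=dict)  # group name -> GroupResult


def complete_case_filter(cohort: pd.DataFrame) -> tuple[pd.DataFrame, CohortAccounting]:
    """Drop patients missing any paired measurement; return kept rows + accounting.

    Mirrors an intention-to-treat analysis restricted to patients with a
    completed follow-up assessment: change scores cannot be computed for
    dropouts, so they are excluded and counted.
    """
    required = ["sbp_baseline", "sbp_followup", "tc_baseline", "tc_followup", "age"]
    mask = cohort[required].notna().all(axis=1)
    kept = cohort[mask]
    return kept, CohortAccounting(
        n_input=len(cohort), n_excluded=int((~mask).sum()), n_analyzed=len(kept)
    )


def paired_change(
    baseline, followup, confidence: float = 0.95, percent: bool = True
) -> PairedChangeStats:
    """Paired-sample change statistics with a Student t test on the differences.

    Parameters
    ----------
    baseline, followup : array-like
        Pairwise-complete measurements, equal length, n >= 2.
    confidence : float
        Two-sided confidence level for the change CIs (t distribution, n-1 df).
    percent : bool
        Also summarise per-patient fractional change; requires nonzero baselines.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape or b.ndim != 1:
        raise ValueError("baseline and followup must be 1-d arrays of equal length")
    if b.size < 2:
        raise ValueError("paired analysis requires n >= 2")
    if np.isnan(b).any() or np.isnan(f).any():
        raise ValueError("inputs must be pairwise complete (no NaN)")
    n = b.size
    diff = f - b
    if percent and np.any(b == 0):
        raise ValueError("percent change undefined: baseline contains zero")
    pct = diff / b if percent else np.full(n, np.nan)

    sd_diff = float(np.std(diff, ddof=1))
    degenerate = sd_diff == 0.0
    if degenerate:
        t_stat, p_val = float("nan"), float("nan")
    else:
        t_stat, p_val = stats.ttest_rel(f, b)
        t_stat, p_val = float(t_stat), float(p_val)

    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)

    def ci(x):
        m = float(np.mean(x))
        half = tcrit * float(np.std(x, ddof=1)) / math.sqrt(n)
        return (m - half, m + half)

    return PairedChangeStats(
        n=n,
        mean_baseline=float(np.mean(b)),
        sd_baseline=float(np.std(b, ddof=1)),
        mean_followup=float(np.mean(f)),
        sd_followup=float(np.std(f, ddof=1)),
        mean_abs_change=float(np.mean(diff)),
        sd_abs_change=sd_diff,
        ci95_abs=ci(diff),
        mean_pct_change=float(np.mean(pct)) if percent else float("nan"),
        sd_pct_change=float(np.std(pct, ddof=1)) if percent else float("nan"),
        ci95_pct=ci(pct) if percent else (float("nan"), float("nan")),
        t_statistic=t_stat,
        p_value=p_val,
        degenerate=degenerate,
    )


def stratify(cohort: pd.DataFrame) -> dict:
    """Split a cohort into the five analysis groups (overlapping membership).

    Returns total, hypertension, diabetes, metabolic_syndrome and smokers
    sub-cohorts; a patient with several comorbid conditions appears in each
    matching group.
    """
    out = {}
    for name, flag in SUBGROUP_FLAGS.items():
        out[name] = cohort if flag is None else cohort[cohort[flag].astype(bool)]
    return out


def risk_to_rate(mean_risk: float) -> float:
    """Convert a mean 10-year risk to deaths per 100,000 person-years.

    The 10-year probability is spread uniformly over the horizon:
    rate = risk * 100,000 / 10.
    """
    risk = np.asarray(mean_risk, dtype=float)
    if np.any(risk < 0) or np.any(risk > 1):
        raise ValueError("mean_risk must lie in [0, 1]")
    out = risk * PERSON_YEARS_SCALE / 10.0
    return out if out.ndim else float(out)


def rate_rr_ci(
    deaths_baseline: float, deaths_followup: float, confidence: float = 0.95
) -> RateComparison:
    """Rate-ratio RR with a log-scale CI treating the rates as Poisson counts.

    RR = followup/baseline; SE(log RR) = sqrt(1/d_f + 1/d_b) with the
    per-100,000-person-year figures taken as the event counts; bounds are
    exp(log RR +/- z * SE).
    """
    if not (deaths_baseline > 0 and deaths_followup > 0):
        raise ValueError("both rates must be positive")
    rr = deaths_followup / deaths_baseline
    se = math.sqrt(1.0 / deaths_followup + 1.0 / deaths_baseline)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return RateComparison(
        deaths_baseline=deaths_baseline,
        deaths_followup=deaths_followup,
        rr=rr,
        rr_ci95_low=rr * math.exp(-z * se),
        rr_ci95_high=rr * math.exp(z * se),
    )


def compute_risks(cohort: pd.DataFrame, model: SCOREModel) -> pd.DataFrame:
    """Per-patient 10-year risks at both visits.

    Baseline risks use (sbp_baseline, tc_baseline), follow-up risks
    (sbp_followup, tc_followup); age and smoking status are held fixed at
    their screening values.  Returns a copy of the cohort with columns
    chd_baseline, chd_followup, cvd_baseline, cvd_followup.
    """
    from .model import endpoint_risk_arrays

    male = cohort["sex"].map(lambda s: _parse_sex(s) is Sex.MALE).to_numpy()
    smoker = cohort["smoker"].astype(bool).to_numpy()
    age = cohort["age"].to_numpy(dtype=float)
    out = cohort.copy()
    for visit in ("baseline", "followup"):
        sbp = cohort[f"sbp_{visit}"].to_numpy(dtype=float)
        tc = cohort[f"tc_{visit}"].to_numpy(dtype=float)
        chd = endpoint_risk_arrays(age, male, smoker, sbp, tc, model, Endpoint.CHD)
        non_chd = endpoint_risk_arrays(
            age, male, smoker, sbp, tc, model, Endpoint.NON_CHD_CVD
        )
        out[f"chd_{visit}"] = chd
        out[f"cvd_{visit}"] = chd + non_chd
    return out


#: report variables -> (baseline column, follow-up column)
_CHANGE_VARS = {
    "sbp": ("sbp_baseline", "sbp_followup"),
    "tc": ("tc_baseline", "tc_followup"),
    "chd_risk": ("chd_baseline", "chd_followup"),
    "cvd_risk": ("cvd_baseline", "cvd_followup"),
}


def analyze_cohort(
    cohort: pd.DataFrame,
    model: SCOREModel | None = None,
    confidence: float = 0.95,
) -> CohortReport:
    """Full study analysis: change tables and mortality-rate comparisons.

    For each of the five patient groups, paired change statistics for SBP,
    TC and both SCORE risks, plus CHD and total-CVD death-rate comparisons
    (deaths per 100,000 person-years with rate-ratio RR and CI).  Empty
    subgroups yield None cells, never zeros.
    """
    if model is None:
        model = build_model()
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    kept, accounting = complete_case_filter(cohort)
    risks = compute_risks(kept, model)

    report = CohortReport(
        region=model.region.value, confidence=confidence, accounting=accounting
    )
    for name, sub in stratify(risks).items():
        result = GroupResult(name=name, n=len(sub))
        if len(sub) == 0:
            result.changes = {var: None for var in _CHANGE_VARS}
            result.rates = {"chd": None, "cvd": None}
        else:
            for var, (bcol, fcol) in _CHANGE_VARS.items():
                if len(sub) >= 2:
                    result.changes[var] = paired_change(
                        sub[bcol], sub[fcol], confidence=confidence
                    )
                else:  # n = 1: means are defined, dispersion and t are not
                    b = float(sub[bcol].iloc[0])
                    f = float(sub[fcol].iloc[0])
                    nan = float("nan")
                    result.changes[var] = PairedChangeStats(
                        n=1,
                        mean_baseline=b,
                        sd_baseline=nan,
                        mean_followup=f,
                        sd_followup=nan,
                        mean_abs_change=f - b,
                        sd_abs_change=nan,
                        ci95_abs=(nan, nan),
                        mean_pct_change=(f - b) / b if b != 0 else nan,
                        sd_pct_change=nan,
                        ci95_pct=(nan, nan),
                        t_statistic=nan,
                        p_value=nan,
                        degenerate=True,
                    )
            for ep, bcol, fcol in (
                ("chd", "chd_baseline", "chd_followup"),
                ("cvd", "cvd_baseline", "cvd_followup"),
            ):
                rate_b = risk_to_rate(float(sub[bcol].mean()))
                rate_f = risk_to_rate(float(sub[fcol].mean()))
                result.rates[ep] = (
                    rate_rr_ci(rate_b, rate_f, confidence=confidence)
                    if rate_b > 0 and rate_f > 0
                    else None
                )
        report.groups[name] = result
    return report
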