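"""Cohort CSV reading/writing, report serialisation and configuration.

The on-disk cohort format is a UTF-8, comma-separated, decimal-point CSV
with LF line endings and one row per patient:

    patient_id,age,sex,smoker,sbp_baseline,sbp_followup,tc_baseline,
    tc_followup,hypertension,diabetes,metabolic_syndrome

Sex accepts male/female/M/F/1/0; flags accept 0/1 or true/false.  Missing
follow-up measurements are allowed on read (the complete-case filter is
applied by the analysis, not the reader).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import COHORT_COLUMNS, CohortReport
from .model import Region, _parse_sex

__all__ = [
    "RoundingProfile",
    "AnalysisConfig",
    "read_cohort",
    "write_cohort",
    "write_report",
    "plot_rates",
]

_BOOL_TOKENS = {
    "0": 0, "1": 1, "false": 0, "true": 1, "no": 0, "yes": 1,
}
_FLAG_COLUMNS = ["smoker", "hypertension", "diabetes", "metabolic_syndrome"]
_MEASUREMENTS = ["sbp_baseline", "sbp_followup", "tc_baseline", "tc_followup"]


@dataclass(frozen=True)
class RoundingProfile:
    """Decimal places used when rendering report files."""

    risk: int = 3
    rate: int = 0
    ratio: int = 3
    measurement: int = 2
    pct: int = 3


@dataclass(frozen=True)
class AnalysisConfig:
    """Top-level analysis settings (region, confidence, paths, seed)."""

    region: Region = Region.LOW_RISK
    confidence: float = 0.95
    rounding: RoundingProfile = field(default_factory=RoundingProfile)
    input_path: str | None = None
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "region", Region(self.region))
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "rounding" in raw:
            raw["rounding"] = RoundingProfile(**raw["rounding"])
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _parse_flag(value, column: str, row: int):
    if pd.isna(value):
        raise ValueError(f"row {row}: missing value in column {column!r}")
    token = str(value).strip().lower()
    if token.endswith(".0"):
        token = token[:-2]
    if token not in _BOOL_TOKENS:
        raise ValueError(
            f"row {row}: cannot parse {value!r} in column {column!r} as a 0/1 flag"
        )
    return _BOOL_TOKENS[token]


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises on missing columns or unparseable/invalid rows with row-numbered
    messages (row numbers count data rows from 1).  Rows missing follow-up
    measurements are kept; the complete-case filter runs downstream.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    if df.empty:
        raise ValueError(f"{path}: cohort file contains no data rows")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[COHORT_COLUMNS].copy()

    errors = []
    sexes = []
    for i, value in enumerate(df["sex"], start=1):
        try:
            sexes.append(_parse_sex(value).value)
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
    for col in _FLAG_COLUMNS:
        parsed = []
        for i, value in enumerate(df[col], start=1):
            try:
                parsed.append(_parse_flag(value, col, i))
            except ValueError as exc:
                errors.append(str(exc))
                parsed.append(0)
        df[col] = parsed
    for col in _MEASUREMENTS + ["age"]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(f"row {i + 1}: unparseable number {df[col].iloc[i]!r} in {col!r}")
        df[col] = numeric
        if col != "age":
            nonpos = numeric.notna() & (numeric <= 0)
            for i in np.flatnonzero(nonpos.to_numpy()):
                errors.append(f"row {i + 1}: {col} must be positive, got {numeric.iloc[i]!r}")
    if errors:
        raise ValueError(f"{path}: invalid cohort rows:\n" + "\n".join(errors))
    df["sex"] = sexes
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV (UTF-8, LF, decimal point); byte-deterministic."""
    cohort[COHORT_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def _fmt(value, decimals: int):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return f"{value:.{decimals}f}" if decimals > 0 else f"{value:.0f}"


def report_frames(report: CohortReport, rounding: RoundingProfile | None = None) -> dict:
    """Render a report as table-shaped DataFrames (strings at profile precision).

    Returns risk_factors (SBP/TC change table), chd_score and cvd_score
    (risk change tables), and mortality_rates (rate + RR table).  Cells for
    empty subgroups are blank, not zero.
    """
    r = rounding or RoundingProfile()
    factor_rows, risk_rows = [], {"chd_risk": [], "cvd_risk": []}
    rate_rows = []
    for name, group in report.groups.items():
        row = {"group": name, "n": group.n}
        for var, dec in (("sbp", r.measurement), ("tc", r.measurement)):
            st = group.changes.get(var)
            row.update(_change_cells(var, st, dec, r))
        factor_rows.append(row)
        for var in ("chd_risk", "cvd_risk"):
            st = group.changes.get(var)
            rrow = {"group": name, "n": group.n}
            rrow.update(_change_cells("", st, r.risk, r, prefix=False))
            risk_rows[var].append(rrow)
        for ep in ("chd", "cvd"):
            rc = group.rates.get(ep)
            rate_rows.append(
                {
                    "group": name,
                    "endpoint": ep,
                    "rate_baseline": _fmt(rc.deaths_baseline if rc else None, r.rate),
                    "rate_followup": _fmt(rc.deaths_followup if rc else None, r.rate),
                    "rr": _fmt(rc.rr if rc else None, r.ratio),
                    "rr_ci_low": _fmt(rc.rr_ci95_low if rc else None, r.ratio),
                    "rr_ci_high": _fmt(rc.rr_ci95_high if rc else None, r.ratio),
                }
            )
    return {
        "risk_factors": pd.DataFrame(factor_rows),
        "chd_score": pd.DataFrame(risk_rows["chd_risk"]),
        "cvd_score": pd.DataFrame(risk_rows["cvd_risk"]),
        "mortality_rates": pd.DataFrame(rate_rows),
    }


def _change_cells(var, st, decimals, r: RoundingProfile, prefix: bool = True):
    p = f"{var}_" if prefix and var else ""
    if st is None:
        keys = (
            "baseline_mean", "baseline_sd", "followup_mean", "followup_sd",
            "abs_change_mean", "abs_change_sd", "abs_change_ci_low",
            "abs_change_ci_high", "pct_change_mean", "pct_change_ci_low",
            "pct_change_ci_high", "p_value",
        )
        return {p + k: "" for k in keys}
    return {
        p + "baseline_mean": _fmt(st.mean_baseline, decimals),
        p + "baseline_sd": _fmt(st.sd_baseline, decimals),
        p + "followup_mean": _fmt(st.mean_followup, decimals),
        p + "followup_sd": _fmt(st.sd_followup, decimals),
        p + "abs_change_mean": _fmt(st.mean_abs_change, decimals),
        p + "abs_change_sd": _fmt(st.sd_abs_change, decimals),
        p + "abs_change_ci_low": _fmt(st.ci95_abs[0], decimals),
        p + "abs_change_ci_high": _fmt(st.ci95_abs[1], decimals),
        p + "pct_change_mean": _fmt(st.mean_pct_change, r.pct),
        p + "pct_change_ci_low": _fmt(st.ci95_pct[0], r.pct),
        p + "pct_change_ci_high": _fmt(st.ci95_pct[1], r.pct),
        p + "p_value": "" if st.degenerate else _fmt(st.p_value, 4),
    }


def write_report(
    report: CohortReport, out_dir, rounding: RoundingProfile | None = None
) -> list:
    """Write one CSV per report table into ``out_dir``; returns written paths.

    Output is deterministic: fixed column order, fixed group order, LF line
    endings, values rendered at the rounding profile.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in report_frames(report, rounding).items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, lineterminator="\n")
        paths.append(path)
    return paths


def plot_rates(report: CohortReport, path) -> None:
    """Bar chart of baseline vs follow-up death rates per 100,000 PY by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=False)
    for ax, ep, title in zip(axes, ("chd", "cvd"), ("CHD mortality", "Total CVD mortality")):
        groups = [g for g in report.groups.values() if g.rates.get(ep)]
        x = np.arange(len(groups))
        base = [g.rates[ep].deaths_baseline for g in groups]
        follow = [g.rates[ep].deaths_followup for g in groups]
        ax.bar(x - 0.2, base, width=0.4, label="baseline")
        ax.bar(x + 0.2, follow, width=0.4, label="6 weeks")
        ax.set_xticks(x)
        ax.set_xticklabels([g.name for g in groups], rotation=30, ha="right")
        ax.set_ylabel("estimated deaths / 100,000 PY")
        ax.set_title(title)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
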