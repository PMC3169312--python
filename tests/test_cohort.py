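"""Cohort-analysis pipeline tests: paired statistics, stratification,
rate conversion and rate-ratio confidence intervals."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from scorerisk import (
    analyze_cohort,
    complete_case_filter,
    compute_risks,
    paired_change,
    rate_rr_ci,
    risk_to_rate,
    stratify,
)
from scorerisk.cohort import COHORT_COLUMNS


def make_cohort(rows):
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def one_patient(**overrides):
    base = dict(
        patient_id="P1", age=60.0, sex="male", smoker=0,
        sbp_baseline=130.0, sbp_followup=130.0,
        tc_baseline=5.5, tc_followup=5.5,
        hypertension=0, diabetes=0, metabolic_syndrome=0,
    )
    base.update(overrides)
    return base


class TestPairedChange:
    def test_hand_computed_oracle(self):
        # diffs (-1, -0.5, -0.2): mean -0.56667, sd 0.40415, t = -2.4286
        st_ = paired_change([5, 6, 7], [4, 5.5, 6.8])
        assert st_.n == 3
        assert st_.mean_abs_change == pytest.approx(-0.56667, abs=5e-6)
        assert st_.sd_abs_change == pytest.approx(0.40415, abs=5e-6)
        assert st_.t_statistic == pytest.approx(-2.4286, abs=5e-5)
        assert st_.ci95_abs[0] < st_.mean_abs_change < st_.ci95_abs[1]
        assert st_.ci95_pct[0] < st_.mean_pct_change < st_.ci95_pct[1]

    def test_identity_vectors_flagged_degenerate(self):
        st_ = paired_change([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert st_.mean_abs_change == 0.0
        assert st_.mean_pct_change == 0.0
        assert st_.degenerate
        assert math.isnan(st_.t_statistic)

    def test_percent_change_is_mean_of_ratios(self):
        # mean of per-patient fractional changes, not ratio of means
        st_ = paired_change([2.0, 10.0], [1.0, 11.0])
        assert st_.mean_pct_change == pytest.approx((-0.5 + 0.1) / 2)

    @pytest.mark.parametrize(
        "baseline,followup,match",
        [
            ([1, 2], [1, 2, 3], "equal length"),
            ([1], [2], "n >= 2"),
            ([0.0, 1.0], [1.0, 2.0], "zero"),
            ([1.0, np.nan], [1.0, 2.0], "complete"),
        ],
    )
    def test_invalid_inputs(self, baseline, followup, match):
        with pytest.raises(ValueError, match=match):
            paired_change(baseline, followup)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        b=arrays(float, st.integers(2, 30), elements=st.floats(0.5, 100.0)),
        data=st.data(),
    )
    def test_agrees_with_direct_formula_oracle(self, b, data):
        f = data.draw(
            arrays(float, b.size, elements=st.floats(0.5, 100.0))
        )
        st_ = paired_change(b, f)
        d = f - b
        n = d.size
        assert st_.mean_abs_change == pytest.approx(d.mean(), abs=1e-10)
        sd = math.sqrt(((d - d.mean()) ** 2).sum() / (n - 1))
        assert st_.sd_abs_change == pytest.approx(sd, abs=1e-10)
        if sd > 1e-12:
            assert st_.t_statistic == pytest.approx(
                d.mean() / (sd / math.sqrt(n)), rel=1e-9
            )


class TestStratify:
    def test_no_flags_only_total(self):
        cohort = make_cohort([one_patient(patient_id=f"P{i}") for i in range(3)])
        groups = stratify(cohort)
        assert len(groups["total"]) == 3
        for name in ("hypertension", "diabetes", "metabolic_syndrome", "smokers"):
            assert len(groups[name]) == 0

    def test_all_flags_appears_everywhere(self):
        cohort = make_cohort(
            [one_patient(smoker=1, hypertension=1, diabetes=1, metabolic_syndrome=1)]
        )
        groups = stratify(cohort)
        assert all(len(g) == 1 for g in groups.values())

    def test_groups_overlap(self, default_cohort):
        groups = stratify(default_cohort)
        total = len(groups["total"])
        assert sum(len(g) for n, g in groups.items() if n != "total") > total / 2
        assert all(len(g) <= total for g in groups.values())


class TestRiskToRate:
    @pytest.mark.parametrize("risk,rate", [(0.047, 470.0), (0.053, 530.0), (0.0, 0.0)])
    def test_ten_year_risk_spread_uniformly(self, risk, rate):
        assert risk_to_rate(risk) == rate

    def test_linearity(self):
        r = 0.031
        assert risk_to_rate(2 * r) == pytest.approx(2 * risk_to_rate(r))

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            risk_to_rate(bad)


class TestRateRRCI:
    def test_chd_rates(self):
        rc = rate_rr_ci(470.0, 337.0)
        assert rc.rr == pytest.approx(0.7170, abs=5e-4)
        assert rc.rr_ci95_low == pytest.approx(0.623, abs=2e-3)
        assert rc.rr_ci95_high == pytest.approx(0.825, abs=2e-3)

    def test_cvd_rates(self):
        rc = rate_rr_ci(685.0, 530.0)
        assert rc.rr == pytest.approx(0.7737, abs=5e-4)
        assert rc.rr_ci95_low == pytest.approx(0.691, abs=2e-3)
        assert rc.rr_ci95_high == pytest.approx(0.866, abs=2e-3)

    def test_equal_rates_ci_straddles_one(self):
        rc = rate_rr_ci(500.0, 500.0)
        assert rc.rr == 1.0
        assert rc.rr_ci95_low < 1.0 < rc.rr_ci95_high

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_rr_ci(0.0, 100.0)


class TestCompleteCase:
    def test_accounting(self):
        rows = [one_patient(patient_id=f"P{i}") for i in range(10)]
        for row in rows[:3]:
            row["tc_followup"] = np.nan
        kept, acc = complete_case_filter(make_cohort(rows))
        assert (acc.n_input, acc.n_excluded, acc.n_analyzed) == (10, 3, 7)
        assert len(kept) == 7
        assert kept["tc_followup"].notna().all()


class TestAnalyzeCohort:
    def test_single_patient_no_change(self, low_risk_model):
        cohort = make_cohort([one_patient()])
        report = analyze_cohort(cohort, low_risk_model)
        total = report.groups["total"]
        assert total.n == 1
        for var in ("sbp", "tc", "chd_risk", "cvd_risk"):
            assert total.changes[var].mean_abs_change == 0.0
            assert total.changes[var].degenerate
        for ep in ("chd", "cvd"):
            assert total.rates[ep].rr == pytest.approx(1.0)

    def test_empty_subgroup_cells_absent_not_zero(self, low_risk_model):
        cohort = make_cohort([one_patient(patient_id=f"P{i}") for i in range(4)])
        report = analyze_cohort(cohort, low_risk_model)
        assert report.groups["smokers"].n == 0
        assert report.groups["smokers"].changes["sbp"] is None
        assert report.groups["smokers"].rates["chd"] is None

    def test_empty_cohort_rejected(self, low_risk_model):
        with pytest.raises(ValueError, match="empty"):
            analyze_cohort(make_cohort([]), low_risk_model)

    def test_default_cohort_report(self, low_risk_model, default_cohort):
        report = analyze_cohort(default_cohort, low_risk_model)
        # plausibility bracket for the total-group CHD rate ratio
        assert 0.6 < report.groups["total"].rates["chd"].rr < 0.85
        for group in report.groups.values():
            assert group.n >= 2
            chd = group.changes["chd_risk"]
            cvd = group.changes["cvd_risk"]
            # CHD risk never exceeds total CVD risk in any cell
            assert chd.mean_baseline <= cvd.mean_baseline
            assert chd.mean_followup <= cvd.mean_followup
            assert group.rates["chd"].deaths_baseline <= group.rates["cvd"].deaths_baseline

    def test_risks_use_fixed_age_and_smoking(self, low_risk_model, default_cohort):
        risks = compute_risks(default_cohort.head(20), low_risk_model)
        same = default_cohort.head(20).copy()
        same["sbp_followup"] = same["sbp_baseline"]
        same["tc_followup"] = same["tc_baseline"]
        frozen = compute_risks(same, low_risk_model)
        assert np.allclose(frozen["chd_baseline"], frozen["chd_followup"])
        assert np.allclose(risks["chd_baseline"], frozen["chd_baseline"])
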