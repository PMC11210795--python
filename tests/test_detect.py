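"""Detectors: spikes, fences, missing years, value anomalies."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssdqa import AnalysisConfig, load_catalog
from ssdqa.detect import (detect_issues, detect_missing_years, detect_spikes,
                          detect_value_anomalies, loo_zscores,
                          tukey_fence_outliers)

CFG = AnalysisConfig()


def _completeness_rows(check_num, site, year_values, denom=10):
    return [{"check_num": check_num, "site_id": site, "stratum": str(y),
             "value": v, "denominator": denom if v is not None else 0}
            for y, v in year_values]


def _frame(rows):
    return pd.DataFrame(rows, columns=["check_num", "site_id", "stratum",
                                       "value", "denominator"])


def scr_trend_check():
    checks = load_catalog("DQ2")
    return [c for c in checks if c.executor == "completeness_trend"
            and c.params.get("variable") == "serum_creatinine"]


class TestSpikes:
    def test_single_high_spike_with_floored_sd(self):
        z = loo_zscores(np.array([100, 100, 100, 100, 300]), 0.05)
        # year 5: leave-one-out mean 100, SD floored at 5 -> z = 200/5 = 40
        assert z[-1] == pytest.approx(40.0)
        assert np.all(np.abs(z[:-1]) < 2)

    def test_constant_series_no_spike(self):
        z = loo_zscores(np.array([50.0] * 6), 0.05)
        assert np.all(z == 0)

    def test_low_spike_symmetric(self):
        z = loo_zscores(np.array([100, 100, 100, 100, 20]), 0.05)
        assert z[-1] == pytest.approx(-16.0)

    def test_detect_spikes_emits_issue(self):
        checks = [c for c in load_catalog("DQ2")
                  if c.executor == "yearly_count_trend"
                  and c.params.get("variable") == "visits"]
        rows = [{"check_num": checks[0].check_num, "site_id": "s1",
                 "stratum": str(2010 + i), "value": v, "denominator": 50}
                for i, v in enumerate([100, 100, 100, 100, 300])]
        issues = detect_spikes(_frame(rows), checks, CFG)
        assert len(issues) == 1
        assert issues[0]["dq_issue"] == "high spike"
        assert "2014" in issues[0]["info"]


class TestFences:
    def test_hand_computed_fence(self):
        idx, lo, hi = tukey_fence_outliers([0.30, 0.32, 0.33, 0.35, 0.80])
        assert hi == pytest.approx(0.395)
        assert list(idx) == [4]

    def test_all_equal_no_outliers(self):
        idx, _, _ = tukey_fence_outliers([0.4] * 8)
        assert len(idx) == 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([0.0, 0.1, 0.2, 0.3, 0.5, 1.0, 2.0, 5.0]),
                    min_size=5, max_size=15))
    def test_fence_matches_brute_force(self, values):
        """Grid-enumerated cross-check against an independent quantile path."""
        idx, lo, hi = tukey_fence_outliers(values)
        s = sorted(values)
        n = len(s)

        def q(p):  # type-7 quantile by direct interpolation
            h = (n - 1) * p
            f, c = int(np.floor(h)), int(np.ceil(h))
            return s[f] + (h - f) * (s[c] - s[f])

        iqr = q(0.75) - q(0.25)
        expect = [i for i, v in enumerate(values)
                  if v < q(0.25) - 1.5 * iqr or v > q(0.75) + 1.5 * iqr]
        assert list(idx) == expect


class TestMissingYears:
    def test_interior_zero_year_is_missingness(self):
        checks = scr_trend_check()
        rows = _completeness_rows(checks[0].check_num, "s1",
                                  [(y, 0.0 if y == 2014 else 0.6)
                                   for y in range(2010, 2017)])
        issues = detect_missing_years(_frame(rows), checks, CFG)
        assert len(issues) == 1
        assert issues[0]["dq_issue"] == "missingness"
        assert issues[0]["element"] == "serum_creatinine"
        assert issues[0]["info"] == "calendar years missing: 2014"

    def test_leading_zeros_become_late_onset(self):
        checks = scr_trend_check()
        rows = _completeness_rows(checks[0].check_num, "s1",
                                  [(y, 0.0 if y <= 2013 else 0.6)
                                   for y in range(2009, 2017)])
        issues = detect_missing_years(_frame(rows), checks, CFG)
        assert len(issues) == 1
        assert issues[0]["element"] == "cohort_entry"
        assert issues[0]["info"] == ("calendar years missing: "
                                     "2009, 2010, 2011, 2012, 2013")

    def test_inactive_leading_years_become_late_onset(self):
        checks = scr_trend_check()
        rows = ([{"check_num": checks[0].check_num, "site_id": "s1",
                  "stratum": str(y), "value": 0.0, "denominator": 0}
                 for y in range(2009, 2015)]
                + _completeness_rows(checks[0].check_num, "s1",
                                     [(y, 0.5) for y in range(2015, 2022)]))
        issues = detect_missing_years(_frame(rows), checks, CFG)
        assert len(issues) == 1
        assert issues[0]["element"] == "cohort_entry"

    def test_all_years_zero_is_total_missingness(self):
        checks = scr_trend_check()
        rows = _completeness_rows(checks[0].check_num, "s1",
                                  [(y, 0.0) for y in range(2010, 2016)])
        issues = detect_missing_years(_frame(rows), checks, CFG)
        assert len(issues) == 1
        assert issues[0]["info"] == "all calendar years missing"

    def test_no_zero_years_no_issue(self):
        checks = scr_trend_check()
        rows = _completeness_rows(checks[0].check_num, "s1",
                                  [(y, 0.4) for y in range(2010, 2016)])
        assert detect_missing_years(_frame(rows), checks, CFG) == []


class TestValueAnomalies:
    def _dist_rows(self, check, site="s1", top=0.0, oor=0.0, median=100.0):
        return [{"check_num": check.check_num, "site_id": site, "stratum": s,
                 "value": v, "denominator": 1000}
                for s, v in [("q1", 50.0), ("median", median), ("q3", 150.0),
                             ("mean", 100.0), ("top_mass_fraction", top),
                             ("out_of_range_fraction", oor)]]

    def test_defaulted_labs_raise_both_issue_kinds(self):
        checks = [c for c in load_catalog("DQ2")
                  if c.executor == "value_distribution"
                  and c.params.get("variable") == "urine_protein_quant"]
        rows = self._dist_rows(checks[0], top=0.2, oor=0.2)
        issues = detect_value_anomalies(_frame(rows), checks, CFG)
        kinds = {i["dq_issue"] for i in issues}
        assert kinds == {"atypical numeric distribution", "outlier values"}

    def test_clean_distribution_no_issue(self):
        checks = [c for c in load_catalog("DQ2")
                  if c.executor == "value_distribution"
                  and c.params.get("variable") == "urine_protein_quant"]
        rows = self._dist_rows(checks[0], top=0.01, oor=0.0)
        assert detect_value_anomalies(_frame(rows), checks, CFG) == []

    def test_negative_bp_correlation_is_discordant(self):
        checks = [c for c in load_catalog("DQ2")
                  if c.executor == "pair_correlation"]
        rows = [{"check_num": checks[0].check_num, "site_id": "s1",
                 "stratum": "all", "value": -0.4, "denominator": 5000}]
        issues = detect_value_anomalies(_frame(rows), checks, CFG)
        assert issues[0]["dq_issue"] == "discordant values"


def test_every_emitted_issue_validates_against_value_sets(planted_runs):
    from ssdqa.catalog import DQ_ISSUES
    from ssdqa.priority import PRIORITIES
    from ssdqa.themes import THEMES
    for run in planted_runs[:2]:
        issues = run.issues
        assert issues["dq_issue"].isin(DQ_ISSUES).all()
        assert issues["priority"].isin(PRIORITIES).all()
        for themes in issues["themes"]:
            names = themes.split(";")
            assert names and all(t in THEMES for t in names)
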