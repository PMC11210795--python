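"""Executor families: counting semantics on hand-built micro-datasets."""

import numpy as np
import pandas as pd
import pytest

from ssdqa import AnalysisConfig
from ssdqa.executors import (ExecutionContext, apply_prevalence_filter,
                             code_utilization, completeness_trend,
                             geocode_granularity, med_timing, pair_correlation,
                             same_day_concordance, unit_mapped_proportion,
                             value_distribution)

from conftest import height_row, make_dataset, patient_row, scr_row, visit_row


def ctx_for(ds, years=(2015, 2015)):
    return ExecutionContext(dataset=ds, config=AnalysisConfig(), years=years)


def bp_row(pid, date, measure, value):
    return {"patient_id": pid, "date": date, "measure": measure,
            "value": value, "unit": "mmHg"}


def test_completeness_trend_counts_patients_once():
    patients = [patient_row(f"p{i}") for i in range(4)]
    visits = [visit_row(f"p{i}", "2015-02-01") for i in range(4)]
    labs = [scr_row("p0", "2015-03-01", 1.0), scr_row("p1", "2015-04-01", 1.0),
            scr_row("p1", "2015-05-01", 1.1)]    # second record must not recount
    ds = make_dataset(patients=patients, visits=visits, labs=labs)
    out = completeness_trend(ctx_for(ds), "serum_creatinine")
    assert out.iloc[0]["value"] == 0.5 and out.iloc[0]["denominator"] == 4


def test_completeness_trend_full_coverage():
    patients = [patient_row(f"p{i}") for i in range(4)]
    visits = [visit_row(f"p{i}", "2015-02-01") for i in range(4)]
    labs = [scr_row(f"p{i}", "2015-03-01", 1.0) for i in range(4)]
    ds = make_dataset(patients=patients, visits=visits, labs=labs)
    out = completeness_trend(ctx_for(ds), "serum_creatinine")
    assert out.iloc[0]["value"] == 1.0


def test_same_day_concordance_fraction():
    vitals = [bp_row("p1", "2015-01-01", "systolic_bp", 110),
              bp_row("p1", "2015-01-01", "diastolic_bp", 70),
              bp_row("p1", "2015-02-01", "systolic_bp", 112),
              bp_row("p1", "2015-03-01", "systolic_bp", 108),
              bp_row("p1", "2015-03-01", "diastolic_bp", 66)]
    ds = make_dataset(patients=[patient_row("p1")], vitals=vitals)
    out = same_day_concordance(ctx_for(ds))
    assert out.iloc[0]["value"] == pytest.approx(2 / 3)


@pytest.mark.parametrize("slope,expected_r", [(0.5, 1.0), (-1.0, -1.0)])
def test_pair_correlation_perfect_linearity(slope, expected_r):
    vitals = []
    for i, s in enumerate([100.0, 110.0, 120.0, 130.0]):
        d = f"2015-01-{i + 1:02d}"
        dia = slope * s + (170.0 if slope < 0 else 0.0)
        vitals += [bp_row("p1", d, "systolic_bp", s),
                   bp_row("p1", d, "diastolic_bp", dia)]
    ds = make_dataset(patients=[patient_row("p1")], vitals=vitals)
    out = pair_correlation(ctx_for(ds))
    assert out.iloc[0]["value"] == pytest.approx(expected_r)


def test_pair_correlation_needs_minimum_pairs():
    vitals = [bp_row("p1", "2015-01-01", "systolic_bp", 110),
              bp_row("p1", "2015-01-01", "diastolic_bp", 70)]
    ds = make_dataset(patients=[patient_row("p1")], vitals=vitals)
    assert len(pair_correlation(ctx_for(ds))) == 0


def test_unit_mapped_proportion_counts():
    labs = [dict(scr_row("p1", f"2015-01-{d:02d}", 1.0),
                 lab="urine_protein_quant",
                 unit="mg/dL" if d <= 4 else "missing", mapped_unit=d <= 4)
            for d in range(1, 6)]
    ds = make_dataset(patients=[patient_row("p1")], labs=labs)
    out = unit_mapped_proportion(ctx_for(ds), "urine_protein_quant")
    assert out.iloc[0]["value"] == pytest.approx(0.8)


def test_no_lab_records_yields_no_row():
    ds = make_dataset(patients=[patient_row("p1")])
    assert len(unit_mapped_proportion(ctx_for(ds), "urine_protein_quant")) == 0


def test_code_utilization_patient_year_dedup():
    procs = [{"patient_id": "p1", "date": f"2015-0{m}-01", "code": "90935",
              "code_group": "chronic_dialysis"} for m in range(1, 6)]
    ds = make_dataset(patients=[patient_row("p1")],
                      visits=[visit_row("p1", "2015-01-01")], procs=procs)
    out = code_utilization(ctx_for(ds), "chronic_dialysis")
    assert out.iloc[0]["value"] == 1.0  # 5 identical codes -> 1 patient-year


def test_code_utilization_invariant_to_duplication():
    procs = [{"patient_id": "p1", "date": "2015-03-01", "code": "90935",
              "code_group": "chronic_dialysis"}]
    ds = make_dataset(patients=[patient_row("p1")],
                      visits=[visit_row("p1", "2015-01-01")], procs=procs)
    base = code_utilization(ctx_for(ds), "chronic_dialysis")
    ds.procs = pd.concat([ds.procs, ds.procs], ignore_index=True)
    doubled = code_utilization(ctx_for(ds), "chronic_dialysis")
    pd.testing.assert_frame_equal(base, doubled)


def test_prevalence_filter_drops_rare_codes_keeps_zero_rows():
    rows = pd.DataFrame({
        "check_num": "X", "site_id": ["s1", "s2", "s1", "s2"],
        "stratum": ["common", "common", "rare", "rare"],
        "value": [30.0, 0.0, 1.0, 0.0],
        "denominator": [150, 150, 150, 150],
    })
    out = apply_prevalence_filter(rows, 0.005)
    assert set(out["stratum"]) == {"common"}
    # the all-zero site row for a kept code is preserved
    assert ((out["site_id"] == "s2") & (out["value"] == 0.0)).any()


def test_geocode_partition_sums_to_one():
    patients = ([patient_row(f"p{i}", geocode="block_group") for i in range(5)]
                + [patient_row(f"t{i}", geocode="tract") for i in range(3)]
                + [patient_row(f"z{i}", geocode="zip5") for i in range(2)])
    ds = make_dataset(patients=patients)
    out = geocode_granularity(ctx_for(ds))
    got = dict(zip(out["stratum"], out["value"]))
    assert got == {"none": 0.0, "zip5": 0.2, "zip9": 0.0, "tract": 0.3,
                   "block_group": 0.5}
    assert sum(got.values()) == pytest.approx(1.0)


def test_value_distribution_mass_and_range():
    rng = np.random.default_rng(0)
    vals = list(rng.uniform(10, 200, 800)) + [9999.0] * 200
    labs = [dict(scr_row("p1", "2015-01-01", v), lab="urine_protein_quant")
            for v in vals]
    ds = make_dataset(patients=[patient_row("p1")], labs=labs)
    out = value_distribution(ctx_for(ds), "urine_protein_quant")
    got = dict(zip(out["stratum"], out["value"]))
    assert got["top_mass_fraction"] == pytest.approx(0.2)
    assert got["out_of_range_fraction"] >= 0.2


def test_value_distribution_all_distinct_in_range():
    labs = [dict(scr_row("p1", "2015-01-01", v), lab="urine_protein_quant")
            for v in [10.0, 20.0, 30.0, 40.0]]
    ds = make_dataset(patients=[patient_row("p1")], labs=labs)
    out = value_distribution(ctx_for(ds), "urine_protein_quant")
    got = dict(zip(out["stratum"], out["value"]))
    assert got["top_mass_fraction"] == pytest.approx(0.25)
    assert got["out_of_range_fraction"] == 0.0


def test_med_timing_negative_offset(analysis_config):
    from ssdqa.attrition import COHORT_COLUMNS
    ds = make_dataset(patients=[patient_row("p1")],
                      meds=[{"patient_id": "p1", "date": "2015-01-01",
                             "drug_class": "acei_arb"}])
    cohort = pd.DataFrame([{"patient_id": "p1", "site_id": "hs01",
                            "ced": pd.Timestamp("2015-01-31")}],
                          columns=COHORT_COLUMNS)
    ctx = ctx_for(ds)
    ctx._attrition = (pd.DataFrame(), cohort)
    out = med_timing(ctx)
    got = dict(zip(out["stratum"], out["value"]))
    assert got["median"] == -30.0
    assert got["frac_negative"] == 1.0
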