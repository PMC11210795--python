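"""The 11-step eligibility sequence, entry dates, and eGFR characterization."""

import numpy as np
import pandas as pd
import pytest

from ssdqa import (AnalysisConfig, apply_attrition, egfr_threshold_curve,
                   egfr_trajectory_medians, qualifying_entry, trajectory_slope)

from conftest import height_row, make_dataset, patient_row, scr_row, visit_row
from oracle import oracle_attrition


def _scr_for_egfr(egfr, height):
    return 0.413 * height / egfr


def _qualifying_patient(egfr3=44.0, insert_normal=False):
    """One patient engineered to satisfy every step (hand-traceable)."""
    pid = "p1"
    patients = [patient_row(pid, birth="2005-02-20")]   # age ~10 in 2015
    visits = [visit_row(pid, "2015-03-01", specialty="nephrology")]
    labs = [scr_row(pid, "2015-03-01", 1.2)]            # h=140 -> eGFR 48.18
    vitals = [height_row(pid, "2015-03-11", 140.0)]     # delta = 10 d
    labs.append(scr_row(pid, "2015-06-09", _scr_for_egfr(45.0, 140.0)))   # +100 d
    labs.append(scr_row(pid, "2015-09-27", _scr_for_egfr(egfr3, 140.0)))  # +210 d
    vitals.append(height_row(pid, "2015-06-09", 140.0))
    vitals.append(height_row(pid, "2015-09-27", 140.0))
    if insert_normal:
        labs.append(scr_row(pid, "2015-04-15", _scr_for_egfr(95.0, 140.0)))
    return make_dataset(patients=patients, visits=visits, vitals=vitals,
                        labs=labs)


def test_hand_traced_patient_retained_through_all_steps():
    report, cohort = apply_attrition(_qualifying_patient())
    counts = report.sort_values("step")["retained"].tolist()
    assert counts == [1] * 11
    assert cohort.iloc[0]["ced"] == pd.Timestamp("2015-03-01")


def test_intervening_normal_excludes_at_step_seven():
    report, cohort = apply_attrition(_qualifying_patient(insert_normal=True))
    counts = report.sort_values("step")["retained"].tolist()
    assert counts[:7] == [1] * 7 and counts[7:] == [0] * 4
    assert len(cohort) == 0


def test_prior_dialysis_excludes_only_before_entry():
    ds = _qualifying_patient()
    before = ds.procs.copy()
    row = {"patient_id": "p1", "date": pd.Timestamp("2015-01-01"),
           "code": "90935", "code_group": "chronic_dialysis"}
    ds.procs = pd.DataFrame([row])
    report, cohort = apply_attrition(ds)
    assert report.sort_values("step")["retained"].tolist()[-2:] == [0, 0]
    ds.procs = pd.DataFrame([dict(row, date=pd.Timestamp("2016-01-01"))])
    report, cohort = apply_attrition(ds)
    assert len(cohort) == 1
    assert len(before) == 0


def test_empty_dataset_all_steps_zero():
    ds = make_dataset(patients=[patient_row("p1")])
    report, cohort = apply_attrition(ds)
    assert (report["retained"] == 0).all() and len(cohort) == 0


def test_qualifying_entry_gap_boundary():
    low = 30.0
    d = np.array(["2015-01-01", "2015-03-31", "2015-04-01", "2015-06-01"],
                 dtype="datetime64[D]")
    v = np.array([50.0, 50.0, 50.0, 50.0])
    # first additional low lands on day 89 (no) vs day 90 (yes)
    assert qualifying_entry(d[[0, 1, 3]], v[:3], gap_days=90) is None
    assert qualifying_entry(d[[0, 2, 3]], v[:3], gap_days=90) is not None


def test_attrition_matches_oracle_on_adversarial_data():
    from oracle import random_adversarial_dataset
    cfg = AnalysisConfig()
    rng = np.random.default_rng(99)
    for _ in range(25):
        ds = random_adversarial_dataset(rng, make_dataset, patient_row,
                                        visit_row, scr_row, height_row)
        report, cohort = apply_attrition(ds, cfg)
        counts_o, survivors_o = oracle_attrition(ds, cfg)
        for site, expected in counts_o.items():
            got = report[report["site_id"] == site].sort_values("step")
            assert got["retained"].tolist() == expected
        assert dict(zip(cohort["patient_id"], cohort["ced"])) == survivors_o


def test_threshold_curve_counting_and_monotonicity():
    egfrs = pd.DataFrame({
        "patient_id": ["a", "b", "c", "d"],
        "egfr": [35.0, 48.0, 62.0, 85.0],
        "date": pd.Timestamp("2015-01-01"),
    })
    cohort = pd.DataFrame({"patient_id": list("abcd"), "site_id": "s1",
                           "ced": pd.Timestamp("2015-01-01")})
    curve = egfr_threshold_curve(egfrs, cohort, [40.0, 50.0, 60.0])
    props = dict(zip(curve["threshold"], curve["proportion"]))
    assert props == {40.0: 0.25, 50.0: 0.5, 60.0: 0.5}
    assert (curve.sort_values("threshold")["proportion"].diff().dropna() >= 0).all()


def test_single_patient_threshold_curve():
    egfrs = pd.DataFrame({"patient_id": ["a"], "egfr": [48.0],
                          "date": pd.Timestamp("2015-01-01")})
    cohort = pd.DataFrame({"patient_id": ["a"], "site_id": "s1",
                           "ced": pd.Timestamp("2015-01-01")})
    curve = egfr_threshold_curve(egfrs, cohort, [40.0, 50.0, 60.0])
    assert curve["proportion"].tolist() == [0.0, 1.0, 1.0]


def test_empty_cohort_threshold_curve_empty():
    out = egfr_threshold_curve(pd.DataFrame(), pd.DataFrame(), [50.0])
    assert len(out) == 0


def test_trajectory_offsets_floor_arithmetic():
    ced = pd.Timestamp("2016-01-01")
    egfrs = pd.DataFrame({
        "patient_id": ["a", "a"],
        "date": [ced - pd.Timedelta(days=400), ced],
        "egfr": [80.0, 48.0],
    })
    cohort = pd.DataFrame({"patient_id": ["a"], "site_id": "s1", "ced": ced})
    med = egfr_trajectory_medians(cohort, egfrs)
    got = dict(zip(med["offset"], med["median_egfr"]))
    assert got == {-2: 80.0, 0: 48.0}


def test_decline_rate_recovered_from_simulated_truth(medium_sim, analysis_config):
    from ssdqa import egfr_results
    cfg, ds, _ = medium_sim
    egfrs = egfr_results(ds, analysis_config)
    report, cohort = apply_attrition(ds, analysis_config, egfrs=egfrs)
    assert len(cohort) >= 500
    med = egfr_trajectory_medians(cohort, egfrs)
    slope = trajectory_slope(med)
    assert slope == pytest.approx(cfg.egfr_decline_mean, abs=1.0)
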