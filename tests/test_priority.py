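"""The prioritization decision table, calibrated to the published site summary."""

import pytest

from ssdqa import AnalysisConfig, assign_priority, element_tier
from ssdqa.priority import normalize_dq_issue, normalize_element

CFG = AnalysisConfig()

# the 13 published site-summary issues: (domain, element, dq issue, info) -> priority
SITE_SUMMARY_ROWS = [
    ("cohort definition", "attrition step 5", "counts high",
     "see also domain: anthropometrics, element:height", "urgent"),
    ("anthropometrics", "height", "values low",
     "see also domain: cohort_definition, element:attrition_step_5", "urgent"),
    ("laboratory tests", "serum creatinine", "missingness",
     "calendar years missing: 2014", "high"),
    ("cohort definition", "high serum creatinine cohort", "counts low",
     "NA", "medium"),
    ("cohort entry", "cohort entry", "missingness",
     "calendar years missing: 2009, 2010, 2011, 2012, 2013", "medium"),
    ("laboratory tests", "quantitative urine protein measurement", "missingness",
     "calendar years missing: 2014", "medium"),
    ("anthropometrics", "height", "counts high", "NA", "medium"),
    ("anthropometrics", "weight", "counts high", "NA", "medium"),
    ("blood_pressure", "diastolic", "counts high", "NA", "medium"),
    ("blood_pressure", "systolic", "counts high", "NA", "medium"),
    ("laboratory tests", "serum cystatin", "missingness",
     "calendar years missing: 2014, 2015, 2018, 2019", "low"),
    ("medications", "calcium channel blockers", "counts high", "NA", "low"),
    ("medications", "loop diuretics", "counts high", "NA", "low"),
]


@pytest.mark.parametrize("domain,element,dq_issue,info,expected",
                         SITE_SUMMARY_ROWS)
def test_published_site_summary_priorities(domain, element, dq_issue, info,
                                           expected):
    issue = {"domain": domain, "element": element, "dq_issue": dq_issue,
             "info": info}
    assert assign_priority(issue, CFG) == expected


def test_priority_distribution_matches_published_rows():
    got = [assign_priority({"domain": d, "element": e, "dq_issue": q, "info": i},
                           CFG)
           for d, e, q, i, _ in SITE_SUMMARY_ROWS]
    assert got.count("urgent") == 2 and got.count("high") == 1
    assert got.count("medium") == 7 and got.count("low") == 3


def test_dq_issue_normalization():
    assert normalize_dq_issue("values low") == "outlier values"
    assert normalize_dq_issue("counts high") == "high counts"
    assert normalize_dq_issue("missingness") == "missingness"


def test_element_normalization():
    assert normalize_element("serum cystatin") == "serum_cystatin_c"
    assert normalize_element("attrition step 5") == "attrition_step_5"
    assert normalize_element("Height") == "height"


def test_tiers():
    assert element_tier("height", CFG) == "eligibility"
    assert element_tier("attrition step 8", CFG) == "eligibility"
    assert element_tier("systolic_bp", CFG) == "exposure_outcome"
    assert element_tier("urine_protein_quant", CFG) == "covariate"


def test_total_missingness_of_eligibility_element_is_urgent():
    issue = {"domain": "specialty", "element": "nephrology_specialty",
             "dq_issue": "missingness", "info": "all calendar years missing"}
    assert assign_priority(issue, CFG) == "urgent"


def test_unknown_element_defaults_to_covariate_with_warning(caplog):
    import logging
    with caplog.at_level(logging.WARNING, logger="ssdqa.priority"):
        p = assign_priority({"domain": "laboratory tests",
                             "element": "mystery_assay",
                             "dq_issue": "missingness",
                             "info": "calendar years missing: 2014"}, CFG)
    assert p == "medium"
    assert any("tier map" in r.message for r in caplog.records)
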