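"""The DQ1/DQ2 check catalogs with their taxonomy metadata.

Every check carries the framework's annotation axes: a Kahn-style *check
category* (completeness, conformance, plausibility, concordance, consistency),
a method-directed *check type*, a *clinical goal*, a *data-quality probe*, the
domain(s) interrogated, and the executor family bound to it.  A single
computation can serve several categories through distinct postprocessing, so
category assignments can outnumber checks.

The aggregate round (DQ1) catalog has 79 checks; the row-level round (DQ2)
catalog has 65 unique checks spanning 68 domain assignments (three checks
cover two domains).  Checks aimed at domains outside the simplified CDM
(diagnoses/conditions, cross-domain fact testing) carry no executor and are
skipped at run time with a logged warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

CHECK_CATEGORIES = ("completeness", "conformance", "plausibility",
                    "concordance", "consistency")
CHECK_TYPES = (
    "attribution", "attrition step check", "clinical correlation",
    "clinical fact relationships", "clinical fact density", "clinical thresholds",
    "code utilization", "frequency distributions", "specialty correlation",
    "summary statistics", "temporal relationships", "trends over time",
    "utilization thresholds", "variable stratifications",
)
CLINICAL_GOALS = ("clinical care", "diagnostic evaluation",
                  "epidemiologic distribution", "utilization")
DQ_PROBES = ("anomalous event sequencing", "anomalous values",
             "data representation error", "inconsistent trends")
DQ_ISSUES = ("atypical code distribution", "atypical numeric distribution",
             "discordant values", "high counts", "high spike", "low counts",
             "low spike", "mapping error", "missingness", "outlier values")
ROUNDS = ("DQ1", "DQ2")


@dataclass(frozen=True)
class CheckSpec:
    check_num: str
    summary: str
    check_type: str
    domains: Tuple[str, ...]
    variable: str
    check_categories: Tuple[str, ...]
    dq_probe: str
    clinical_goal: str
    round: str
    executor: Optional[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.round not in ROUNDS:
            raise ValueError(f"{self.check_num}: round must be DQ1 or DQ2")
        if self.check_type not in CHECK_TYPES:
            raise ValueError(f"{self.check_num}: unknown check type {self.check_type}")
        if self.dq_probe not in DQ_PROBES:
            raise ValueError(f"{self.check_num}: unknown probe {self.dq_probe}")
        if self.clinical_goal not in CLINICAL_GOALS:
            raise ValueError(f"{self.check_num}: unknown goal {self.clinical_goal}")
        bad = [c for c in self.check_categories if c not in CHECK_CATEGORIES]
        if bad or not self.check_categories:
            raise ValueError(f"{self.check_num}: bad categories {bad}")
        if not 1 <= len(self.domains) <= 2:
            raise ValueError(f"{self.check_num}: a check covers 1-2 domains")


def _mk(round_, seq, summary, ctype, domains, var_label, cats, probe, goal,
        executor, **params) -> CheckSpec:
    if isinstance(domains, str):
        domains = (domains,)
    return CheckSpec(
        check_num=f"{round_}-{seq:03d}", summary=summary, check_type=ctype,
        domains=tuple(domains), variable=var_label, check_categories=tuple(cats),
        dq_probe=probe, clinical_goal=goal, round=round_, executor=executor,
        params=params)


_PRETTY = {"height": "height", "weight": "weight", "systolic_bp": "systolic BP",
           "diastolic_bp": "diastolic BP", "serum_creatinine": "serum creatinine",
           "serum_cystatin_c": "serum cystatin C",
           "urine_protein_quant": "quantitative urine protein",
           "urine_creatinine": "urine creatinine"}


def build_dq1_catalog() -> List[CheckSpec]:
    checks: List[CheckSpec] = []
    n = iter(range(1, 200))

    for var in ("height", "weight"):          # anthropometrics: 8
        p = _PRETTY[var]
        checks += [
            _mk("DQ1", next(n), f"proportion of patients with at least one {p} per year",
                "trends over time", "anthropometrics", var, ["completeness"],
                "data representation error", "utilization", "completeness_trend", variable=var),
            _mk("DQ1", next(n), f"{p} measurements per patient",
                "clinical fact density", "anthropometrics", var, ["plausibility"],
                "anomalous values", "utilization", "per_patient_density", variable=var),
            _mk("DQ1", next(n), f"distribution of {p} values against physiologic bounds",
                "frequency distributions", "anthropometrics", var,
                ["plausibility", "conformance"], "anomalous values", "clinical care",
                "value_distribution", variable=var),
            _mk("DQ1", next(n), f"yearly {p} record counts",
                "trends over time", "anthropometrics", var,
                ["completeness", "plausibility"], "inconsistent trends", "utilization",
                "yearly_count_trend", variable=var),
        ]

    for var in ("systolic_bp", "diastolic_bp"):   # vital signs: 8 (with 2 shared)
        p = _PRETTY[var]
        checks += [
            _mk("DQ1", next(n), f"proportion of patients with at least one {p} per year",
                "trends over time", "vital signs", var, ["completeness"],
                "data representation error", "utilization", "completeness_trend", variable=var),
            _mk("DQ1", next(n), f"distribution of {p} values",
                "frequency distributions", "vital signs", var, ["plausibility"],
                "anomalous values", "clinical care", "value_distribution", variable=var),
            _mk("DQ1", next(n), f"{p} measurements per patient",
                "clinical fact density", "vital signs", var, ["plausibility"],
                "anomalous values", "utilization", "per_patient_density", variable=var),
        ]
    checks += [
        _mk("DQ1", next(n), "systolic and diastolic BP measurements present on the same day",
            "clinical fact relationships", "vital signs", "blood_pressure",
            ["concordance"], "data representation error", "clinical care", "same_day_concordance"),
        _mk("DQ1", next(n), "correlation of systolic and diastolic blood pressures",
            "clinical correlation", "vital signs", "blood_pressure",
            ["concordance", "plausibility"], "inconsistent trends", "clinical care",
            "pair_correlation"),
    ]

    # diagnoses/conditions: 8 — outside the simplified CDM, no executor bound
    diag_cats = [["completeness", "concordance"], ["completeness", "concordance"],
                 ["completeness", "concordance"], ["concordance", "conformance"],
                 ["conformance", "plausibility"], ["conformance", "plausibility"],
                 ["plausibility"], ["plausibility"]]
    diag_types = ["code utilization", "clinical fact relationships",
                  "trends over time", "code utilization", "frequency distributions",
                  "code utilization", "clinical fact density", "variable stratifications"]
    for i, (cats, ctype) in enumerate(zip(diag_cats, diag_types), start=1):
        checks.append(_mk("DQ1", next(n),
                          f"CKD-related condition codes, facet {i}",
                          ctype, "diagnoses", "ckd_diagnosis", cats,
                          "data representation error", "diagnostic evaluation", None))

    for lab in ("serum_creatinine", "serum_cystatin_c",
                "urine_protein_quant", "urine_creatinine"):   # laboratory: 16
        p = _PRETTY[lab]
        checks += [
            _mk("DQ1", next(n), f"proportion of patients with at least one {p} per year",
                "trends over time", "laboratory", lab, ["completeness"],
                "data representation error", "utilization", "completeness_trend", variable=lab),
            _mk("DQ1", next(n), f"quantitative distribution of {p} results",
                "frequency distributions", "laboratory", lab, ["plausibility"],
                "anomalous values", "clinical care", "value_distribution", variable=lab),
            _mk("DQ1", next(n), f"proportion of {p} values with unit type mapped",
                "frequency distributions", "laboratory", lab, ["conformance"],
                "data representation error", "clinical care", "unit_mapped_proportion", lab=lab),
            _mk("DQ1", next(n), f"yearly {p} record counts",
                "trends over time", "laboratory", lab, ["completeness"],
                "inconsistent trends", "utilization", "yearly_count_trend", variable=lab),
        ]

    for cls in ("acei_arb", "calcium_channel_blocker", "loop_diuretic",
                "thiazide", "beta_blocker", "other"):          # medications: 24
        checks += [
            _mk("DQ1", next(n), f"yearly {cls} order counts",
                "trends over time", "medications", cls, ["completeness"],
                "inconsistent trends", "utilization", "yearly_count_trend",
                variable=f"med:{cls}"),
            _mk("DQ1", next(n), f"{cls} orders per treated patient",
                "clinical fact density", "medications", cls, ["plausibility"],
                "anomalous values", "utilization", "per_patient_density",
                variable=f"med:{cls}"),
            _mk("DQ1", next(n), f"share of medication orders in class {cls}",
                "code utilization", "medications", cls, ["conformance"],
                "data representation error", "epidemiologic distribution",
                "category_frequency", domain="meds", fld="drug_class", focus=cls),
            _mk("DQ1", next(n), f"{cls} orders concordant with condition records",
                "clinical fact relationships", "medications", cls, ["concordance"],
                "anomalous event sequencing", "clinical care", None),
        ]

    for grp in ("chronic_dialysis", "kidney_transplant"):      # procedures: 8
        checks += [
            _mk("DQ1", next(n), f"{grp} procedure code frequency by site",
                "code utilization", "procedures", grp, ["plausibility", "conformance"],
                "data representation error", "utilization", "code_utilization",
                code_group=grp),
            _mk("DQ1", next(n), f"yearly {grp} procedure counts",
                "trends over time", "procedures", grp, ["completeness"],
                "inconsistent trends", "utilization", "yearly_count_trend",
                variable=f"proc:{grp}"),
            _mk("DQ1", next(n), f"{grp} procedures per affected patient",
                "clinical fact density", "procedures", grp, ["plausibility"],
                "anomalous values", "utilization", "per_patient_density",
                variable=f"proc:{grp}"),
            _mk("DQ1", next(n), f"{grp} procedures concordant with visit records",
                "clinical fact relationships", "procedures", grp, ["concordance"],
                "anomalous event sequencing", "clinical care", None),
        ]

    checks += [                                                # other eligibility: 4
        _mk("DQ1", next(n), "patients retained at each cohort attrition step",
            "attrition step check", "cohort definition", "attrition",
            ["completeness", "plausibility"], "anomalous values",
            "epidemiologic distribution", "attrition"),
        _mk("DQ1", next(n), "proportion of cohort with at least one eGFR below threshold",
            "clinical thresholds", "cohort definition", "egfr",
            ["plausibility"], "anomalous values", "epidemiologic distribution",
            "egfr_threshold_curve"),
        _mk("DQ1", next(n), "proportion of patients with an in-person visit per year",
            "trends over time", "cohort definition", "in_person_visit",
            ["completeness"], "data representation error", "utilization",
            "completeness_trend", variable="in_person_visit"),
        _mk("DQ1", next(n), "distribution of computed eGFR values",
            "frequency distributions", "cohort definition", "egfr",
            ["plausibility"], "anomalous values", "clinical care",
            "value_distribution", variable="egfr"),
        # secular trends: 1
        _mk("DQ1", next(n), "cohort entries per calendar year",
            "temporal relationships", "secular trends", "cohort_entry",
            ["plausibility"], "inconsistent trends", "epidemiologic distribution",
            "yearly_count_trend", variable="cohort_entry"),
        # specialty: 1
        _mk("DQ1", next(n), "proportion of patients with a nephrology visit per year",
            "specialty correlation", "specialty", "nephrology_specialty",
            ["completeness"], "data representation error", "utilization",
            "completeness_trend", variable="nephrology_visit"),
        # follow-up duration: 1
        _mk("DQ1", next(n), "years of follow-up per patient",
            "clinical fact density", "follow-up", "followup_years",
            ["completeness", "plausibility"], "anomalous values", "utilization",
            "per_patient_density", variable="followup_years"),
    ]
    return checks


def build_dq2_catalog() -> List[CheckSpec]:
    checks: List[CheckSpec] = []
    n = iter(range(1, 200))

    for var in ("systolic_bp", "diastolic_bp"):   # vital signs: 13
        p = _PRETTY[var]
        cats_yearly = (["completeness", "consistency"] if var == "systolic_bp"
                       else ["completeness"])
        checks += [
            _mk("DQ2", next(n), f"proportion of patients with at least one {p} per year",
                "trends over time", "vital signs", var, ["completeness"],
                "data representation error", "utilization", "completeness_trend", variable=var),
            _mk("DQ2", next(n), f"yearly {p} record counts",
                "trends over time", "vital signs", var, cats_yearly,
                "inconsistent trends", "utilization", "yearly_count_trend", variable=var),
            _mk("DQ2", next(n), f"distribution of {p} values",
                "frequency distributions", "vital signs", var, ["plausibility"],
                "anomalous values", "clinical care", "value_distribution", variable=var),
            _mk("DQ2", next(n), f"{p} measurements per patient",
                "clinical fact density", "vital signs", var, ["plausibility"],
                "anomalous values", "utilization", "per_patient_density", variable=var),
        ]
    checks += [
        _mk("DQ2", next(n), "systolic and diastolic BP measurements present on the same day",
            "clinical fact relationships", "vital signs", "blood_pressure",
            ["concordance"], "data representation error", "clinical care", "same_day_concordance"),
        _mk("DQ2", next(n), "correlation of systolic and diastolic blood pressures",
            "clinical correlation", "vital signs", "blood_pressure",
            ["consistency"], "inconsistent trends", "clinical care", "pair_correlation"),
        _mk("DQ2", next(n), "distribution of same-day pulse pressure",
            "summary statistics", "vital signs", "pulse_pressure", ["plausibility"],
            "anomalous values", "clinical care", "value_distribution",
            variable="pulse_pressure"),
        _mk("DQ2", next(n), "BP measurement by visit-type stratification",
            "variable stratifications", "vital signs", "blood_pressure",
            ["plausibility"], "inconsistent trends", "utilization", None),
        _mk("DQ2", next(n), "BP unit conformance",
            "frequency distributions", "vital signs", "blood_pressure",
            ["conformance"], "data representation error", "clinical care",
            "category_frequency", domain="vitals", fld="unit"),
    ]

    # diagnoses/conditions: 9 — outside the simplified CDM, no executor bound
    diag_cats = [["completeness"], ["concordance"], ["concordance"], ["concordance"],
                 ["conformance"], ["conformance"], ["consistency"], ["consistency"],
                 ["consistency"]]
    diag_types = ["trends over time", "clinical fact relationships",
                  "clinical fact relationships", "code utilization",
                  "code utilization", "frequency distributions",
                  "temporal relationships", "trends over time",
                  "variable stratifications"]
    for i, (cats, ctype) in enumerate(zip(diag_cats, diag_types), start=1):
        checks.append(_mk("DQ2", next(n),
                          f"CKD-related condition codes, facet {i}",
                          ctype, "diagnoses", "ckd_diagnosis", cats,
                          "data representation error", "diagnostic evaluation", None))

    checks += [                                    # geographic: 8
        _mk("DQ2", next(n), "distribution of geocode granularity levels",
            "frequency distributions", "geographic", "geocode_level",
            ["conformance", "plausibility"], "data representation error",
            "epidemiologic distribution", "geocode_granularity"),
        _mk("DQ2", next(n), "proportion of patients with any geographic location data",
            "frequency distributions", "geographic", "geocode_level",
            ["completeness"], "data representation error", "epidemiologic distribution",
            "geocode_granularity", nonmissing=True),
    ]
    for level in ("zip5", "zip9", "tract", "block_group", "none"):
        checks.append(_mk("DQ2", next(n),
                          f"proportion of the cohort with {level} location data",
                          "frequency distributions", "geographic", "geocode_level",
                          ["completeness"], "data representation error", "epidemiologic distribution",
                          "geocode_granularity", level=level))
    checks.append(_mk("DQ2", next(n), "geocode availability by year",
                      "trends over time", "geographic", "geocode_level",
                      ["consistency"], "inconsistent trends",
                      "epidemiologic distribution", None))

    for lab in ("serum_creatinine", "serum_cystatin_c",
                "urine_protein_quant", "urine_creatinine"):    # laboratory: 11 singles
        p = _PRETTY[lab]
        checks += [
            _mk("DQ2", next(n), f"proportion of patients with at least one {p} per year",
                "trends over time", "laboratory", lab, ["completeness"],
                "data representation error", "utilization", "completeness_trend", variable=lab),
            _mk("DQ2", next(n), f"quantitative distribution of {p} results",
                "frequency distributions", "laboratory", lab, ["plausibility"],
                "anomalous values", "clinical care", "value_distribution", variable=lab),
        ]
    checks += [
        _mk("DQ2", next(n), "proportion of urine protein values with unit type mapped",
            "frequency distributions", "laboratory", "urine_protein_quant",
            ["conformance"], "data representation error", "clinical care",
            "unit_mapped_proportion", lab="urine_protein_quant"),
        _mk("DQ2", next(n), "yearly serum creatinine record counts",
            "trends over time", "laboratory", "serum_creatinine",
            ["completeness", "consistency"], "inconsistent trends", "utilization",
            "yearly_count_trend", variable="serum_creatinine"),
        _mk("DQ2", next(n), "yearly quantitative urine protein record counts",
            "trends over time", "laboratory", "urine_protein_quant",
            ["completeness", "consistency"], "inconsistent trends", "utilization",
            "yearly_count_trend", variable="urine_protein_quant"),
        # derivations: 2 singles
        _mk("DQ2", next(n), "proportion of cohort with at least one eGFR below threshold",
            "clinical thresholds", "derivations", "egfr", ["plausibility"],
            "anomalous values", "epidemiologic distribution", "egfr_threshold_curve"),
        _mk("DQ2", next(n), "distribution of computed eGFR values",
            "frequency distributions", "derivations", "egfr", ["plausibility"],
            "anomalous values", "clinical care", "value_distribution", variable="egfr"),
        # medications: 3 singles
        _mk("DQ2", next(n), "yearly antihypertensive order counts",
            "trends over time", "medications", "antihypertensive",
            ["completeness", "plausibility"], "inconsistent trends", "utilization",
            "yearly_count_trend", variable="med:antihypertensive"),
        _mk("DQ2", next(n), "medication orders per treated patient",
            "clinical fact density", "medications", "medications", ["plausibility"],
            "anomalous values", "utilization", "per_patient_density", variable="meds"),
        _mk("DQ2", next(n), "distribution of drug classes among orders",
            "code utilization", "medications", "drug_class", ["conformance"],
            "data representation error", "epidemiologic distribution",
            "category_frequency", domain="meds", fld="drug_class"),
        # procedures: 5
        _mk("DQ2", next(n), "chronic dialysis procedure code frequency by site",
            "code utilization", "procedures", "chronic_dialysis", ["plausibility"],
            "data representation error", "utilization", "code_utilization",
            code_group="chronic_dialysis"),
        _mk("DQ2", next(n), "kidney transplant procedure code frequency by site",
            "code utilization", "procedures", "kidney_transplant", ["plausibility"],
            "data representation error", "utilization", "code_utilization",
            code_group="kidney_transplant"),
        _mk("DQ2", next(n), "yearly chronic dialysis procedure counts",
            "trends over time", "procedures", "chronic_dialysis", ["completeness"],
            "inconsistent trends", "utilization", "yearly_count_trend",
            variable="proc:chronic_dialysis"),
        _mk("DQ2", next(n), "yearly kidney transplant procedure counts",
            "trends over time", "procedures", "kidney_transplant", ["completeness"],
            "inconsistent trends", "utilization", "yearly_count_trend",
            variable="proc:kidney_transplant"),
        _mk("DQ2", next(n), "procedure records per patient",
            "clinical fact density", "procedures", "procedures", ["plausibility"],
            "anomalous values", "utilization", "per_patient_density", variable="procs"),
        # eligibility: 2
        _mk("DQ2", next(n), "patients retained at each cohort attrition step",
            "attrition step check", "cohort definition", "attrition",
            ["completeness", "plausibility"], "anomalous values",
            "epidemiologic distribution", "attrition"),
        _mk("DQ2", next(n), "cross-site comparison of attrition step proportions",
            "attrition step check", "cohort definition", "attrition",
            ["plausibility"], "anomalous values", "epidemiologic distribution",
            "attrition", proportions=True),
        # secular trends: 2
        _mk("DQ2", next(n), "cohort entries per calendar year",
            "temporal relationships", "secular trends", "cohort_entry",
            ["completeness", "plausibility"], "inconsistent trends",
            "epidemiologic distribution", "yearly_count_trend", variable="cohort_entry"),
        _mk("DQ2", next(n), "distribution of cohort entry years across sites",
            "temporal relationships", "secular trends", "cohort_entry",
            ["plausibility"], "inconsistent trends", "epidemiologic distribution",
            "yearly_count_trend", variable="cohort_entry"),
        # specialty: 2
        _mk("DQ2", next(n), "proportion of patients with a nephrology visit per year",
            "specialty correlation", "specialty", "nephrology_specialty",
            ["completeness", "plausibility"], "data representation error", "utilization",
            "completeness_trend", variable="nephrology_visit"),
        _mk("DQ2", next(n), "distribution of provider specialties among visits",
            "attribution", "specialty", "provider_specialty", ["conformance"],
            "data representation error", "utilization",
            "category_frequency", domain="visits", fld="provider_specialty"),
        # cross-domain clinical fact testing: 1 (outside simplified CDM)
        _mk("DQ2", next(n), "cross-domain agreement of CKD-related clinical facts",
            "clinical fact relationships", "cross-domain", "clinical_facts",
            ["concordance"], "anomalous event sequencing", "diagnostic evaluation",
            None),
        # visit characteristics: 4
        _mk("DQ2", next(n), "distribution of visit types",
            "frequency distributions", "visits", "visit_type", ["conformance"],
            "data representation error", "utilization",
            "category_frequency", domain="visits", fld="visit_type"),
        _mk("DQ2", next(n), "yearly visit counts",
            "trends over time", "visits", "visits", ["completeness"],
            "inconsistent trends", "utilization", "yearly_count_trend",
            variable="visits"),
        _mk("DQ2", next(n), "visits per patient",
            "clinical fact density", "visits", "visits", ["plausibility"],
            "anomalous values", "utilization", "per_patient_density", variable="visits"),
        _mk("DQ2", next(n), "proportion of patients with an in-person visit per year",
            "trends over time", "visits", "in_person_visit", ["completeness"],
            "data representation error", "utilization", "completeness_trend",
            variable="in_person_visit"),
        # dual-domain checks: 3
        _mk("DQ2", next(n), "days from cohort entry to first antihypertensive order",
            "temporal relationships", ("medications", "derivations"),
            "antihypertensive_timing", ["plausibility"],
            "anomalous event sequencing", "clinical care", "med_timing"),
        _mk("DQ2", next(n), "median eGFR by years from cohort entry",
            "trends over time", ("laboratory", "derivations"), "egfr_trajectory",
            ["consistency", "plausibility"], "anomalous event sequencing",
            "clinical care", "egfr_trajectory_medians"),
        _mk("DQ2", next(n), "proportion of eligible creatinines with a linkable height",
            "clinical fact relationships", ("anthropometrics", "laboratory"),
            "height_creatinine_link", ["completeness", "plausibility"],
            "data representation error", "clinical care", "linkage_completeness"),
    ]
    return checks


def load_catalog(round_: str) -> List[CheckSpec]:
    """The encoded catalog for one round ('DQ1' or 'DQ2')."""
    if round_ == "DQ1":
        return build_dq1_catalog()
    if round_ == "DQ2":
        return build_dq2_catalog()
    raise ValueError(f"round must be one of {ROUNDS}, got {round_!r}")


def catalog_frame(checks: List[CheckSpec]) -> pd.DataFrame:
    """Catalog as a tidy frame (one row per check; domains/categories joined)."""
    return pd.DataFrame([{
        "check_num": c.check_num, "summary": c.summary, "check_type": c.check_type,
        "domains": ";".join(c.domains), "variable": c.variable,
        "check_categories": ";".join(c.check_categories), "dq_probe": c.dq_probe,
        "clinical_goal": c.clinical_goal, "round": c.round,
        "executor": c.executor or "",
    } for c in checks])


def domain_counts(checks: List[CheckSpec]) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for c in checks:
        for d in c.domains:
            out[d] = out.get(d, 0) + 1
    return out


def category_counts(checks: List[CheckSpec]) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for c in checks:
        for cat in c.check_categories:
            out[cat] = out.get(cat, 0) + 1
    return out
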