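"""Issue prioritization: a four-level decision table over (element tier,
dq-issue kind, missingness pattern).

Priorities mean: *urgent* — analyses would be impossible with the affected
data (cohort attrition anomalies, total missingness or out-of-range values of
eligibility-critical variables); *high* — missingness/distortion of variables
not foundational but disruptive to specific analyses; *medium* — abnormalities
likely characteristic of source data (interior-year gaps of covariates, count
anomalies on clinical domains, late data onset); *low* — source-data quirks
with minimal analytic impact (expected-sparse labs, medication count
anomalies, demographic distribution shifts).
"""

from __future__ import annotations

import logging
import re

from . import schema
from .config import AnalysisConfig

log = logging.getLogger(__name__)

PRIORITIES = ("urgent", "high", "medium", "low")

_DQ_ALIASES = {
    "values low": "outlier values",
    "values high": "outlier values",
    "counts high": "high counts",
    "counts low": "low counts",
}

_ELEMENT_ALIASES = {
    "serum cystatin": "serum_cystatin_c",
    "serum cystatin c": "serum_cystatin_c",
    "serum creatinine": "serum_creatinine",
    "quantitative urine protein measurement": "urine_protein_quant",
    "urine protein": "urine_protein_quant",
    "urine creatinine": "urine_creatinine",
    "calcium channel blockers": "calcium_channel_blocker",
    "loop diuretics": "loop_diuretic",
    "beta blockers": "beta_blocker",
    "systolic": "systolic_bp",
    "diastolic": "diastolic_bp",
    "cohort entry": "cohort_entry",
    "high serum creatinine cohort": "high_serum_creatinine_cohort",
    "nephrology specialty": "nephrology_specialty",
}


def normalize_dq_issue(dq_issue: str) -> str:
    s = str(dq_issue).strip().lower()
    return _DQ_ALIASES.get(s, s)


def normalize_element(element: str) -> str:
    s = str(element).strip().lower()
    s = _ELEMENT_ALIASES.get(s, s)
    return re.sub(r"\s+", "_", s)


def element_tier(element: str, config: AnalysisConfig) -> str:
    """eligibility > exposure/outcome > covariate."""
    el = normalize_element(element)
    if el.startswith("attrition_step") or el in {normalize_element(e) for e in
                                                 config.eligibility_elements}:
        return "eligibility"
    if el in {normalize_element(e) for e in config.exposure_outcome_elements}:
        return "exposure_outcome"
    return "covariate"


def _leading_years(info: str, config: AnalysisConfig) -> bool:
    """True when the missing calendar years in ``info`` are a consecutive run
    starting at the study interval's first year."""
    years = sorted(int(y) for y in re.findall(r"(?:19|20)\d{2}", str(info)))
    if not years or years[0] != config.study_interval[0]:
        return False
    return years == list(range(years[0], years[0] + len(years)))


def assign_priority(issue: dict, config: AnalysisConfig | None = None) -> str:
    """One priority for one issue tuple (domain, element, dq issue, info)."""
    config = config or AnalysisConfig()
    dq = normalize_dq_issue(issue.get("dq_issue", ""))
    el = normalize_element(issue.get("element", ""))
    domain = str(issue.get("domain", "")).strip().lower()
    info = str(issue.get("info", ""))
    tier = element_tier(el, config)
    if tier == "covariate" and el not in _KNOWN_ELEMENTS(config):
        log.warning("element %r not in tier map; defaulting to covariate tier", el)

    sparse = {normalize_element(e) for e in config.expected_sparse_elements}
    demographic = {normalize_element(e) for e in config.demographic_elements}

    if dq == "missingness":
        if el in sparse:
            return "low"
        if el == "cohort_entry" or _leading_years(info, config):
            return "medium"                      # late data onset
        if "all calendar years" in info:
            return "urgent" if tier == "eligibility" else "high"
        return "high" if tier in ("eligibility", "exposure_outcome") else "medium"
    if dq == "outlier values":
        return "urgent" if tier == "eligibility" else "high"
    if dq in ("high counts", "low counts"):
        if el.startswith("attrition_step"):
            return "urgent"
        if domain == "medications" or el in schema.DRUG_CLASSES:
            return "low"
        return "medium"                          # incl. secondary cohorts
    if dq in ("high spike", "low spike"):
        return "medium"
    if dq == "mapping error":
        return "urgent" if tier == "eligibility" else "high"
    if dq == "atypical numeric distribution":
        if tier == "eligibility":
            return "urgent"
        return "high" if tier == "exposure_outcome" else "medium"
    if dq == "discordant values":
        return "high"
    if dq == "atypical code distribution":
        return "low" if el in demographic else "medium"
    return "medium"


def _KNOWN_ELEMENTS(config: AnalysisConfig) -> set:
    out = set()
    for group in (config.eligibility_elements, config.exposure_outcome_elements,
                  config.expected_sparse_elements, config.secondary_cohort_elements,
                  config.demographic_elements):
        out |= {normalize_element(e) for e in group}
    out |= {normalize_element(e) for e in
            schema.LABS + schema.VITAL_MEASURES + schema.DRUG_CLASSES
            + schema.PROC_CODE_GROUPS}
    out |= {"drug_class", "visit_type", "provider_specialty", "geocode_level",
            "blood_pressure", "pulse_pressure", "visits", "procedures",
            "medications", "height_creatinine_link", "followup_years"}
    return out
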