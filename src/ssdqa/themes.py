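"""Theme assignment: many-to-one lookup from issue signature to the broader
impact categories used to summarize findings for the study team.

Themes are descriptive labels, not inference; an issue can carry several
(e.g. out-of-range heights affect both value plausibility and eligibility).
Every issue receives at least one theme.
"""

from __future__ import annotations

from typing import List

from . import schema
from .config import AnalysisConfig
from .priority import element_tier, normalize_dq_issue, normalize_element

THEMES = (
    "Anomalies affecting eligibility",
    "Variation in time of cohort entry",
    "Variation in clinical utilization",
    "Missingness of major variables",
    "Duplication of values",
    "Variation in code utilization",
    "Implausible value detection",
    "Implausible temporal trends",
    "Anomalous distribution of results",
    "Event sequencing anomalies",
    "Comparatively anomalous institutional clinical values",
)

_VITAL_ANTHRO = {"height", "weight", "systolic_bp", "diastolic_bp"}
_UTILIZATION_ELEMENTS = {"visit_type", "provider_specialty", "visits",
                         "in_person_visit"}


def assign_theme(issue: dict, config: AnalysisConfig | None = None) -> List[str]:
    config = config or AnalysisConfig()
    dq = normalize_dq_issue(issue.get("dq_issue", ""))
    el = normalize_element(issue.get("element", ""))
    tier = element_tier(el, config)
    themes: List[str] = []

    def add(t: str) -> None:
        if t not in themes:
            themes.append(t)

    if el == "cohort_entry" and dq == "missingness":
        add("Variation in time of cohort entry")
    if dq == "missingness" and el != "cohort_entry":
        if el == "nephrology_specialty":
            add("Anomalies affecting eligibility")
        add("Missingness of major variables")
    if dq in ("high counts", "low counts"):
        if el.startswith("attrition_step") or el in {
                normalize_element(e) for e in config.secondary_cohort_elements}:
            add("Anomalies affecting eligibility")
        elif dq == "high counts" and el in _VITAL_ANTHRO:
            add("Duplication of values")
        elif el in schema.DRUG_CLASSES or el in _UTILIZATION_ELEMENTS:
            add("Variation in clinical utilization")
        else:
            add("Comparatively anomalous institutional clinical values")
    if dq in ("high spike", "low spike"):
        add("Implausible temporal trends")
    if dq == "outlier values":
        add("Implausible value detection")
        if tier == "eligibility":
            add("Anomalies affecting eligibility")
    if dq == "atypical numeric distribution":
        if el == "antihypertensive_timing":
            add("Event sequencing anomalies")
        else:
            add("Anomalous distribution of results")
    if dq == "discordant values":
        add("Comparatively anomalous institutional clinical values")
    if dq == "mapping error":
        add("Anomalies affecting eligibility")
    if dq == "atypical code distribution":
        if el in _UTILIZATION_ELEMENTS:
            add("Variation in clinical utilization")
        else:
            add("Variation in code utilization")

    if not themes:
        add("Comparatively anomalous institutional clinical values")
    return themes
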