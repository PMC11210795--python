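"""Value sets and table schemas for the simplified common data model (CDM).

The CDM used here is a deliberately small, six-domain subset of the kind of
relational schema multi-site EHR research networks standardize on: patients,
visits, vitals, labs, medication orders, and procedures, linked by opaque
patient identifiers.  Each coded field carries an explicit value set; structural
conformance checking validates against these sets.
"""

from __future__ import annotations

DOMAINS = ("patients", "visits", "vitals", "labs", "meds", "procs")

SEX = ("female", "male", "unknown")
RACE = ("white", "black", "asian", "multiple", "other", "unknown")
ETHNICITY = ("hispanic", "non_hispanic", "missing")
GEOCODE_LEVELS = ("none", "zip5", "zip9", "tract", "block_group")

VISIT_TYPES = ("inpatient", "outpatient", "other_ambulatory", "telehealth", "administrative")
IN_PERSON_VISIT_TYPES = ("inpatient", "outpatient", "other_ambulatory")
SPECIALTIES = ("nephrology", "cardiology", "general_pediatrics", "none")

VITAL_MEASURES = ("systolic_bp", "diastolic_bp", "height", "weight")
VITAL_UNITS = ("cm", "kg", "mmHg", "in", "lb", "missing")
#: unit a conformant record of each measure is expected to carry
VITAL_ALLOWED_UNITS = {
    "systolic_bp": ("mmHg",),
    "diastolic_bp": ("mmHg",),
    "height": ("cm",),
    "weight": ("kg",),
}

LABS = ("serum_creatinine", "serum_cystatin_c", "urine_protein_quant", "urine_creatinine")
#: allowed (mapped) unit strings per lab; anything else, or "missing", is unmapped
LAB_ALLOWED_UNITS = {
    "serum_creatinine": ("mg/dL",),
    "serum_cystatin_c": ("mg/L",),
    "urine_protein_quant": ("mg/dL",),
    "urine_creatinine": ("mg/dL",),
}

DRUG_CLASSES = ("acei_arb", "calcium_channel_blocker", "loop_diuretic",
                "thiazide", "beta_blocker", "other")
ANTIHYPERTENSIVE_CLASSES = ("acei_arb", "calcium_channel_blocker", "loop_diuretic",
                            "thiazide", "beta_blocker")

PROC_CODE_GROUPS = ("chronic_dialysis", "kidney_transplant", "other")

#: column order per domain table; also the CSV header written by ``write_dataset``
COLUMNS = {
    "patients": ["patient_id", "site_id", "birth_date", "sex", "race",
                 "ethnicity", "geocode_level"],
    "visits": ["visit_id", "patient_id", "date", "visit_type",
               "provider_specialty", "in_person"],
    "vitals": ["patient_id", "date", "measure", "value", "unit"],
    "labs": ["patient_id", "date", "lab", "value", "unit", "mapped_unit"],
    "meds": ["patient_id", "date", "drug_class"],
    "procs": ["patient_id", "date", "code", "code_group"],
}

DATE_COLUMNS = {
    "patients": ["birth_date"],
    "visits": ["date"],
    "vitals": ["date"],
    "labs": ["date"],
    "meds": ["date"],
    "procs": ["date"],
}

NUMERIC_COLUMNS = {"vitals": ["value"], "labs": ["value"]}
BOOL_COLUMNS = {"visits": ["in_person"], "labs": ["mapped_unit"]}

#: value-set constraints checked by structural conformance validation
VALUE_SETS = {
    ("patients", "sex"): SEX,
    ("patients", "race"): RACE,
    ("patients", "ethnicity"): ETHNICITY,
    ("patients", "geocode_level"): GEOCODE_LEVELS,
    ("visits", "visit_type"): VISIT_TYPES,
    ("visits", "provider_specialty"): SPECIALTIES,
    ("vitals", "measure"): VITAL_MEASURES,
    ("vitals", "unit"): VITAL_UNITS,
    ("labs", "lab"): LABS,
    ("meds", "drug_class"): DRUG_CLASSES,
    ("procs", "code_group"): PROC_CODE_GROUPS,
}

#: canonical sort keys per domain (after a site_id merge), for reproducible output
SORT_KEYS = {
    "patients": ["site_id", "patient_id"],
    "visits": ["site_id", "patient_id", "date", "visit_id"],
    "vitals": ["site_id", "patient_id", "date", "measure", "value"],
    "labs": ["site_id", "patient_id", "date", "lab", "value"],
    "meds": ["site_id", "patient_id", "date", "drug_class"],
    "procs": ["site_id", "patient_id", "date", "code"],
}


def default_schema_config() -> dict:
    """Schema description (required columns and value sets) as a plain dict.

    This is what a ``schema.yaml`` sidecar would contain; ``load_dataset``
    accepts either this default or a user-supplied equivalent mapping.
    """
    return {
        "domains": {
            d: {
                "file": f"{d}.csv",
                "columns": list(COLUMNS[d]),
                "date_columns": list(DATE_COLUMNS[d]),
            }
            for d in DOMAINS
        },
        "value_sets": {f"{dom}.{col}": list(vals) for (dom, col), vals in VALUE_SETS.items()},
        "lab_allowed_units": {k: list(v) for k, v in LAB_ALLOWED_UNITS.items()},
    }
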