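"""Structural conformance validation of a Dataset against the CDM schema.

Each violated invariant yields one finding row per (site, domain, field):
value-set codes outside their enumeration, lab units outside the allowed set,
missing units, duplicate patient identifiers, out-of-window birth dates, and
in_person/visit_type inconsistency.  A fully conformant dataset yields an
empty frame.
"""

from __future__ import annotations

import pandas as pd

from . import schema
from .config import AnalysisConfig
from .dataset import Dataset

FINDING_COLUMNS = ["site_id", "domain", "field", "dq_issue", "count", "detail"]


def _finding(site, domain, field, dq_issue, count, detail=""):
    return {"site_id": site, "domain": domain, "field": field,
            "dq_issue": dq_issue, "count": int(count), "detail": detail}


def validate_conformance(ds: Dataset, config: AnalysisConfig | None = None) -> pd.DataFrame:
    config = config or AnalysisConfig()
    rows = []

    for (domain, field), allowed in schema.VALUE_SETS.items():
        df = ds.with_site(domain)
        if not len(df):
            continue
        bad = ~df[field].astype(str).isin(allowed)
        if bad.any():
            for site, n in df.loc[bad, "site_id"].value_counts().items():
                codes = sorted(df.loc[bad & (df["site_id"] == site), field].astype(str).unique())
                rows.append(_finding(site, domain, field, "mapping error", n,
                                     "codes outside value set: " + ", ".join(codes[:5])))

    # lab units: unmapped-but-present units are mapping errors, absent units missingness
    labs = ds.with_site("labs")
    if len(labs):
        unit = labs["unit"].astype(str)
        missing = unit.isin(["missing", "nan", ""]) | labs["unit"].isna()
        allowed = labs.apply(
            lambda r: str(r["unit"]) in schema.LAB_ALLOWED_UNITS.get(r["lab"], ()), axis=1)
        for lab_name, grp in labs.groupby("lab"):
            g_missing = missing.loc[grp.index]
            g_bad = ~allowed.loc[grp.index] & ~g_missing
            for site, n in grp.loc[g_missing, "site_id"].value_counts().items():
                rows.append(_finding(site, "labs", lab_name, "missingness", n,
                                     "unit missing"))
            for site, n in grp.loc[g_bad, "site_id"].value_counts().items():
                rows.append(_finding(site, "labs", lab_name, "mapping error", n,
                                     "unit not in allowed set"))

    # duplicate patient ids within a site
    pats = ds.patients
    if len(pats):
        dup = pats.duplicated(subset=["site_id", "patient_id"], keep=False)
        if dup.any():
            for site, n in pats.loc[dup, "site_id"].value_counts().items():
                rows.append(_finding(site, "patients", "patient_id", "high counts", n,
                                     "duplicate patient_id"))

        lo = pd.Timestamp("1990-01-01")
        hi = pd.Timestamp(f"{config.study_interval[1]}-12-31")
        bad_birth = (pats["birth_date"] < lo) | (pats["birth_date"] > hi)
        for site, n in pats.loc[bad_birth, "site_id"].value_counts().items():
            rows.append(_finding(site, "patients", "birth_date", "outlier values", n,
                                 "birth_date outside plausible window"))

    # in_person must be False exactly for telehealth/administrative visits
    visits = ds.with_site("visits")
    if len(visits):
        expect = visits["visit_type"].isin(schema.IN_PERSON_VISIT_TYPES)
        bad = visits["in_person"].astype(bool) != expect
        for site, n in visits.loc[bad, "site_id"].value_counts().items():
            rows.append(_finding(site, "visits", "in_person", "discordant values", n,
                                 "in_person inconsistent with visit_type"))

    out = pd.DataFrame(rows, columns=FINDING_COLUMNS)
    return out.sort_values(["site_id", "domain", "field"]).reset_index(drop=True)
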