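"""Anomaly injection with a ground-truth plant registry.

Each injector perturbs exactly one site's records in one domain, emulating a
data-quality failure mode seen in real multi-site extracts (ETL duplication,
unit miscoding, defaulted lab values, qualitative-to-quantitative conversion
artifacts, dropped specialty mappings, truncated history, ...).  Every
injection returns a registry entry recording the detection signature the
pipeline is expected to raise: (site, expected element, expected dq-issue
code).  The registry is the acceptance surface for detection recall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .attrition import apply_attrition
from .config import AnalysisConfig
from .dataset import Dataset

ANOMALY_KINDS = (
    "drop_specialty", "duplicate_vitals", "height_unit_error", "default_9999_labs",
    "qualitative_urine_protein_masses", "missing_lab_year", "volume_spike_year",
    "pre_entry_med_spike", "geocode_downgrade", "ethnicity_mapping_error",
    "late_data_onset",
)

#: default parameters per kind; magnitudes chosen so detection is unambiguous
DEFAULT_PARAMS: Dict[str, dict] = {
    "drop_specialty": {"fraction": 1.0},
    "duplicate_vitals": {"measure": "height", "fraction": 1.0},
    "height_unit_error": {"fraction": 0.3},
    "default_9999_labs": {"lab": "urine_protein_quant", "fraction": 0.2,
                          "default_value": 9999.0},
    "qualitative_urine_protein_masses": {"mass_points": [60.0, 100.0, 150.0],
                                         "fraction": 0.5},
    "missing_lab_year": {"lab": "serum_creatinine", "year": 2014},
    "volume_spike_year": {"year": 2016, "extra_copies": 2},
    "pre_entry_med_spike": {"fraction": 0.8},
    "geocode_downgrade": {"fraction": 0.6},
    "ethnicity_mapping_error": {"bad_code": "H", "fraction": 1.0},
    "late_data_onset": {"cutoff_year": 2015},
}

_MEASURE_ELEMENT = {"height": "height", "weight": "weight",
                    "systolic_bp": "systolic_bp", "diastolic_bp": "diastolic_bp"}


@dataclass(frozen=True)
class AnomalySpec:
    kind: str
    site_id: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ANOMALY_KINDS:
            raise ValueError(f"unknown anomaly kind: {self.kind}")
        merged = {**DEFAULT_PARAMS[self.kind], **self.params}
        frac = merged.get("fraction")
        if frac is not None and not (0.0 < frac <= 1.0):
            raise ValueError("fraction must be in (0, 1]")
        object.__setattr__(self, "params", merged)


@dataclass(frozen=True)
class PlantEntry:
    spec: AnomalySpec
    expected_dq_issue: str
    expected_element: str


@dataclass
class PlantRegistry:
    plants: List[PlantEntry] = field(default_factory=list)

    def add(self, entry: PlantEntry) -> None:
        self.plants.append(entry)

    def to_frame(self) -> pd.DataFrame:
        return plant_expectations(self)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PlantRegistry":
        df = pd.read_csv(path, dtype=str)
        reg = cls()
        for _, r in df.iterrows():
            spec = AnomalySpec(r["kind"], r["site_id"], json.loads(r["params_json"]))
            reg.add(PlantEntry(spec, r["expected_dq_issue"], r["expected_element"]))
        return reg


def plant_expectations(registry: PlantRegistry) -> pd.DataFrame:
    """One expected-issue row per plant: (site_id, kind, params_json,
    expected_dq_issue, expected_element)."""
    rows = [{
        "site_id": e.spec.site_id, "kind": e.spec.kind,
        "params_json": json.dumps(e.spec.params, sort_keys=True),
        "expected_dq_issue": e.expected_dq_issue,
        "expected_element": e.expected_element,
    } for e in registry.plants]
    cols = ["site_id", "kind", "params_json", "expected_dq_issue", "expected_element"]
    return pd.DataFrame(rows, columns=cols)


def _expected_signature(spec: AnomalySpec) -> Tuple[str, str]:
    p = spec.params
    return {
        "drop_specialty": ("missingness", "nephrology_specialty"),
        "duplicate_vitals": ("high counts", _MEASURE_ELEMENT[p.get("measure", "height")]),
        "height_unit_error": ("outlier values", "height"),
        "default_9999_labs": ("outlier values", p.get("lab", "urine_protein_quant")),
        "qualitative_urine_protein_masses": ("atypical numeric distribution",
                                             "urine_protein_quant"),
        "missing_lab_year": ("missingness", p.get("lab", "serum_creatinine")),
        "volume_spike_year": ("high spike", "visits"),
        "pre_entry_med_spike": ("atypical numeric distribution",
                                "antihypertensive_timing"),
        "geocode_downgrade": ("atypical code distribution", "geocode_level"),
        "ethnicity_mapping_error": ("mapping error", "ethnicity"),
        "late_data_onset": ("missingness", "cohort_entry"),
    }[spec.kind]


def inject_anomaly(ds: Dataset, spec: AnomalySpec, seed: int = 0
                   ) -> Tuple[Dataset, PlantEntry]:
    """Apply one anomaly; only the targeted site/domain differs from input."""
    if spec.site_id not in set(ds.patients["site_id"]):
        raise ValueError(f"unknown site: {spec.site_id}")
    rng = np.random.default_rng(seed)
    out = ds.copy()
    p = spec.params
    site_pats = set(out.patients.loc[out.patients["site_id"] == spec.site_id,
                                     "patient_id"])

    def site_mask(df):
        return df["patient_id"].isin(site_pats)

    def sample(index, fraction):
        k = int(round(fraction * len(index)))
        return pd.Index(rng.choice(index, size=k, replace=False)) if k else pd.Index([])

    if spec.kind == "drop_specialty":
        idx = out.visits.index[site_mask(out.visits)
                               & (out.visits["provider_specialty"] == "nephrology")]
        out.visits.loc[sample(idx, p["fraction"]), "provider_specialty"] = "none"

    elif spec.kind == "duplicate_vitals":
        idx = out.vitals.index[site_mask(out.vitals)
                               & (out.vitals["measure"] == p["measure"])]
        dup = out.vitals.loc[sample(idx, p["fraction"])]
        out.vitals = pd.concat([out.vitals, dup], ignore_index=True)

    elif spec.kind == "height_unit_error":
        idx = out.vitals.index[site_mask(out.vitals)
                               & (out.vitals["measure"] == "height")]
        chosen = sample(idx, p["fraction"])
        out.vitals.loc[chosen, "value"] = out.vitals.loc[chosen, "value"] / 2.54

    elif spec.kind == "default_9999_labs":
        idx = out.labs.index[site_mask(out.labs) & (out.labs["lab"] == p["lab"])]
        out.labs.loc[sample(idx, p["fraction"]), "value"] = p["default_value"]

    elif spec.kind == "qualitative_urine_protein_masses":
        idx = out.labs.index[site_mask(out.labs)
                             & (out.labs["lab"] == "urine_protein_quant")]
        chosen = sample(idx, p["fraction"])
        out.labs.loc[chosen, "value"] = rng.choice(
            np.asarray(p["mass_points"], dtype=float), len(chosen))

    elif spec.kind == "missing_lab_year":
        drop = out.labs.index[site_mask(out.labs) & (out.labs["lab"] == p["lab"])
                              & (out.labs["date"].dt.year == p["year"])]
        out.labs = out.labs.drop(index=drop).reset_index(drop=True)

    elif spec.kind == "volume_spike_year":
        idx = out.visits.index[site_mask(out.visits)
                               & (out.visits["date"].dt.year == p["year"])]
        copies = []
        for c in range(int(p["extra_copies"])):
            dup = out.visits.loc[idx].copy()
            dup["visit_id"] = dup["visit_id"] + f"-dup{c}"
            copies.append(dup)
        out.visits = pd.concat([out.visits, *copies], ignore_index=True)

    elif spec.kind == "pre_entry_med_spike":
        sub = out.subset_site(spec.site_id)
        _, cohort = apply_attrition(sub, AnalysisConfig())
        chosen = sample(cohort.index, p["fraction"])
        members = cohort.loc[chosen]
        lead = rng.integers(10, 61, len(members))
        new = pd.DataFrame({
            "patient_id": members["patient_id"].to_numpy(),
            "date": members["ced"].to_numpy() - lead.astype("timedelta64[D]"),
            "drug_class": "acei_arb",
        })
        out.meds = pd.concat([out.meds, new], ignore_index=True)

    elif spec.kind == "geocode_downgrade":
        idx = out.patients.index[(out.patients["site_id"] == spec.site_id)
                                 & (out.patients["geocode_level"] == "block_group")]
        out.patients.loc[sample(idx, p["fraction"]), "geocode_level"] = "zip5"

    elif spec.kind == "ethnicity_mapping_error":
        idx = out.patients.index[(out.patients["site_id"] == spec.site_id)
                                 & (out.patients["ethnicity"] == "hispanic")]
        out.patients.loc[sample(idx, p["fraction"]), "ethnicity"] = p["bad_code"]

    elif spec.kind == "late_data_onset":
        cutoff = pd.Timestamp(f"{p['cutoff_year']}-01-01")
        for dom in ("visits", "vitals", "labs", "meds", "procs"):
            df = getattr(out, dom)
            drop = df.index[site_mask(df) & (df["date"] < cutoff)]
            setattr(out, dom, df.drop(index=drop).reset_index(drop=True))

    dq_issue, element = _expected_signature(spec)
    return out, PlantEntry(spec, dq_issue, element)


def inject_all(ds: Dataset, specs: List[AnomalySpec], seed: int = 0
               ) -> Tuple[Dataset, PlantRegistry]:
    """Apply a list of anomalies in order, collecting the registry."""
    registry = PlantRegistry()
    for i, spec in enumerate(specs):
        ds, entry = inject_anomaly(ds, spec, seed=seed + i)
        registry.add(entry)
    return ds, registry


def default_plant_suite(site_ids: List[str]) -> List[AnomalySpec]:
    """One plant of each kind, round-robin over the given sites."""
    return [AnomalySpec(kind, site_ids[i % len(site_ids)])
            for i, kind in enumerate(ANOMALY_KINDS)]
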