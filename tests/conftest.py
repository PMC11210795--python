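"""Shared fixtures: programmatic micro-datasets and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ssdqa import (AnalysisConfig, Dataset, SimConfig, default_plant_suite,
                   generate_network, inject_all, run_dq)


def make_dataset(patients=None, visits=None, vitals=None, labs=None,
                 meds=None, procs=None) -> Dataset:
    """Build a Dataset from row dicts, filling any missing domain with an
    empty, correctly typed table."""
    def frame(rows, columns, dates, numerics=(), bools=()):
        df = pd.DataFrame(rows or [], columns=columns)
        for c in columns:
            if c not in df.columns:
                df[c] = pd.Series(dtype=object)
        for c in dates:
            df[c] = pd.to_datetime(df[c])
        for c in numerics:
            df[c] = pd.to_numeric(df[c])
        for c in bools:
            df[c] = df[c].astype(bool) if len(df) else df[c]
        return df[columns]

    return Dataset(
        patients=frame(patients, ["patient_id", "site_id", "birth_date", "sex",
                                  "race", "ethnicity", "geocode_level"],
                       ["birth_date"]),
        visits=frame(visits, ["visit_id", "patient_id", "date", "visit_type",
                              "provider_specialty", "in_person"],
                     ["date"], bools=["in_person"]),
        vitals=frame(vitals, ["patient_id", "date", "measure", "value", "unit"],
                     ["date"], numerics=["value"]),
        labs=frame(labs, ["patient_id", "date", "lab", "value", "unit",
                          "mapped_unit"],
                   ["date"], numerics=["value"], bools=["mapped_unit"]),
        meds=frame(meds, ["patient_id", "date", "drug_class"], ["date"]),
        procs=frame(procs, ["patient_id", "date", "code", "code_group"], ["date"]),
    )


def patient_row(pid, site="hs01", birth="2004-06-15", ethnicity="non_hispanic",
                geocode="block_group", sex="female", race="white"):
    return {"patient_id": pid, "site_id": site, "birth_date": birth, "sex": sex,
            "race": race, "ethnicity": ethnicity, "geocode_level": geocode}


def visit_row(pid, date, vid=None, vtype="outpatient", specialty="none"):
    in_person = vtype in ("inpatient", "outpatient", "other_ambulatory")
    return {"visit_id": vid or f"v-{pid}-{date}", "patient_id": pid, "date": date,
            "visit_type": vtype, "provider_specialty": specialty,
            "in_person": in_person}


def scr_row(pid, date, value):
    return {"patient_id": pid, "date": date, "lab": "serum_creatinine",
            "value": value, "unit": "mg/dL", "mapped_unit": True}


def height_row(pid, date, value):
    return {"patient_id": pid, "date": date, "measure": "height",
            "value": value, "unit": "cm"}


@pytest.fixture(scope="session")
def analysis_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def medium_sim():
    """Clean mid-size network: enough cohort members (>500) and BP pairs
    (>10k) for parameter-recovery checks, with the generated truth."""
    cfg = SimConfig(n_sites=6, patients_per_site=400, seed=2025)
    ds, truth = generate_network(cfg, return_truth=True)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def default_network():
    """The default-scale network (15 sites x 1000 patients), clean."""
    cfg = SimConfig(seed=42)
    ds = generate_network(cfg)
    return cfg, ds


@pytest.fixture(scope="session")
def planted_network(default_network):
    """Default-scale network with one plant of each anomaly kind."""
    _, ds = default_network
    specs = default_plant_suite(ds.site_ids())
    planted, registry = inject_all(ds, specs, seed=7)
    return planted, registry


@pytest.fixture(scope="session")
def planted_runs(planted_network):
    """Both assessment rounds over the planted default network."""
    planted, registry = planted_network
    dq1 = run_dq(planted, "DQ1")
    dq2 = run_dq(planted, "DQ2")
    return dq1, dq2, registry
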