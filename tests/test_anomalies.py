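"""Anomaly injection and the plant registry."""

import numpy as np
import pandas as pd
import pytest

from ssdqa import (AnomalySpec, PlantRegistry, SimConfig, default_plant_suite,
                   generate_network, inject_all, inject_anomaly,
                   plant_expectations)
from ssdqa.anomalies import ANOMALY_KINDS


@pytest.fixture(scope="module")
def base_ds():
    return generate_network(SimConfig(n_sites=3, patients_per_site=150, seed=21))


def test_unknown_kind_rejected():
    with pytest.raises(ValueError, match="unknown anomaly kind"):
        AnomalySpec("flood_the_labs", "hs01")


def test_bad_fraction_rejected():
    with pytest.raises(ValueError, match="fraction"):
        AnomalySpec("duplicate_vitals", "hs01", {"fraction": 0.0})


def test_unknown_site_rejected(base_ds):
    with pytest.raises(ValueError, match="unknown site"):
        inject_anomaly(base_ds, AnomalySpec("duplicate_vitals", "nowhere"))


def test_full_duplication_doubles_every_height(base_ds):
    site = base_ds.site_ids()[0]
    out, entry = inject_anomaly(
        base_ds, AnomalySpec("duplicate_vitals", site, {"fraction": 1.0}))
    pats = set(out.patients.loc[out.patients["site_id"] == site, "patient_id"])
    before = base_ds.vitals[(base_ds.vitals["measure"] == "height")
                            & base_ds.vitals["patient_id"].isin(pats)]
    after = out.vitals[(out.vitals["measure"] == "height")
                       & out.vitals["patient_id"].isin(pats)]
    assert len(after) == 2 * len(before)
    counts = after.groupby(["patient_id", "date"]).size()
    assert (counts == 2).all()
    assert entry.expected_dq_issue == "high counts"


def test_height_unit_error_divides_by_inch_factor(base_ds):
    site = base_ds.site_ids()[1]
    out, _ = inject_anomaly(
        base_ds, AnomalySpec("height_unit_error", site, {"fraction": 0.3}),
        seed=5)
    pats = set(out.patients.loc[out.patients["site_id"] == site, "patient_id"])
    before = base_ds.vitals[(base_ds.vitals["measure"] == "height")
                            & base_ds.vitals["patient_id"].isin(pats)]
    after = out.vitals[(out.vitals["measure"] == "height")
                       & out.vitals["patient_id"].isin(pats)]
    ratio = (after["value"].to_numpy() / before["value"].to_numpy())
    n_changed = int(np.isclose(ratio, 1 / 2.54).sum())
    assert n_changed == round(0.3 * len(before))
    assert int(np.isclose(ratio, 1.0).sum()) == len(before) - n_changed


def test_mass_points_reach_planted_fraction(base_ds):
    site = base_ds.site_ids()[2]
    out, _ = inject_anomaly(
        base_ds, AnomalySpec("qualitative_urine_protein_masses", site,
                             {"fraction": 0.5}), seed=2)
    pats = set(out.patients.loc[out.patients["site_id"] == site, "patient_id"])
    vals = out.labs[(out.labs["lab"] == "urine_protein_quant")
                    & out.labs["patient_id"].isin(pats)]["value"]
    on_mass = vals.isin([60.0, 100.0, 150.0]).mean()
    assert on_mass >= 0.5


def test_only_targeted_site_changes(base_ds):
    target = base_ds.site_ids()[1]
    others = [s for s in base_ds.site_ids() if s != target]
    out, _ = inject_anomaly(base_ds, AnomalySpec("default_9999_labs", target))
    for site in others:
        pats = set(out.patients.loc[out.patients["site_id"] == site,
                                    "patient_id"])
        a = base_ds.labs[base_ds.labs["patient_id"].isin(pats)]
        b = out.labs[out.labs["patient_id"].isin(pats)]
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))


def test_late_onset_truncates_site_span(base_ds):
    site = base_ds.site_ids()[0]
    out, _ = inject_anomaly(
        base_ds, AnomalySpec("late_data_onset", site, {"cutoff_year": 2015}))
    assert out.site_span()[site][0] == 2015
    for other in base_ds.site_ids()[1:]:
        assert out.site_span()[other][0] == base_ds.site_span()[other][0]


def test_injection_deterministic_under_seed(base_ds):
    site = base_ds.site_ids()[0]
    spec = AnomalySpec("geocode_downgrade", site)
    a, _ = inject_anomaly(base_ds, spec, seed=11)
    b, _ = inject_anomaly(base_ds, spec, seed=11)
    pd.testing.assert_frame_equal(a.patients, b.patients)


def test_plant_expectations_one_row_per_plant(base_ds):
    specs = default_plant_suite(base_ds.site_ids())[:5]
    _, registry = inject_all(base_ds, specs, seed=0)
    table = plant_expectations(registry)
    assert len(table) == 5
    assert set(table.columns) == {"site_id", "kind", "params_json",
                                  "expected_dq_issue", "expected_element"}


def test_empty_registry_gives_empty_table():
    assert len(plant_expectations(PlantRegistry())) == 0


def test_registry_round_trips_through_csv(tmp_path, base_ds):
    specs = default_plant_suite(base_ds.site_ids())
    _, registry = inject_all(base_ds, specs, seed=0)
    registry.to_csv(tmp_path / "plants.csv")
    back = PlantRegistry.from_csv(tmp_path / "plants.csv")
    pd.testing.assert_frame_equal(plant_expectations(registry),
                                  plant_expectations(back))


def test_every_kind_has_default_and_signature():
    assert len(ANOMALY_KINDS) == 11
    for kind in ANOMALY_KINDS:
        spec = AnomalySpec(kind, "hs01")
        assert spec.params  # defaults merged
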