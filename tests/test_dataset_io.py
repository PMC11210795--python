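"""Dataset loading, writing, and round-trip identity."""

import logging

import pytest

from ssdqa import SimConfig, datasets_equal, generate_network, load_dataset, write_dataset
from ssdqa.dataset import empty_dataset

from conftest import make_dataset, patient_row, scr_row, visit_row


@pytest.fixture(scope="module")
def small_ds():
    return generate_network(SimConfig(n_sites=2, patients_per_site=40, seed=5))


def test_write_load_round_trip(tmp_path, small_ds):
    write_dataset(small_ds, tmp_path)
    loaded = load_dataset(tmp_path)
    assert loaded.counts() == small_ds.counts()
    assert datasets_equal(small_ds, loaded)


def test_second_write_is_byte_identical(tmp_path, small_ds):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_dataset(small_ds, d1)
    write_dataset(load_dataset(d1), d2)
    for name in ("patients", "visits", "vitals", "labs", "meds", "procs"):
        assert (d1 / f"{name}.csv").read_bytes() == (d2 / f"{name}.csv").read_bytes()


def test_write_empty_dataset(tmp_path):
    write_dataset(empty_dataset(), tmp_path)
    for name in ("patients", "visits", "vitals", "labs", "meds", "procs"):
        lines = (tmp_path / f"{name}.csv").read_text().strip().splitlines()
        assert len(lines) == 1  # header only


def test_missing_file_is_fatal(tmp_path, small_ds):
    write_dataset(small_ds, tmp_path)
    (tmp_path / "labs.csv").unlink()
    with pytest.raises(FileNotFoundError, match="labs.csv"):
        load_dataset(tmp_path)


def test_orphan_rows_dropped_with_warning(tmp_path, caplog):
    ds = make_dataset(patients=[patient_row("p1")],
                      visits=[visit_row("p1", "2015-01-01")],
                      labs=[scr_row("p1", "2015-01-01", 0.8),
                            scr_row("ghost", "2015-01-01", 0.9)])
    write_dataset(ds, tmp_path)
    with caplog.at_level(logging.WARNING):
        loaded = load_dataset(tmp_path)
    assert len(loaded.labs) == 1
    assert any("unknown patient_id" in r.message for r in caplog.records)


def test_unknown_columns_ignored_and_bad_dates_rejected(tmp_path, caplog):
    ds = make_dataset(patients=[patient_row("p1")],
                      visits=[visit_row("p1", "2015-01-01")])
    write_dataset(ds, tmp_path)
    text = (tmp_path / "visits.csv").read_text().splitlines()
    text[0] += ",mystery_column"
    text[1] += ",42"
    text.append(text[1].replace(",2015-01-01,", ",not-a-date,", 1))
    (tmp_path / "visits.csv").write_text("\n".join(text) + "\n")
    with caplog.at_level(logging.WARNING):
        loaded = load_dataset(tmp_path)
    assert "mystery_column" not in loaded.visits.columns
    assert len(loaded.visits) == 1
    msgs = " ".join(r.message for r in caplog.records)
    assert "unknown columns" in msgs and "unparseable" in msgs


def test_site_span_from_visits(small_ds):
    span = small_ds.site_span()
    assert set(span) == set(small_ds.site_ids())
    for first, last in span.values():
        assert 2009 <= first <= last <= 2021


def test_empty_visits_site_absent_from_span():
    ds = make_dataset(patients=[patient_row("p1")])
    assert ds.site_span() == {}
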