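"""The Dataset container and CSV readers/writers for the simplified CDM.

A :class:`Dataset` holds one pandas DataFrame per domain.  Records link to
``patients`` via ``patient_id``; site attribution of any record goes through
that link.  ``load_dataset``/``write_dataset`` round-trip a directory of one
CSV per domain; writing uses a canonical row order so repeated writes of the
same data are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Tuple

import pandas as pd

from . import schema

log = logging.getLogger(__name__)


@dataclass
class Dataset:
    patients: pd.DataFrame
    visits: pd.DataFrame
    vitals: pd.DataFrame
    labs: pd.DataFrame
    meds: pd.DataFrame
    procs: pd.DataFrame

    def __post_init__(self) -> None:
        for dom in schema.DOMAINS:
            df = getattr(self, dom)
            missing = [c for c in schema.COLUMNS[dom] if c not in df.columns]
            if missing:
                raise ValueError(f"{dom} table missing columns {missing}")

    @property
    def tables(self) -> Dict[str, pd.DataFrame]:
        return {dom: getattr(self, dom) for dom in schema.DOMAINS}

    def site_of(self) -> pd.Series:
        """patient_id -> site_id mapping."""
        return self.patients.set_index("patient_id")["site_id"]

    def with_site(self, domain: str) -> pd.DataFrame:
        """Domain table with a site_id column merged in via patient_id."""
        df = getattr(self, domain)
        if domain == "patients" or "site_id" in df.columns:
            return df
        return df.merge(self.patients[["patient_id", "site_id"]], on="patient_id", how="left")

    def site_ids(self) -> list:
        return sorted(self.patients["site_id"].unique().tolist())

    def site_span(self) -> Dict[str, Tuple[int, int]]:
        """site_id -> (first_year, last_year) of any visit at the site."""
        v = self.with_site("visits")
        span: Dict[str, Tuple[int, int]] = {}
        for site in self.site_ids():
            years = v.loc[v["site_id"] == site, "date"].dt.year
            if len(years):
                span[site] = (int(years.min()), int(years.max()))
        return span

    def subset_site(self, site_id: str) -> "Dataset":
        """The dataset restricted to one site's patients (aggregate-round view)."""
        pats = self.patients[self.patients["site_id"] == site_id]
        keep = set(pats["patient_id"])
        out = {"patients": pats.reset_index(drop=True)}
        for dom in schema.DOMAINS[1:]:
            df = getattr(self, dom)
            out[dom] = df[df["patient_id"].isin(keep)].reset_index(drop=True)
        return Dataset(**out)

    def copy(self) -> "Dataset":
        return Dataset(**{dom: getattr(self, dom).copy() for dom in schema.DOMAINS})

    def counts(self) -> Dict[str, int]:
        return {dom: len(getattr(self, dom)) for dom in schema.DOMAINS}


def empty_dataset() -> Dataset:
    frames = {}
    for dom in schema.DOMAINS:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in schema.COLUMNS[dom]})
        frames[dom] = _coerce_types(df, dom)
    return Dataset(**frames)


def _parse_float(series: pd.Series) -> pd.Series:
    """Correctly-rounded string->float (exact round-trip through CSV)."""
    if series.dtype.kind == "f":
        return series

    def conv(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return float("nan")

    return series.map(conv).astype(float)


def _coerce_types(df: pd.DataFrame, domain: str) -> pd.DataFrame:
    for col in schema.DATE_COLUMNS[domain]:
        df[col] = pd.to_datetime(df[col], errors="coerce")
    for col in schema.NUMERIC_COLUMNS.get(domain, []):
        df[col] = _parse_float(df[col])
    for col in schema.BOOL_COLUMNS.get(domain, []):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(["true", "1", "1.0"])
    return df


def load_dataset(directory, schema_config: dict | None = None) -> Dataset:
    """Read one CSV per domain from ``directory`` into a Dataset.

    Rows with unparseable dates are rejected (warning names the row numbers);
    records referencing a patient_id absent from patients.csv are dropped with
    a warning; unknown columns are ignored with a warning.  A missing required
    file raises ``FileNotFoundError`` naming it.
    """
    cfg = schema_config or schema.default_schema_config()
    directory = Path(directory)
    frames: Dict[str, pd.DataFrame] = {}
    for dom in schema.DOMAINS:
        path = directory / cfg["domains"][dom]["file"]
        if not path.exists():
            raise FileNotFoundError(f"required domain file not found: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
        expected = cfg["domains"][dom]["columns"]
        unknown = [c for c in df.columns if c not in expected]
        if unknown:
            log.warning("%s: ignoring unknown columns %s", path.name, unknown)
            df = df.drop(columns=unknown)
        missing = [c for c in expected if c not in df.columns]
        # mapped_unit is derivable; tolerate its absence, fail on anything else
        for col in list(missing):
            if dom == "labs" and col == "mapped_unit":
                df["mapped_unit"] = ""
                missing.remove(col)
        if missing:
            raise ValueError(f"{path.name} missing required columns {missing}")
        for col in cfg["domains"][dom]["date_columns"]:
            parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
            bad = df.index[parsed.isna() & df[col].notna()]
            if len(bad):
                log.warning("%s: rejected %d rows with unparseable %s (rows %s)",
                            path.name, len(bad), col, list(bad[:10]))
                df = df.drop(index=bad)
                parsed = parsed.drop(index=bad)
            df[col] = parsed
        df = _coerce_types(df.reset_index(drop=True), dom)
        frames[dom] = df[expected]

    known = set(frames["patients"]["patient_id"])
    for dom in schema.DOMAINS[1:]:
        df = frames[dom]
        orphan = ~df["patient_id"].isin(known)
        if orphan.any():
            log.warning("%s: dropped %d rows referencing unknown patient_id",
                        dom, int(orphan.sum()))
            frames[dom] = df[~orphan].reset_index(drop=True)

    # the invariant defines mapped_unit from unit, so it is always (re)derived
    labs = frames["labs"]
    if len(labs):
        allowed = cfg.get("lab_allowed_units", schema.LAB_ALLOWED_UNITS)
        derived = [str(u) in allowed.get(lab, ())
                   for lab, u in zip(labs["lab"], labs["unit"])]
        labs["mapped_unit"] = pd.Series(derived, index=labs.index, dtype=bool)
    return Dataset(**frames)


def _canonical(ds: Dataset, domain: str) -> pd.DataFrame:
    df = ds.with_site(domain)
    df = df.sort_values(schema.SORT_KEYS[domain], kind="mergesort").reset_index(drop=True)
    return df[schema.COLUMNS[domain]]


def write_dataset(ds: Dataset, directory) -> None:
    """Write one CSV per domain in canonical row order (ISO dates, lowercase bools)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for dom in schema.DOMAINS:
        df = _canonical(ds, dom).copy()
        for col in schema.DATE_COLUMNS[dom]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        for col in schema.BOOL_COLUMNS.get(dom, []):
            df[col] = df[col].map({True: "true", False: "false"})
        df.to_csv(directory / f"{dom}.csv", index=False)


def datasets_equal(a: Dataset, b: Dataset) -> bool:
    """Field-for-field equality under canonical ordering."""
    for dom in schema.DOMAINS:
        x, y = _canonical(a, dom), _canonical(b, dom)
        if len(x) != len(y):
            return False
        try:
            pd.testing.assert_frame_equal(x, y, check_dtype=False)
        except AssertionError:
            return False
    return True
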