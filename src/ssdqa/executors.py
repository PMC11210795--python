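"""Executor families: the computations behind catalog checks.

Every executor maps a dataset (via an :class:`ExecutionContext`) to a tidy
frame of ``(site_id, stratum, value, denominator)`` rows — aggregate by
construction, which is what makes the distributed (aggregate-only) round
possible.  Expensive shared inputs (eGFR series, attrition/cohort) are
computed once per context and reused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import schema
from .attrition import (apply_attrition, egfr_threshold_curve,
                        egfr_trajectory_medians)
from .config import AnalysisConfig
from .dataset import Dataset
from .egfr import egfr_results

RESULT_COLUMNS = ["site_id", "stratum", "value", "denominator"]


@dataclass
class ExecutionContext:
    """One dataset plus lazily computed shared derivations."""
    dataset: Dataset
    config: AnalysisConfig
    #: calendar years every per-year executor reports over (network-wide range)
    years: Tuple[int, int]
    _egfrs: Optional[pd.DataFrame] = field(default=None, repr=False)
    _attrition: Optional[Tuple[pd.DataFrame, pd.DataFrame]] = field(default=None,
                                                                    repr=False)

    @property
    def egfrs(self) -> pd.DataFrame:
        if self._egfrs is None:
            self._egfrs = egfr_results(self.dataset, self.config)
        return self._egfrs

    @property
    def attrition(self) -> Tuple[pd.DataFrame, pd.DataFrame]:
        if self._attrition is None:
            self._attrition = apply_attrition(self.dataset, self.config,
                                              egfrs=self.egfrs)
        return self._attrition

    @property
    def cohort(self) -> pd.DataFrame:
        return self.attrition[1]


def _result(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _records_for(ctx: ExecutionContext, variable: str) -> pd.DataFrame:
    """Record selector: (patient_id, date[, site_id]) rows for a named variable."""
    ds = ctx.dataset
    if variable in schema.LABS:
        df = ds.labs[ds.labs["lab"] == variable]
    elif variable in schema.VITAL_MEASURES:
        df = ds.vitals[ds.vitals["measure"] == variable]
    elif variable == "visits":
        df = ds.visits
    elif variable == "in_person_visit":
        df = ds.visits[ds.visits["in_person"].astype(bool)]
    elif variable == "nephrology_visit":
        df = ds.visits[(ds.visits["provider_specialty"] == "nephrology")
                       & ds.visits["in_person"].astype(bool)]
    elif variable == "meds":
        df = ds.meds
    elif variable == "procs":
        df = ds.procs
    elif variable.startswith("med:"):
        cls = variable.split(":", 1)[1]
        if cls == "antihypertensive":
            df = ds.meds[ds.meds["drug_class"].isin(schema.ANTIHYPERTENSIVE_CLASSES)]
        else:
            df = ds.meds[ds.meds["drug_class"] == cls]
    elif variable.startswith("proc:"):
        grp = variable.split(":", 1)[1]
        df = ds.procs[ds.procs["code_group"] == grp]
    elif variable == "cohort_entry":
        out = ctx.cohort.rename(columns={"ced": "date"})[["patient_id", "date",
                                                          "site_id"]].copy()
        out["date"] = pd.to_datetime(out["date"])
        return out
    else:
        raise ValueError(f"no record selector for variable {variable!r}")
    out = df[["patient_id", "date"]].copy()
    return out.merge(ctx.dataset.patients[["patient_id", "site_id"]],
                     on="patient_id", how="left")


def _active_patient_years(ctx: ExecutionContext) -> pd.DataFrame:
    """Distinct (site_id, year, patient_id) with >=1 visit — the denominators."""
    v = ctx.dataset.with_site("visits")[["site_id", "patient_id", "date"]].copy()
    v["year"] = v["date"].dt.year
    return v.drop_duplicates(subset=["site_id", "year", "patient_id"])


def completeness_trend(ctx: ExecutionContext, variable: str) -> pd.DataFrame:
    """Per site-year: proportion of active patients with >=1 qualifying record."""
    active = _active_patient_years(ctx)
    denom = active.groupby(["site_id", "year"])["patient_id"].nunique()
    rec = _records_for(ctx, variable)
    rec = rec.assign(year=rec["date"].dt.year)
    have = rec.merge(active, on=["site_id", "year", "patient_id"])
    num = have.groupby(["site_id", "year"])["patient_id"].nunique()
    rows = []
    y0, y1 = ctx.years
    for site in ctx.dataset.site_ids():
        for year in range(y0, y1 + 1):
            d = int(denom.get((site, year), 0))
            v = int(num.get((site, year), 0))
            rows.append({"site_id": site, "stratum": str(year),
                         "value": (v / d) if d else 0.0, "denominator": d})
    return _result(rows)


def yearly_count_trend(ctx: ExecutionContext, variable: str) -> pd.DataFrame:
    """Raw record counts per site-year (denominator: active patients)."""
    rec = _records_for(ctx, variable)
    rec = rec.assign(year=rec["date"].dt.year)
    counts = rec.groupby(["site_id", "year"]).size()
    denom = _active_patient_years(ctx).groupby(["site_id", "year"])["patient_id"].nunique()
    rows = []
    y0, y1 = ctx.years
    for site in ctx.dataset.site_ids():
        for year in range(y0, y1 + 1):
            rows.append({"site_id": site, "stratum": str(year),
                         "value": float(counts.get((site, year), 0)),
                         "denominator": int(denom.get((site, year), 0))})
    return _result(rows)


def per_patient_density(ctx: ExecutionContext, variable: str) -> pd.DataFrame:
    """Mean records per patient (or mean follow-up years for followup_years)."""
    pats = ctx.dataset.patients
    rows = []
    if variable == "followup_years":
        v = ctx.dataset.with_site("visits")
        span = v.groupby(["site_id", "patient_id"])["date"].agg(["min", "max"])
        span["years"] = (span["max"] - span["min"]).dt.days / 365.25
        for site, grp in span.groupby(level="site_id"):
            rows.append({"site_id": site, "stratum": "all",
                         "value": float(grp["years"].mean()),
                         "denominator": int(len(grp))})
        return _result(rows)
    rec = _records_for(ctx, variable)
    counts = rec.groupby("site_id").size()
    n_pat = pats.groupby("site_id")["patient_id"].nunique()
    for site in ctx.dataset.site_ids():
        n = int(n_pat.get(site, 0))
        rows.append({"site_id": site, "stratum": "all",
                     "value": float(counts.get(site, 0)) / n if n else 0.0,
                     "denominator": n})
    return _result(rows)


def same_day_concordance(ctx: ExecutionContext) -> pd.DataFrame:
    """Fraction of patient-days with a systolic value that also have a diastolic."""
    v = ctx.dataset.with_site("vitals")
    sys_days = v[v["measure"] == "systolic_bp"][["site_id", "patient_id", "date"]] \
        .drop_duplicates()
    dia_days = v[v["measure"] == "diastolic_bp"][["site_id", "patient_id", "date"]] \
        .drop_duplicates()
    both = sys_days.merge(dia_days, on=["site_id", "patient_id", "date"])
    n_sys = sys_days.groupby("site_id").size()
    n_both = both.groupby("site_id").size()
    rows = []
    for site in ctx.dataset.site_ids():
        d = int(n_sys.get(site, 0))
        if d == 0:
            continue
        rows.append({"site_id": site, "stratum": "all",
                     "value": float(n_both.get(site, 0)) / d, "denominator": d})
    return _result(rows)


def pair_correlation(ctx: ExecutionContext) -> pd.DataFrame:
    """Pearson r of same-day systolic/diastolic patient-day means, per site."""
    v = ctx.dataset.with_site("vitals")
    bp = v[v["measure"].isin(["systolic_bp", "diastolic_bp"])]
    means = bp.pivot_table(index=["site_id", "patient_id", "date"],
                           columns="measure", values="value", aggfunc="mean")
    means = means.dropna()
    rows = []
    for site, grp in means.groupby(level="site_id"):
        if len(grp) < ctx.config.min_pairs_for_correlation:
            continue
        r = float(np.corrcoef(grp["systolic_bp"], grp["diastolic_bp"])[0, 1])
        rows.append({"site_id": site, "stratum": "all", "value": r,
                     "denominator": int(len(grp))})
    return _result(rows)


def unit_mapped_proportion(ctx: ExecutionContext, lab: str) -> pd.DataFrame:
    labs = ctx.dataset.with_site("labs")
    labs = labs[labs["lab"] == lab]
    rows = []
    for site, grp in labs.groupby("site_id"):
        rows.append({"site_id": site, "stratum": "all",
                     "value": float(grp["mapped_unit"].astype(bool).mean()),
                     "denominator": int(len(grp))})
    return _result(rows)


def code_utilization(ctx: ExecutionContext, code_group: str) -> pd.DataFrame:
    """Per (site, code): distinct patient-years carrying the code.

    One code per patient per calendar year is counted; the denominator is the
    site's active patient-years.  The pooled-prevalence exclusion is applied
    centrally (see :func:`apply_prevalence_filter`) so both rounds agree.
    """
    procs = ctx.dataset.with_site("procs")
    procs = procs[procs["code_group"] == code_group].copy()
    procs["year"] = procs["date"].dt.year
    pt_years = procs.drop_duplicates(subset=["site_id", "patient_id", "year", "code"])
    counts = pt_years.groupby(["site_id", "code"]).size()
    denom = _active_patient_years(ctx).groupby("site_id").size()
    codes = sorted(procs["code"].unique().tolist())
    rows = []
    for site in ctx.dataset.site_ids():
        d = int(denom.get(site, 0))
        for code in codes:
            rows.append({"site_id": site, "stratum": str(code),
                         "value": float(counts.get((site, code), 0)),
                         "denominator": d})
    return _result(rows)


def apply_prevalence_filter(results: pd.DataFrame, prevalence_min: float
                            ) -> pd.DataFrame:
    """Drop codes whose pooled patient-year prevalence is below the floor."""
    if not len(results):
        return results
    pooled = results.groupby("stratum").agg(v=("value", "sum"),
                                            d=("denominator", "sum"))
    keep = pooled.index[pooled["v"] / pooled["d"].clip(lower=1) >= prevalence_min]
    return results[results["stratum"].isin(keep)].reset_index(drop=True)


def med_timing(ctx: ExecutionContext) -> pd.DataFrame:
    """Days from cohort entry to first antihypertensive: per-site quartiles and
    the fraction starting before entry; members without one are the gap between
    denominator and the site cohort size."""
    cohort = ctx.cohort
    meds = ctx.dataset.meds
    anti = meds[meds["drug_class"].isin(schema.ANTIHYPERTENSIVE_CLASSES)]
    first = anti.groupby("patient_id")["date"].min()
    rows = []
    for site, grp in cohort.groupby("site_id"):
        delta = (grp["patient_id"].map(first) - grp["ced"]).dt.days.dropna()
        n = int(len(delta))
        if n == 0:
            continue
        q1, q2, q3 = np.percentile(delta, [25, 50, 75])
        for stratum, value in [("q1", q1), ("median", q2), ("q3", q3),
                               ("frac_negative", float((delta < 0).mean()))]:
            rows.append({"site_id": site, "stratum": stratum,
                         "value": float(value), "denominator": n})
    return _result(rows)


def geocode_granularity(ctx: ExecutionContext, level: str | None = None,
                        nonmissing: bool = False) -> pd.DataFrame:
    """Proportions of geocode granularity levels per site (partition sums to 1)."""
    pats = ctx.dataset.patients
    rows = []
    for site, grp in pats.groupby("site_id"):
        n = len(grp)
        props = grp["geocode_level"].value_counts(normalize=True)
        if nonmissing:
            rows.append({"site_id": site, "stratum": "any_geocode",
                         "value": 1.0 - float(props.get("none", 0.0)),
                         "denominator": n})
        elif level is not None:
            rows.append({"site_id": site, "stratum": level,
                         "value": float(props.get(level, 0.0)), "denominator": n})
        else:
            for lvl in schema.GEOCODE_LEVELS:
                rows.append({"site_id": site, "stratum": lvl,
                             "value": float(props.get(lvl, 0.0)), "denominator": n})
    return _result(rows)


def value_distribution(ctx: ExecutionContext, variable: str) -> pd.DataFrame:
    """Summary of a numeric variable: quartiles, mean, the largest exact-value
    mass fraction, and the fraction outside physiologic bounds."""
    ds = ctx.dataset
    if variable == "egfr":
        df = ctx.egfrs.rename(columns={"egfr": "value"})[["patient_id", "value"]]
        df = df.merge(ds.patients[["patient_id", "site_id"]], on="patient_id")
    elif variable == "pulse_pressure":
        v = ds.with_site("vitals")
        bp = v[v["measure"].isin(["systolic_bp", "diastolic_bp"])]
        means = bp.pivot_table(index=["site_id", "patient_id", "date"],
                               columns="measure", values="value",
                               aggfunc="mean").dropna()
        df = (means["systolic_bp"] - means["diastolic_bp"]).rename("value") \
            .reset_index()
    elif variable in schema.LABS:
        df = ds.with_site("labs")
        df = df[df["lab"] == variable]
    elif variable in schema.VITAL_MEASURES:
        df = ds.with_site("vitals")
        df = df[df["measure"] == variable]
    else:
        raise ValueError(f"value_distribution: no numeric selector for {variable!r}")
    lo, hi = ctx.config.bounds.get(variable, (-np.inf, np.inf))
    rows = []
    for site, grp in df.groupby("site_id"):
        vals = grp["value"].dropna().to_numpy(dtype=float)
        if not len(vals):
            continue
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        top_mass = float(pd.Series(vals).value_counts(normalize=True).iloc[0])
        oor = float(np.mean((vals < lo) | (vals > hi)))
        for stratum, value in [("q1", q1), ("median", q2), ("q3", q3),
                               ("mean", float(vals.mean())),
                               ("top_mass_fraction", top_mass),
                               ("out_of_range_fraction", oor)]:
            rows.append({"site_id": site, "stratum": stratum,
                         "value": float(value), "denominator": int(len(vals))})
    return _result(rows)


def attrition(ctx: ExecutionContext, proportions: bool = False) -> pd.DataFrame:
    """Retained counts per attrition step (or proportions of step 0)."""
    report, _ = ctx.attrition
    rows = []
    for site, grp in report.groupby("site_id"):
        grp = grp.sort_values("step")
        base = float(grp["retained"].iloc[0])
        for _, r in grp.iterrows():
            value = (r["retained"] / base if base else 0.0) if proportions \
                else float(r["retained"])
            rows.append({"site_id": site, "stratum": f"step_{r['step']}",
                         "value": value, "denominator": int(base)})
    return _result(rows)


def threshold_curve(ctx: ExecutionContext) -> pd.DataFrame:
    curve = egfr_threshold_curve(ctx.egfrs, ctx.cohort,
                                 ctx.config.egfr_thresholds)
    if not len(curve):
        return _result([])
    out = curve.rename(columns={"threshold": "stratum", "proportion": "value"})
    out["stratum"] = out["stratum"].map(lambda t: f"{t:g}")
    return out[RESULT_COLUMNS]


def trajectory_medians(ctx: ExecutionContext) -> pd.DataFrame:
    med = egfr_trajectory_medians(ctx.cohort, ctx.egfrs)
    if not len(med):
        return _result([])
    out = med.rename(columns={"offset": "stratum", "median_egfr": "value",
                              "n": "denominator"})
    out["stratum"] = out["stratum"].map(str)
    return out[RESULT_COLUMNS]


def linkage_completeness(ctx: ExecutionContext) -> pd.DataFrame:
    """Fraction of age-eligible serum creatinines with a linkable height."""
    ds, cfg = ctx.dataset, ctx.config
    scr = ds.with_site("labs")
    scr = scr[(scr["lab"] == "serum_creatinine") & (scr["value"] > 0)]
    births = ds.patients.set_index("patient_id")["birth_date"]
    age = (scr["date"] - scr["patient_id"].map(births)).dt.days / 365.25
    scr = scr[(age >= cfg.age_min) & (age <= cfg.age_max)]
    n_linked_by_site = ctx.egfrs.merge(
        ds.patients[["patient_id", "site_id"]], on="patient_id") \
        .groupby("site_id").size()
    n_scr = scr.groupby("site_id").size()
    rows = []
    for site in ds.site_ids():
        d = int(n_scr.get(site, 0))
        if d == 0:
            continue
        rows.append({"site_id": site, "stratum": "all",
                     "value": float(n_linked_by_site.get(site, 0)) / d,
                     "denominator": d})
    return _result(rows)


def category_frequency(ctx: ExecutionContext, domain: str, fld: str,
                       focus: str | None = None) -> pd.DataFrame:
    """Per-site distribution over a categorical field (or one focal category)."""
    df = ctx.dataset.with_site(domain)
    rows = []
    for site, grp in df.groupby("site_id"):
        n = len(grp)
        props = grp[fld].astype(str).value_counts(normalize=True)
        if focus is not None:
            rows.append({"site_id": site, "stratum": focus,
                         "value": float(props.get(focus, 0.0)), "denominator": n})
        else:
            for cat, p in props.sort_index().items():
                rows.append({"site_id": site, "stratum": str(cat),
                             "value": float(p), "denominator": n})
    return _result(rows)


EXECUTORS = {
    "completeness_trend": completeness_trend,
    "yearly_count_trend": yearly_count_trend,
    "per_patient_density": per_patient_density,
    "same_day_concordance": same_day_concordance,
    "pair_correlation": pair_correlation,
    "unit_mapped_proportion": unit_mapped_proportion,
    "code_utilization": code_utilization,
    "med_timing": med_timing,
    "geocode_granularity": geocode_granularity,
    "value_distribution": value_distribution,
    "attrition": attrition,
    "egfr_threshold_curve": threshold_curve,
    "egfr_trajectory_medians": trajectory_medians,
    "linkage_completeness": linkage_completeness,
    "category_frequency": category_frequency,
}
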