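"""Sequential CKD cohort attrition and eGFR-based cohort characterization.

The eligibility sequence is applied strictly in order; a patient counted at
step k satisfies every step 0..k:

0.  any encounter in the study eligibility interval
1.  any in-person visit in the interval
2.  at least one serum creatinine value
3.  age 1-18 years at time of a serum creatinine measurement
4.  height measurement within 90 days of an eligible serum creatinine
5.  at least 1 eGFR value in [30, 90) mL/min/1.73m^2
6.  two additional eGFRs in this range, each at least 90 days after the first
7.  no intervening normal (>=90) eGFR between the qualifying low eGFRs
8.  any in-person visit with a nephrologist
9.  no chronic dialysis procedure codes prior to cohort entry
10. no kidney transplant procedure codes prior to cohort entry

The cohort entry date (CED) is the date of the first eGFR of the earliest
sequence satisfying steps 5-7.  "Prior to" in steps 9-10 is strict.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .dataset import Dataset
from .egfr import egfr_results

STEP_LABELS = [
    "any encounter in study interval",
    "any in-person visit",
    "serum creatinine present",
    "age 1-18 at creatinine measurement",
    "height within 90 days of creatinine",
    "one eGFR in [30, 90)",
    "two additional low eGFRs >= 90 days after first",
    "no intervening normal eGFR",
    "in-person nephrology visit",
    "no dialysis before entry",
    "no transplant before entry",
]

ATTRITION_COLUMNS = ["site_id", "step", "label", "retained"]
COHORT_COLUMNS = ["patient_id", "site_id", "ced"]


def qualifying_entry(dates: np.ndarray, values: np.ndarray,
                     low: float = 30.0, high: float = 90.0,
                     gap_days: int = 90) -> Optional[np.datetime64]:
    """Earliest entry date of a qualifying low-eGFR sequence, or None.

    A sequence qualifies when a low eGFR (low <= v < high) is followed by two
    further low records each >= gap_days later, with no normal (>= high)
    record strictly between the first and the last of the three.
    """
    order = np.argsort(dates, kind="stable")
    dates, values = np.asarray(dates)[order], np.asarray(values)[order]
    low_mask = (values >= low) & (values < high)
    normal_dates = dates[values >= high]
    low_dates = dates[low_mask]
    for d0 in low_dates:
        nxt = normal_dates[normal_dates > d0]
        barrier = nxt[0] if len(nxt) else None
        later = low_dates[(low_dates - d0) >= np.timedelta64(gap_days, "D")]
        if barrier is not None:
            # a normal strictly between d0 and the last qualifying low disqualifies;
            # lows on the barrier date itself are still acceptable
            later = later[later <= barrier]
        if len(later) >= 2:
            return d0
    return None


def _has_additional_lows(dates: np.ndarray, values: np.ndarray,
                         low: float, high: float, gap_days: int) -> bool:
    """Step 6 in isolation: some low eGFR followed by >=2 lows >= gap later."""
    order = np.argsort(dates, kind="stable")
    dates, values = np.asarray(dates)[order], np.asarray(values)[order]
    low_dates = dates[(values >= low) & (values < high)]
    for d0 in low_dates:
        if np.sum((low_dates - d0) >= np.timedelta64(gap_days, "D")) >= 2:
            return True
    return False


def apply_attrition(ds: Dataset, config: AnalysisConfig | None = None,
                    egfrs: pd.DataFrame | None = None
                    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the 11-step eligibility sequence.

    Returns ``(report, cohort)``: per-site retained counts for steps 0-10 and
    the surviving members with their cohort entry dates.  ``egfrs`` may be a
    precomputed :func:`ssdqa.egfr.egfr_results` frame.
    """
    config = config or AnalysisConfig()
    y0, y1 = config.study_interval
    t0, t1 = pd.Timestamp(f"{y0}-01-01"), pd.Timestamp(f"{y1}-12-31")
    site_of = ds.site_of()

    visits = ds.visits[(ds.visits["date"] >= t0) & (ds.visits["date"] <= t1)]
    step_sets: List[set] = []
    s = set(visits["patient_id"])                                   # 0
    step_sets.append(s)
    s = s & set(visits.loc[visits["in_person"].astype(bool), "patient_id"])  # 1
    step_sets.append(s)
    scr = ds.labs[(ds.labs["lab"] == "serum_creatinine") & ds.labs["value"].notna()]
    s = s & set(scr["patient_id"])                                  # 2
    step_sets.append(s)
    births = ds.patients.set_index("patient_id")["birth_date"]
    age = (scr["date"] - scr["patient_id"].map(births)).dt.days / 365.25
    age_ok = scr[(age >= config.age_min) & (age <= config.age_max)]
    s = s & set(age_ok["patient_id"])                               # 3
    step_sets.append(s)

    if egfrs is None:
        egfrs = egfr_results(ds, config)
    s = s & set(egfrs["patient_id"])                                # 4
    step_sets.append(s)

    low = (egfrs["egfr"] >= config.egfr_low) & (egfrs["egfr"] < config.egfr_high)
    s = s & set(egfrs.loc[low, "patient_id"])                       # 5
    step_sets.append(s)

    step6, step7, ceds = set(), set(), {}
    grouped = egfrs[egfrs["patient_id"].isin(s)].groupby("patient_id", sort=False)
    for pid, grp in grouped:
        dates = grp["date"].to_numpy(dtype="datetime64[D]")
        values = grp["egfr"].to_numpy(dtype=float)
        if _has_additional_lows(dates, values, config.egfr_low, config.egfr_high,
                                config.gap_days):
            step6.add(pid)
            ced = qualifying_entry(dates, values, config.egfr_low,
                                   config.egfr_high, config.gap_days)
            if ced is not None:
                step7.add(pid)
                ceds[pid] = pd.Timestamp(ced)
    step_sets.append(step6)                                         # 6
    s = step7
    step_sets.append(s)                                             # 7

    neph = visits[(visits["provider_specialty"] == "nephrology")
                  & visits["in_person"].astype(bool)]
    s = s & set(neph["patient_id"])                                 # 8
    step_sets.append(s)

    for group in ("chronic_dialysis", "kidney_transplant"):         # 9, 10
        ex = ds.procs[ds.procs["code_group"] == group]
        excluded = {pid for pid, d in zip(ex["patient_id"], ex["date"])
                    if pid in ceds and d < ceds[pid]}
        s = s - excluded
        step_sets.append(s)

    sites = ds.site_ids()
    rows = []
    for step, members in enumerate(step_sets):
        per_site = pd.Series([site_of.get(p) for p in members]).value_counts()
        for site in sites:
            rows.append({"site_id": site, "step": step, "label": STEP_LABELS[step],
                         "retained": int(per_site.get(site, 0))})
    report = pd.DataFrame(rows, columns=ATTRITION_COLUMNS)

    final = sorted(step_sets[-1])
    cohort = pd.DataFrame({
        "patient_id": final,
        "site_id": [site_of.get(p) for p in final],
        "ced": [ceds[p] for p in final],
    }, columns=COHORT_COLUMNS)

    # invariant: counts are non-increasing over steps within every site
    for site in sites:
        counts = report.loc[report["site_id"] == site, "retained"].to_numpy()
        if np.any(np.diff(counts) > 0):
            raise AssertionError(f"attrition counts increased at site {site}")
    return report, cohort


def egfr_threshold_curve(egfrs: pd.DataFrame, cohort: pd.DataFrame,
                         thresholds: List[float],
                         site_of: pd.Series | None = None) -> pd.DataFrame:
    """Per-site fraction of cohort members with >=1 eGFR below each threshold."""
    if not len(cohort):
        return pd.DataFrame(columns=["site_id", "threshold", "proportion", "denominator"])
    eg = egfrs[egfrs["patient_id"].isin(set(cohort["patient_id"]))]
    eg = eg.merge(cohort[["patient_id", "site_id"]], on="patient_id")
    min_egfr = eg.groupby(["site_id", "patient_id"])["egfr"].min().reset_index()
    rows = []
    for site, grp in min_egfr.groupby("site_id"):
        n = len(set(cohort.loc[cohort["site_id"] == site, "patient_id"]))
        for t in thresholds:
            rows.append({"site_id": site, "threshold": float(t),
                         "proportion": float((grp["egfr"] < t).sum()) / n if n else 0.0,
                         "denominator": n})
    return pd.DataFrame(rows)


def egfr_trajectory_medians(cohort: pd.DataFrame, egfrs: pd.DataFrame) -> pd.DataFrame:
    """Median eGFR per site per integer-year offset from cohort entry."""
    if not len(cohort):
        return pd.DataFrame(columns=["site_id", "offset", "median_egfr", "n"])
    eg = egfrs.merge(cohort[["patient_id", "site_id", "ced"]], on="patient_id")
    eg["offset"] = np.floor((eg["date"] - eg["ced"]).dt.days / 365.25).astype(int)
    out = (eg.groupby(["site_id", "offset"])["egfr"]
           .agg(median_egfr="median", n="size").reset_index())
    return out


def trajectory_slope(medians: pd.DataFrame) -> float:
    """Count-weighted least-squares slope of median eGFR vs year offset,
    pooled over sites (mL/min/1.73m^2 per year)."""
    if len(medians) < 2:
        return float("nan")
    w = medians["n"].to_numpy(dtype=float)
    x = medians["offset"].to_numpy(dtype=float)
    y = medians["median_egfr"].to_numpy(dtype=float)
    coeffs = np.polyfit(x, y, 1, w=np.sqrt(w))
    return float(coeffs[0])
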