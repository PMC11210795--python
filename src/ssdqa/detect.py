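"""Turn check results into a prioritized, themed issue catalog.

All detectors are pure functions of the results table (which includes CONF-*
conformance pseudo-checks), the catalog that produced it, and the analysis
configuration — so the same detection pass can be re-run on a later round's
results to decide which issues resolved.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .catalog import CheckSpec
from .config import AnalysisConfig
from .priority import assign_priority
from .themes import assign_theme

log = logging.getLogger(__name__)

ISSUE_COLUMNS = ["issue_id", "site_id", "priority", "domain", "element",
                 "dq_issue", "info", "report_ref", "themes", "status",
                 "check_num", "stratum", "metric"]

#: report table each executor family's findings point back to
REPORT_REF = {
    "completeness_trend": "completeness_trends",
    "yearly_count_trend": "yearly_counts",
    "per_patient_density": "densities",
    "value_distribution": "distributions",
    "pair_correlation": "correlations",
    "same_day_concordance": "correlations",
    "unit_mapped_proportion": "unit_mapping",
    "code_utilization": "code_matrix",
    "med_timing": "timing_distributions",
    "geocode_granularity": "geocode_bars",
    "attrition": "attrition_bars",
    "egfr_threshold_curve": "threshold_curves",
    "egfr_trajectory_medians": "trajectories",
    "category_frequency": "category_frequencies",
    "linkage_completeness": "densities",
}

#: completeness variables whose per-year gaps are scanned for missingness
_ELEMENT_OF_VARIABLE = {
    "nephrology_visit": "nephrology_specialty",
    "in_person_visit": "in_person_visit",
}

#: attrition steps monitored for cross-site divergence
_MONITORED_STEPS = ("step_4", "step_5", "step_8")


def _element(variable: str) -> str:
    if variable.startswith("med:"):
        return variable.split(":", 1)[1]
    if variable.startswith("proc:"):
        return variable.split(":", 1)[1]
    return _ELEMENT_OF_VARIABLE.get(variable, variable)


def _issue(site, domain, element, dq_issue, info, check, stratum="", metric=np.nan):
    return {"site_id": site, "domain": domain, "element": element,
            "dq_issue": dq_issue, "info": info,
            "report_ref": (REPORT_REF.get(check.executor, "conformance_findings")
                           if check is not None else "conformance_findings"),
            "status": "open",
            "check_num": check.check_num if check is not None else "",
            "stratum": str(stratum), "metric": metric}


def _runs(years: List[int]) -> List[List[int]]:
    """Split a sorted year list into consecutive runs."""
    runs: List[List[int]] = []
    for y in years:
        if runs and y == runs[-1][-1] + 1:
            runs[-1].append(y)
        else:
            runs.append([y])
    return runs


def detect_missing_years(results: pd.DataFrame, checks: List[CheckSpec],
                         config: AnalysisConfig) -> List[dict]:
    """Zero-completeness calendar years: interior gaps are missingness of the
    variable; a leading run (or entirely inactive leading years) is late data
    onset (element cohort_entry); all-years-zero is total missingness."""
    issues: List[dict] = []
    late_sites: set = set()
    trend_checks = [c for c in checks if c.executor == "completeness_trend"]
    for check in trend_checks:
        sub = results[results["check_num"] == check.check_num]
        if not len(sub):
            continue
        element = _element(check.params.get("variable", check.variable))
        for site, grp in sub.groupby("site_id"):
            grp = grp.assign(year=grp["stratum"].astype(int)).sort_values("year")
            all_years = grp["year"].tolist()
            active = grp[grp["denominator"] > 0]
            if not len(active):
                continue
            first_active = int(active["year"].min())
            # site entirely inactive in leading years -> late data onset
            lead_inactive = [y for y in all_years if y < first_active]
            if lead_inactive and site not in late_sites:
                late_sites.add(site)
                issues.append(_issue(
                    site, "cohort entry", "cohort_entry", "missingness",
                    "calendar years missing: " + ", ".join(map(str, lead_inactive)),
                    check, stratum=str(lead_inactive[0]),
                    metric=float(len(lead_inactive))))
            zero_years = active.loc[active["value"] == 0, "year"].tolist()
            if not zero_years:
                continue
            if len(zero_years) == len(active):
                issues.append(_issue(
                    site, check.domains[0], element, "missingness",
                    "all calendar years missing", check,
                    stratum=str(zero_years[0]), metric=0.0))
                continue
            runs = _runs(zero_years)
            interior: List[int] = []
            for run in runs:
                if run[0] == first_active:
                    if site not in late_sites:
                        late_sites.add(site)
                        issues.append(_issue(
                            site, "cohort entry", "cohort_entry", "missingness",
                            "calendar years missing: " + ", ".join(map(str, run)),
                            check, stratum=str(run[0]), metric=float(len(run))))
                else:
                    interior.extend(run)
            if interior:
                issues.append(_issue(
                    site, check.domains[0], element, "missingness",
                    "calendar years missing: " + ", ".join(map(str, interior)),
                    check, stratum=str(interior[0]), metric=float(len(interior))))
    return issues


def loo_zscores(counts: np.ndarray, sd_floor_fraction: float) -> np.ndarray:
    """Leave-one-out z-score per point, SD floored at a fraction of the
    leave-one-out mean (guards near-constant series)."""
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    z = np.zeros(n)
    for i in range(n):
        rest = np.delete(counts, i)
        m = rest.mean()
        sd = rest.std(ddof=1) if len(rest) > 1 else 0.0
        sd = max(sd, sd_floor_fraction * abs(m), 1e-9)
        z[i] = (counts[i] - m) / sd
    return z


#: yearly-count variables scanned for spikes (volume-like series only)
def _spike_eligible(variable: str) -> bool:
    return (variable in ("visits", "in_person_visit")
            or variable in ("height", "weight", "systolic_bp", "diastolic_bp")
            or variable in ("serum_creatinine", "serum_cystatin_c",
                            "urine_protein_quant", "urine_creatinine"))


def detect_spikes(results: pd.DataFrame, checks: List[CheckSpec],
                  config: AnalysisConfig) -> List[dict]:
    """|LOO z| > spike_z on per-site yearly record counts -> high/low spike."""
    issues: List[dict] = []
    for check in [c for c in checks if c.executor == "yearly_count_trend"]:
        variable = check.params.get("variable", check.variable)
        if not _spike_eligible(variable):
            continue
        sub = results[results["check_num"] == check.check_num]
        for site, grp in sub.groupby("site_id"):
            grp = grp.assign(year=grp["stratum"].astype(int)).sort_values("year")
            grp = grp[grp["denominator"] > 0]
            if len(grp) < 4:
                continue
            z = loo_zscores(grp["value"].to_numpy(), config.sd_floor_fraction)
            years_all = grp["year"].to_numpy()
            for direction, mask in (("high spike", z > config.spike_z),
                                    ("low spike", z < -config.spike_z)):
                if mask.any():
                    years = years_all[mask].tolist()
                    issues.append(_issue(
                        site, check.domains[0], _element(variable), direction,
                        "anomalous years: " + ", ".join(map(str, years)),
                        check, stratum=str(years[0]),
                        metric=float(np.max(np.abs(z[mask])))))
    return issues


def tukey_fence_outliers(values: np.ndarray, multiplier: float = 1.5):
    """Indices outside [Q1 - m*IQR, Q3 + m*IQR] (type-7 quartiles), with the
    fences; the brute-force-checkable core of cross-site outlier detection."""
    values = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    return np.flatnonzero((values < lo) | (values > hi)), lo, hi


_OUTLIER_FAMILIES = ("per_patient_density", "attrition", "egfr_threshold_curve",
                     "geocode_granularity", "category_frequency")


def _outlier_signature(check: CheckSpec, stratum: str):
    """(element, dq-issue pair, domain) for a cross-site outlier on a check."""
    fam = check.executor
    if fam == "per_patient_density":
        el = _element(check.params.get("variable", check.variable))
        return el, ("high counts", "low counts"), check.domains[0]
    if fam == "attrition":
        if not check.params.get("proportions") or stratum not in _MONITORED_STEPS:
            return None
        return f"attrition_{stratum}", ("high counts", "low counts"), "cohort definition"
    if fam == "egfr_threshold_curve":
        if stratum != "50":
            return None
        return "low_egfr_cohort", ("high counts", "low counts"), "cohort definition"
    if fam == "geocode_granularity":
        if check.params:      # only the full-distribution check is scanned
            return None
        return "geocode_level", ("atypical code distribution",) * 2, "geographic"
    if fam == "category_frequency":
        return (check.params.get("fld", check.variable),
                ("atypical code distribution",) * 2, check.domains[0])
    return None


def detect_site_outliers(results: pd.DataFrame, checks: List[CheckSpec],
                         config: AnalysisConfig) -> List[dict]:
    """Cross-site Tukey-fence outliers on per-site check values.

    A site is flagged when it falls outside the 1.5*IQR fence *and* deviates
    from the cross-site median by more than ``min_relative_deviation`` (a
    practical-significance floor so tight homogeneous clusters don't alarm).
    Fewer than ``min_sites_for_fence`` sites yields no result.
    """
    issues: List[dict] = []
    for check in [c for c in checks if c.executor in _OUTLIER_FAMILIES]:
        sub = results[results["check_num"] == check.check_num]
        for stratum, grp in sub.groupby("stratum"):
            sig = _outlier_signature(check, str(stratum))
            if sig is None:
                continue
            element, (dq_hi, dq_lo), domain = sig
            if len(grp) < config.min_sites_for_fence:
                log.info("check %s stratum %s: %d sites < %d, fence skipped",
                         check.check_num, stratum, len(grp),
                         config.min_sites_for_fence)
                continue
            vals = grp["value"].to_numpy(dtype=float)
            idx, lo, hi = tukey_fence_outliers(vals, config.fence_multiplier)
            med = float(np.median(vals))
            scale = max(abs(med), 1e-9)
            for i in idx:
                if abs(vals[i] - med) / scale < config.min_relative_deviation:
                    continue
                high = vals[i] > hi
                issues.append(_issue(
                    grp["site_id"].iloc[i], domain, element,
                    dq_hi if high else dq_lo,
                    f"site value {vals[i]:.4g} vs cross-site median {med:.4g} "
                    f"(fence [{lo:.4g}, {hi:.4g}])",
                    check, stratum=stratum, metric=float(vals[i])))
    return issues


def detect_value_anomalies(results: pd.DataFrame, checks: List[CheckSpec],
                           config: AnalysisConfig) -> List[dict]:
    """Distribution pathologies: exact-value mass concentration, out-of-range
    fractions, discordant BP correlation, majority-pre-entry med timing, and
    unmapped units."""
    issues: List[dict] = []
    for check in [c for c in checks if c.executor == "value_distribution"]:
        variable = check.params.get("variable", check.variable)
        element = _element(variable)
        sub = results[results["check_num"] == check.check_num]
        piv = sub.pivot_table(index="site_id", columns="stratum", values="value")
        for site, row in piv.iterrows():
            top = float(row.get("top_mass_fraction", 0.0))
            oor = float(row.get("out_of_range_fraction", 0.0))
            if top > config.mass_fraction_threshold:
                issues.append(_issue(
                    site, check.domains[0], element, "atypical numeric distribution",
                    f"largest exact-value mass fraction {top:.3f}",
                    check, stratum="top_mass_fraction", metric=top))
            if oor > 0:
                lo, hi = config.bounds.get(variable, (None, None))
                med = row.get("median", np.nan)
                low_med = lo is not None and pd.notna(med) and med < lo
                issues.append(_issue(
                    site, check.domains[0], element, "outlier values",
                    (f"{oor:.3f} of values outside [{lo}, {hi}]"
                     + ("; values low" if low_med else "")),
                    check, stratum="out_of_range_fraction", metric=oor))
    for check in [c for c in checks if c.executor == "pair_correlation"]:
        sub = results[results["check_num"] == check.check_num]
        for _, r in sub.iterrows():
            if r["value"] < config.correlation_floor:
                issues.append(_issue(
                    r["site_id"], check.domains[0], "blood_pressure",
                    "discordant values",
                    f"systolic/diastolic correlation r={r['value']:.3f} below "
                    f"{config.correlation_floor}",
                    check, stratum="all", metric=float(r["value"])))
    for check in [c for c in checks if c.executor == "med_timing"]:
        sub = results[(results["check_num"] == check.check_num)
                      & (results["stratum"] == "frac_negative")]
        for _, r in sub.iterrows():
            if r["value"] > config.timing_negative_fraction:
                issues.append(_issue(
                    r["site_id"], check.domains[0], "antihypertensive_timing",
                    "atypical numeric distribution",
                    f"{r['value']:.2f} of first antihypertensives precede cohort entry",
                    check, stratum="frac_negative", metric=float(r["value"])))
    for check in [c for c in checks if c.executor == "unit_mapped_proportion"]:
        sub = results[results["check_num"] == check.check_num]
        for _, r in sub.iterrows():
            if r["value"] < 0.8:
                issues.append(_issue(
                    r["site_id"], check.domains[0],
                    _element(check.params.get("lab", check.variable)),
                    "mapping error",
                    f"only {r['value']:.2f} of units mapped",
                    check, stratum="all", metric=float(r["value"])))
    return issues


def detect_conformance(results: pd.DataFrame, config: AnalysisConfig) -> List[dict]:
    issues: List[dict] = []
    sub = results[results["check_num"].str.startswith("CONF-")]
    for _, r in sub.iterrows():
        _, domain, fld = r["check_num"].split("-", 2)
        issues.append(_issue(
            r["site_id"], domain, fld, str(r["stratum"]),
            f"{int(r['value'])} nonconforming records", None,
            stratum=r["stratum"], metric=float(r["value"])))
    return issues


def detect_issues(results: pd.DataFrame, checks: List[CheckSpec],
                  config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Full detection pass -> prioritized, themed issue catalog."""
    config = config or AnalysisConfig()
    raw: List[dict] = []
    raw += detect_missing_years(results, checks, config)
    raw += detect_spikes(results, checks, config)
    raw += detect_site_outliers(results, checks, config)
    raw += detect_value_anomalies(results, checks, config)
    raw += detect_conformance(results, config)

    for issue in raw:
        issue["priority"] = assign_priority(issue, config)
        issue["themes"] = ";".join(assign_theme(issue, config))

    raw.sort(key=lambda d: (d["site_id"], d["element"], d["dq_issue"],
                            d["check_num"]))
    for i, issue in enumerate(raw, start=1):
        issue["issue_id"] = f"I-{i:04d}"
        log.info("issue %s: site=%s element=%s dq_issue=%s priority=%s",
                 issue["issue_id"], issue["site_id"], issue["element"],
                 issue["dq_issue"], issue["priority"])
    return pd.DataFrame(raw, columns=ISSUE_COLUMNS)
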