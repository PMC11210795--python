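"""Synthetic multi-site EHR network with known-truth CKD structure.

The generator emulates the substrate the quality checks run on: a network of
heterogeneous pediatric sites observed over a fixed study interval, where a
configurable fraction of patients carry a declining-eGFR CKD trajectory.
Serum creatinine is back-computed from the target eGFR and the same-day height
through the bedside Schwartz relation, so the eGFR recovered downstream equals
the generated truth exactly — a known-truth surface for parameter-recovery
tests.  Blood pressure pairs are bivariate normal with a configured
correlation; nephrology visits, antihypertensive orders, dialysis/transplant
codes and neighborhood geocode granularity complete the picture.

Everything is drawn from a single seeded generator: identical seeds give
identical datasets.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .dataset import Dataset

# piecewise-linear median height-for-age curve (cm); ordinal plausibility only
GROWTH_AGES = np.array([1.0, 2.0, 5.0, 10.0, 14.0, 18.0])
GROWTH_HEIGHTS = np.array([75.0, 87.0, 110.0, 138.0, 160.0, 170.0])

DIALYSIS_CODES = ["90935", "90937", "90945", "90947", "90999"]
TRANSPLANT_CODE = "50360"
OTHER_PROC_CODE = "36415"

SCHWARTZ_K = 0.413  # must match the analysis-side constant for exact inversion


def median_height(age_years: np.ndarray) -> np.ndarray:
    return np.interp(age_years, GROWTH_AGES, GROWTH_HEIGHTS)


def generate_network(cfg: SimConfig | None = None, return_truth: bool = False):
    """Build the network Dataset (optionally also the per-measurement eGFR truth).

    Returns ``Dataset`` or ``(Dataset, truth)`` where ``truth`` has columns
    (patient_id, date, egfr_true), one row per serum creatinine record.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    y0, y1 = cfg.study_interval
    t_start = np.datetime64(f"{y0}-01-01")
    t_end = np.datetime64(f"{y1}-12-31")

    sites = np.array([f"hs{i + 1:02d}" for i in range(cfg.n_sites)])
    site_rate = 1.0 + rng.uniform(-cfg.site_rate_jitter, cfg.site_rate_jitter,
                                  cfg.n_sites)
    # per-site preference over dialysis codes (coding heterogeneity)
    site_code_pref = rng.dirichlet(np.ones(len(DIALYSIS_CODES)) * 1.2, cfg.n_sites)

    n = cfg.n_sites * cfg.patients_per_site
    site_idx = np.repeat(np.arange(cfg.n_sites), cfg.patients_per_site)
    pid = np.array([f"{sites[s]}-p{j:05d}"
                    for s, j in zip(site_idx, np.tile(np.arange(cfg.patients_per_site),
                                                      cfg.n_sites))])

    b0 = np.datetime64(f"{cfg.birth_year_range[0]}-01-01")
    b1 = np.datetime64(f"{cfg.birth_year_range[1]}-12-31")
    birth = b0 + rng.integers(0, (b1 - b0).astype(int) + 1, n).astype("timedelta64[D]")

    sex = rng.choice(["female", "male"], n)
    race = rng.choice(["white", "black", "asian", "multiple", "other", "unknown"],
                      n, p=[0.55, 0.2, 0.06, 0.05, 0.09, 0.05])
    ethnicity = rng.choice(["hispanic", "non_hispanic", "missing"], n,
                           p=[0.22, 0.73, 0.05])
    geocode = rng.choice(["none", "zip5", "zip9", "tract", "block_group"], n,
                         p=[0.05, 0.10, 0.10, 0.15, 0.60])
    ckd = rng.random(n) < cfg.ckd_fraction

    patients = pd.DataFrame({
        "patient_id": pid, "site_id": sites[site_idx],
        "birth_date": pd.to_datetime(birth), "sex": sex, "race": race,
        "ethnicity": ethnicity, "geocode_level": geocode,
    })

    # ---- visits -----------------------------------------------------------
    active_start = np.maximum(t_start, birth + np.timedelta64(365, "D"))
    span_days = (t_end - active_start).astype(int) + 1
    years_active = span_days / 365.25
    lam = cfg.visit_rate * site_rate[site_idx] * years_active
    n_visits = 1 + rng.poisson(np.maximum(lam - 1, 0.1))

    v_pat = np.repeat(np.arange(n), n_visits)
    v_date = (active_start[v_pat]
              + (rng.random(len(v_pat)) * span_days[v_pat]).astype(int)
              .astype("timedelta64[D]"))
    v_type = rng.choice(["inpatient", "outpatient", "other_ambulatory",
                         "telehealth", "administrative"],
                        len(v_pat), p=[0.07, 0.55, 0.20, 0.10, 0.08])
    spec = np.where(
        ckd[v_pat],
        rng.choice(["nephrology", "general_pediatrics", "cardiology", "none"],
                   len(v_pat), p=[0.35, 0.40, 0.05, 0.20]),
        rng.choice(["general_pediatrics", "cardiology", "none"],
                   len(v_pat), p=[0.60, 0.10, 0.30]))
    in_person = np.isin(v_type, ["inpatient", "outpatient", "other_ambulatory"])

    visits = pd.DataFrame({
        "visit_id": [f"v{i:08d}" for i in range(len(v_pat))],
        "patient_id": pid[v_pat], "date": pd.to_datetime(v_date),
        "visit_type": v_type, "provider_specialty": spec, "in_person": in_person,
    })

    # ---- measurement flags per visit -------------------------------------
    is_ckd_v = ckd[v_pat]
    has_bp = rng.random(len(v_pat)) < 0.70
    has_wt = rng.random(len(v_pat)) < 0.50
    has_scr = rng.random(len(v_pat)) < np.where(is_ckd_v, 0.60, 0.20)
    has_ht = (rng.random(len(v_pat)) < 0.50) | has_scr  # creatinine days get a height
    has_cys = rng.random(len(v_pat)) < np.where(is_ckd_v, 0.10, 0.02)
    has_upr = rng.random(len(v_pat)) < np.where(is_ckd_v, 0.25, 0.03)
    has_ucr = rng.random(len(v_pat)) < np.where(is_ckd_v, 0.20, 0.02)

    age_at_visit = (v_date - birth[v_pat]).astype(int) / 365.25
    ht_offset = rng.normal(0.0, 6.0, n)  # patient-level height offset (cm)

    def _vital(mask, measure, values, unit):
        return pd.DataFrame({
            "patient_id": pid[v_pat[mask]], "date": pd.to_datetime(v_date[mask]),
            "measure": measure, "value": values, "unit": unit,
        })

    m = has_ht
    height_vals = np.round(np.clip(
        median_height(age_at_visit[m]) + ht_offset[v_pat[m]]
        + rng.normal(0.0, 0.8, int(m.sum())), 45.0, 215.0), 1)
    vitals_ht = _vital(m, "height", height_vals, "cm")

    m = has_wt
    bmi = np.clip(rng.normal(17.5, 2.5, int(m.sum())), 12.0, 35.0)
    med_h = median_height(age_at_visit[m]) + ht_offset[v_pat[m]]
    weight_vals = np.round(np.clip(bmi * (med_h / 100.0) ** 2, 3.0, 200.0), 1)
    vitals_wt = _vital(m, "weight", weight_vals, "kg")

    m = has_bp
    nbp = int(m.sum())
    rho = cfg.bp_correlation
    z1, z2 = rng.standard_normal(nbp), rng.standard_normal(nbp)
    sbp = cfg.bp_mean[0] + cfg.bp_sd[0] * z1
    dbp = cfg.bp_mean[1] + cfg.bp_sd[1] * (rho * z1 + np.sqrt(1 - rho ** 2) * z2)
    sbp = np.round(np.clip(sbp, 60, 230))
    dbp = np.round(np.clip(dbp, 30, 140))
    vitals_bp = pd.concat([
        _vital(m, "systolic_bp", sbp, "mmHg"),
        _vital(m, "diastolic_bp", dbp, "mmHg"),
    ])

    vitals = pd.concat([vitals_ht, vitals_wt, vitals_bp], ignore_index=True)
    vitals = vitals.drop_duplicates(subset=["patient_id", "date", "measure"],
                                    keep="first").reset_index(drop=True)

    # ---- eGFR truth and labs ---------------------------------------------
    base_ckd = rng.uniform(*cfg.baseline_egfr_range, n)
    rate = rng.normal(cfg.egfr_decline_mean, cfg.egfr_decline_sd, n)
    base_normal = rng.uniform(*cfg.normal_egfr_range, n)

    m = has_scr
    scr_pat, scr_date = v_pat[m], v_date[m]
    t_years = (scr_date - active_start[scr_pat]).astype(int) / 365.25
    noise = rng.normal(0.0, cfg.egfr_noise_sd, int(m.sum()))
    egfr_true = np.where(
        ckd[scr_pat],
        np.clip(base_ckd[scr_pat] + rate[scr_pat] * t_years + noise, 5.0, 160.0),
        np.clip(base_normal[scr_pat] + noise, 60.0, 200.0))

    scr_labs = pd.DataFrame({
        "patient_id": pid[scr_pat], "date": pd.to_datetime(scr_date),
        "egfr_true": egfr_true,
    }).drop_duplicates(subset=["patient_id", "date"], keep="first")
    height_lookup = vitals_ht.drop_duplicates(subset=["patient_id", "date"])
    scr_labs = scr_labs.merge(
        height_lookup[["patient_id", "date", "value"]].rename(columns={"value": "height"}),
        on=["patient_id", "date"], how="left")
    # every creatinine day carries a height by construction
    scr_labs = scr_labs.dropna(subset=["height"])
    scr_labs["value"] = SCHWARTZ_K * scr_labs["height"] / scr_labs["egfr_true"]

    def _lab(mask, lab, values, unit):
        return pd.DataFrame({
            "patient_id": pid[v_pat[mask]], "date": pd.to_datetime(v_date[mask]),
            "lab": lab, "value": values, "unit": unit, "mapped_unit": True,
        }).drop_duplicates(subset=["patient_id", "date"], keep="first")

    m = has_cys
    cys = _lab(m, "serum_cystatin_c",
               np.round(np.clip(rng.normal(1.5, 0.4, int(m.sum())), 0.2, 5.0), 2),
               "mg/L")
    m = has_upr
    upr = _lab(m, "urine_protein_quant",
               np.round(np.clip(rng.lognormal(3.2, 1.0, int(m.sum())), 0.5, 4800.0), 1),
               "mg/dL")
    m = has_ucr
    ucr = _lab(m, "urine_creatinine",
               np.round(np.clip(rng.normal(100.0, 40.0, int(m.sum())), 5.0, 400.0), 1),
               "mg/dL")

    labs = pd.concat([
        pd.DataFrame({
            "patient_id": scr_labs["patient_id"], "date": scr_labs["date"],
            "lab": "serum_creatinine", "value": scr_labs["value"],
            "unit": "mg/dL", "mapped_unit": True,
        }),
        cys, upr, ucr,
    ], ignore_index=True)

    truth = scr_labs[["patient_id", "date", "egfr_true"]].reset_index(drop=True)

    # ---- medications ------------------------------------------------------
    first_scr = (labs[labs["lab"] == "serum_creatinine"]
                 .groupby("patient_id")["date"].min())
    treated = np.flatnonzero(ckd & (rng.random(n) < 0.70)
                             & pd.Series(pid).isin(first_scr.index).to_numpy())
    f_dates = first_scr.loc[pid[treated]].to_numpy(dtype="datetime64[D]")
    start_offset = rng.integers(-100, 366, len(treated)).astype("timedelta64[D]")
    med_date = np.minimum(np.maximum(f_dates + start_offset, active_start[treated]), t_end)
    med_class = rng.choice(["acei_arb", "calcium_channel_blocker", "beta_blocker",
                            "loop_diuretic", "thiazide"],
                           len(treated), p=[0.5, 0.2, 0.1, 0.1, 0.1])
    refills = rng.poisson(2.0, len(treated))
    r_pat = np.repeat(treated, refills)
    r_cls = np.repeat(med_class, refills)
    r_date = np.minimum(np.repeat(med_date, refills)
                        + rng.integers(30, 700, len(r_pat)).astype("timedelta64[D]"),
                        t_end)
    other = np.flatnonzero(~ckd & (rng.random(n) < 0.05))
    o_date = (active_start[other] + (rng.random(len(other))
                                     * span_days[other]).astype(int)
              .astype("timedelta64[D]"))
    meds = pd.DataFrame({
        "patient_id": np.concatenate([pid[treated], pid[r_pat], pid[other]]),
        "date": pd.to_datetime(np.concatenate([med_date, r_date, o_date])),
        "drug_class": np.concatenate([med_class, r_cls,
                                      np.full(len(other), "other")]),
    })

    # ---- procedures -------------------------------------------------------
    end_egfr = base_ckd + rate * years_active
    reaches_eskd = ckd & (rate < 0) & (end_egfr < 15.0)
    cross_years = np.where(rate < 0, (base_ckd - 15.0) / np.maximum(-rate, 1e-9), np.inf)
    eskd = np.flatnonzero(reaches_eskd)
    cross_date = active_start[eskd] + (cross_years[eskd] * 365.25).astype(int) \
        .astype("timedelta64[D]")
    cross_date = np.minimum(cross_date, t_end)
    n_dial = 1 + rng.poisson(3.0, len(eskd))
    d_pat = np.repeat(eskd, n_dial)
    d_cross = np.repeat(cross_date, n_dial)
    d_span = np.maximum((t_end - d_cross).astype(int), 1)
    d_date = d_cross + (rng.random(len(d_pat)) * d_span).astype(int) \
        .astype("timedelta64[D]")
    # site-specific code preference
    d_codes = np.empty(len(d_pat), dtype=object)
    for s in range(cfg.n_sites):
        m_s = site_idx[d_pat] == s
        if m_s.any():
            d_codes[m_s] = rng.choice(DIALYSIS_CODES, int(m_s.sum()),
                                      p=site_code_pref[s])
    tx_mask = rng.random(len(eskd)) < 0.35
    tx_first = np.minimum(cross_date[tx_mask] + np.timedelta64(180, "D"), t_end)
    # transplant and annual post-transplant follow-up codes until interval end
    tx_years = ((t_end - tx_first).astype(int) // 365) + 1
    tx = np.repeat(eskd[tx_mask], tx_years)
    tx_steps = (np.concatenate([np.arange(k) for k in tx_years])
                if len(tx_years) else np.zeros(0, dtype=int))
    tx_date = (np.repeat(tx_first, tx_years)
               + tx_steps.astype("timedelta64[D]") * 365)
    oth = np.flatnonzero(rng.random(n) < 0.15)
    oth_date = (active_start[oth] + (rng.random(len(oth)) * span_days[oth]).astype(int)
                .astype("timedelta64[D]"))
    procs = pd.DataFrame({
        "patient_id": np.concatenate([pid[d_pat], pid[tx], pid[oth]]),
        "date": pd.to_datetime(np.concatenate([d_date, tx_date, oth_date])),
        "code": np.concatenate([d_codes, np.full(len(tx), TRANSPLANT_CODE),
                                np.full(len(oth), OTHER_PROC_CODE)]),
        "code_group": np.concatenate([
            np.full(len(d_pat), "chronic_dialysis"),
            np.full(len(tx), "kidney_transplant"),
            np.full(len(oth), "other")]),
    })

    ds = Dataset(patients=patients, visits=visits, vitals=vitals,
                 labs=labs.reset_index(drop=True), meds=meds, procs=procs)
    if return_truth:
        return ds, truth
    return ds
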