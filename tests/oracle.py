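"""Brute-force oracles, independent of the library's vectorized paths.

The attrition oracle tests every patient against every eligibility criterion
with explicit loops and exhaustive enumeration (all height candidates per
creatinine, all low-eGFR triples for the entry sequence).  It shares nothing
with ``ssdqa.attrition`` beyond the eligibility definition itself.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def oracle_egfr_series(ds, pid, config):
    """(date, egfr) pairs for one patient by exhaustive height scanning."""
    birth = ds.patients.set_index("patient_id")["birth_date"][pid]
    labs = ds.labs
    scr = labs[(labs["patient_id"] == pid) & (labs["lab"] == "serum_creatinine")
               & (labs["value"] > 0)]
    heights = ds.vitals[(ds.vitals["patient_id"] == pid)
                        & (ds.vitals["measure"] == "height")
                        & (ds.vitals["value"] > 0)]
    out = []
    for _, lab in scr.iterrows():
        age = (lab["date"] - birth).days / 365.25
        if not (config.age_min <= age <= config.age_max):
            continue
        best = None
        for _, h in heights.iterrows():
            delta = abs((lab["date"] - h["date"]).days)
            if delta > config.height_window_days:
                continue
            key = (delta, h["date"])
            if best is None or key < best[0]:
                best = (key, h["value"])
        if best is not None:
            out.append((lab["date"], config.schwartz_k * best[1] / lab["value"]))
    out.sort(key=lambda t: t[0])
    return out


def oracle_entry_date(egfrs, config):
    """Earliest qualifying entry date by exhaustive triple enumeration."""
    lows = [(d, v) for d, v in egfrs
            if config.egfr_low <= v < config.egfr_high]
    normals = [d for d, v in egfrs if v >= config.egfr_high]
    best = None
    for (d0, _), (d1, _), (d2, _) in itertools.combinations(lows, 3):
        dj = max(d1, d2)
        if (d1 - d0).days < config.gap_days or (d2 - d0).days < config.gap_days:
            continue
        if any(d0 < dn < dj for dn in normals):
            continue
        if best is None or d0 < best:
            best = d0
    return best


def oracle_attrition(ds, config):
    """Per-patient pass/fail for steps 0-10 plus entry dates."""
    t0 = pd.Timestamp(f"{config.study_interval[0]}-01-01")
    t1 = pd.Timestamp(f"{config.study_interval[1]}-12-31")
    results = {}
    ceds = {}
    for _, pat in ds.patients.iterrows():
        pid = pat["patient_id"]
        visits = ds.visits[(ds.visits["patient_id"] == pid)
                           & (ds.visits["date"] >= t0) & (ds.visits["date"] <= t1)]
        labs = ds.labs[(ds.labs["patient_id"] == pid)
                       & (ds.labs["lab"] == "serum_creatinine")
                       & ds.labs["value"].notna()]
        passes = [False] * 11
        passes[0] = len(visits) > 0
        passes[1] = passes[0] and visits["in_person"].astype(bool).any()
        passes[2] = passes[1] and len(labs) > 0
        ages = [(d - pat["birth_date"]).days / 365.25 for d in labs["date"]]
        passes[3] = passes[2] and any(config.age_min <= a <= config.age_max
                                      for a in ages)
        egfrs = oracle_egfr_series(ds, pid, config)
        passes[4] = passes[3] and len(egfrs) > 0
        lows = [(d, v) for d, v in egfrs
                if config.egfr_low <= v < config.egfr_high]
        passes[5] = passes[4] and len(lows) > 0
        step6 = any(sum((d - d0).days >= config.gap_days for d, _ in lows) >= 2
                    for d0, _ in lows)
        passes[6] = passes[5] and step6
        ced = oracle_entry_date(egfrs, config)
        passes[7] = passes[6] and ced is not None
        if passes[7]:
            ceds[pid] = ced
        neph = visits[(visits["provider_specialty"] == "nephrology")
                      & visits["in_person"].astype(bool)]
        passes[8] = passes[7] and len(neph) > 0
        procs = ds.procs[ds.procs["patient_id"] == pid]
        dial = procs[procs["code_group"] == "chronic_dialysis"]
        tx = procs[procs["code_group"] == "kidney_transplant"]
        passes[9] = passes[8] and (ced is None
                                   or not any(d < ced for d in dial["date"]))
        passes[10] = passes[9] and (ced is None
                                    or not any(d < ced for d in tx["date"]))
        results[pid] = passes
    site_of = ds.patients.set_index("patient_id")["site_id"]
    counts = {}
    for site in sorted(site_of.unique()):
        counts[site] = [sum(1 for pid, p in results.items()
                            if site_of[pid] == site and p[k])
                        for k in range(11)]
    survivors = {pid: ceds[pid] for pid, p in results.items() if p[10]}
    return counts, survivors


def random_adversarial_dataset(rng: np.random.Generator, make_dataset,
                               patient_row, visit_row, scr_row, height_row,
                               n_patients=None):
    """Small random dataset with values and gaps concentrated at the
    eligibility boundaries (eGFR 30/90, 90-day windows, strict pre-entry)."""
    n = int(n_patients or rng.integers(1, 51))
    n_sites = int(rng.integers(1, 4))
    patients, visits, vitals, labs, procs = [], [], [], [], []
    boundary_egfr = [25.0, 29.99, 30.0, 45.0, 60.0, 89.0, 89.99, 90.0, 95.0, 120.0]
    gaps = [30, 80, 89, 90, 91, 120, 200]
    deltas = [0, 5, 45, 89, 90, 91, 120]
    for i in range(n):
        site = f"s{rng.integers(0, n_sites) + 1}"
        pid = f"{site}-p{i}"
        birth = pd.Timestamp("2000-01-01") + pd.Timedelta(
            days=int(rng.integers(0, 3000)))
        patients.append(patient_row(pid, site=site, birth=str(birth.date())))
        base = pd.Timestamp("2012-01-01") + pd.Timedelta(
            days=int(rng.integers(0, 2000)))
        if rng.random() < 0.9:
            vtype = "outpatient" if rng.random() < 0.8 else "telehealth"
            spec = "nephrology" if rng.random() < 0.7 else "none"
            visits.append(visit_row(pid, str(base.date()), vtype=vtype,
                                    specialty=spec))
        d = base
        for k in range(int(rng.integers(0, 6))):
            d = d + pd.Timedelta(days=int(rng.choice(gaps)))
            egfr = float(rng.choice(boundary_egfr))
            height = float(rng.uniform(90, 180))
            scr = 0.413 * height / egfr
            labs.append(scr_row(pid, str(d.date()), scr))
            if rng.random() < 0.85:
                hd = d + pd.Timedelta(days=int(rng.choice(deltas))
                                      * int(rng.choice([-1, 1])))
                vitals.append(height_row(pid, str(hd.date()), height))
        if rng.random() < 0.25:
            procs.append({"patient_id": pid,
                          "date": str((base + pd.Timedelta(
                              days=int(rng.integers(-200, 600)))).date()),
                          "code": "90935",
                          "code_group": str(rng.choice(
                              ["chronic_dialysis", "kidney_transplant", "other"]))})
    return make_dataset(patients=patients, visits=visits, vitals=vitals,
                        labs=labs, procs=procs)
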