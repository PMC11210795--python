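"""Pediatric eGFR from serum creatinine and height (bedside Schwartz).

``eGFR = k * height(cm) / SCr(mg/dL)`` with k = 0.413 mL/min/1.73m^2 per
(cm per mg/dL).  Each creatinine measured at ages 1-18 is paired with the
nearest-in-time height within a +/-90 day window (ties broken toward the
earlier height), mirroring how a registry-quality eGFR series is assembled
from routinely collected labs and anthropometrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .dataset import Dataset

EGFR_COLUMNS = ["patient_id", "date", "egfr", "scr", "height_used", "height_date"]


def compute_egfr(scr, height, k: float = 0.413):
    """Bedside Schwartz eGFR (mL/min/1.73m^2); inputs must be positive."""
    scr = np.asarray(scr, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(scr <= 0) or np.any(height <= 0):
        raise ValueError("implausible record: serum creatinine and height must be > 0")
    out = k * height / scr
    return float(out) if out.ndim == 0 else out


def link_height(patient_labs: pd.DataFrame, patient_heights: pd.DataFrame,
                config: AnalysisConfig | None = None,
                birth_date=None) -> pd.DataFrame:
    """Pair one patient's creatinines with heights; convenience over the
    vectorized :func:`egfr_results` path."""
    config = config or AnalysisConfig()
    labs = patient_labs.copy()
    if "patient_id" not in labs.columns:
        labs["patient_id"] = "p"
    heights = patient_heights.copy()
    if "patient_id" not in heights.columns:
        heights["patient_id"] = "p"
    births = None
    if birth_date is not None and len(labs):
        births = pd.Series({pid: pd.Timestamp(birth_date)
                            for pid in labs["patient_id"].unique()})
    return _link(labs, heights, config, birth_dates=births)


def egfr_results(ds: Dataset, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """All patients' eGFR series: creatinines at ages 1-18 paired with heights."""
    config = config or AnalysisConfig()
    labs = ds.labs[(ds.labs["lab"] == "serum_creatinine") & (ds.labs["value"] > 0)]
    labs = labs[["patient_id", "date", "value"]].rename(columns={"value": "scr"})
    heights = ds.vitals[(ds.vitals["measure"] == "height") & (ds.vitals["value"] > 0)]
    heights = heights[["patient_id", "date", "value"]].rename(
        columns={"date": "height_date", "value": "height_used"})
    births = ds.patients.set_index("patient_id")["birth_date"]
    return _link(labs, heights, config, birth_dates=births)


def _link(labs: pd.DataFrame, heights: pd.DataFrame, config: AnalysisConfig,
          birth_dates: pd.Series | None) -> pd.DataFrame:
    if "scr" not in labs.columns:
        labs = labs.rename(columns={"value": "scr"})
    if "height_used" not in heights.columns:
        heights = heights.rename(columns={"date": "height_date", "value": "height_used"})
    labs = labs[["patient_id", "date", "scr"]].dropna().reset_index(drop=True)
    labs["lab_row"] = labs.index
    heights = heights[["patient_id", "height_date", "height_used"]].dropna()
    if not len(labs) or not len(heights):
        return pd.DataFrame(columns=EGFR_COLUMNS)

    if birth_dates is not None:
        age = (labs["date"] - labs["patient_id"].map(birth_dates)).dt.days / 365.25
        labs = labs[(age >= config.age_min) & (age <= config.age_max)]
        if not len(labs):
            return pd.DataFrame(columns=EGFR_COLUMNS)

    pairs = labs.merge(heights, on="patient_id", how="inner")
    pairs["abs_delta"] = (pairs["date"] - pairs["height_date"]).dt.days.abs()
    pairs = pairs[pairs["abs_delta"] <= config.height_window_days]
    if not len(pairs):
        return pd.DataFrame(columns=EGFR_COLUMNS)
    # nearest height wins; equidistant before/after resolves to the earlier one
    pairs = pairs.sort_values(["lab_row", "abs_delta", "height_date"], kind="mergesort")
    pairs = pairs.drop_duplicates(subset=["lab_row"], keep="first")
    pairs["egfr"] = compute_egfr(pairs["scr"], pairs["height_used"], config.schwartz_k)
    out = pairs[EGFR_COLUMNS].sort_values(["patient_id", "date"]).reset_index(drop=True)
    return out
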