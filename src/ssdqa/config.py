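"""Analysis and simulation configuration.

Two validated configuration objects drive everything:

* :class:`AnalysisConfig` — thresholds and constants for the eGFR/attrition
  pipeline and the data-quality detectors.
* :class:`SimConfig` — the synthetic multi-site EHR generator's parameters.

Both load from YAML mappings (``from_yaml``) and reject invalid values with an
error naming the offending field (pydantic validation).
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class AnalysisConfig(BaseModel):
    """Constants of the cohort pipeline and detection thresholds.

    The kidney-function estimator is the bedside Schwartz formula
    ``eGFR = k * height(cm) / SCr(mg/dL)`` with ``k = 0.413``; eligibility uses
    eGFR in ``[egfr_low, egfr_high)`` mL/min/1.73m^2.  All day windows are
    closed intervals (|delta| <= window).
    """

    schwartz_k: float = 0.413
    egfr_low: float = 30.0
    egfr_high: float = 90.0
    height_window_days: int = 90
    gap_days: int = 90
    age_min: float = 1.0
    age_max: float = 18.0
    study_interval: Tuple[int, int] = (2009, 2021)

    # detection thresholds
    spike_z: float = 2.0                 # |leave-one-out z| beyond which a yearly count is a spike
    sd_floor_fraction: float = 0.05      # SD floor, as a fraction of the leave-one-out mean
    fence_multiplier: float = 1.5        # Tukey fence multiplier for cross-site outliers
    min_sites_for_fence: int = 5
    min_relative_deviation: float = 0.2  # practical-significance floor for cross-site outliers
    prevalence_min: float = 0.005        # pooled prevalence below which a code is dropped
    mass_fraction_threshold: float = 0.10  # single exact value carrying more mass is atypical
    correlation_floor: float = 0.2       # same-day BP correlation below this is discordant
    min_pairs_for_correlation: int = 3
    timing_negative_fraction: float = 0.5  # majority of first med starts before entry

    egfr_thresholds: List[float] = Field(
        default_factory=lambda: [20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0])

    #: physiologic bounds per numeric variable (inclusive), for out-of-range detection
    bounds: Dict[str, Tuple[float, float]] = Field(default_factory=lambda: {
        "height": (40.0, 220.0),
        "weight": (2.0, 250.0),
        "systolic_bp": (50.0, 250.0),
        "diastolic_bp": (20.0, 150.0),
        "serum_creatinine": (0.05, 20.0),
        "serum_cystatin_c": (0.1, 10.0),
        "urine_protein_quant": (0.0, 5000.0),
        "urine_creatinine": (1.0, 500.0),
        "egfr": (1.0, 250.0),
    })

    #: variable-importance tiers used by the issue prioritizer
    eligibility_elements: List[str] = Field(default_factory=lambda: [
        "serum_creatinine", "height", "egfr", "nephrology_specialty",
        "in_person_visit", "cohort_entry", "age"])
    exposure_outcome_elements: List[str] = Field(default_factory=lambda: [
        "systolic_bp", "diastolic_bp", "antihypertensive_timing", "egfr_trajectory"])
    #: elements whose sparseness is expected, demoting missingness to low priority
    expected_sparse_elements: List[str] = Field(default_factory=lambda: [
        "serum_cystatin_c"])
    #: derived/secondary cohort count metrics (not the primary attrition sequence)
    secondary_cohort_elements: List[str] = Field(default_factory=lambda: [
        "high_serum_creatinine_cohort", "low_egfr_cohort"])
    #: demographic categorical elements (distribution shifts are low priority)
    demographic_elements: List[str] = Field(default_factory=lambda: [
        "ethnicity", "race", "sex"])

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        if not self.egfr_low < self.egfr_high:
            raise ValueError("egfr_low must be < egfr_high")
        for name in ("height_window_days", "gap_days", "spike_z", "fence_multiplier",
                     "prevalence_min", "mass_fraction_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.study_interval[0] > self.study_interval[1]:
            raise ValueError("study_interval start must be <= end")
        return self

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class SimConfig(BaseModel):
    """Parameters of the synthetic multi-site EHR network.

    Defaults emulate the study conditions of a 15-site pediatric CKD network
    observed over 2009-2021: roughly a third of patients carry a CKD
    trajectory with baseline eGFR uniform on ``baseline_egfr_range`` declining
    at ``egfr_decline_mean`` mL/min/1.73m^2 per year, blood pressures drawn
    from a bivariate normal with correlation ``bp_correlation``.
    """

    n_sites: int = 15
    patients_per_site: int = 1000
    study_interval: Tuple[int, int] = (2009, 2021)
    ckd_fraction: float = 0.3
    baseline_egfr_range: Tuple[float, float] = (30.0, 90.0)
    egfr_decline_mean: float = -3.0   # mL/min/1.73m^2 per year
    egfr_decline_sd: float = 1.0
    egfr_noise_sd: float = 3.0        # per-measurement biological + assay noise
    normal_egfr_range: Tuple[float, float] = (100.0, 140.0)
    bp_correlation: float = 0.6
    bp_mean: Tuple[float, float] = (105.0, 65.0)   # systolic, diastolic mmHg
    bp_sd: Tuple[float, float] = (12.0, 9.0)
    visit_rate: float = 2.0           # mean visits per patient-year
    site_rate_jitter: float = 0.1     # per-site visit-rate multiplier ~ U(1 -/+ jitter)
    birth_year_range: Tuple[int, int] = (1992, 2008)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.patients_per_site < 1:
            raise ValueError("patients_per_site must be >= 1")
        if not 0.0 <= self.ckd_fraction <= 1.0:
            raise ValueError("ckd_fraction must be in [0, 1]")
        if not -1.0 < self.bp_correlation < 1.0:
            raise ValueError("bp_correlation must be in (-1, 1)")
        if self.visit_rate <= 0:
            raise ValueError("visit_rate must be > 0")
        if self.study_interval[0] > self.study_interval[1]:
            raise ValueError("study_interval start must be <= end")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
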