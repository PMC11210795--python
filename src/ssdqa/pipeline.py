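"""End-to-end orchestration: catalog execution plus issue detection."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import pandas as pd

from .catalog import CheckSpec, load_catalog
from .config import AnalysisConfig
from .dataset import Dataset
from .detect import detect_issues
from .engine import run_round


@dataclass
class DQRun:
    round: str
    results: pd.DataFrame
    issues: pd.DataFrame
    checks: List[CheckSpec]


def run_dq(ds: Dataset, round_: str, config: AnalysisConfig | None = None,
           checks: Optional[List[CheckSpec]] = None) -> DQRun:
    """Execute one assessment round and detect issues from its results."""
    config = config or AnalysisConfig()
    checks = checks if checks is not None else load_catalog(round_)
    results = run_round(ds, round_, config, checks)
    issues = detect_issues(results, checks, config)
    return DQRun(round=round_, results=results, issues=issues, checks=checks)


def run_study(ds: Dataset, config: AnalysisConfig | None = None
              ) -> "tuple[DQRun, DQRun, pd.DataFrame]":
    """Both assessment rounds over one dataset.

    Returns (dq1, dq2, combined_issues): the aggregate round, the row-level
    round, and the union of their issue catalogs deduplicated on the
    (site, element, dq-issue) signature (the aggregate round's entry wins,
    since that is the round sites see first)."""
    config = config or AnalysisConfig()
    dq1 = run_dq(ds, "DQ1", config)
    dq2 = run_dq(ds, "DQ2", config)
    combined = pd.concat([dq1.issues.assign(round="DQ1"),
                          dq2.issues.assign(round="DQ2")], ignore_index=True)
    combined = combined.drop_duplicates(
        subset=["site_id", "element", "dq_issue"], keep="first")
    return dq1, dq2, combined.reset_index(drop=True)
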