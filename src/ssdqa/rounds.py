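"""Round-over-round issue tracking.

The later round re-executes the earlier round's checks; an issue is resolved
exactly when the detection pass over the after-results no longer raises it
(same site, element, dq-issue signature).  Resolved issues get status
"improvement"; unresolved ones keep their annotated status (a metric may
improve yet stay outside the fence — that is still unresolved).
"""

from __future__ import annotations

import logging
from typing import List

import numpy as np
import pandas as pd

from .catalog import CheckSpec
from .config import AnalysisConfig
from .detect import detect_issues

log = logging.getLogger(__name__)

RESOLUTION_STATUSES = ("open", "improvement", "clinical practice",
                       "EHR architecture", "source data", "not dq issue",
                       "prioritized other issues")

COMPARISON_COLUMNS = ["issue_id", "site_id", "element", "dq_issue",
                      "metric_before", "metric_after", "resolved", "status"]


def _metric_lookup(results: pd.DataFrame, check_num: str, site_id, stratum: str):
    sub = results[(results["check_num"] == check_num)
                  & (results["site_id"] == site_id)
                  & (results["stratum"].astype(str) == str(stratum))]
    return float(sub["value"].iloc[0]) if len(sub) else np.nan


def compare_rounds(issues_before: pd.DataFrame, results_before: pd.DataFrame,
                   results_after: pd.DataFrame, checks: List[CheckSpec],
                   config: AnalysisConfig | None = None) -> pd.DataFrame:
    """One comparison row per before-issue."""
    config = config or AnalysisConfig()
    issues_after = detect_issues(results_after, checks, config)
    after_keys = set(zip(issues_after["site_id"], issues_after["element"],
                         issues_after["dq_issue"]))
    rows = []
    for _, issue in issues_before.iterrows():
        key = (issue["site_id"], issue["element"], issue["dq_issue"])
        resolved = key not in after_keys
        status = "improvement" if resolved else issue.get("status", "open")
        if not issue.get("check_num"):
            log.warning("issue %s has no check reference; left open",
                        issue.get("issue_id"))
        metric_after = _metric_lookup(results_after, issue["check_num"],
                                      issue["site_id"], issue["stratum"])
        rows.append({
            "issue_id": issue["issue_id"], "site_id": issue["site_id"],
            "element": issue["element"], "dq_issue": issue["dq_issue"],
            "metric_before": issue.get("metric", np.nan),
            "metric_after": metric_after,
            "resolved": bool(resolved), "status": status,
        })
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
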