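"""Anonymized cross-site report bundles and per-site issue summaries.

A bundle is a set of tidy tables (one per figure family), the issue catalog,
and a site alias map: raw site identifiers never appear in any output —
sites are renamed "site 1".."site n" in stable sorted order.  Rendered
figures (log-scale attrition bars, dialysis-code heatmap, eGFR threshold
curves) accompany the underlying CSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np
import pandas as pd

from .catalog import CheckSpec
from .detect import REPORT_REF

_PRIORITY_ORDER = {"urgent": 0, "high": 1, "medium": 2, "low": 3}

#: every table a bundle always carries (issue report_refs must point here)
TABLE_NAMES = tuple(sorted(set(REPORT_REF.values()))) + ("conformance_findings",)

SUMMARY_COLUMNS = ["unique issue id", "priority", "clinical or data domain",
                   "data element", "dq issue", "info", "report reference"]


@dataclass
class ReportBundle:
    round: str
    tables: Dict[str, pd.DataFrame]
    issues: pd.DataFrame
    alias_map: Dict[str, str]


def site_alias_map(site_ids: List[str]) -> Dict[str, str]:
    return {s: f"site {i + 1}" for i, s in enumerate(sorted(site_ids))}


def build_report(results: pd.DataFrame, issues: pd.DataFrame, round_: str,
                 checks: List[CheckSpec]) -> ReportBundle:
    """Collect one round's results and issues into an anonymized bundle.

    Raises on catalog-integrity violation: an issue whose report_ref names a
    table the bundle does not produce.
    """
    site_ids = sorted(set(results["site_id"].dropna())
                      | set(issues["site_id"].dropna()))
    alias = site_alias_map(site_ids)

    family_of = {c.check_num: REPORT_REF.get(c.executor) for c in checks}
    tables: Dict[str, pd.DataFrame] = {name: [] for name in TABLE_NAMES}
    for check_num, grp in results.groupby("check_num"):
        name = ("conformance_findings" if str(check_num).startswith("CONF-")
                else family_of.get(check_num))
        if name is None:
            continue
        tables[name].append(grp)
    out_tables = {}
    for name, frames in tables.items():
        df = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["check_num", "site_id", "stratum",
                                         "value", "denominator"]))
        df = df.copy()
        df["site_id"] = df["site_id"].map(alias)
        out_tables[name] = df.sort_values(
            ["check_num", "site_id", "stratum"]).reset_index(drop=True)

    dangling = sorted(set(issues["report_ref"]) - set(out_tables))
    if dangling:
        raise ValueError(f"issues reference missing report tables: {dangling}")

    anon_issues = issues.copy()
    anon_issues["site_id"] = anon_issues["site_id"].map(alias)
    return ReportBundle(round=round_, tables=out_tables, issues=anon_issues,
                        alias_map=alias)


def site_summary(issues: pd.DataFrame, site_id: str) -> pd.DataFrame:
    """Tailored per-site issue table, ordered urgent > high > medium > low."""
    sub = issues[issues["site_id"] == site_id].copy()
    if not len(sub):
        import logging
        logging.getLogger(__name__).warning("no issues for site %s", site_id)
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    sub["_p"] = sub["priority"].map(_PRIORITY_ORDER)
    sub = sub.sort_values(["_p", "issue_id"])
    return pd.DataFrame({
        "unique issue id": sub["issue_id"],
        "priority": sub["priority"],
        "clinical or data domain": sub["domain"],
        "data element": sub["element"],
        "dq issue": sub["dq_issue"],
        "info": sub["info"],
        "report reference": sub["report_ref"],
    }).reset_index(drop=True)


def write_bundle(bundle: ReportBundle, outdir, render: bool = True) -> None:
    """Write the bundle: one CSV per table, the issue catalog, and figures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    bundle.issues.to_csv(outdir / "issues.csv", index=False)
    pd.DataFrame({"alias": sorted(bundle.alias_map.values())}) \
        .to_csv(outdir / "sites.csv", index=False)
    if render:
        _render_figures(bundle, outdir)


def _render_figures(bundle: ReportBundle, outdir: Path) -> None:
    attr = bundle.tables.get("attrition_bars")
    if attr is not None and len(attr):
        attr = attr[attr["check_num"] == attr["check_num"].iloc[0]]
        fig, ax = plt.subplots(figsize=(9, 4))
        for site, grp in attr.groupby("site_id"):
            grp = grp.sort_values("stratum")
            ax.plot(grp["stratum"], grp["value"].clip(lower=0.5), marker="o",
                    label=site, alpha=0.6)
        ax.set_yscale("log")
        ax.set_xlabel("attrition step")
        ax.set_ylabel("patients retained (log scale)")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(outdir / "attrition.png", dpi=100)
        plt.close(fig)

    curves = bundle.tables.get("threshold_curves")
    if curves is not None and len(curves):
        curves = curves[curves["check_num"] == curves["check_num"].iloc[0]].copy()
        curves["t"] = curves["stratum"].astype(float)
        fig, ax = plt.subplots(figsize=(7, 4))
        for site, grp in curves.groupby("site_id"):
            grp = grp.sort_values("t")
            ax.plot(grp["t"], grp["value"], marker=".", label=site, alpha=0.6)
        ax.set_xlabel("eGFR threshold (mL/min/1.73m$^2$)")
        ax.set_ylabel("proportion with >=1 eGFR below threshold")
        fig.tight_layout()
        fig.savefig(outdir / "threshold_curves.png", dpi=100)
        plt.close(fig)

    matrix = bundle.tables.get("code_matrix")
    if matrix is not None and len(matrix):
        matrix = matrix[matrix["check_num"] == matrix["check_num"].iloc[0]]
        piv = matrix.pivot_table(index="site_id", columns="stratum",
                                 values="value", fill_value=0.0)
        if piv.size:
            fig, ax = plt.subplots(figsize=(7, 4))
            im = ax.imshow(piv.to_numpy(), aspect="auto", cmap="Blues")
            ax.set_xticks(np.arange(len(piv.columns)), piv.columns, rotation=45)
            ax.set_yticks(np.arange(len(piv.index)), piv.index)
            fig.colorbar(im, ax=ax, label="patient-year proportion")
            fig.tight_layout()
            fig.savefig(outdir / "code_matrix.png", dpi=100)
            plt.close(fig)
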