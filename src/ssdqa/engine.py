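"""Catalog execution in the two assessment modes.

DQ1 emulates a fully distributed query: each site's records are processed in
isolation and only aggregate rows leave the site.  DQ2 emulates a centralized
row-level query over the pooled records.  Executors are per-site aggregations,
so for every check computable in both modes the per-site values are identical
— an invariant the tests pin down exactly.

Shared computations are cached per (executor, params), so catalog entries that
reuse one computation under different postprocessing don't pay for it twice.
"""

from __future__ import annotations

import logging
from typing import List, Optional

import pandas as pd

from .catalog import CheckSpec, load_catalog
from .config import AnalysisConfig
from .conformance import validate_conformance
from .dataset import Dataset
from .executors import (EXECUTORS, RESULT_COLUMNS, ExecutionContext,
                        apply_prevalence_filter)

log = logging.getLogger(__name__)

RESULT_SCHEMA = ["check_num", "site_id", "stratum", "value", "denominator"]


def _network_years(ds: Dataset, config: AnalysisConfig) -> tuple:
    """Calendar-year range all per-year checks report over: the union of site
    spans, clipped to the study interval."""
    spans = ds.site_span()
    y0, y1 = config.study_interval
    if spans:
        first = min(a for a, _ in spans.values())
        last = max(b for _, b in spans.values())
        return (max(y0, first), min(y1, last))
    return (y0, y1)


def _execute_catalog(ctx: ExecutionContext, checks: List[CheckSpec]) -> pd.DataFrame:
    cache: dict = {}
    frames = []
    for check in checks:
        if check.executor is None:
            log.warning("check %s (%s): no executor for domain(s) %s — skipped",
                        check.check_num, check.summary, "/".join(check.domains))
            continue
        key = (check.executor, tuple(sorted(check.params.items())))
        if key not in cache:
            fn = EXECUTORS[check.executor]
            cache[key] = fn(ctx, **check.params)
        res = cache[key].copy()
        res.insert(0, "check_num", check.check_num)
        frames.append(res)
        log.info("check %s executed: %d result rows", check.check_num, len(res))
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=RESULT_SCHEMA)
    return pd.concat(frames, ignore_index=True)[RESULT_SCHEMA]


def _postprocess(results: pd.DataFrame, checks: List[CheckSpec],
                 config: AnalysisConfig) -> pd.DataFrame:
    """Central postprocessing applied identically in both modes."""
    for check in checks:
        if check.executor == "code_utilization":
            mask = results["check_num"] == check.check_num
            sub = apply_prevalence_filter(results[mask], config.prevalence_min)
            # convert patient-year counts to proportions once pooled filter is set
            sub = sub.copy()
            sub["value"] = sub["value"] / sub["denominator"].clip(lower=1)
            results = pd.concat([results[~mask], sub], ignore_index=True)
    return results


def conformance_results(ds: Dataset, config: AnalysisConfig) -> pd.DataFrame:
    """Structural conformance findings folded into the results schema as
    CONF-* pseudo-checks, so detection is a pure function of results."""
    findings = validate_conformance(ds, config)
    rows = []
    for _, f in findings.iterrows():
        rows.append({
            "check_num": f"CONF-{f['domain']}-{f['field']}",
            "site_id": f["site_id"],
            "stratum": f["dq_issue"],
            "value": float(f["count"]),
            "denominator": 0,
        })
    return pd.DataFrame(rows, columns=RESULT_SCHEMA)


def run_round(ds: Dataset, round_: str, config: AnalysisConfig | None = None,
              checks: Optional[List[CheckSpec]] = None) -> pd.DataFrame:
    """Execute one round's catalog; returns the results table.

    ``round_`` selects both the catalog and the execution mode: DQ1 iterates
    sites and computes from each site's records in isolation (aggregates
    only), DQ2 computes from the pooled rows.
    """
    config = config or AnalysisConfig()
    checks = checks if checks is not None else load_catalog(round_)
    years = _network_years(ds, config)

    if round_ == "DQ1":
        frames = []
        for site in ds.site_ids():
            sub = ds.subset_site(site)
            ctx = ExecutionContext(dataset=sub, config=config, years=years)
            frames.append(_execute_catalog(ctx, checks))
        results = (pd.concat(frames, ignore_index=True) if frames
                   else pd.DataFrame(columns=RESULT_SCHEMA))
    elif round_ == "DQ2":
        ctx = ExecutionContext(dataset=ds, config=config, years=years)
        results = _execute_catalog(ctx, checks)
    else:
        raise ValueError(f"round must be DQ1 or DQ2, got {round_!r}")

    results = _postprocess(results, checks, config)
    conf = conformance_results(ds, config)
    if len(conf):
        results = pd.concat([results, conf], ignore_index=True)
    return results.sort_values(["check_num", "site_id", "stratum"]) \
        .reset_index(drop=True)
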