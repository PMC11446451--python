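"""End-to-end orchestration: ledger + claims -> cohort -> status -> reports."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from dminc.ascertain import (
    CodeSet,
    carry_forward,
    utilization_flags,
    yearly_diagnosis_flags,
)
from dminc.cohort import build_cohort, open_population
from dminc.estimate import (
    annual_prevalence_table,
    cumulative_prevalence_series,
    fit_weighted_model,
    incidence_slope,
    pooled_slope,
)
from dminc.fiscal import StudyWindow
from dminc.report import render_reports


def run_pipeline(
    ledger: pd.DataFrame,
    claims: pd.DataFrame,
    outdir: str | Path,
    window: StudyWindow | None = None,
    codes: CodeSet | None = None,
    mask_threshold: int = 10,
) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a summary dict with the continuity counts, the pooled and
    model estimates, and the list of files written.
    """
    window = window or StudyWindow()
    codes = codes or CodeSet()

    cohort, status_counts = build_cohort(ledger, window)
    if cohort.empty:
        raise ValueError("cohort is empty after continuity and age filters")
    popn = open_population(ledger, window)

    all_persons = sorted(ledger["person_id"].unique())
    raw_dx = yearly_diagnosis_flags(claims, all_persons, codes, window)
    med = utilization_flags(claims, all_persons, "medication", codes, window)
    ins = utilization_flags(claims, all_persons, "insulin", codes, window)
    status = carry_forward(raw_dx)

    n_ignored = int(
        (~claims["person_id"].isin(all_persons)).sum()
        + (~claims["fiscal_year"].astype(int).isin(window.fiscal_years)).sum()
    ) if len(claims) else 0

    table1 = annual_prevalence_table(popn, raw_dx, med, ins)
    strata = cumulative_prevalence_series(status, cohort, include_overall=False)
    per_stratum = [incidence_slope(s) for s in strata]
    pooled = pooled_slope(strata)
    model = (
        fit_weighted_model(strata) if len(strata) > 1
        else incidence_slope(strata[0])
    )

    run_log = {f"continuity_{k}": v for k, v in status_counts.items()}
    run_log["cohort_size"] = len(cohort)
    run_log["claims_out_of_scope"] = n_ignored
    files = render_reports(
        outdir, table1, strata, per_stratum, pooled, model,
        run_log=run_log, threshold=mask_threshold,
    )
    return {
        "cohort_size": len(cohort),
        "status_counts": status_counts,
        "pooled": pooled,
        "model": model,
        "per_stratum": per_stratum,
        "files": files,
    }
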