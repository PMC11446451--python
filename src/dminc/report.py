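"""Publication-shaped output tables with small-cell disclosure control.

Cells whose case count is positive but below a threshold (default 10) are
masked in the rendered tables to prevent re-identification; the mask applies
to the display layer only — every estimate upstream uses raw counts. Zero
counts are displayed: the rule targets small non-zero groups.
"""

from __future__ import annotations

import json
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from dminc.estimate import IncidenceEstimate, PrevalenceSeries

MASK_MARKER = "―"  # horizontal bar, as printed in masked tables

_BAND_ORDER = {
    b: i for i, b in enumerate(
        ["40-44", "45-49", "50-54", "55-59", "60-64", "65-69",
         "70-74", "75-79", "80-84", "85-89", "90-94", "95-"]
    )
}


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as in the
    rendered percentage tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(x: float, ndigits: int = 1) -> str:
    return f"{round_half_up(100.0 * x, ndigits):.{ndigits}f}%"


def mask_small_cells(
    table: pd.DataFrame,
    count_col: str = "cases",
    companion_cols: tuple[str, ...] = ("proportion",),
    threshold: int = 10,
    marker: str = MASK_MARKER,
) -> pd.DataFrame:
    """Mask count cells with 0 < count < threshold (and their companions).

    Returns a copy with the affected columns as strings; the marker replaces
    both the count and any companion column (e.g. the proportion) on masked
    rows. Rows with count 0 or >= threshold display normally.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    out = table.copy()
    masked = (out[count_col] > 0) & (out[count_col] < threshold)
    for col in (count_col, *companion_cols):
        out[col] = out[col].astype(object)
        out.loc[masked, col] = marker
    return out


def _wide_measure_table(table1: pd.DataFrame, threshold: int,
                        marker: str) -> pd.DataFrame:
    """Long measure rows -> one row per sex/band/FY with display strings."""
    disp = table1.copy()
    disp["display"] = [
        f"{format_pct(p)} ({int(c)})" if pd.notna(p) else ""
        for p, c in zip(disp["proportion"], disp["cases"])
    ]
    small = (disp["cases"] > 0) & (disp["cases"] < threshold)
    disp.loc[small, "display"] = marker
    wide = disp.pivot_table(
        index=["sex", "age_band", "fiscal_year", "n"],
        columns="measure", values="display", aggfunc="first",
    ).reset_index()
    wide["_o"] = wide["age_band"].map(_BAND_ORDER)
    wide = wide.sort_values(["sex", "_o", "fiscal_year"]).drop(columns="_o")
    return wide


def render_reports(
    outdir: str | Path,
    table1: pd.DataFrame | None,
    strata: list[PrevalenceSeries],
    per_stratum: list[IncidenceEstimate],
    pooled: IncidenceEstimate,
    model: IncidenceEstimate,
    run_log: dict | None = None,
    threshold: int = 10,
    marker: str = MASK_MARKER,
) -> list[Path]:
    """Write the report bundle: table1.csv (per-FY prevalence/utilization,
    masked), table2.csv (cumulative prevalence, masked), table3.csv
    (per-stratum annual incidence), estimates.json and run_log.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    masked_cells = 0

    if table1 is not None and len(table1):
        wide = _wide_measure_table(table1, threshold, marker)
        masked_cells += int((wide == marker).sum().sum())
        p = outdir / "table1.csv"
        wide.to_csv(p, index=False, lineterminator="\n")
        written.append(p)

    rows = []
    for s in strata:
        for fy_ix, c in enumerate(s.counts):
            rows.append({"sex": s.sex, "age_band": s.age_band, "n": s.n,
                         "year_index": fy_ix, "cases": c,
                         "proportion": c / s.n})
    t2 = mask_small_cells(pd.DataFrame(rows), threshold=threshold,
                          marker=marker)
    masked_cells += int((t2 == marker).sum().sum())
    p = outdir / "table2.csv"
    t2.to_csv(p, index=False, lineterminator="\n")
    written.append(p)

    t3 = pd.DataFrame(
        [{"label": e.label,
          "annual_incidence_pct": round_half_up(100.0 * e.slope, 2)}
         for e in per_stratum]
    )
    p = outdir / "table3.csv"
    t3.to_csv(p, index=False, lineterminator="\n")
    written.append(p)

    estimates = []
    for e in (*per_stratum, pooled, model):
        estimates.append(
            {"label": e.label, "slope": e.slope, "se": e.se,
             "ci_low": e.ci_low, "ci_high": e.ci_high}
        )
    p = outdir / "estimates.json"
    p.write_text(json.dumps(estimates, indent=2) + "\n")
    written.append(p)

    log = dict(run_log or {})
    log["masked_cells"] = masked_cells
    p = outdir / "run_log.txt"
    with p.open("w") as fh:
        for k, v in log.items():
            fh.write(f"{k}: {v}\n")
    written.append(p)
    return written
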