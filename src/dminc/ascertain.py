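"""Claims-based case ascertainment.

Turns claim lines into per-person, per-fiscal-year indicators: a raw
type II diabetes diagnosis flag (ICD-10 E11–E14, suspected diagnoses
excluded), an ever-diagnosed status after monotone carry-forward (diabetes
is treated as incurable, so a single qualifying claim makes every later
year positive), and yearly antidiabetic-medication and insulin utilization
flags (no carry-forward: utilization can lapse).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from dminc.fiscal import StudyWindow

RECORD_TYPES = ("diagnosis", "prescription")

# Synthetic placeholder insulin product codes (price-reference group 2492).
# Insulin preparations sit outside the oral-antidiabetic prefix 396, so they
# are matched by an explicit, configurable code list.
DEFAULT_INSULIN_CODES = ("2492400A1", "2492402G1", "2492410A1")


@dataclass(frozen=True)
class CodeSet:
    """Codes defining case and utilization ascertainment.

    diagnosis_prefixes: ICD-10 category prefixes; E11–E14 match any
    subdivision (E11.9 etc.) by prefix.
    medication_prefix: first three digits of the Japanese drug price
    reference code for antidiabetic agents (396).
    insulin_codes: explicit drug codes counted as insulin.
    """

    diagnosis_prefixes: tuple[str, ...] = ("E11", "E12", "E13", "E14")
    medication_prefix: str = "396"
    insulin_codes: tuple[str, ...] = DEFAULT_INSULIN_CODES

    def __post_init__(self) -> None:
        if not self.diagnosis_prefixes or any(not p for p in self.diagnosis_prefixes):
            raise ValueError("diagnosis_prefixes must be non-empty strings")
        if not self.medication_prefix:
            raise ValueError("medication_prefix must be non-empty")


def _validate_claims(claims: pd.DataFrame) -> None:
    required = {"person_id", "fiscal_year", "record_type", "code", "suspected"}
    missing = required - set(claims.columns)
    if missing:
        raise ValueError(f"claims missing columns: {sorted(missing)}")
    bad = set(claims["record_type"].unique()) - set(RECORD_TYPES)
    if bad:
        raise ValueError(f"unknown record_type values: {sorted(bad)}")


def _flag_matrix(
    claims: pd.DataFrame,
    persons: Sequence,
    window: StudyWindow,
) -> pd.DataFrame:
    """Pivot selected claim rows into a person x fiscal-year boolean frame."""
    index = pd.Index(persons, name="person_id")
    columns = pd.Index(window.fiscal_years, name="fiscal_year")
    if not len(claims):
        return pd.DataFrame(False, index=index, columns=columns)
    hits = claims[["person_id", "fiscal_year"]].drop_duplicates().assign(v=True)
    hits["fiscal_year"] = hits["fiscal_year"].astype(int)
    piv = hits.pivot_table(
        index="person_id", columns="fiscal_year", values="v",
        aggfunc="any", fill_value=False,
    )
    return (
        piv.reindex(index=index, columns=columns, fill_value=False)
        .fillna(False)
        .astype(bool)
    )


def yearly_diagnosis_flags(
    claims: pd.DataFrame,
    persons: Sequence,
    codes: CodeSet | None = None,
    window: StudyWindow | None = None,
) -> pd.DataFrame:
    """Raw per-year diagnosis flags (before carry-forward).

    A cell is true iff the person has at least one non-suspected diagnosis
    claim in that fiscal year whose code starts with one of the diabetes
    ICD-10 prefixes. Prescription claims never set diagnosis flags. Claims
    outside the window or from persons not listed are ignored.
    """
    codes = codes or CodeSet()
    window = window or StudyWindow()
    _validate_claims(claims)
    sel = claims[
        (claims["record_type"] == "diagnosis")
        & (claims["suspected"].astype(int) == 0)
        & claims["code"].astype(str).str.startswith(tuple(codes.diagnosis_prefixes))
        & claims["fiscal_year"].astype(int).isin(window.fiscal_years)
    ]
    return _flag_matrix(sel, persons, window)


def carry_forward(raw: pd.DataFrame) -> pd.DataFrame:
    """Monotone ever-diagnosed status: cumulative OR along each row.

    Implements the irreversibility assumption: a no/yes/no pattern over
    three years becomes no/yes/yes. Idempotent.
    """
    cols = sorted(raw.columns)
    return raw[cols].astype(bool).cummax(axis=1)


def utilization_flags(
    claims: pd.DataFrame,
    persons: Sequence,
    kind: str,
    codes: CodeSet | None = None,
    window: StudyWindow | None = None,
) -> pd.DataFrame:
    """Per-year prescription utilization flags (no carry-forward).

    kind='medication': any prescription claim with the antidiabetic price-
    reference prefix that year. kind='insulin': any prescription claim whose
    code is in the configured insulin list.
    """
    codes = codes or CodeSet()
    window = window or StudyWindow()
    _validate_claims(claims)
    rx = claims[claims["record_type"] == "prescription"]
    code_str = rx["code"].astype(str)
    if kind == "medication":
        sel = rx[code_str.str.startswith(codes.medication_prefix)]
    elif kind == "insulin":
        if not codes.insulin_codes:
            raise ValueError("insulin_codes is empty; configure the code list")
        sel = rx[code_str.isin(codes.insulin_codes)]
    else:
        raise ValueError(f"kind must be 'medication' or 'insulin', got {kind!r}")
    sel = sel[sel["fiscal_year"].astype(int).isin(window.fiscal_years)]
    return _flag_matrix(sel, persons, window)


def status_long(
    dm_status: pd.DataFrame,
    med: pd.DataFrame,
    insulin: pd.DataFrame,
) -> pd.DataFrame:
    """Tidy per-person-year indicators: person_id, fiscal_year, dm_status,
    med_use, insulin_use."""
    frames = {"dm_status": dm_status, "med_use": med, "insulin_use": insulin}
    out = None
    for name, mat in frames.items():
        long = mat.stack().rename(name).reset_index()
        out = long if out is None else out.merge(long, on=["person_id", "fiscal_year"])
    return out.sort_values(["person_id", "fiscal_year"]).reset_index(drop=True)
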