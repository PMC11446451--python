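"""Cohort construction from the insured-person ledger.

The analysis cohort is fixed at baseline: persons aged >= 40 in the first
fiscal year whose enrollment is month-contiguous from the window start either
through the window end or until an in-window death. Persons who disenroll
(e.g. move away), have coverage gaps, or enter late are excluded; decedents
are retained so the denominator stays constant across fiscal years.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from dminc.fiscal import StudyWindow, fiscal_year_of, month_index

CONTINUOUS = "continuous"
DIED_DURING = "died_during"
LEFT = "left"
GAP = "gap"
LATE_ENTRY = "late_entry"

UNDER_40 = "under-40"

_BAND_EDGES = list(range(40, 96, 5))  # 40, 45, ..., 95


class DataIntegrityError(ValueError):
    """Ledger or claims rows violate structural assumptions."""


def assign_age_band(age_at_baseline: int) -> str:
    """Five-year age band for the baseline age: '40-44' .. '90-94', '95-'.

    Ages below 40 map to the sentinel 'under-40' band, which
    :func:`build_cohort` excludes. The band is frozen at baseline: a person
    aged 63 in the first fiscal year stays in '60-64' for the whole window.
    """
    age = int(age_at_baseline)
    if age < 0:
        raise ValueError(f"age_at_baseline must be non-negative, got {age}")
    if age < 40:
        return UNDER_40
    if age >= 95:
        return "95-"
    lo = 40 + 5 * ((age - 40) // 5)
    return f"{lo}-{lo + 4}"


def _spell_months(spell: Mapping) -> tuple[int, int]:
    start = month_index(str(spell["spell_start"]))
    end = month_index(str(spell["spell_end"]))
    if start > end:
        raise DataIntegrityError(
            f"spell_start after spell_end for person {spell.get('person_id')}"
        )
    return start, end


def assess_continuity(spells: Sequence[Mapping], window: StudyWindow) -> str:
    """Classify one person's enrollment spells against the study window.

    Returns one of ``continuous``, ``died_during``, ``left``, ``gap``,
    ``late_entry``. Spells must be sorted by start and non-overlapping;
    overlap raises :class:`DataIntegrityError`. Precedence: late entry is
    checked first, then internal gaps, then in-window death with contiguous
    prior coverage; otherwise full coverage is ``continuous`` and truncated
    coverage is ``left``.
    """
    if not spells:
        raise ValueError("no spells supplied")
    intervals = [_spell_months(s) for s in spells]
    for (s0, e0), (s1, _e1) in zip(intervals, intervals[1:]):
        if s1 <= e0:
            raise DataIntegrityError(
                f"overlapping spells for person {spells[0].get('person_id')}"
            )
        if s1 < s0:
            raise DataIntegrityError("spells not sorted by start")

    if intervals[0][0] > window.start_month:
        return LATE_ENTRY

    # Contiguous coverage from the window start; stop at the first hole.
    covered_until = intervals[0][1]
    end_reason = str(spells[0]["end_reason"])
    has_gap = False
    for (s, e), spell in zip(intervals[1:], spells[1:]):
        if s > covered_until + 1:
            has_gap = True
            break
        covered_until = e
        end_reason = str(spell["end_reason"])

    if has_gap:
        return GAP
    if end_reason == "death" and covered_until <= window.end_month:
        return DIED_DURING
    if covered_until >= window.end_month:
        return CONTINUOUS
    return LEFT


def build_cohort(
    ledger: pd.DataFrame, window: StudyWindow | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the continuity and age filters to the enrollment ledger.

    Parameters
    ----------
    ledger
        One row per enrollment spell with columns person_id, sex,
        age_at_baseline, spell_start, spell_end, end_reason.
    window
        Study window; defaults to FY2015–FY2019.

    Returns
    -------
    cohort, status_counts
        ``cohort`` has one row per retained person (columns person_id, sex,
        age_band, death_fy — empty string for survivors) and is sorted by
        person_id. ``status_counts`` tallies every ledger person by
        continuity status plus the count excluded for age alone.
    """
    window = window or StudyWindow()
    required = {"person_id", "sex", "age_at_baseline",
                "spell_start", "spell_end", "end_reason"}
    missing = required - set(ledger.columns)
    if missing:
        raise ValueError(f"ledger missing columns: {sorted(missing)}")

    members = []
    counts: dict[str, int] = {
        CONTINUOUS: 0, DIED_DURING: 0, LEFT: 0, GAP: 0, LATE_ENTRY: 0,
        "under_40_excluded": 0,
    }
    records = ledger.sort_values(["person_id", "spell_start"]).to_dict("records")
    from itertools import groupby as _groupby

    for person_id, grp_iter in _groupby(records, key=lambda r: r["person_id"]):
        spells = list(grp_iter)
        if (len({str(s["sex"]) for s in spells}) > 1
                or len({int(s["age_at_baseline"]) for s in spells}) > 1):
            raise DataIntegrityError(
                f"conflicting sex/age for person {person_id}"
            )
        status = assess_continuity(spells, window)
        counts[status] += 1
        if status not in (CONTINUOUS, DIED_DURING):
            continue
        band = assign_age_band(int(spells[0]["age_at_baseline"]))
        if band == UNDER_40:
            counts["under_40_excluded"] += 1
            continue
        death_fy = ""
        if status == DIED_DURING:
            death_month = str(
                [s for s in spells if str(s["end_reason"]) == "death"][-1]["spell_end"]
            )
            death_fy = str(fiscal_year_of(death_month))
        members.append(
            {"person_id": person_id, "sex": str(spells[0]["sex"]),
             "age_band": band, "death_fy": death_fy}
        )
    cohort = pd.DataFrame(
        members, columns=["person_id", "sex", "age_band", "death_fy"]
    )
    return cohort, counts


def open_population(
    ledger: pd.DataFrame, window: StudyWindow | None = None
) -> pd.DataFrame:
    """Per-fiscal-year enrolled population (the open denominator).

    A person contributes to a fiscal year if any enrollment month overlaps
    it and their baseline age is >= 40. Age bands are frozen at baseline.
    Returns columns person_id, sex, age_band, fiscal_year.
    """
    window = window or StudyWindow()
    persons = (
        ledger.groupby("person_id", sort=True)
        .agg(sex=("sex", "first"), age_at_baseline=("age_at_baseline", "first"))
        .reset_index()
    )
    persons["age_band"] = persons["age_at_baseline"].map(assign_age_band)
    persons = persons[persons["age_band"] != UNDER_40]

    spans = ledger.copy()
    spans["start_idx"] = spans["spell_start"].astype(str).map(month_index)
    spans["end_idx"] = spans["spell_end"].astype(str).map(month_index)

    rows = []
    for fy in window.fiscal_years:
        fy_start = fy * 12 + 3
        fy_end = fy_start + 11
        hit = spans[(spans["start_idx"] <= fy_end) & (spans["end_idx"] >= fy_start)]
        ids = hit["person_id"].unique()
        sub = persons[persons["person_id"].isin(ids)].copy()
        sub["fiscal_year"] = fy
        rows.append(sub[["person_id", "sex", "age_band", "fiscal_year"]])
    return pd.concat(rows, ignore_index=True)
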