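"""Synthetic insurer ledger and claims generator.

Emulates the administrative data the pipeline consumes: an enrollment ledger
covering every insured person (including the roughly 10% who never use
healthcare), and claim lines carrying ICD-10 diagnosis codes (type II
diabetes = E11–E14, occasionally flagged as suspected/rule-out) or Japanese
drug price reference codes (antidiabetic prefix 396, insulin by explicit
code). Deaths end the enrollment spell but keep the person in the baseline
cohort; disenrollment (migration) removes them from follow-up.

The onset process parameterizes the estimand directly: per not-yet-diagnosed,
alive person-year the onset hazard is ``annual_increase / (1 - expected
prevalence so far)``, so the expected year-on-year increase in the fixed
baseline cohort's ever-diagnosed proportion equals ``annual_increase``
exactly (in the absence of deaths).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from dminc.ascertain import DEFAULT_INSULIN_CODES
from dminc import refdata

_DM_CODES = ("E11", "E119", "E112", "E14", "E140", "E13")
_GENERIC_CODES = ("J069", "I10", "M545", "K297")
_MED_CODES = ("3961007F1", "3962001F1", "3969004F1")


@dataclass(frozen=True)
class Stratum:
    """One sex x age-band population stratum of the simulation."""

    sex: str
    age_band: str
    weight: float
    baseline_prevalence: float
    annual_increase: float


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic population.

    ``annual_death_prob`` may be a single probability or one per stratum.
    ``no_use_fraction`` is the probability that a person generates no claims
    at all while undiagnosed. ``claim_emission_prob`` is the probability a
    prevalent case emits a diabetes diagnosis claim in each year after onset
    (the onset year always emits); carry-forward makes downstream results
    insensitive to it.
    """

    n_persons: int = 60000
    baseline_fy: int = 2015
    n_years: int = 5
    strata: tuple[Stratum, ...] = ()
    annual_death_prob: float | tuple[float, ...] = 0.03
    annual_leave_prob: float = 0.02
    no_use_fraction: float = 0.10
    suspected_claim_rate: float = 0.01
    medication_prob_given_case: float = 0.45
    insulin_prob_given_case: float = 0.08
    claim_emission_prob: float = 1.0
    seed: int = 0

    def death_probs(self) -> np.ndarray:
        if np.isscalar(self.annual_death_prob):
            return np.full(len(self.strata), float(self.annual_death_prob))
        arr = np.asarray(self.annual_death_prob, dtype=float)
        if arr.shape != (len(self.strata),):
            raise ValueError(
                "annual_death_prob: expected a scalar or one value per stratum"
            )
        return arr

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons: must be positive")
        if self.n_years < 2:
            raise ValueError("n_years: must be >= 2")
        if not self.strata:
            raise ValueError("strata: at least one stratum required")
        wsum = sum(s.weight for s in self.strata)
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"strata: weights must sum to 1, got {wsum!r}")
        for s in self.strata:
            for name in ("baseline_prevalence", "annual_increase", "weight"):
                v = getattr(s, name)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"strata[{s.sex} {s.age_band}].{name}: "
                                     f"{v!r} outside [0, 1]")
            if s.baseline_prevalence + self.n_years * s.annual_increase > 1.0:
                raise ValueError(
                    f"strata[{s.sex} {s.age_band}]: baseline_prevalence + "
                    "n_years * annual_increase exceeds 1"
                )
        for name in ("annual_leave_prob", "no_use_fraction",
                     "suspected_claim_rate", "medication_prob_given_case",
                     "insulin_prob_given_case", "claim_emission_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: {v!r} outside [0, 1]")
        for v in np.atleast_1d(self.death_probs()):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"annual_death_prob: {v!r} outside [0, 1]")


def default_config(n_persons: int = 60000, seed: int = 0) -> SimConfig:
    """Study-condition defaults: strata calibrated to the published
    stratified cumulative counts (weights, baseline prevalence and per-
    stratum annual increase), with the remaining rates set to realistic
    municipal-insurer values."""
    x = np.arange(refdata.N_YEARS, dtype=float)
    xc = x - x.mean()
    sxx = float(np.dot(xc, xc))
    total = sum(n for _, _, n, _ in refdata.REFERENCE_CUMULATIVE_COUNTS)
    strata = []
    for sex, band, n, counts in refdata.REFERENCE_CUMULATIVE_COUNTS:
        y = np.asarray(counts, dtype=float) / n
        slope = float(np.dot(xc, y - y.mean()) / sxx)
        strata.append(
            Stratum(sex=sex, age_band=band, weight=n / total,
                    baseline_prevalence=counts[0] / n,
                    annual_increase=slope)
        )
    return SimConfig(n_persons=n_persons, strata=tuple(strata), seed=seed)


def _band_bounds(band: str) -> tuple[int, int]:
    if band.endswith("-"):
        lo = int(band[:-1])
        return lo, lo + 4
    lo, hi = band.split("-")
    return int(lo), int(hi)


def generate_population(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (ledger, claims, truth) tables.

    Deterministic for a fixed config + seed. Every person appears in the
    ledger with exactly one spell starting at the window start; deaths and
    disenrollments truncate the spell with the corresponding end reason.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    n_years = config.n_years
    fy0 = config.baseline_fy
    strata = config.strata
    death_p = config.death_probs()

    stratum_ix = rng.choice(
        len(strata), size=n, p=[s.weight for s in strata]
    )
    sexes = np.array([s.sex for s in strata])[stratum_ix]
    bands = np.array([s.age_band for s in strata])[stratum_ix]
    bounds = np.array([_band_bounds(s.age_band) for s in strata])
    lo, hi = bounds[stratum_ix, 0], bounds[stratum_ix, 1]
    ages = lo + (rng.random(n) * (hi - lo + 1)).astype(int)

    bp = np.array([s.baseline_prevalence for s in strata])[stratum_ix]
    ai = np.array([s.annual_increase for s in strata])[stratum_ix]

    onset_year = np.full(n, -1)  # year index within window, -1 = never
    onset_year[rng.random(n) < bp] = 0
    exit_year = np.full(n, n_years)  # first year with a death/leave event
    exit_kind = np.full(n, "", dtype=object)  # "death" | "leave"
    exit_month = np.zeros(n, dtype=int)  # FY month 1..12 of the event year
    no_use = rng.random(n) < config.no_use_fraction

    for y in range(n_years):
        at_risk = exit_year == n_years
        dies = at_risk & (rng.random(n) < death_p[stratum_ix])
        leaves = at_risk & ~dies & (rng.random(n) < config.annual_leave_prob)
        for mask, kind in ((dies, "death"), (leaves, "leave")):
            exit_year[mask] = y
            exit_kind[mask] = kind
            exit_month[mask] = rng.integers(1, 13, size=int(mask.sum()))
        if y >= 1:
            expected_prev = bp + (y - 1) * ai
            hazard = np.divide(
                ai, 1.0 - expected_prev,
                out=np.zeros_like(ai), where=expected_prev < 1.0,
            )
            eligible = (onset_year == -1) & (exit_year >= y)
            newly = eligible & (rng.random(n) < hazard)
            onset_year[newly] = y

    # --- ledger -----------------------------------------------------------
    start = f"{fy0}-04"
    default_end = f"{fy0 + n_years}-03"
    ends = np.full(n, default_end, dtype=object)
    reasons = np.full(n, "study_end", dtype=object)
    has_event = exit_year < n_years
    for i in np.flatnonzero(has_event):
        fy = fy0 + exit_year[i]
        m = exit_month[i]  # FY month 1..12 -> calendar Apr..Mar
        cal_year = fy if m <= 9 else fy + 1
        cal_month = m + 3 if m <= 9 else m - 9
        ends[i] = f"{cal_year}-{cal_month:02d}"
        reasons[i] = "death" if exit_kind[i] == "death" else "disenrollment"
    person_ids = np.array([f"P{i:06d}" for i in range(n)])
    ledger = pd.DataFrame(
        {"person_id": person_ids, "sex": sexes, "age_at_baseline": ages,
         "spell_start": start, "spell_end": ends, "end_reason": reasons}
    )

    # --- claims -----------------------------------------------------------
    frames = []

    def emit(mask: np.ndarray, fy: int, record_type: str,
             code_pool: tuple[str, ...], suspected: int) -> None:
        ix = np.flatnonzero(mask)
        if not ix.size:
            return
        codes = np.asarray(code_pool)[rng.integers(0, len(code_pool), ix.size)]
        frames.append(pd.DataFrame(
            {"person_id": person_ids[ix], "fiscal_year": fy,
             "record_type": record_type, "code": codes,
             "suspected": suspected}
        ))

    for y in range(n_years):
        fy = fy0 + y
        present = exit_year >= y  # enrolled for at least part of FY y
        case = (onset_year != -1) & (onset_year <= y)
        new_case = onset_year == y
        emits_dx = present & (
            new_case
            | (case & (rng.random(n) < config.claim_emission_prob))
        )
        emit(emits_dx, fy, "diagnosis", _DM_CODES, 0)
        emit(present & case & (rng.random(n) < config.medication_prob_given_case),
             fy, "prescription", _MED_CODES, 0)
        emit(present & case & (rng.random(n) < config.insulin_prob_given_case),
             fy, "prescription", DEFAULT_INSULIN_CODES, 0)
        undiagnosed_user = present & ~case & ~no_use
        emit(undiagnosed_user & (rng.random(n) < config.suspected_claim_rate),
             fy, "diagnosis", ("E11", "E119"), 1)
        emit(undiagnosed_user, fy, "diagnosis", _GENERIC_CODES, 0)

    if frames:
        claims = pd.concat(frames, ignore_index=True)
        claims = claims.sort_values(
            ["person_id", "fiscal_year", "record_type", "code", "suspected"],
            kind="mergesort",
        ).reset_index(drop=True)
    else:
        claims = pd.DataFrame(
            columns=["person_id", "fiscal_year", "record_type", "code",
                     "suspected"]
        )

    # --- truth ------------------------------------------------------------
    truth = pd.DataFrame(
        {"person_id": person_ids, "sex": sexes, "age_band": bands,
         "onset_fy": np.where(onset_year >= 0,
                              (fy0 + np.maximum(onset_year, 0)).astype(str), ""),
         "death_fy": np.where(exit_kind == "death",
                              (fy0 + np.minimum(exit_year, n_years - 1)).astype(str), ""),
         "leave_fy": np.where(exit_kind == "leave",
                              (fy0 + np.minimum(exit_year, n_years - 1)).astype(str), "")}
    )
    return ledger, claims, truth


def write_tables(
    outdir: str | Path,
    ledger: pd.DataFrame,
    claims: pd.DataFrame,
    truth: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the simulated tables as CSV with stable byte layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (("ledger", ledger), ("claims", claims), ("truth", truth)):
        if df is None:
            continue
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Hand-built fixtures


def _fixture_persons() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Six-person ledger/claims pair exercising every cohort edge case:
    intermittent coding (diagnosis claim in one mid-window year only), a
    mover, a coverage gap, an in-window death, suspected-only claims, and a
    person with no healthcare use."""
    ledger = pd.DataFrame(
        [
            ("P1", "M", 63, "2015-04", "2020-03", "study_end"),
            ("P2", "F", 50, "2015-04", "2017-09", "disenrollment"),
            ("P3", "M", 71, "2015-04", "2016-03", "disenrollment"),
            ("P3", "M", 71, "2016-06", "2020-03", "study_end"),
            ("P4", "F", 82, "2015-04", "2017-09", "death"),
            ("P5", "M", 45, "2015-04", "2020-03", "study_end"),
            ("P6", "F", 67, "2015-04", "2020-03", "study_end"),
        ],
        columns=["person_id", "sex", "age_at_baseline", "spell_start",
                 "spell_end", "end_reason"],
    )
    claims = pd.DataFrame(
        [
            # P1: one diabetes claim in FY2016 only -> no, yes, yes, yes, yes
            ("P1", 2015, "diagnosis", "J069", 0),
            ("P1", 2016, "diagnosis", "E119", 0),
            ("P1", 2018, "diagnosis", "I10", 0),
            # P2 (mover): diabetes claims but excluded by continuity
            ("P2", 2015, "diagnosis", "E11", 0),
            ("P2", 2016, "prescription", "3961007F1", 0),
            # P3 (gap): a claim either side of the gap
            ("P3", 2015, "diagnosis", "E14", 0),
            ("P3", 2017, "diagnosis", "E14", 0),
            # P4 (decedent): diagnosed at baseline, on medication, then dies
            ("P4", 2015, "diagnosis", "E11", 0),
            ("P4", 2015, "prescription", "3962001F1", 0),
            ("P4", 2016, "prescription", "3962001F1", 0),
            ("P4", 2017, "prescription", "2492400A1", 0),
            # P5: suspected-only diabetes claims -> never a case
            ("P5", 2015, "diagnosis", "E11", 1),
            ("P5", 2017, "diagnosis", "E119", 1),
            ("P5", 2016, "diagnosis", "E10", 0),  # type I: not a case
            # P6: no claims at all
        ],
        columns=["person_id", "fiscal_year", "record_type", "code",
                 "suspected"],
    )
    return ledger, claims


def write_fixture_suite(outdir: str | Path) -> list[dict]:
    """Write the hand-built test fixtures; returns a file manifest.

    Files: fixture_ledger.csv / fixture_claims.csv (the 6-person edge-case
    pair) and reference_counts.csv (the published stratified cumulative
    counts in long form, the aggregate-ingest input).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ledger, claims = _fixture_persons()
    ref = refdata.reference_counts_frame()
    manifest = []
    for name, df, desc in (
        ("fixture_ledger.csv", ledger,
         "6-person ledger: full coverage, mover, gap, death, suspected-only, no-use"),
        ("fixture_claims.csv", claims,
         "claims for the 6-person fixture"),
        ("reference_counts.csv", ref,
         "published stratified cumulative case counts (fixed denominators)"),
    ):
        path = outdir / name
        df.to_csv(path, index=False, lineterminator="\n")
        manifest.append({"file": str(path), "description": desc})
    return manifest
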