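"""Prevalence tables and incidence estimation.

Two denominators are deliberately distinct. Per-fiscal-year prevalence and
utilization tables use the open population enrolled in each year. Cumulative
("up to FY") prevalence uses the fixed baseline cohort: the denominator is
the stratum's first-year count in every later year, and decedents retain
their last disease status. Under carry-forward ascertainment the cumulative
series is non-decreasing, and its year-on-year increase is the annual
incidence; the estimator is the ordinary least-squares slope of cumulative
prevalence against year index. Strata are pooled either by summing counts
over summed fixed denominators, or by a denominator-weighted linear model
(WLS, identity link) with age-band, sex and their interaction as covariates
and a single shared year coefficient — for a balanced stratum-year table the
two pooled estimates coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class PrevalenceSeries:
    """Fixed-denominator cumulative case counts for one stratum.

    ``n`` is the stratum's baseline (first fiscal year) cohort size, used as
    the denominator for every year. ``counts`` are cumulative ever-diagnosed
    counts, ordered by fiscal year.
    """

    sex: str
    age_band: str
    n: int
    counts: tuple[int, ...]

    @property
    def proportions(self) -> tuple[float, ...]:
        return tuple(c / self.n for c in self.counts)

    @property
    def label(self) -> str:
        return f"{self.sex} {self.age_band}"


@dataclass(frozen=True)
class IncidenceEstimate:
    """An annual incidence: a slope on the proportion-per-year scale."""

    label: str
    slope: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.slope <= self.ci_high):
                raise ValueError("CI must bracket the point estimate")


def incidence_slope(series: PrevalenceSeries) -> IncidenceEstimate:
    """OLS slope of cumulative prevalence against year index 0..k-1.

    slope = sum((x - xbar) * (y - ybar)) / sum((x - xbar)^2); invariant to
    any affine recoding of the year axis.
    """
    y = np.asarray(series.proportions, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two fiscal years to estimate a slope")
    x = np.arange(y.size, dtype=float)
    xc = x - x.mean()
    slope = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    return IncidenceEstimate(label=series.label, slope=slope)


def cumulative_prevalence_series(
    status: pd.DataFrame,
    cohort: pd.DataFrame,
    include_overall: bool = True,
) -> list[PrevalenceSeries]:
    """Per-stratum fixed-denominator cumulative case series.

    ``status`` is the carried-forward person x fiscal-year boolean matrix,
    ``cohort`` the fixed cohort (person_id, sex, age_band). Every cohort
    member must have a status row; the cohort defines both numerator
    membership and the constant denominator (decedents included). The
    optional trailing 'overall' series sums counts and denominators over
    all strata.
    """
    missing = set(cohort["person_id"]) - set(status.index)
    if missing:
        raise ValueError(
            f"status matrix missing {len(missing)} cohort person(s)"
        )
    status = status.loc[cohort["person_id"]]
    years = sorted(status.columns)
    merged = status[years].reset_index().merge(
        cohort[["person_id", "sex", "age_band"]], on="person_id"
    )
    out: list[PrevalenceSeries] = []
    for (sex, band), grp in merged.groupby(["sex", "age_band"], sort=True):
        counts = tuple(int(grp[fy].sum()) for fy in years)
        out.append(PrevalenceSeries(sex=sex, age_band=band, n=len(grp), counts=counts))
    if include_overall and out:
        total_n = sum(s.n for s in out)
        totals = tuple(sum(s.counts[k] for s in out) for k in range(len(years)))
        out.append(PrevalenceSeries(sex="all", age_band="all", n=total_n, counts=totals))
    return out


def pooled_slope(strata: list[PrevalenceSeries]) -> IncidenceEstimate:
    """Overall annual incidence: slope of the aggregated series.

    Counts and fixed denominators are summed across strata; because each
    stratum's denominator is constant over years, this equals the
    denominator-weighted mean of the per-stratum slopes.
    """
    strata = [s for s in strata if not (s.sex == "all" and s.age_band == "all")]
    if not strata:
        raise ValueError("no strata supplied")
    k = len(strata[0].counts)
    if any(len(s.counts) != k for s in strata):
        raise ValueError("strata have unequal series lengths")
    total_n = sum(s.n for s in strata)
    totals = tuple(sum(s.counts[i] for s in strata) for i in range(k))
    agg = PrevalenceSeries(sex="all", age_band="all", n=total_n, counts=totals)
    est = incidence_slope(agg)
    return IncidenceEstimate(label="overall", slope=est.slope)


def _stratum_year_frame(strata: list[PrevalenceSeries]) -> pd.DataFrame:
    rows = []
    for s in strata:
        if s.sex == "all" and s.age_band == "all":
            continue
        for k, c in enumerate(s.counts):
            rows.append(
                {"sex": s.sex, "age_band": s.age_band, "year_index": k,
                 "n": s.n, "cases": c, "proportion": c / s.n}
            )
    return pd.DataFrame(rows)


def fit_weighted_model(strata: list[PrevalenceSeries]) -> IncidenceEstimate:
    """Denominator-weighted linear trend model pooled over strata.

    Fits proportion ~ year_index + age_band * sex by weighted least squares
    (Gaussian error, identity link) with the fixed stratum denominator as
    weight, and returns the shared year coefficient with a Wald 95% CI from
    the model's standard error. Factor terms with a single level are dropped
    (e.g. a single-sex table).
    """
    df = _stratum_year_frame(strata)
    if df.empty:
        raise ValueError("no strata supplied")
    terms = ["year_index"]
    n_bands = df["age_band"].nunique()
    n_sex = df["sex"].nunique()
    if n_bands > 1:
        terms.append("C(age_band)")
    if n_sex > 1:
        terms.append("C(sex)")
    if n_bands > 1 and n_sex > 1:
        terms.append("C(age_band):C(sex)")
    formula = "proportion ~ " + " + ".join(terms)
    fit = smf.wls(formula, data=df, weights=df["n"]).fit()
    coef = float(fit.params["year_index"])
    se = float(fit.bse["year_index"])
    return IncidenceEstimate(
        label="model", slope=coef, se=se,
        ci_low=coef - Z_95 * se, ci_high=coef + Z_95 * se,
    )


def annual_prevalence_table(
    population: pd.DataFrame,
    raw_diagnosis: pd.DataFrame,
    medication: pd.DataFrame,
    insulin: pd.DataFrame,
) -> pd.DataFrame:
    """Per-fiscal-year prevalence/utilization over the open population.

    ``population`` has one row per person per enrolled fiscal year
    (person_id, sex, age_band, fiscal_year); the flag matrices are person x
    fiscal-year booleans. Diagnosis flags are the raw yearly flags, not the
    carried-forward status. Returns long-form rows: measure (PR/MU/IU), sex,
    age_band, fiscal_year, n, cases, proportion (NaN when n == 0).
    """
    measures = {"PR": raw_diagnosis, "MU": medication, "IU": insulin}
    rows = []
    for (sex, band, fy), grp in population.groupby(
        ["sex", "age_band", "fiscal_year"], sort=True
    ):
        ids = grp["person_id"]
        n = len(ids)
        for name, mat in measures.items():
            present = ids[ids.isin(mat.index)]
            cases = int(mat.loc[present, int(fy)].sum()) if len(present) else 0
            rows.append(
                {"measure": name, "sex": sex, "age_band": band,
                 "fiscal_year": int(fy), "n": n, "cases": cases,
                 "proportion": cases / n if n else float("nan")}
            )
    return pd.DataFrame(rows)


def series_from_aggregates(agg: pd.DataFrame) -> list[PrevalenceSeries]:
    """Build per-stratum series from a pre-aggregated counts table.

    Expects long-form columns sex, age_band, n, fiscal_year, cases with one
    row per stratum-year and a constant n within stratum (the fixed
    denominator).
    """
    required = {"sex", "age_band", "n", "fiscal_year", "cases"}
    missing = required - set(agg.columns)
    if missing:
        raise ValueError(f"aggregate table missing columns: {sorted(missing)}")
    out = []
    for (sex, band), grp in agg.groupby(["sex", "age_band"], sort=True):
        if grp["n"].nunique() != 1:
            raise ValueError(
                f"denominator not constant within stratum {sex} {band}"
            )
        grp = grp.sort_values("fiscal_year")
        out.append(
            PrevalenceSeries(
                sex=sex, age_band=band, n=int(grp["n"].iloc[0]),
                counts=tuple(int(c) for c in grp["cases"]),
            )
        )
    return out


def estimate_from_aggregates(
    agg: pd.DataFrame,
) -> tuple[list[IncidenceEstimate], IncidenceEstimate, IncidenceEstimate]:
    """Full trend estimation from a pre-aggregated stratum-year table.

    Returns (per-stratum slopes, pooled slope, weighted-model estimate).
    """
    strata = series_from_aggregates(agg)
    per_stratum = [incidence_slope(s) for s in strata]
    return per_stratum, pooled_slope(strata), fit_weighted_model(strata)
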