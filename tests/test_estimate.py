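"""Slope estimation, pooling, and the weighted trend model."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from dminc.ascertain import carry_forward, yearly_diagnosis_flags
from dminc.cohort import build_cohort
from dminc.estimate import (
    IncidenceEstimate,
    PrevalenceSeries,
    cumulative_prevalence_series,
    estimate_from_aggregates,
    fit_weighted_model,
    incidence_slope,
    pooled_slope,
    series_from_aggregates,
)
from dminc.fiscal import StudyWindow
from dminc.report import round_half_up

WINDOW = StudyWindow(2015, 5)


def oracle_slope(counts, n):
    """Exact normal-equations slope on integer counts, in Fraction
    arithmetic; independent of the implementation under test."""
    y = [Fraction(c, n) for c in counts]
    k = len(y)
    x = [Fraction(i) for i in range(k)]
    xbar = sum(x) / k
    ybar = sum(y) / k
    num = sum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    den = sum((xi - xbar) ** 2 for xi in x)
    return num / den


def series(counts, n, sex="M", band="60-64"):
    return PrevalenceSeries(sex=sex, age_band=band, n=n,
                            counts=tuple(counts))


def test_slope_on_published_stratum_counts():
    # cumulative counts (67, 86, 108, 129, 149) over n=1148 -> 1.80%/year
    est = incidence_slope(series([67, 86, 108, 129, 149], 1148))
    assert round_half_up(100 * est.slope, 2) == 1.80
    # (445, 594, 719, 823, 921) over n=2559 -> 4.62%/year
    est = incidence_slope(series([445, 594, 719, 823, 921], 2559))
    assert round_half_up(100 * est.slope, 2) == 4.62
    assert est.slope == pytest.approx(
        float(oracle_slope([445, 594, 719, 823, 921], 2559)), abs=1e-15
    )


def test_flat_series_has_zero_slope():
    assert incidence_slope(series([50, 50, 50, 50], 200)).slope == 0.0


def test_exactly_linear_series_recovers_increment():
    # proportions (0, c, 2c, 3c, 4c) with c = 7/350
    est = incidence_slope(series([0, 7, 14, 21, 28], 350))
    assert est.slope == pytest.approx(7 / 350, abs=1e-15)


def test_slope_invariant_to_affine_year_recoding():
    counts, n = [67, 86, 108, 129, 149], 1148
    y = np.array(counts) / n
    for x in (np.arange(5), np.arange(2015, 2020), 2 * np.arange(5) + 7):
        xc = x - x.mean()
        recoded = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
        scale = (x[1] - x[0])
        assert recoded * scale == pytest.approx(
            incidence_slope(series(counts, n)).slope, abs=1e-12
        )


def test_too_short_series_rejected():
    with pytest.raises(ValueError):
        incidence_slope(series([5], 10))


def test_slope_agrees_with_exact_oracle_on_random_series():
    """1000 random integer-count series vs the Fraction oracle."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        k = int(rng.integers(2, 8))
        n = int(rng.integers(1, 5000))
        counts = rng.integers(0, n + 1, size=k).tolist()
        got = incidence_slope(series(counts, n)).slope
        assert got == pytest.approx(float(oracle_slope(counts, n)),
                                    abs=1e-12)


def test_pooled_slope_equals_denominator_weighted_mean():
    rng = np.random.default_rng(7)
    strata = []
    for i in range(10):
        n = int(rng.integers(100, 3000))
        counts = np.sort(rng.integers(0, n, size=5)).tolist()
        strata.append(series(counts, n, band=f"b{i}"))
    pooled = pooled_slope(strata)
    wmean = sum(s.n * incidence_slope(s).slope for s in strata) / sum(
        s.n for s in strata
    )
    assert pooled.slope == pytest.approx(wmean, abs=1e-10)


def test_pooled_slope_of_single_stratum_is_its_slope():
    s = series([67, 86, 108, 129, 149], 1148)
    assert pooled_slope([s]).slope == incidence_slope(s).slope


def test_pooled_slope_of_equal_n_strata_is_plain_mean():
    a = series([0, 10, 20, 30, 40], 1000, band="40-44")
    b = series([0, 30, 60, 90, 120], 1000, band="45-49")
    pooled = pooled_slope([a, b])
    sa = incidence_slope(a).slope
    sb = incidence_slope(b).slope
    assert pooled.slope == pytest.approx((sa + sb) / 2, abs=1e-15)


def test_weighted_model_single_stratum_equals_ols_slope():
    s = series([67, 86, 108, 129, 149], 1148)
    m = fit_weighted_model([s])
    assert m.slope == pytest.approx(incidence_slope(s).slope, abs=1e-10)


def test_weighted_model_three_to_one_weighting():
    """With n1 = 3*n2 the year coefficient is (3*slope1 + slope2)/4."""
    s1 = series([30, 60, 90, 120, 150], 3000, band="40-44")
    s2 = series([5, 25, 30, 55, 70], 1000, band="45-49")
    m = fit_weighted_model([s1, s2])
    expected = (3 * incidence_slope(s1).slope + incidence_slope(s2).slope) / 4
    assert m.slope == pytest.approx(expected, abs=1e-10)


def test_weighted_model_coefficient_equals_weighted_mean_of_slopes(
    reference_agg,
):
    strata = series_from_aggregates(reference_agg)
    m = fit_weighted_model(strata)
    total = sum(s.n for s in strata)
    wmean = sum(s.n * incidence_slope(s).slope for s in strata) / total
    assert m.slope == pytest.approx(wmean, abs=1e-10)
    assert m.ci_low < m.slope < m.ci_high


def test_weighted_model_handles_single_sex_table():
    strata = [
        series([10, 20, 30, 40, 50], 500, sex="F", band="40-44"),
        series([50, 60, 80, 90, 110], 800, sex="F", band="45-49"),
    ]
    m = fit_weighted_model(strata)
    total = sum(s.n for s in strata)
    wmean = sum(s.n * incidence_slope(s).slope for s in strata) / total
    assert m.slope == pytest.approx(wmean, abs=1e-10)


def test_cumulative_series_fixed_denominator_includes_decedent(
    fixture_ledger, fixture_claims
):
    cohort, _ = build_cohort(fixture_ledger, WINDOW)
    persons = cohort["person_id"].tolist()
    status = carry_forward(
        yearly_diagnosis_flags(fixture_claims, persons, window=WINDOW)
    )
    strata = cumulative_prevalence_series(status, cohort)
    overall = strata[-1]
    assert (overall.sex, overall.age_band) == ("all", "all")
    # denominator stays 4 (P1, P4, P5, P6) in every year; P4 dies in FY2017
    assert overall.n == 4
    # P4 diagnosed FY2015; P1 from FY2016; P4's status persists after death
    assert overall.counts == (1, 2, 2, 2, 2)
    # monotone
    assert all(a <= b for a, b in zip(overall.counts, overall.counts[1:]))


def test_status_rows_must_cover_cohort(fixture_ledger, fixture_claims):
    cohort, _ = build_cohort(fixture_ledger, WINDOW)
    status = carry_forward(
        yearly_diagnosis_flags(fixture_claims, ["P1"], window=WINDOW)
    )
    with pytest.raises(ValueError, match="missing"):
        cumulative_prevalence_series(status, cohort)


def test_cumulative_series_monotone_on_synthetic_data():
    import dataclasses

    from dminc.synth import default_config, generate_population

    cfg = dataclasses.replace(default_config(n_persons=4000, seed=9),
                              claim_emission_prob=0.6)
    ledger, claims, _ = generate_population(cfg)
    cohort, _ = build_cohort(ledger, WINDOW)
    status = carry_forward(
        yearly_diagnosis_flags(claims, cohort["person_id"].tolist(),
                               window=WINDOW)
    )
    for s in cumulative_prevalence_series(status, cohort):
        assert all(a <= b for a, b in zip(s.counts, s.counts[1:]))


def test_estimate_from_aggregates_reproduces_published_trend(reference_agg):
    per_stratum, pooled, model = estimate_from_aggregates(reference_agg)
    assert len(per_stratum) == 24
    assert round_half_up(100 * pooled.slope, 2) == 3.03
    assert round_half_up(100 * model.slope, 2) == 3.03


def test_aggregate_table_with_varying_denominator_rejected(reference_agg):
    bad = reference_agg.copy()
    bad.loc[0, "n"] = 999
    with pytest.raises(ValueError, match="denominator"):
        series_from_aggregates(bad)


def test_ci_must_bracket_point_estimate():
    with pytest.raises(ValueError):
        IncidenceEstimate(label="x", slope=0.05, se=0.01,
                          ci_low=0.06, ci_high=0.07)
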