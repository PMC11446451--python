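"""Reference stratified cumulative case counts.

Published five-year cumulative type II diabetes case counts from a Japanese
municipal insurance claims cohort (FY2015–FY2019), by sex and five-year
FY2015 age band. Each row carries the fixed FY2015 denominator ``n`` and the
cumulative ever-diagnosed counts for FY2015 through FY2019. These aggregates
are the canonical input for the trend-estimation stage when person-level data
are unavailable, and they calibrate the synthetic generator's defaults.
"""

from __future__ import annotations

import pandas as pd

AGE_BANDS = (
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69",
    "70-74", "75-79", "80-84", "85-89", "90-94", "95-",
)

# (sex, age_band, n, counts FY2015..FY2019)
REFERENCE_CUMULATIVE_COUNTS: tuple[tuple, ...] = (
    ("M", "40-44", 1148, (67, 86, 108, 129, 149)),
    ("M", "45-49", 1303, (120, 150, 178, 202, 236)),
    ("M", "50-54", 1188, (160, 207, 247, 278, 307)),
    ("M", "55-59", 1468, (242, 292, 336, 372, 412)),
    ("M", "60-64", 2559, (445, 594, 719, 823, 921)),
    ("M", "65-69", 4781, (1424, 1629, 1830, 1986, 2135)),
    ("M", "70-74", 2754, (1023, 1136, 1239, 1330, 1391)),
    ("M", "75-79", 4528, (1754, 1959, 2136, 2282, 2402)),
    ("M", "80-84", 3684, (1428, 1576, 1681, 1794, 1877)),
    ("M", "85-89", 2180, (752, 840, 903, 952, 1000)),
    ("M", "90-94", 824, (254, 293, 309, 324, 330)),
    ("M", "95-", 174, (41, 51, 51, 53, 55)),
    ("F", "40-44", 911, (29, 42, 54, 66, 72)),
    ("F", "45-49", 1008, (60, 86, 102, 121, 135)),
    ("F", "50-54", 1175, (86, 115, 130, 147, 164)),
    ("F", "55-59", 1604, (185, 237, 275, 307, 345)),
    ("F", "60-64", 3250, (406, 537, 656, 747, 846)),
    ("F", "65-69", 5829, (1297, 1539, 1741, 1906, 2044)),
    ("F", "70-74", 3344, (948, 1068, 1183, 1275, 1366)),
    ("F", "75-79", 5977, (1735, 1970, 2197, 2378, 2549)),
    ("F", "80-84", 5738, (1577, 1796, 1970, 2112, 2259)),
    ("F", "85-89", 4142, (1058, 1170, 1292, 1393, 1494)),
    ("F", "90-94", 2189, (463, 523, 587, 615, 648)),
    ("F", "95-", 859, (118, 135, 152, 159, 166)),
)

FIRST_FY = 2015
N_YEARS = 5


def reference_counts_frame() -> pd.DataFrame:
    """Reference aggregates in long form.

    Columns: sex, age_band, n (fixed FY2015 denominator), fiscal_year,
    cases (cumulative ever-diagnosed count).
    """
    records = []
    for sex, band, n, counts in REFERENCE_CUMULATIVE_COUNTS:
        for k, c in enumerate(counts):
            records.append(
                {"sex": sex, "age_band": band, "n": n,
                 "fiscal_year": FIRST_FY + k, "cases": c}
            )
    return pd.DataFrame.from_records(records)
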