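"""Japanese fiscal-year calendar helpers.

A fiscal year (FY) runs April through March: FY2015 is April 2015 to
March 2020's predecessor, i.e. 2015-04 .. 2016-03. Enrollment spells are
month-resolved ("YYYY-MM" strings); claims carry only the FY label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_YM = re.compile(r"^(\d{4})-(\d{2})$")


def month_index(ym: str) -> int:
    """Absolute month counter for a 'YYYY-MM' string (Jan of year 0 == 0)."""
    m = _YM.match(ym)
    if not m:
        raise ValueError(f"expected 'YYYY-MM', got {ym!r}")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range in {ym!r}")
    return year * 12 + (month - 1)


def ym_string(idx: int) -> str:
    """Inverse of :func:`month_index`."""
    return f"{idx // 12:04d}-{idx % 12 + 1:02d}"


def fiscal_year_of(ym: str) -> int:
    """FY label of a calendar month: Jan–Mar belong to the previous FY."""
    idx = month_index(ym)
    year, month = idx // 12, idx % 12 + 1
    return year if month >= 4 else year - 1


def fy_start_index(fy: int) -> int:
    """Month index of April of the given fiscal year."""
    return fy * 12 + 3


@dataclass(frozen=True)
class StudyWindow:
    """Observation window: ``n_years`` fiscal years starting at ``first_fy``.

    The default is the five fiscal years FY2015–FY2019, i.e. April 2015
    through March 2020.
    """

    first_fy: int = 2015
    n_years: int = 5

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")

    @property
    def fiscal_years(self) -> list[int]:
        return list(range(self.first_fy, self.first_fy + self.n_years))

    @property
    def last_fy(self) -> int:
        return self.first_fy + self.n_years - 1

    @property
    def start_month(self) -> int:
        """Month index of the first covered month (April of first_fy)."""
        return fy_start_index(self.first_fy)

    @property
    def end_month(self) -> int:
        """Month index of the last covered month (March after last_fy)."""
        return fy_start_index(self.first_fy + self.n_years) - 1
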