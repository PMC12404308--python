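"""Derivation of oral-health outcomes and ordered SES variables.

The five analysis outcomes are self-reported indicators recommended for
oral-health inequality monitoring: use of toothbrush/toothpaste/floss,
functional dentition (20+ natural teeth, from per-arch missing-teeth
counts), ever having visited a dentist, a dental visit in the previous
year, and — among last-year visitors only — whether the most recent
visit was for prevention (cleaning, prevention, or revision).

SES dimensions are schooling in six ordered levels and per-capita family
income in five minimum-wage bands.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SCHOOLING_LEVELS",
    "INCOME_BAND_LABELS",
    "derive_functional_dentition",
    "derive_preventive_use",
    "categorize_income",
    "order_schooling",
]

log = logging.getLogger(__name__)

MAX_TEETH_PER_ARCH = 16  # self-report maximum; 32-tooth reference dentition
FUNCTIONAL_MIN_TEETH = 20  # functional dentition threshold

#: Ascending schooling levels (Brazilian classification), rank 1..6.
SCHOOLING_LEVELS: tuple[str, ...] = (
    "no schooling",
    "incomplete primary school",
    "complete primary school",
    "incomplete high school",
    "complete high school",
    "higher education (incomplete or higher)",
)

#: Per-capita income band labels in minimum-wage multiples, rank 1..5.
INCOME_BAND_LABELS: tuple[str, ...] = (
    "up to 1",
    "> 1-2",
    "> 2-3",
    "> 3-5",
    "> 5",
)
_INCOME_CUTS = (1.0, 2.0, 3.0, 5.0)


def derive_functional_dentition(missing_upper, missing_lower):
    """1 if 20+ teeth remain out of a 32-tooth reference dentition.

    With at most 16 missing per arch, functional dentition holds iff the
    total number of missing teeth is <= 12. Accepts scalars or arrays;
    out-of-range counts raise. Monotone non-increasing in each argument.
    """
    up = np.asarray(missing_upper, dtype=float)
    lo = np.asarray(missing_lower, dtype=float)
    for name, arr in (("missing_upper", up), ("missing_lower", lo)):
        valid = (arr >= 0) & (arr <= MAX_TEETH_PER_ARCH)
        if not np.all(valid | np.isnan(arr)):
            bad = np.asarray(arr)[~(valid | np.isnan(arr))]
            raise ValueError(
                f"{name} must be within 0..{MAX_TEETH_PER_ARCH}; "
                f"got {bad.ravel()[:5].tolist()}"
            )
    teeth = 32 - up - lo
    out = np.where(np.isnan(teeth), np.nan, (teeth >= FUNCTIONAL_MIN_TEETH))
    if out.ndim == 0:
        return float(out) if np.isnan(out) else int(out)
    return out


def derive_preventive_use(
    visit_last_year, last_visit_reason, prevention_codes: Iterable = ("prevention",)
):
    """Preventive-care use among last-year dental visitors.

    Respondents without a visit in the previous year are outside the
    denominator and get ``NA`` (excluded, not counted as 0). Visitors
    get 1 iff their last-visit reason is one of ``prevention_codes`` —
    both survey editions' wordings of the cleaning/prevention/revision
    answer should be mapped to the same code in the variable map, so
    the indicator is comparable across editions. A visitor with a
    missing reason yields a missing outcome.
    """
    visited = pd.Series(visit_last_year).map(
        {True: True, False: False, "yes": True, "no": False, 1: True, 0: False}
    )
    if visited.isna().any():
        bad = pd.Series(visit_last_year)[visited.isna()]
        raise ValueError(
            f"visit_last_year must be yes/no; got {bad.unique()[:5].tolist()}"
        )
    reason = pd.Series(last_visit_reason, index=visited.index)
    out = pd.Series(pd.NA, index=visited.index, dtype="Float64")
    codes = set(prevention_codes)
    mask = visited & reason.notna()
    out[mask] = reason[mask].isin(codes).astype(float)
    # visited with missing reason stays NA (missing outcome);
    # not visited stays NA (not applicable — outside the denominator)
    if np.isscalar(visit_last_year) or visit_last_year is None:
        v = out.iloc[0]
        return None if pd.isna(v) else int(v)
    return out


def categorize_income(per_capita_income):
    """Ordered income band 1..5 from minimum-wage multiples.

    Band boundaries follow the printed labels: [0, 1], (1, 2], (2, 3],
    (3, 5], (5, inf) — "up to 1" includes exactly 1.0 minimum wage. The
    bands partition [0, inf); negative income raises.
    """
    x = np.asarray(per_capita_income, dtype=float)
    if np.any(x < 0):
        raise ValueError(
            f"income must be >= 0; got {x[np.asarray(x) < 0].ravel()[:5].tolist()}"
        )
    band = np.searchsorted(_INCOME_CUTS, x, side="left") + 1
    band = np.where(np.isnan(x), np.nan, band)
    if band.ndim == 0:
        return float(band) if np.isnan(band) else int(band)
    return band


# alternative printed wordings of the same six levels
_SCHOOLING_ALIASES = {
    "no formal education": "no schooling",
    "incomplete primary school education": "incomplete primary school",
    "complete primary school education": "complete primary school",
    "incomplete high school education": "incomplete high school",
    "complete high school education": "complete high school",
    "higher education": "higher education (incomplete or higher)",
}


def order_schooling(level) -> int:
    """Rank 1..6 of a schooling label, ascending educational attainment."""
    key = str(level).strip().lower()
    key = _SCHOOLING_ALIASES.get(key, key)
    try:
        return SCHOOLING_LEVELS.index(key) + 1
    except ValueError:
        raise ValueError(
            f"unknown schooling label {level!r}; expected one of "
            f"{list(SCHOOLING_LEVELS)}"
        ) from None
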