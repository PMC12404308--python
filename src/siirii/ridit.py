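"""Ridit scoring of ordered socioeconomic categories.

The Ridit score of an ordered category is the midpoint of the cumulative
population share up to and including it: with shares f_1..f_K (lowest
socioeconomic position first) and F_k the cumulative sum,

    s_k = F_{k-1} + f_k / 2,

which ranks individuals from 0 to 1 by ascending socioeconomic position.
Weighted shares from the survey itself are used, so the scores reflect
the population distribution of each survey edition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dataset import SurveyDataset

__all__ = ["RiditTable", "ridit_midpoints", "ridit_scores", "attach_ridit"]

log = logging.getLogger(__name__)


def ridit_midpoints(shares: Sequence[float]) -> np.ndarray:
    """Midpoint-of-cumulative-distribution scores for ordered shares.

    ``shares`` must be positive and sum to 1; no renormalization or
    category dropping is applied here (see :func:`ridit_scores` for the
    tolerant front end).
    """
    f = np.asarray(shares, dtype=float)
    return np.cumsum(f) - f / 2


@dataclass(frozen=True)
class RiditTable:
    """Per-category Ridit scores for one dimension (and optionally year)."""

    dimension: str
    year: str | None
    categories: tuple
    scores: tuple[float, ...]
    source_proportions: tuple[float, ...]

    def as_mapping(self) -> dict:
        return dict(zip(self.categories, self.scores))


def ridit_scores(
    weighted_shares: Sequence[float] | Mapping,
    dimension: str = "ses",
    year: str | None = None,
    tol: float = 1e-6,
) -> RiditTable:
    """Score ordered categories by the midpoint of the cumulative share.

    ``weighted_shares`` is either an ordered sequence of shares (lowest
    category first) or a mapping from category label to share, taken in
    mapping order. Shares must be non-negative and sum to 1 within
    ``tol`` (renormalized with a log message if slightly off);
    zero-mass categories are dropped with a warning, negative shares
    are a hard error.
    """
    if isinstance(weighted_shares, Mapping):
        categories = tuple(weighted_shares.keys())
        f = np.asarray(list(weighted_shares.values()), dtype=float)
    else:
        f = np.asarray(weighted_shares, dtype=float)
        categories = tuple(range(1, len(f) + 1))
    if (f < 0).any():
        raise ValueError(f"negative share in {dimension!r}: {f.tolist()}")
    keep = f > 0
    if not keep.all():
        dropped = [c for c, k in zip(categories, keep) if not k]
        log.warning(
            "dropping zero-mass categories of %r before Ridit scoring: %s",
            dimension,
            dropped,
        )
        categories = tuple(c for c, k in zip(categories, keep) if k)
        f = f[keep]
    if len(f) == 0:
        raise ValueError(f"no categories with positive mass in {dimension!r}")
    total = f.sum()
    if abs(total - 1.0) > tol:
        raise ValueError(
            f"shares of {dimension!r} sum to {total:.8f}, not 1 (tol {tol:g})"
        )
    if total != 1.0:
        log.info("renormalizing shares of %r (sum %.10f)", dimension, total)
        f = f / total
    s = ridit_midpoints(f)
    return RiditTable(
        dimension=dimension,
        year=year,
        categories=categories,
        scores=tuple(s.tolist()),
        source_proportions=tuple(f.tolist()),
    )


def attach_ridit(
    data: SurveyDataset,
    dimension: str,
    per_year: bool = True,
    column: str | None = None,
) -> tuple[str, list[RiditTable]]:
    """Add a Ridit-score column for ``dimension`` to the dataset in place.

    Scores come from the survey-weighted category shares — computed
    separately within each survey year by default (each edition's
    population distribution defines its own 0-1 ranking), or pooled
    across years with ``per_year=False``.

    Returns the new column name (default ``"ridit_<dimension>"``) and
    the :class:`RiditTable` objects used.
    """
    df = data.df
    if dimension not in df.columns:
        raise KeyError(f"dimension column {dimension!r} not in dataset")
    column = column or f"ridit_{dimension}"
    w = data.weights
    tables: list[RiditTable] = []
    out = np.full(len(df), np.nan)
    groups = (
        df.groupby(data.design.year, observed=True).groups
        if per_year
        else {None: df.index}
    )
    for year, idx in groups.items():
        shares = (
            w.loc[idx].groupby(df.loc[idx, dimension], observed=True).sum()
        )
        shares = shares.sort_index() / shares.sum()
        table = ridit_scores(
            shares.to_dict(),
            dimension=dimension,
            year=None if year is None else str(year),
        )
        tables.append(table)
        out[df.index.get_indexer(idx)] = (
            df.loc[idx, dimension].map(table.as_mapping()).to_numpy(float)
        )
    df[column] = out
    return column, tables
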