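"""Design-based estimation for stratified multistage samples.

Weighted prevalences are Horvitz-Thompson ratio estimates with standard
errors by Taylor linearization, treating the primary sampling unit (PSU)
as the ultimate cluster within its stratum. Confidence intervals are
computed on the logit scale and back-transformed, keeping bounds inside
[0, 1] even for prevalences near the boundaries. Year contrasts use a
design-based Wald chi-square on the prevalence difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .dataset import SurveyDataset, SurveyDesign, ValidationError

__all__ = [
    "PrevalenceEstimate",
    "WaldTestResult",
    "read_microdata",
    "weighted_prevalence",
    "prevalence_table",
    "year_comparison_test",
    "linearized_cov",
    "linearized_variance",
]

log = logging.getLogger(__name__)

Z975 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

def read_microdata(
    path: str | Path, mapping: Mapping | None = None
) -> SurveyDataset:
    """Read delimited microdata into a validated :class:`SurveyDataset`.

    ``mapping`` (a dict, typically loaded from YAML/JSON) may contain:

    ``rename``
        file column name -> canonical column name
    ``design``
        overrides for the design column names
        (``stratum`` / ``psu`` / ``weight`` / ``year``)
    ``categories``
        column -> allowed values (list), or column -> {code: label}
        recode map; values outside it are a fatal error naming the
        offending value and rows.

    Survey-specific code lists therefore live in the mapping, never in
    code.
    """
    mapping = dict(mapping or {})
    df = pd.read_csv(path)
    if "rename" in mapping:
        df = df.rename(columns=dict(mapping["rename"]))
    for col, spec in dict(mapping.get("categories", {})).items():
        if col not in df.columns:
            raise ValidationError(f"category column {col!r} not in file")
        if isinstance(spec, Mapping):
            known = set(spec.keys())
            bad = df.loc[~df[col].isin(known) & df[col].notna(), col]
            if len(bad):
                raise ValidationError(
                    f"unknown code(s) in column {col!r}: "
                    f"{sorted(map(repr, bad.unique()))[:5]} at rows "
                    f"{list(bad.index[:5])}"
                )
            df[col] = df[col].map(dict(spec))
        else:
            bad = df.loc[~df[col].isin(list(spec)) & df[col].notna(), col]
            if len(bad):
                raise ValidationError(
                    f"value(s) outside declared categories in {col!r}: "
                    f"{sorted(map(repr, bad.unique()))[:5]} at rows "
                    f"{list(bad.index[:5])}"
                )
    design = SurveyDesign(**dict(mapping.get("design", {})))
    if design.year in df.columns:
        df[design.year] = df[design.year].astype(str)  # years are labels
    return SurveyDataset(df, design)


# ---------------------------------------------------------------------------
# linearized variance
# ---------------------------------------------------------------------------

def _collapse_singleton_strata(stratum: pd.Series, psu: pd.Series) -> pd.Series:
    """Merge strata containing a single PSU into an adjacent stratum.

    Linearized variance needs >= 2 PSUs per stratum; a lone PSU is
    collapsed into the neighbouring stratum (by sorted label) with a
    logged warning.
    """
    counts = psu.groupby(stratum, observed=True).nunique()
    singletons = counts.index[counts < 2]
    if len(singletons) == 0:
        return stratum
    order = list(counts.sort_index().index)
    remap = {}
    for s in singletons:
        i = order.index(s)
        neighbour = order[i - 1] if i > 0 else order[i + 1] if len(order) > 1 else s
        remap[s] = neighbour
    log.warning(
        "collapsing single-PSU stratum(a) into neighbours: %s", remap
    )
    collapsed = stratum.replace(remap)
    # a neighbour could itself be a singleton; recurse until stable
    if (psu.groupby(collapsed, observed=True).nunique() < 2).any() and len(
        collapsed.unique()
    ) > 1:
        return _collapse_singleton_strata(collapsed, psu)
    return collapsed


def linearized_cov(
    z: np.ndarray, stratum: pd.Series, psu: pd.Series
) -> np.ndarray:
    """Covariance of the column sums of ``z`` under with-replacement
    PSU sampling within strata.

    ``z`` is (n_rows, k) of per-row linearized contributions (zeros
    outside the domain of interest — rows from other domains still
    anchor their PSU totals at zero, which is what makes domain
    estimation correct). Per stratum h with n_h PSU total vectors t_hj:

        cov = sum_h n_h/(n_h - 1) * sum_j (t_hj - tbar_h)(t_hj - tbar_h)'
    """
    z = np.asarray(z, float)
    if z.ndim != 2:
        raise ValueError("z must be 2-d (rows x components)")
    stratum = _collapse_singleton_strata(
        pd.Series(stratum).reset_index(drop=True),
        pd.Series(psu).reset_index(drop=True),
    )
    totals = (
        pd.DataFrame(z)
        .groupby([stratum.to_numpy(), np.asarray(psu)], observed=True)
        .sum()
    )
    k = z.shape[1]
    cov = np.zeros((k, k))
    for _, t in totals.groupby(level=0, observed=True):
        n_h = len(t)
        if n_h < 2:
            continue  # an irreducible singleton stratum contributes nothing
        c = t.to_numpy() - t.to_numpy().mean(axis=0)
        cov += n_h / (n_h - 1) * (c.T @ c)
    return cov


def linearized_variance(
    z: np.ndarray, stratum: pd.Series, psu: pd.Series
) -> float:
    """Scalar case of :func:`linearized_cov`: variance of ``sum(z)``."""
    return float(linearized_cov(np.asarray(z, float)[:, None], stratum, psu)[0, 0])


# ---------------------------------------------------------------------------
# prevalence estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrevalenceEstimate:
    """Weighted prevalence of a binary outcome in one domain."""

    outcome: str
    year: object
    cell: dict = field(default_factory=dict)
    estimate: float = np.nan
    se: float = np.nan
    ci95: tuple[float, float] = (np.nan, np.nan)
    n_unweighted: int = 0
    flagged: bool = False


def _logit_ci(p: float, se: float) -> tuple[float, float]:
    if not np.isfinite(se):
        return (np.nan, np.nan)
    if p <= 0.0 or p >= 1.0 or se == 0.0:
        return (p, p)
    half = Z975 * se / (p * (1 - p))
    return (float(expit(logit(p) - half)), float(expit(logit(p) + half)))


def weighted_prevalence(
    data: SurveyDataset,
    outcome: str,
    by: str | Sequence[str] | None = None,
) -> list[PrevalenceEstimate]:
    """Horvitz-Thompson prevalence per (year x optional cell) domain.

    Rows with a missing outcome are excluded per domain (complete-case).
    The estimate is scale-invariant in the weights; the SE comes from
    Taylor linearization of the ratio Σwy/Σw with PSU-within-stratum
    clustering. Domains covered by fewer than two PSUs get ``se = nan``
    and ``flagged = True``.
    """
    d = data.design
    df = data.df
    if outcome not in df.columns:
        raise KeyError(f"outcome column {outcome!r} not in dataset")
    by_cols = [by] if isinstance(by, str) else list(by or [])
    y_all = pd.to_numeric(df[outcome], errors="coerce")
    observed = y_all.notna()
    bad = y_all.dropna()
    if not bad.isin([0, 1]).all():
        raise ValidationError(f"outcome {outcome!r} is not binary (0/1)")
    w_all = data.weights.to_numpy()
    results: list[PrevalenceEstimate] = []
    group_cols = [d.year] + by_cols
    for key, idx in df.groupby(group_cols, observed=True).groups.items():
        key = key if isinstance(key, tuple) else (key,)
        domain = df.index.isin(idx) & observed.to_numpy()
        n = int(domain.sum())
        cell = dict(zip(by_cols, key[1:]))
        if n == 0:
            results.append(
                PrevalenceEstimate(outcome, key[0], cell, flagged=True)
            )
            continue
        w = np.where(domain, w_all, 0.0)
        y = np.where(domain, y_all.fillna(0.0).to_numpy(), 0.0)
        wsum = w.sum()
        p = float((w * y).sum() / wsum)
        n_psu = df.loc[domain, d.psu].nunique()
        if n_psu < 2:
            results.append(
                PrevalenceEstimate(
                    outcome, key[0], cell, p, np.nan, (np.nan, np.nan), n, True
                )
            )
            continue
        z = w * (y - p) / wsum
        var = linearized_variance(z, df[d.stratum], df[d.psu])
        se = float(np.sqrt(var))
        results.append(
            PrevalenceEstimate(
                outcome, key[0], cell, p, se, _logit_ci(p, se), n, False
            )
        )
    return results


def prevalence_table(
    data: SurveyDataset,
    outcomes: Sequence[str],
    by: str | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tidy table of :func:`weighted_prevalence` across outcomes."""
    rows = []
    for outcome in outcomes:
        for est in weighted_prevalence(data, outcome, by=by):
            rows.append(
                {
                    "outcome": est.outcome,
                    "year": est.year,
                    **est.cell,
                    "estimate": est.estimate,
                    "se": est.se,
                    "ci_low": est.ci95[0],
                    "ci_high": est.ci95[1],
                    "n": est.n_unweighted,
                    "flagged": est.flagged,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# year comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaldTestResult:
    statistic: float
    df: int
    pvalue: float


def year_comparison_test(data: SurveyDataset, outcome: str) -> WaldTestResult:
    """Design-based Wald chi-square for a prevalence change between years.

    Requires exactly two year labels. The statistic is
    ``(p1 - p2)^2 / (se1^2 + se2^2)`` on 1 df, with linearized variances
    per year (the samples of the two editions are independent).
    """
    years = data.years
    if len(years) != 2:
        raise ValueError(
            f"year comparison needs exactly 2 years, found {len(years)}: {years}"
        )
    ests = {e.year: e for e in weighted_prevalence(data, outcome)}
    e1, e2 = ests[years[0]], ests[years[1]]
    if e1.flagged or e2.flagged:
        raise ValueError("a year has too few PSUs for a variance estimate")
    denom = e1.se**2 + e2.se**2
    if denom == 0.0:
        stat = 0.0 if e1.estimate == e2.estimate else np.inf
    else:
        stat = float((e1.estimate - e2.estimate) ** 2 / denom)
    return WaldTestResult(stat, 1, float(stats.chi2.sf(stat, 1)))
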