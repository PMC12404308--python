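"""Slope and relative indices of inequality from survey-weighted fits.

The gradient model is a log-link pseudo-likelihood ("Poisson") regression
of a binary outcome on the Ridit score of an ordered SES dimension,
adjusted for sex and age group, with a year main effect and an optional
Ridit x year interaction when two survey editions are pooled:

    log E[y] = b0 + b_r * ridit + covariates + year (+ ridit x year)

Variances are cluster-robust (sandwich) with PSUs as clusters within
strata. Predicted prevalences at the extremes of the socioeconomic
ranking are obtained by marginal standardization (g-computation):
average the model prediction at Ridit 0 and at Ridit 1 over the weighted
covariate distribution of the sample. Then, per year,

    SII = 100 * (p(ridit=1) - p(ridit=0))   [percentage points]
    RII = p(ridit=1) / p(ridit=0)

Under the log link the covariate factors cancel in the ratio, so the RII
equals exp(b_r + b_interaction[year]) exactly; the SII confidence
interval uses the delta method, the RII interval is Wald on the log
scale. A Ridit x year interaction is retained only when its Wald test is
significant; otherwise the model is refit with a single pooled gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dataset import SurveyDataset
from .ridit import attach_ridit
from .survey import Z975, linearized_cov

__all__ = [
    "SurveyGlmFit",
    "InequalityEstimate",
    "fit_inequality_model",
    "estimate_sii_rii",
    "trend_rule",
    "inequality_estimates",
    "inequality_table",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# model specification / design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _ModelSpec:
    """Fixed structure of one fit: which columns enter and their levels."""

    ridit_col: str
    covariates: tuple[str, ...]
    cov_levels: dict
    years: tuple
    with_interaction: bool

    @property
    def has_year(self) -> bool:
        return len(self.years) > 1

    def column_names(self) -> list[str]:
        names = ["const", "ridit"]
        for c in self.covariates:
            names += [f"{c}[{lev}]" for lev in self.cov_levels[c][1:]]
        if self.has_year:
            names += [f"year[{y}]" for y in self.years[1:]]
            if self.with_interaction:
                names += [f"ridit:year[{y}]" for y in self.years[1:]]
        return names

    def matrix(
        self,
        df: pd.DataFrame,
        year_col: str,
        ridit: float | None = None,
        year=None,
    ) -> pd.DataFrame:
        """Design matrix; ``ridit``/``year`` override the data columns
        (used for g-computation at the Ridit extremes)."""
        n = len(df)
        r = (
            np.full(n, float(ridit))
            if ridit is not None
            else df[self.ridit_col].to_numpy(float)
        )
        cols: dict[str, np.ndarray] = {"const": np.ones(n), "ridit": r}
        for c in self.covariates:
            vals = df[c].to_numpy()
            for lev in self.cov_levels[c][1:]:
                cols[f"{c}[{lev}]"] = (vals == lev).astype(float)
        if self.has_year:
            yvals = (
                np.full(n, year, dtype=object)
                if year is not None
                else df[year_col].to_numpy()
            )
            for y in self.years[1:]:
                ind = (yvals == y).astype(float)
                cols[f"year[{y}]"] = ind
                if self.with_interaction:
                    cols[f"ridit:year[{y}]"] = r * ind
        return pd.DataFrame(cols, index=df.index)


@dataclass(frozen=True)
class SurveyGlmFit:
    """Coefficients and cluster-robust covariance of a log-link fit."""

    outcome: str
    dimension: str
    params: pd.Series
    vcov: pd.DataFrame
    converged: bool
    n: int
    spec: _ModelSpec
    row_index: pd.Index
    n_clusters: int

    def coef(self, name: str) -> float:
        return float(self.params[name])


@dataclass(frozen=True)
class InequalityEstimate:
    """SII (percentage points) and RII (ratio) with 95% CIs for one
    outcome x dimension x year."""

    outcome: str
    dimension: str
    year: object
    sii: float
    sii_ci: tuple[float, float]
    rii: float
    rii_ci: tuple[float, float]
    interaction_retained: bool | None = None
    interaction_p: float | None = None
    warnings: tuple[str, ...] = field(default=())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_inequality_model(
    data: SurveyDataset,
    outcome: str,
    dimension: str,
    with_interaction: bool = False,
    covariates: Sequence[str] = ("sex", "age_group"),
    per_year_ridit: bool = True,
) -> SurveyGlmFit:
    """Survey-weighted log-link regression of ``outcome`` on the Ridit
    score of ``dimension`` plus covariates (and year terms when the data
    pool several editions).

    The Ridit column is attached from the weighted category shares
    (per year by default) if not already present. Rows with a missing
    outcome, covariate or SES code are dropped (complete case). The
    covariance is the sandwich estimator clustered on PSU within
    stratum.
    """
    d = data.design
    df = data.df
    ridit_col = f"ridit_{dimension}"
    if ridit_col not in df.columns:
        attach_ridit(data, dimension, per_year=per_year_ridit)
        df = data.df

    years = tuple(sorted(df[d.year].unique()))
    if with_interaction and len(years) < 2:
        raise ValueError("a ridit x year interaction needs at least two years")

    used = df[[outcome, ridit_col, *covariates]].notna().all(axis=1)
    sub = df.loc[used]
    y = pd.to_numeric(sub[outcome]).to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {outcome!r} is not binary (0/1)")
    if y.min() == y.max():
        raise ValueError(
            f"outcome {outcome!r} is constant ({y[0]:g}) in the analysis rows; "
            "the gradient model is not identifiable"
        )
    cov_levels = {c: sorted(sub[c].unique()) for c in covariates}
    spec = _ModelSpec(
        ridit_col=ridit_col,
        covariates=tuple(covariates),
        cov_levels=cov_levels,
        years=years,
        with_interaction=with_interaction,
    )
    X = spec.matrix(sub, year_col=d.year)
    w = sub[d.weight].to_numpy(float)
    model = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w)
    res = model.fit(maxiter=200, tol=1e-10)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        log.warning("log-link fit for %r on %r did not converge", outcome, dimension)

    # sandwich covariance, PSU totals within strata (Taylor linearization):
    # bread = (X' diag(w*mu) X)^-1, meat = stratified PSU-level score cov
    Xa = X.to_numpy(float)
    mu = np.exp(Xa @ res.params.to_numpy(float))
    bread = np.linalg.inv(Xa.T @ (Xa * (w * mu)[:, None]))
    scores = (w * (y - mu))[:, None] * Xa
    meat = linearized_cov(scores, sub[d.stratum], sub[d.psu])
    vcov = bread @ meat @ bread
    return SurveyGlmFit(
        outcome=outcome,
        dimension=dimension,
        params=res.params,
        vcov=pd.DataFrame(vcov, index=X.columns, columns=X.columns),
        converged=converged,
        n=len(sub),
        spec=spec,
        row_index=sub.index,
        n_clusters=int(sub.groupby([d.stratum, d.psu], observed=True).ngroups),
    )


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------

def estimate_sii_rii(
    fit: SurveyGlmFit, data: SurveyDataset, year=None
) -> InequalityEstimate:
    """SII and RII for one year from a fitted gradient model.

    Predicted prevalences at Ridit 0 and 1 are standardized over the
    weighted covariate distribution of all rows used in the fit, with
    the year fixed at ``year``. The SII CI comes from the delta method
    on the standardized difference; the RII CI is symmetric Wald on the
    log scale. Standardized predictions above 1 (a log-link artifact)
    are recorded as warnings, not errors.
    """
    if not fit.converged:
        raise ValueError("refusing to compute indices from a non-converged fit")
    spec = fit.spec
    if year is None:
        if spec.has_year:
            raise ValueError("year must be given for a multi-year fit")
        year = spec.years[0]
    elif year not in spec.years:
        raise KeyError(f"year {year!r} not among fitted years {spec.years}")

    d = data.design
    sub = data.df.loc[fit.row_index]
    w = sub[d.weight].to_numpy(float)
    wsum = w.sum()
    beta = fit.params.to_numpy(float)
    V = fit.vcov.to_numpy(float)

    X0 = spec.matrix(sub, year_col=d.year, ridit=0.0, year=year)
    X1 = spec.matrix(sub, year_col=d.year, ridit=1.0, year=year)
    mu0 = np.exp(X0.to_numpy(float) @ beta)
    mu1 = np.exp(X1.to_numpy(float) @ beta)
    warnings = []
    if (mu1 > 1).any() or (mu0 > 1).any():
        warnings.append(
            f"{int((mu0 > 1).sum() + (mu1 > 1).sum())} standardized "
            "prediction(s) exceed 1 (log-link artifact)"
        )
    p0 = float(w @ mu0 / wsum)
    p1 = float(w @ mu1 / wsum)

    sii = 100.0 * (p1 - p0)
    g = (w @ (mu1[:, None] * X1.to_numpy(float))
         - w @ (mu0[:, None] * X0.to_numpy(float))) / wsum
    sii_se = 100.0 * float(np.sqrt(g @ V @ g))
    sii_ci = (sii - Z975 * sii_se, sii + Z975 * sii_se)

    rii = p1 / p0
    c = np.zeros(len(beta))
    c[fit.params.index.get_loc("ridit")] = 1.0
    iname = f"ridit:year[{year}]"
    if spec.with_interaction and iname in fit.params.index:
        c[fit.params.index.get_loc(iname)] = 1.0
    log_rii_se = float(np.sqrt(c @ V @ c))
    rii_ci = (
        rii * np.exp(-Z975 * log_rii_se),
        rii * np.exp(Z975 * log_rii_se),
    )
    return InequalityEstimate(
        outcome=fit.outcome,
        dimension=fit.dimension,
        year=year,
        sii=sii,
        sii_ci=sii_ci,
        rii=rii,
        rii_ci=rii_ci,
        warnings=tuple(warnings),
    )


def trend_rule(
    fit_with_interaction: SurveyGlmFit, alpha: float = 0.05
) -> tuple[bool, float]:
    """Wald test of the Ridit x year interaction against zero.

    Returns ``(retained, p)``: the interaction is retained in the final
    model iff ``p < alpha`` (strict — a p exactly at alpha drops it).
    With more than two years the test is a joint Wald chi-square on all
    interaction coefficients.
    """
    fit = fit_with_interaction
    names = [n for n in fit.params.index if n.startswith("ridit:year[")]
    if not names:
        raise ValueError("fit has no ridit x year interaction term")
    idx = [fit.params.index.get_loc(n) for n in names]
    b = fit.params.to_numpy(float)[idx]
    Vbb = fit.vcov.to_numpy(float)[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(Vbb, b))
    p = float(stats.chi2.sf(stat, len(idx)))
    return (p < alpha), p


# ---------------------------------------------------------------------------
# pipeline-level convenience
# ---------------------------------------------------------------------------

def inequality_estimates(
    data: SurveyDataset,
    outcome: str,
    dimension: str,
    alpha: float = 0.05,
    covariates: Sequence[str] = ("sex", "age_group"),
    per_year_ridit: bool = True,
) -> list[InequalityEstimate]:
    """Per-year SII/RII applying the interaction-retention rule.

    A model with a Ridit x year interaction is fit first; if the
    interaction is not significant at ``alpha`` the final model is refit
    with a single pooled gradient, so the yearly indices then differ
    only through the year main effect entering the standardization.
    Single-year data skip the rule entirely.
    """
    years = data.years
    if len(years) < 2:
        fit = fit_inequality_model(
            data, outcome, dimension, False, covariates, per_year_ridit
        )
        return [estimate_sii_rii(fit, data, years[0])]
    fit_int = fit_inequality_model(
        data, outcome, dimension, True, covariates, per_year_ridit
    )
    retained, p = trend_rule(fit_int, alpha)
    fit = (
        fit_int
        if retained
        else fit_inequality_model(
            data, outcome, dimension, False, covariates, per_year_ridit
        )
    )
    return [
        replace(
            estimate_sii_rii(fit, data, year),
            interaction_retained=retained,
            interaction_p=p,
        )
        for year in years
    ]


def inequality_table(
    data: SurveyDataset,
    outcomes: Sequence[str],
    dimensions: Sequence[str],
    alpha: float = 0.05,
    covariates: Sequence[str] = ("sex", "age_group"),
    per_year_ridit: bool = True,
) -> pd.DataFrame:
    """Tidy SII/RII table across outcomes, dimensions and years."""
    rows = []
    for dim in dimensions:
        for outcome in outcomes:
            for est in inequality_estimates(
                data, outcome, dim, alpha, covariates, per_year_ridit
            ):
                rows.append(
                    {
                        "outcome": est.outcome,
                        "dimension": est.dimension,
                        "year": est.year,
                        "sii": est.sii,
                        "sii_low": est.sii_ci[0],
                        "sii_high": est.sii_ci[1],
                        "rii": est.rii,
                        "rii_low": est.rii_ci[0],
                        "rii_high": est.rii_ci[1],
                        "interaction_p": est.interaction_p,
                        "interaction_retained": est.interaction_retained,
                    }
                )
    return pd.DataFrame(rows)
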