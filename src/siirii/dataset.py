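"""Respondent-level survey container with design metadata.

A :class:`SurveyDataset` wraps a pandas DataFrame holding one row per
respondent together with the names of the complex-design columns
(stratum, primary sampling unit, sampling weight, survey year).  All
estimation routines in :mod:`siirii.survey` and :mod:`siirii.inequality`
operate on this container.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["SurveyDesign", "SurveyDataset", "ValidationError"]


class ValidationError(ValueError):
    """Raised when microdata violate a design invariant."""


@dataclass(frozen=True)
class SurveyDesign:
    """Names of the complex-survey design columns."""

    stratum: str = "stratum"
    psu: str = "psu"
    weight: str = "weight"
    year: str = "year"

    @property
    def columns(self) -> tuple[str, str, str, str]:
        return (self.stratum, self.psu, self.weight, self.year)


class SurveyDataset:
    """One row per respondent plus design metadata.

    Parameters
    ----------
    df
        Respondent-level table. Must contain the four design columns
        named by ``design`` plus any analysis columns.
    design
        Column-name mapping for stratum / PSU / weight / year.
    validate
        Check design invariants on construction (positive weights, PSU
        nesting within a single stratum, no missing design values).

    Raises
    ------
    ValidationError
        If a design column is missing or an invariant fails; messages
        cite the offending column and row numbers.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        design: SurveyDesign | None = None,
        validate: bool = True,
    ) -> None:
        self.design = design or SurveyDesign()
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        d = self.design
        missing = [c for c in d.columns if c not in self.df.columns]
        if missing:
            raise ValidationError(
                f"missing required design column(s): {', '.join(missing)}"
            )
        for col in d.columns:
            bad = self.df.index[self.df[col].isna()]
            if len(bad):
                raise ValidationError(
                    f"design column {col!r} has missing values at rows "
                    f"{_preview(bad)}"
                )
        w = pd.to_numeric(self.df[d.weight], errors="coerce")
        bad = self.df.index[~(w > 0)]
        if len(bad):
            raise ValidationError(
                f"weights must be strictly positive; offending rows {_preview(bad)}"
            )
        # each PSU id must nest within exactly one stratum
        n_strata = self.df.groupby(d.psu, observed=True)[d.stratum].nunique()
        crossing = n_strata[n_strata > 1]
        if len(crossing):
            raise ValidationError(
                "PSU id(s) appear in more than one stratum: "
                f"{list(crossing.index[:5])}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def weights(self) -> pd.Series:
        return self.df[self.design.weight].astype(float)

    @property
    def years(self) -> list:
        return sorted(self.df[self.design.year].unique())

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "SurveyDataset":
        """Row subset sharing the same design (no re-validation)."""
        return SurveyDataset(self.df.loc[mask], self.design, validate=False)

    def cluster_ids(self) -> pd.Series:
        """Stratum-qualified PSU identifiers (PSUs nest within strata)."""
        d = self.design
        return (
            self.df[d.stratum].astype(str) + "//" + self.df[d.psu].astype(str)
        )


def _preview(index, k: int = 5) -> str:
    rows = list(index[:k])
    suffix = ", ..." if len(index) > k else ""
    return f"{rows}{suffix} ({len(index)} total)"
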