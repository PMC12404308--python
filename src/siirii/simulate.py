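"""Synthetic complex-survey microdata with known socioeconomic gradients.

Emulates the design of a national household survey drawn by stratified
multistage cluster sampling: respondents nest in primary sampling units
(PSUs) within strata, carry unequal sampling weights, and report ordered
socioeconomic position (schooling in six levels, per-capita income in
five bands), sex, age group, and binary health outcomes.

Outcomes follow a log-linear gradient in the Ridit score of the chosen
socioeconomic dimension:

    log p = log p0 + beta * ridit(category)
            + sex effect + age effect + PSU effect

so the generator carries closed-form true values of the slope index of
inequality (SII) and relative index of inequality (RII) against which
the estimation pipeline can be checked.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import SurveyDataset, SurveyDesign
from .ridit import ridit_midpoints

__all__ = [
    "OutcomeSpec",
    "SimulationConfig",
    "SimulationTruth",
    "ConfigError",
    "simulate_survey",
    "write_fixture",
]

AGE_GROUPS = ("18-29", "30-59", "60+")

#: Ordered population shares typical of the adult Brazilian population:
#: six schooling levels (none ... higher education) and five per-capita
#: income bands (up to 1 ... > 5 minimum wages), lowest SES first.
DEFAULT_SES_PROPORTIONS: dict[str, tuple[float, ...]] = {
    "schooling": (0.083, 0.307, 0.099, 0.056, 0.281, 0.174),
    "income": (0.497, 0.288, 0.094, 0.064, 0.057),
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class OutcomeSpec:
    """One binary outcome and its true gradient.

    ``beta`` is the log prevalence-ratio per unit Ridit; a mapping makes
    it year-specific (a changing gradient, i.e. a real trend in
    inequality). ``p0`` is the prevalence at Ridit 0 for the reference
    covariate pattern (female, 18-29, PSU effect 0).
    """

    name: str = "outcome"
    p0: float = 0.3
    beta: float | Mapping[str, float] = math.log(2.0)
    dimension: str = "schooling"

    def beta_for(self, year: str) -> float:
        if isinstance(self.beta, Mapping):
            try:
                return float(self.beta[year])
            except KeyError:
                raise ConfigError(
                    f"outcome {self.name!r}: no beta for year {year!r}"
                ) from None
        return float(self.beta)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic survey.

    Sample size per year is ``n_strata * psus_per_stratum *
    respondents_per_psu``. Weights are log-normal with coefficient of
    variation ``weight_cv``, normalized to mean 1 within each year. The
    PSU effect is a shared normal perturbation of the log prevalence
    (sd ``psu_effect_sd``), inducing positive intra-cluster correlation.
    """

    n_strata: int = 10
    psus_per_stratum: int = 8
    respondents_per_psu: int = 25
    years: tuple[str, ...] = ("2013", "2019")
    ses_proportions: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_SES_PROPORTIONS)
    )
    outcomes: tuple[OutcomeSpec, ...] = (OutcomeSpec(),)
    sex_effect: float = -0.10
    age_effects: tuple[float, float] = (-0.10, -0.30)
    prop_male: float = 0.471
    age_proportions: tuple[float, float, float] = (0.261, 0.558, 0.181)
    psu_effect_sd: float = 0.05
    weight_cv: float = 0.5
    seed: int = 0

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if min(self.n_strata, self.psus_per_stratum, self.respondents_per_psu) < 1:
            raise ConfigError("sample-size parameters must be positive integers")
        if len(self.years) != len(set(self.years)):
            raise ConfigError("duplicate year labels")
        for dim, probs in self.ses_proportions.items():
            p = np.asarray(probs, dtype=float)
            if (p <= 0).any():
                raise ConfigError(f"ses_proportions[{dim!r}] must be positive")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    f"ses_proportions[{dim!r}] must sum to 1 "
                    f"(got {p.sum():.12f})"
                )
        if not 0 < self.prop_male < 1:
            raise ConfigError("prop_male must be in (0, 1)")
        a = np.asarray(self.age_proportions, dtype=float)
        if (a <= 0).any() or abs(a.sum() - 1.0) > 1e-9:
            raise ConfigError("age_proportions must be positive and sum to 1")
        if self.psu_effect_sd < 0 or self.weight_cv < 0:
            raise ConfigError("psu_effect_sd and weight_cv must be >= 0")
        cov_max = max(0.0, self.sex_effect) + max(0.0, *self.age_effects, 0.0)
        for spec in self.outcomes:
            if not 0 < spec.p0 < 1:
                raise ConfigError(f"outcome {spec.name!r}: p0 must be in (0, 1)")
            if spec.dimension not in self.ses_proportions:
                raise ConfigError(
                    f"outcome {spec.name!r}: unknown dimension {spec.dimension!r}"
                )
            for year in self.years:
                b = spec.beta_for(year)
                p_max = spec.p0 * math.exp(max(0.0, b) + cov_max)
                if p_max > 1.0:
                    raise ConfigError(
                        f"outcome {spec.name!r}, year {year}: implied probability "
                        f"p0*exp(beta + max covariate effects) = {p_max:.4f} > 1; "
                        "lower p0, beta or the covariate effects"
                    )

    # -- closed-form truth ------------------------------------------------
    def covariate_factor(self) -> float:
        """E[exp(sex + age effects)] over the configured population,
        times the log-normal mean factor of the PSU effect."""
        sex = (1 - self.prop_male) + self.prop_male * math.exp(self.sex_effect)
        ages = (1.0,) + tuple(math.exp(b) for b in self.age_effects)
        age = float(np.dot(self.age_proportions, ages))
        return sex * age * math.exp(self.psu_effect_sd**2 / 2)


@dataclass(frozen=True)
class SimulationTruth:
    """Closed-form population values implied by a configuration.

    ``true_rii[(outcome, year)] = exp(beta)`` — covariate and PSU
    factors cancel in the ratio under the log link.  ``true_sii`` is the
    population-averaged slope index in percentage points,
    ``100 * p0 * (exp(beta) - 1) * E[exp(covariate + PSU effects)]``;
    with all covariate/PSU effects zero this is ``100*p0*(exp(beta)-1)``.
    """

    true_sii: Mapping[tuple[str, str], float]
    true_rii: Mapping[tuple[str, str], float]

    def sii(self, outcome: str = "outcome", year: str | None = None) -> float:
        return self.true_sii[self._key(outcome, year)]

    def rii(self, outcome: str = "outcome", year: str | None = None) -> float:
        return self.true_rii[self._key(outcome, year)]

    def _key(self, outcome: str, year: str | None) -> tuple[str, str]:
        if year is None:
            years = {y for (o, y) in self.true_rii if o == outcome}
            if len(years) != 1:
                raise KeyError("year must be given when truths differ by year")
            year = next(iter(years))
        return (outcome, year)


def _truth(config: SimulationConfig) -> SimulationTruth:
    m = config.covariate_factor()
    sii: dict[tuple[str, str], float] = {}
    rii: dict[tuple[str, str], float] = {}
    for spec in config.outcomes:
        for year in config.years:
            b = spec.beta_for(year)
            rii[(spec.name, year)] = math.exp(b)
            sii[(spec.name, year)] = 100.0 * spec.p0 * (math.exp(b) - 1.0) * m
    return SimulationTruth(true_sii=sii, true_rii=rii)


def simulate_survey(
    config: SimulationConfig,
) -> tuple[SurveyDataset, SimulationTruth]:
    """Draw one synthetic survey; seed fully determines the output.

    Returns the respondent table (one row each, with stratum, PSU,
    weight, year, sex, age group, the SES codes, and one 0/1 column per
    outcome) and the closed-form truth for recovery tests.

    Raises :class:`ConfigError` if the configuration implies a
    probability above 1 for any respondent, including after the random
    PSU perturbation — out-of-range cells are an error, never clipped,
    because clipping would bias the true SII.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_year = (
        config.n_strata * config.psus_per_stratum * config.respondents_per_psu
    )
    dims = {d: np.asarray(p, float) for d, p in config.ses_proportions.items()}
    scores = {d: ridit_midpoints(p) for d, p in dims.items()}

    sigma = math.sqrt(math.log(1.0 + config.weight_cv**2))
    frames = []
    for year in config.years:
        stratum = np.repeat(
            np.arange(1, config.n_strata + 1),
            config.psus_per_stratum * config.respondents_per_psu,
        )
        psu_in_stratum = np.tile(
            np.repeat(
                np.arange(1, config.psus_per_stratum + 1),
                config.respondents_per_psu,
            ),
            config.n_strata,
        )
        psu = np.char.add(
            np.char.add(f"{year}-S", stratum.astype("U4")),
            np.char.add("-P", psu_in_stratum.astype("U4")),
        )
        if sigma > 0:
            w = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=n_year)
        else:
            w = np.ones(n_year)
        w = w / w.mean()

        male = rng.random(n_year) < config.prop_male
        age = rng.choice(3, size=n_year, p=config.age_proportions)
        cols: dict[str, np.ndarray | str] = {
            "stratum": stratum,
            "psu": psu,
            "weight": w,
            "year": year,
            "sex": np.where(male, "male", "female"),
            "age_group": np.asarray(AGE_GROUPS)[age],
        }
        ses_codes: dict[str, np.ndarray] = {}
        for dim, probs in dims.items():
            ses_codes[dim] = rng.choice(len(probs), size=n_year, p=probs)
            cols[dim] = ses_codes[dim] + 1  # ordered codes 1..K

        age_eff = np.asarray((0.0,) + tuple(config.age_effects))
        cov_lp = config.sex_effect * male + age_eff[age]
        psu_codes, psu_index = pd.factorize(psu)
        for spec in config.outcomes:
            u = rng.normal(0.0, config.psu_effect_sd, size=len(psu_index))
            s = scores[spec.dimension][ses_codes[spec.dimension]]
            logp = (
                math.log(spec.p0)
                + spec.beta_for(year) * s
                + cov_lp
                + u[psu_codes]
            )
            p = np.exp(logp)
            if (p > 1.0).any():
                raise ConfigError(
                    f"outcome {spec.name!r}, year {year}: simulated probability "
                    f"exceeds 1 (max {p.max():.4f}) after the PSU perturbation; "
                    "reduce p0, beta, covariate effects or psu_effect_sd"
                )
            cols[spec.name] = (rng.random(n_year) < p).astype(np.int64)
        frames.append(pd.DataFrame(cols))

    df = pd.concat(frames, ignore_index=True)
    data = SurveyDataset(df, SurveyDesign())
    data.meta = {  # type: ignore[attr-defined]
        "seed": config.seed,
        "n_per_year": n_year,
        "years": list(config.years),
        "outcomes": [s.name for s in config.outcomes],
        "dimensions": list(dims),
    }
    return data, _truth(config)


def write_fixture(dataset: SurveyDataset, path: str | Path) -> Path:
    """Write a dataset as a UTF-8 CSV fixture.

    Alongside ``<path>`` this emits ``<path>.meta.json`` (seed and
    provenance, when the dataset came from :func:`simulate_survey`) and
    ``<path>.dict.md`` (a data dictionary of the columns). The CSV
    round-trips losslessly through :func:`siirii.survey.read_microdata`.
    """
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    dataset.df.to_csv(path, index=False)
    meta = dict(getattr(dataset, "meta", {}))
    meta["n_rows"] = len(dataset)
    meta["columns"] = list(dataset.df.columns)
    path.with_name(path.name + ".meta.json").write_text(
        json.dumps(meta, indent=2) + "\n", encoding="utf-8"
    )
    d = dataset.design
    known = {
        d.stratum: "design stratum identifier",
        d.psu: "primary sampling unit (nested within stratum)",
        d.weight: "sampling weight (> 0, mean 1 within year)",
        d.year: "survey year label",
        "sex": "female / male",
        "age_group": "18-29 / 30-59 / 60+",
        "schooling": "ordered schooling level, 1 (none) .. 6 (higher education)",
        "income": "ordered per-capita income band, 1 (lowest) .. 5 (highest)",
    }
    lines = ["# Data dictionary", ""]
    for col in dataset.df.columns:
        lines.append(f"- `{col}`: {known.get(col, 'binary outcome (0/1)')}")
    path.with_name(path.name + ".dict.md").write_text(
        "\n".join(lines) + "\n", encoding="utf-8"
    )
    return path
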