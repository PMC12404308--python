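import math

import numpy as np
import pytest

from siirii import SimulationConfig, OutcomeSpec, simulate_survey


def make_config(**kwargs) -> SimulationConfig:
    """Small two-year survey with a known ln(2) schooling gradient."""
    defaults = dict(
        n_strata=6,
        psus_per_stratum=5,
        respondents_per_psu=30,
        outcomes=(OutcomeSpec("outcome", 0.3, math.log(2.0), "schooling"),),
        seed=11,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_survey():
    """900 respondents/year, two years, shared across read-only tests."""
    data, truth = simulate_survey(make_config())
    return data, truth


def marginal_prevalence(config: SimulationConfig, outcome: str, year: str) -> float:
    """Closed-form population prevalence implied by a configuration:
    p0 * E[exp(beta * ridit)] over SES categories, times the covariate
    and PSU log-normal factors. Independent of the estimation path."""
    from siirii.ridit import ridit_midpoints

    spec = next(o for o in config.outcomes if o.name == outcome)
    shares = np.asarray(config.ses_proportions[spec.dimension], float)
    s = ridit_midpoints(shares)
    grad = float(shares @ np.exp(spec.beta_for(year) * s))
    return spec.p0 * grad * config.covariate_factor()
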