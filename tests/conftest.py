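import numpy as np
import pandas as pd
import pytest

import epivote as ev


@pytest.fixture(scope="session")
def sim400():
    """One moderately sized simulated world shared by read-only tests."""
    cfg = ev.SimulationConfig(n_municipalities=400, n_counties=20, seed=7)
    return ev.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def prev_fit400(sim400):
    pop, _ = ev.extrapolate_population(sim400.census_population, "auto")
    fit = ev.estimate_prevalence(pop, sim400.deaths["six_week"], sim400.ifr)
    return fit


@pytest.fixture(scope="session")
def dm400(sim400, prev_fit400):
    tr = ev.transform_prevalence(prev_fit400.estimates, "decile")
    cov = sim400.covariates.drop(columns="_urbanicity")
    return ev.build_design_matrix(sim400.panel, cov, tr)


def single_stratum_tables(n, deaths_base, d2020, years=(2015, 2020)):
    """Helper: one municipality, one stratum, constant population."""
    lo, hi = years
    yrs = list(range(lo, hi + 1))
    pop = pd.DataFrame(
        {
            "municipality_id": "M0",
            "age_band": "80+",
            "sex": "F",
            "year": yrs,
            "population": n,
        }
    )
    dd = list(deaths_base) + [d2020]
    deaths = pop[["municipality_id", "age_band", "sex", "year"]].copy()
    deaths["deaths"] = dd
    return pop, deaths


def single_stratum_ifr(value):
    return pd.DataFrame({"age_band": ["80+"], "sex": ["F"], "ifr": [value]})
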