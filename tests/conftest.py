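import numpy as np
import pandas as pd
import pytest

from rsfpm.cohort import apply_period_window, winsorise_age
from rsfpm.lifetable import LifeTable
from rsfpm.simulate import SimulationParams, simulate_cohort, simulate_lifetable

PERIOD_WINDOW = (2011.0, 2014.0)


def make_flat_lifetable(rate: float) -> LifeTable:
    """Life table with one constant rate everywhere."""
    return LifeTable(np.full((2, 82, 11), rate), 18, 99, 2005, 2015)


def make_age_step_lifetable(rate_young: float, rate_old: float, cut_age: int = 65) -> LifeTable:
    """Rate depending only on attained age: below/at-or-above ``cut_age``."""
    rates = np.full((2, 82, 11), rate_young)
    rates[:, cut_age - 18 :, :] = rate_old
    return LifeTable(rates, 18, 99, 2005, 2015)


@pytest.fixture(scope="session")
def zero_lifetable() -> LifeTable:
    return make_flat_lifetable(0.0)


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated analysis: params, life table, cohort, windowed rows."""
    params = SimulationParams(n=4000, seed=7)
    lt = simulate_lifetable(params)
    cohort = simulate_cohort(params, lt)
    cohort, age_low, age_high = winsorise_age(cohort)
    rows = apply_period_window(cohort, PERIOD_WINDOW)
    return {"params": params, "lifetable": lt, "cohort": cohort,
            "rows": rows, "age_low": age_low, "age_high": age_high}


@pytest.fixture(scope="session")
def weibull_cohort(zero_lifetable):
    """Pure-Weibull excess-only cohort (no population mortality, no age effect)."""
    params = SimulationParams(n=3000, seed=21, beta_age_per10=0.0,
                              excess_shape=1.3, excess_scale=6.0)
    coh = simulate_cohort(params, zero_lifetable)
    rows = coh.assign(t0=0.0, t=coh["exit_date"] - coh["dx_date"],
                      d=(coh["status"] == "dead").astype(int),
                      age_model=coh["age_dx"])
    return params, rows


@pytest.fixture()
def tiny_rows() -> pd.DataFrame:
    """Three hand-checkable rows: deaths at 1 and 2, censoring at 3."""
    return pd.DataFrame({
        "id": [1, 2, 3],
        "sex": ["male", "male", "male"],
        "age_dx": [50.0, 80.0, 80.0],
        "dx_date": [2008.0, 2008.0, 2008.0],
        "t0": [0.0, 0.0, 0.0],
        "t": [1.0, 2.0, 3.0],
        "d": [1, 1, 0],
        "age_model": [50.0, 80.0, 80.0],
    })
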